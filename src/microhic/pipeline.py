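"""End-to-end orchestration: generate or load data, balance, and run the
trans-interaction, compartment and 3D-embedding analyses into a report
directory of plain-text tables."""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.cluster.hierarchy as sch
import yaml

from . import __version__
from . import compartment_calling as cc
from . import embedding_3d as e3
from . import synthetic_nucleus as syn
from . import trans_interaction as ti
from .contact_io import (
    balance,
    bin_genome,
    read_bedgraph_gc,
    read_chrom_sizes,
    read_contacts_triplet,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "PRESETS"]

log = logging.getLogger("microhic")

#: Named micro/macro thresholds: the avian convention (<30 Mb) and the
#: non-avian-reptile natural break (~50 Mb).
PRESETS = {"avian": 30_000_000, "reptile": 50_000_000}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of the two input modes must be active: real inputs
    (``contacts`` + ``chrom_sizes``, optional ``gc_bedgraph``) or synthetic
    generation (``synthetic = True`` with ``synthetic_params`` overrides of
    :class:`~microhic.synthetic_nucleus.NucleusParams`).
    """

    # real inputs
    contacts: str | None = None
    chrom_sizes: str | None = None
    gc_bedgraph: str | None = None
    # synthetic mode
    synthetic: bool = False
    synthetic_params: dict = field(default_factory=dict)
    # shared settings
    bin_size: int = 1_000_000
    micro_threshold_bp: int = PRESETS["avian"]
    balance_max_iter: int = 500
    balance_tol: float = 1e-5
    balance_mask_quantile: float = 0.02
    expected_null: str = "length"  # chromosome-level null: length | marginal
    linkage_method: str = "average"
    linkage_metric: str = "euclidean"
    compartment_expected: str = "chrom-pair"  # bin-level trans null
    ambiguity_threshold: float = 0.1
    mds_alpha: float = 0.5
    mds_max_iter: int = 300
    k_neighbors: int = 10
    seed: int = 1
    outdir: str = "microhic_report"
    log_level: str = "INFO"

    def validate(self) -> None:
        real = self.contacts is not None or self.chrom_sizes is not None
        if self.synthetic and real:
            raise ValueError("provide either real inputs or synthetic=true, not both")
        if not self.synthetic:
            if self.contacts is None or self.chrom_sizes is None:
                raise ValueError(
                    "real-input mode requires both 'contacts' and 'chrom_sizes'"
                )
            for label, path in [
                ("contacts", self.contacts),
                ("chrom_sizes", self.chrom_sizes),
                ("gc_bedgraph", self.gc_bedgraph),
            ]:
                if path is not None and not Path(path).exists():
                    raise ValueError(f"{label} path does not exist: {path}")
        if self.micro_threshold_bp <= 0 or self.bin_size <= 0:
            raise ValueError("bin_size and micro_threshold_bp must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _setup_logging(config: PipelineConfig, outdir: Path) -> None:
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and write the report directory; returns its path.

    On a stage failure, partial outputs are kept, a ``FAILED`` marker names
    the stage, and :class:`PipelineError` is raised.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, outdir)
    config.to_yaml(outdir / "config.yaml")
    log.info("microhic %s, seed %d", __version__, config.seed)
    stage = "load"
    try:
        truth = None
        if config.synthetic:
            stage = "simulate"
            params = syn.NucleusParams(
                **{"seed": config.seed,
                   "bin_size": config.bin_size,
                   "micro_threshold_bp": config.micro_threshold_bp,
                   **config.synthetic_params}
            )
            ds = syn.generate_dataset(params, outdir / "synthetic")
            genome, cmap, gc, truth = ds.genome, ds.cmap, ds.gc, ds.truth
            log.info("simulated %d bins, %d contact entries", genome.n_bins, cmap.n_entries)
        else:
            sizes = read_chrom_sizes(config.chrom_sizes)
            genome = bin_genome(sizes, config.bin_size, config.micro_threshold_bp)
            cmap = read_contacts_triplet(config.contacts, genome)
            gc = read_bedgraph_gc(config.gc_bedgraph, genome) if config.gc_bedgraph else None
            log.info("loaded %d bins, %d contact entries", genome.n_bins, cmap.n_entries)

        stage = "balance"
        t0 = time.time()
        cmap = balance(
            cmap,
            max_iter=config.balance_max_iter,
            tol=config.balance_tol,
            mask_quantile=config.balance_mask_quantile,
        )
        log.info(
            "balanced in %.1fs (converged=%s, %d/%d bins masked)",
            time.time() - t0, cmap.balance_converged,
            int((~cmap.bin_mask).sum()), genome.n_bins,
        )

        stage = "trans_interaction"
        ts = ti.trans_summary(
            cmap,
            null=config.expected_null,
            linkage_method=config.linkage_method,
            linkage_metric=config.linkage_metric,
        )
        ts.per_chromosome.to_csv(outdir / "per_chromosome.tsv", sep="\t", index=False, float_format="%.6f")
        ts.pairwise_table().to_csv(outdir / "pairwise_icf.tsv", sep="\t", index=False, float_format="%.6f")
        ts.stats_table().to_csv(outdir / "trans_stats.tsv", sep="\t", index=False, float_format="%.6g")
        (outdir / "chromosome_dendrogram.nwk").write_text(ts.newick() + "\n")
        if ts.density_test:
            log.info(
                "ICF density micro vs macro: t=%.3f p=%.3g",
                ts.density_test.statistic, ts.density_test.pvalue,
            )

        stage = "compartment_calling"
        track = None
        if gc is not None:
            track = cc.call_compartments(
                cmap, gc,
                expected=config.compartment_expected,
                ambiguity_threshold=config.ambiguity_threshold,
            )
            track.to_bed(outdir / "compartments.bed")
            track.per_chromosome_table().to_csv(
                outdir / "compartments_per_chromosome.tsv", sep="\t", index=False, float_format="%.6f"
            )
            log.info(
                "compartments called; corr(E1, GC)=%.3f%s",
                track.orientation_correlation,
                " (orientation ambiguous)" if track.orientation_ambiguous else "",
            )
        else:
            log.warning("no GC track provided; compartment stage skipped")

        stage = "embedding_3d"
        emb = e3.embed_contacts(
            cmap, alpha=config.mds_alpha, seed=config.seed, max_iter=config.mds_max_iter
        )
        emb.coordinates_table().to_csv(outdir / "coordinates.tsv", sep="\t", index=False, float_format="%.6f")
        emb.chromosome_centroids().to_csv(outdir / "chromosome_centroids.tsv", sep="\t", index=False, float_format="%.6f")
        cent_table, cent_test = e3.centrality_stats(emb)
        cent_table.to_csv(outdir / "centrality.tsv", sep="\t", index=False, float_format="%.6f")
        overlap = e3.territory_overlap(emb, k_neighbors=config.k_neighbors)
        np.savetxt(
            outdir / "territory_overlap.tsv", overlap, delimiter="\t", fmt="%.6f",
            header="\t".join(genome.chrom_names), comments="",
        )
        log.info(
            "embedding stress %.4f; radial micro vs macro t=%.3f p=%.3g",
            emb.stress, cent_test.statistic, cent_test.pvalue,
        )

        stage = "summary"
        summary = ts.per_chromosome.copy()
        if track is not None:
            summary["a_proportion"] = track.per_chromosome_table()["a_proportion"].to_numpy()
        centroids = emb.chromosome_centroids().set_index("chrom")
        summary["mean_radial_distance"] = [
            centroids["mean_radial_distance"].get(name, np.nan)
            for name in summary["chrom"]
        ]
        groups = sch.fcluster(ts.linkage, 2, criterion="maxclust")
        summary["cluster_2cut"] = groups
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format="%.6f")
        if truth is not None and track is not None:
            called = track.labels != "NA"
            acc = float((track.labels[called] == truth.labels[called]).mean())
            log.info("planted compartment label recovery: %.3f", acc)
        log.info("pipeline complete: %s", outdir)
        return outdir
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
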