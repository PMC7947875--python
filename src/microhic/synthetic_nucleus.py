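"""Synthetic-nucleus Hi-C generator with known ground truth.

The generator builds a toy interphase nucleus in which each chromosome
occupies a spherical territory and contacts arise from 3D proximity, so
that every downstream stage of the pipeline can be validated by parameter
recovery rather than by eye:

* **Territory geometry** — macrochromosome territory centers are placed
  uniformly on a shell at ``macro_shell_fraction × nucleus_radius`` (the
  periphery), microchromosome centers uniformly inside a central ball of
  radius ``micro_core_radius × nucleus_radius``. This plants the
  "micro central, macro peripheral" arrangement and, via proximity, the
  micro–micro trans-contact enrichment the analysis stages should recover.
* **Polymer** — each chromosome's bins follow a confined Gaussian random
  walk around its territory center, reflected at the territory boundary
  (radius ``territory_radius_scale × L_Mb^{1/3}``), producing intra-
  chromosomal distance decay without an explicit polymer model.
* **Compartments** — an A/B label is planted per block of
  ``compartment_block_bins`` bins; microchromosomes draw A with probability
  ``micro_A_fraction`` (default 0.9), macrochromosomes with
  ``macro_A_fraction`` (default 0.45). A–A bin pairs receive a
  multiplicative contact boost ``1 + A_affinity``.
* **GC track** — ``gc_base + gc_A_shift·[A] + N(0, gc_noise_sd)``, clipped
  to [0, 1], giving GC the positive A-correlation that compartment callers
  use to orient the eigenvector sign.

Contacts are sampled multinomially from the pairwise propensity

    p_ij = (d_ij + d0)^(−γ) · (1 + A_affinity · [both A]),   i < j

so expected pair counts have a closed form that tests can check exactly.
All randomness flows through one ``numpy`` Generator; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .contact_io import (
    BinnedGenome,
    ChromSizes,
    ContactMap,
    GCTrack,
    bin_genome,
    write_bedgraph,
    write_chrom_sizes,
    write_contacts_triplet,
)

__all__ = [
    "NucleusParams",
    "GroundTruth",
    "SyntheticDataset",
    "default_params",
    "place_chromosomes",
    "plant_compartments",
    "sample_contacts",
    "make_gc_track",
    "generate_dataset",
    "load_truth",
]

#: Default toy karyotype: two 80 Mb macrochromosomes and six microchromosomes
#: of 10–20 Mb, a desk-scale caricature of an avian-like macro/micro genome.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 80_000_000,
    "chr2": 80_000_000,
    "chr3": 20_000_000,
    "chr4": 18_000_000,
    "chr5": 16_000_000,
    "chr6": 14_000_000,
    "chr7": 12_000_000,
    "chr8": 10_000_000,
}


@dataclass
class NucleusParams:
    """Parameters of the synthetic nucleus.

    Lengths are bp; spatial quantities are in arbitrary nucleus units.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    bin_size: int = 1_000_000
    micro_threshold_bp: int = 30_000_000
    nucleus_radius: float = 10.0
    micro_core_radius: float = 0.35  # fraction of nucleus_radius
    macro_shell_fraction: float = 0.75  # fraction of nucleus_radius
    territory_radius_scale: float = 0.5  # × (length in Mb)^(1/3)
    decay_exponent: float = 1.0  # γ in (d + d0)^(-γ)
    d0: float = 0.5  # softening distance
    compartment_block_bins: int = 10
    micro_A_fraction: float = 0.9
    macro_A_fraction: float = 0.45
    A_affinity: float = 0.5  # s: A–A pairs get ×(1+s) contacts
    gc_base: float = 0.40
    gc_A_shift: float = 0.08
    gc_noise_sd: float = 0.01
    n_contacts: int = 2_000_000
    seed: int = 1

    def __post_init__(self) -> None:
        for name, frac in [
            ("micro_core_radius", self.micro_core_radius),
            ("macro_shell_fraction", self.macro_shell_fraction),
            ("micro_A_fraction", self.micro_A_fraction),
            ("macro_A_fraction", self.macro_A_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.nucleus_radius <= 0 or self.decay_exponent < 0 or self.d0 <= 0:
            raise ValueError("nucleus_radius and d0 must be > 0, decay_exponent >= 0")
        if self.n_contacts <= 0:
            raise ValueError("n_contacts must be positive")

    def genome(self) -> BinnedGenome:
        sizes = ChromSizes(
            tuple(self.chrom_lengths), tuple(self.chrom_lengths.values())
        )
        return bin_genome(sizes, self.bin_size, self.micro_threshold_bp)

    def territory_radius(self, length_bp: int) -> float:
        return self.territory_radius_scale * (length_bp / 1e6) ** (1.0 / 3.0)


def default_params(**overrides) -> NucleusParams:
    """The default study conditions, with keyword overrides."""
    return NucleusParams(**overrides)


@dataclass
class GroundTruth:
    """Planted truth: 3D bin coordinates, compartment labels, chromosome class."""

    genome: BinnedGenome
    coords: np.ndarray  # (n_bins, 3)
    labels: np.ndarray  # "A"/"B" per bin

    def radial_distance(self) -> np.ndarray:
        return np.linalg.norm(self.coords, axis=1)


@dataclass
class SyntheticDataset:
    genome: BinnedGenome
    cmap: ContactMap
    gc: GCTrack
    truth: GroundTruth
    params: NucleusParams


def _uniform_on_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return radius * v / norms


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    directions = _uniform_on_sphere(rng, n, 1.0)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return directions * r[:, None]


def place_chromosomes(params: NucleusParams, rng: np.random.Generator) -> GroundTruth:
    """Place territory centers and run the confined random walks.

    Macro centers lie on the peripheral shell, micro centers inside the
    central core ball; each chromosome's bins diffuse around its center with
    Gaussian steps of SD ``territory_radius / 4``, reflected at the
    territory boundary. Raises if any territory cannot fit inside the
    nucleus. Compartment labels are left unset here (see
    :func:`plant_compartments`).
    """
    genome = params.genome()
    is_micro = genome.is_micro
    n_macro = int((~is_micro).sum())
    n_micro = int(is_micro.sum())
    macro_centers = _uniform_on_sphere(
        rng, n_macro, params.macro_shell_fraction * params.nucleus_radius
    )
    micro_centers = _uniform_in_ball(
        rng, n_micro, params.micro_core_radius * params.nucleus_radius
    )
    centers = np.empty((genome.n_chroms, 3))
    centers[~is_micro] = macro_centers
    centers[is_micro] = micro_centers

    coords = np.empty((genome.n_bins, 3))
    for ci in range(genome.n_chroms):
        r_t = params.territory_radius(int(genome.chrom_lengths[ci]))
        center_radius = float(np.linalg.norm(centers[ci]))
        if r_t > params.nucleus_radius or center_radius + r_t > params.nucleus_radius:
            raise ValueError(
                f"territory of {genome.chrom_names[ci]} (radius {r_t:.2f} at "
                f"{center_radius:.2f}) exceeds the nucleus radius "
                f"{params.nucleus_radius}"
            )
        sl = genome.bins_of(ci)
        nb = sl.stop - sl.start
        step_sd = r_t / 4.0 if r_t > 0 else 0.0
        pos = np.zeros(3)  # displacement from territory center; first bin sits there
        for b in range(nb):
            coords[sl.start + b] = centers[ci] + pos
            if step_sd > 0:
                pos = pos + rng.normal(scale=step_sd, size=3)
                d = np.linalg.norm(pos)
                if d > r_t:
                    # reflect the overshoot back inside the territory sphere
                    pos = pos * (2.0 * r_t - d) / d
    labels = np.full(genome.n_bins, "", dtype="<U1")
    return GroundTruth(genome, coords, labels)


def plant_compartments(
    truth: GroundTruth, params: NucleusParams, rng: np.random.Generator
) -> GroundTruth:
    """Assign A/B labels in blocks of ``compartment_block_bins`` bins.

    Each block is labeled A with probability ``micro_A_fraction`` on
    microchromosomes and ``macro_A_fraction`` on macrochromosomes.
    """
    genome = truth.genome
    labels = np.empty(genome.n_bins, dtype="<U1")
    for ci in range(genome.n_chroms):
        sl = genome.bins_of(ci)
        nb = sl.stop - sl.start
        p_a = params.micro_A_fraction if genome.is_micro[ci] else params.macro_A_fraction
        n_blocks = -(-nb // params.compartment_block_bins)
        block_labels = np.where(rng.random(n_blocks) < p_a, "A", "B")
        per_bin = np.repeat(block_labels, params.compartment_block_bins)[:nb]
        labels[sl] = per_bin
    truth.labels = labels
    return truth


def contact_propensities(truth: GroundTruth, params: NucleusParams) -> np.ndarray:
    """Dense symmetric propensity matrix p_ij = (d_ij+d0)^(−γ)·(1+s·[both A]),
    zero on the diagonal."""
    d = squareform(pdist(truth.coords))
    with np.errstate(divide="ignore"):
        p = (d + params.d0) ** (-params.decay_exponent)
    np.fill_diagonal(p, 0.0)
    if params.A_affinity != 0.0 and np.any(truth.labels != ""):
        is_a = truth.labels == "A"
        both_a = np.outer(is_a, is_a)
        p = p * (1.0 + params.A_affinity * both_a)
    return p


def sample_contacts(
    truth: GroundTruth, params: NucleusParams, rng: np.random.Generator
) -> ContactMap:
    """Sample ``n_contacts`` contacts multinomially from the pairwise
    propensities and return them as raw counts."""
    genome = truth.genome
    p = contact_propensities(truth, params)
    iu, ju = np.triu_indices(genome.n_bins, k=1)
    weights = p[iu, ju]
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("pairwise contact propensities are zero or non-finite")
    counts = rng.multinomial(params.n_contacts, weights / total)
    nz = counts > 0
    return ContactMap.from_entries(genome, iu[nz], ju[nz], counts[nz].astype(float))


def make_gc_track(
    truth: GroundTruth, params: NucleusParams, rng: np.random.Generator
) -> GCTrack:
    """GC per bin: base + A-shift + Gaussian noise, clipped to [0, 1]."""
    shift = np.where(truth.labels == "A", params.gc_A_shift, 0.0)
    noise = rng.normal(scale=params.gc_noise_sd, size=truth.genome.n_bins) \
        if params.gc_noise_sd > 0 else 0.0
    gc = np.clip(params.gc_base + shift + noise, 0.0, 1.0)
    return GCTrack(truth.genome, gc)


def generate_dataset(
    params: NucleusParams, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a full dataset (contacts, GC, truth) and optionally write it.

    Deterministic given ``params.seed``: the same parameters produce
    byte-identical files. Written files: ``chrom.sizes``, ``contacts.txt``
    (bin-index triplets), ``gc.bedgraph``, ``truth_bins.tsv``,
    ``truth_chroms.tsv`` and a flat ``manifest.txt`` of the parameters.
    """
    rng = np.random.default_rng(params.seed)
    truth = place_chromosomes(params, rng)
    truth = plant_compartments(truth, params, rng)
    cmap = sample_contacts(truth, params, rng)
    gc = make_gc_track(truth, params, rng)
    ds = SyntheticDataset(truth.genome, cmap, gc, truth, params)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = ds.genome
    write_chrom_sizes(g.sizes(), outdir / "chrom.sizes")
    write_contacts_triplet(ds.cmap, outdir / "contacts.txt")
    write_bedgraph(ds.gc, outdir / "gc.bedgraph")
    names = np.asarray(g.chrom_names)
    bins = pd.DataFrame(
        {
            "chrom": names[g.bin_chrom],
            "start": g.bin_start,
            "end": g.bin_end,
            "label": ds.truth.labels,
            "x": ds.truth.coords[:, 0],
            "y": ds.truth.coords[:, 1],
            "z": ds.truth.coords[:, 2],
        }
    )
    bins.to_csv(outdir / "truth_bins.tsv", sep="\t", index=False, float_format="%.6f")
    chroms = pd.DataFrame(
        {
            "chrom": g.chrom_names,
            "length": g.chrom_lengths,
            "class": g.chrom_class,
        }
    )
    chroms.to_csv(outdir / "truth_chroms.tsv", sep="\t", index=False)
    with open(outdir / "manifest.txt", "w") as fh:
        for key, value in vars(ds.params).items():
            if key == "chrom_lengths":
                value = ",".join(f"{k}:{v}" for k, v in value.items())
            fh.write(f"{key}={value}\n")


def load_truth(outdir: str | Path, genome: BinnedGenome) -> GroundTruth:
    """Read ``truth_bins.tsv`` back into a :class:`GroundTruth`."""
    bins = pd.read_csv(Path(outdir) / "truth_bins.tsv", sep="\t")
    if len(bins) != genome.n_bins:
        raise ValueError("truth table does not match genome bin count")
    coords = bins[["x", "y", "z"]].to_numpy()
    labels = bins["label"].astype(str).to_numpy()
    return GroundTruth(genome, coords, labels)
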