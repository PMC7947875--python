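"""A/B compartment inference from interchromosomal (trans) contacts.

The procedure is the standard one: form a trans observed/expected matrix,
correlate its rows, take the leading eigenvector of the correlation matrix,
orient its sign with a GC track (A = GC-rich), and label bins A/B by sign.

Two trans expected models are provided:

* ``"chrom-pair"`` (default) — E_ij = m_i · m_j · B_kl, where m_i is bin
  i's mean trans contact (its coverage in the trans submatrix) and B_kl a
  per-chromosome-pair factor chosen so each block's expected total matches
  its observed total. Dividing by this removes both territory-level
  contact enrichment (e.g. micro–micro proximity) and residual per-bin
  coverage — a full contact-map balance equalizes cis+trans marginals, so
  trans-only marginals still carry structure — leaving compartment
  covariation as the dominant signal for the eigenvector.
* ``"global"`` — one genome-wide mean trans contact per unmasked bin pair;
  retains chromosome- and bin-level contact enrichment in the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_io import BinnedGenome, ContactMap, GCTrack, write_bed
from .trans_interaction import GroupComparison, compare_groups

__all__ = [
    "CompartmentTrack",
    "trans_oe_matrix",
    "leading_eigenvector",
    "orient_and_label",
    "call_compartments",
    "a_proportions",
]

LABEL_NA = "NA"


@dataclass
class CompartmentTrack:
    """Per-bin compartment eigenvector and labels, plus orientation metadata.

    ``e1`` is NaN on masked bins; labels are "A" for e1 > 0, "B" for
    e1 < 0, "NA" where masked or exactly zero. ``orientation_correlation``
    is the Pearson correlation between the oriented eigenvector and GC
    (>= 0 unless orientation was ambiguous).
    """

    genome: BinnedGenome
    e1: np.ndarray
    labels: np.ndarray
    orientation_correlation: float
    orientation_ambiguous: bool

    def a_proportion(self, chrom: int | str, denominator: str = "called") -> float:
        """Fraction of A bins on a chromosome.

        ``denominator="called"`` divides by A+B bins (NA excluded);
        ``"all"`` divides by every bin of the chromosome.
        """
        sl = self.genome.bins_of(chrom)
        lab = self.labels[sl]
        n_a = int((lab == "A").sum())
        denom = len(lab) if denominator == "all" else n_a + int((lab == "B").sum())
        return n_a / denom if denom > 0 else float("nan")

    def to_bed(self, path) -> None:
        scores = np.where(np.isfinite(self.e1), self.e1, 0.0)
        write_bed(self.genome, path, list(self.labels), scores)

    def per_chromosome_table(self) -> pd.DataFrame:
        g = self.genome
        rows = []
        for ci, name in enumerate(g.chrom_names):
            lab = self.labels[g.bins_of(ci)]
            rows.append(
                {
                    "chrom": name,
                    "class": g.chrom_class[ci],
                    "n_A": int((lab == "A").sum()),
                    "n_B": int((lab == "B").sum()),
                    "n_NA": int((lab == LABEL_NA).sum()),
                    "a_proportion": self.a_proportion(ci),
                }
            )
        return pd.DataFrame(rows)


def trans_oe_matrix(
    cmap: ContactMap,
    expected: str = "chrom-pair",
    balanced: bool = True,
) -> np.ndarray:
    """Dense bin×bin trans observed/expected matrix.

    Intrachromosomal blocks and masked bins are NaN. ``expected`` selects
    the null: "chrom-pair" (per-bin coverage × per-block factor, see module
    docstring) or "global" (one genome-wide mean trans contact per unmasked
    bin pair).
    """
    if expected not in ("chrom-pair", "global"):
        raise ValueError(f"unknown expected model {expected!r}")
    g = cmap.genome
    if g.n_chroms < 2:
        raise ValueError("no trans contacts possible with a single chromosome")
    dense = cmap.to_dense(balanced=balanced)
    mask = cmap.bin_mask
    bc = g.bin_chrom
    same_chrom = bc[:, None] == bc[None, :]
    valid = mask[:, None] & mask[None, :] & ~same_chrom
    if not valid.any() or dense[valid].sum() == 0:
        raise ValueError("contact map has no trans contacts")
    oe = np.full_like(dense, np.nan)
    if expected == "global":
        mean = dense[valid].sum() / valid.sum()
        oe[valid] = dense[valid] / mean
        return oe
    # per-bin trans coverage; bins with zero trans coverage become NaN
    with np.errstate(invalid="ignore"):
        coverage = np.where(valid, dense, 0.0).sum(axis=1) / np.maximum(
            valid.sum(axis=1), 1
        )
    valid &= (coverage > 0)[:, None] & (coverage > 0)[None, :]
    exp = np.outer(coverage, coverage)
    for ci in range(g.n_chroms):
        for cj in range(ci + 1, g.n_chroms):
            si, sj = g.bins_of(ci), g.bins_of(cj)
            block_valid = valid[si, sj]
            if not block_valid.any():
                continue
            obs_total = dense[si, sj][block_valid].sum()
            exp_total = exp[si, sj][block_valid].sum()
            if obs_total <= 0 or exp_total <= 0:
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                block = dense[si, sj] / (exp[si, sj] * (obs_total / exp_total))
            oe[si, sj] = np.where(block_valid, block, np.nan)
            oe[sj, si] = oe[si, sj].T
    return oe


def leading_eigenvector(
    oe: np.ndarray,
    min_unmasked: int = 10,
    min_shared_bins: int = 20,
) -> np.ndarray:
    """Leading eigenvector of the bin–bin correlation of the centered O/E.

    O/E rows are centered by subtracting 1 (the null expectation) and
    correlated over pairwise-complete observations; bins with fewer than
    ``min_shared_bins`` complete pairs against the rest are dropped (NaN in
    the output). The deterministic pre-orientation sign convention is
    "first nonzero component positive"; GC orientation happens later.
    """
    n = oe.shape[0]
    centered = np.ma.masked_invalid(oe - 1.0)
    n_obs = (~centered.mask).sum(axis=1)
    usable = n_obs >= max(1, min(min_shared_bins, n - 2))
    if usable.sum() < min_unmasked:
        raise ValueError(
            f"only {int(usable.sum())} usable bins (< {min_unmasked}); cannot call compartments"
        )
    sub = centered[usable][:, usable]
    corr = np.ma.corrcoef(sub, allow_masked=True)
    corr_f = np.asarray(corr.filled(0.0), dtype=np.float64)
    np.fill_diagonal(corr_f, 1.0)
    corr_f = (corr_f + corr_f.T) / 2.0
    evals, evecs = np.linalg.eigh(corr_f)
    v = evecs[:, -1]
    nz = np.nonzero(v)[0]
    if nz.size and v[nz[0]] < 0:
        v = -v
    e1 = np.full(n, np.nan)
    e1[usable] = v
    return e1


def orient_and_label(
    e1: np.ndarray,
    gc_track: GCTrack,
    ambiguity_threshold: float = 0.1,
) -> CompartmentTrack:
    """Orient the eigenvector sign by GC and assign A/B labels.

    If corr(E1, GC) < 0 the vector is negated so that A (positive E1) is
    the GC-rich state. When |corr| is below ``ambiguity_threshold`` the
    sign is kept as-is and the track is flagged orientation-ambiguous.
    """
    genome = gc_track.genome
    e1 = np.asarray(e1, dtype=np.float64)
    both = np.isfinite(e1) & np.isfinite(gc_track.gc)
    if both.sum() >= 3 and np.std(e1[both]) > 0 and np.std(gc_track.gc[both]) > 0:
        corr = float(np.corrcoef(e1[both], gc_track.gc[both])[0, 1])
    else:
        corr = 0.0
    ambiguous = abs(corr) < ambiguity_threshold
    if corr < 0 and not ambiguous:
        e1 = -e1
        corr = -corr
    labels = np.full(genome.n_bins, LABEL_NA, dtype="<U2")
    labels[np.isfinite(e1) & (e1 > 0)] = "A"
    labels[np.isfinite(e1) & (e1 < 0)] = "B"
    return CompartmentTrack(genome, e1, labels, corr, ambiguous)


def call_compartments(
    cmap: ContactMap,
    gc_track: GCTrack,
    expected: str = "chrom-pair",
    balanced: bool = True,
    ambiguity_threshold: float = 0.1,
    min_shared_bins: int = 20,
) -> CompartmentTrack:
    """Full trans-contact compartment call: O/E → correlation → E1 → GC orientation."""
    oe = trans_oe_matrix(cmap, expected=expected, balanced=balanced)
    e1 = leading_eigenvector(oe, min_shared_bins=min_shared_bins)
    return orient_and_label(e1, gc_track, ambiguity_threshold=ambiguity_threshold)


def a_proportions(
    track: CompartmentTrack,
    denominator: str = "called",
) -> tuple[pd.Series, GroupComparison | None]:
    """Per-chromosome A proportions plus the micro-vs-macro Student t-test.

    Chromosomes with no called bins get NaN and are excluded from the test;
    the test is None when either class has fewer than two testable
    chromosomes.
    """
    g = track.genome
    props = pd.Series(
        [track.a_proportion(ci, denominator=denominator) for ci in range(g.n_chroms)],
        index=list(g.chrom_names),
        name="a_proportion",
    )
    ok = props.notna().to_numpy()
    classes = g.chrom_class[ok]
    test = None
    if (classes == "micro").sum() >= 2 and (classes == "macro").sum() >= 2:
        test = compare_groups(props.to_numpy()[ok], classes)
    return props, test
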