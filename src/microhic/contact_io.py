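"""Binned genomes, Hi-C contact maps, and the plain-text formats that carry them.

The data model is deliberately small:

* :class:`BinnedGenome` — an ordered set of chromosomes cut into fixed-size
  bins (0-based, half-open; the last bin of each chromosome may be short),
  with each chromosome classed ``macro`` or ``micro`` by a length threshold.
* :class:`ContactMap` — a symmetric sparse collection of binned contact
  counts, optionally carrying per-bin balancing weights and a validity mask.
* :class:`GCTrack` — per-bin GC fraction, used downstream to orient the
  compartment eigenvector.

Readers/writers cover chrom.sizes TSV, two sparse-triplet dialects (global
bin indices, or the 7-column genomic form produced by Juicer-style dumps),
bedGraph, and BED. Matrix balancing (:func:`balance`) is iterative
correction toward uniform marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "ChromSizes",
    "BinnedGenome",
    "ContactMap",
    "GCTrack",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "bin_genome",
    "read_contacts_triplet",
    "write_contacts_triplet",
    "read_bedgraph_gc",
    "write_bedgraph",
    "write_bed",
    "balance",
]

MACRO = "macro"
MICRO = "micro"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome names and lengths (bp), prior to binning."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise FormatError("no chromosomes")
        if len(self.names) != len(set(self.names)):
            dup = next(n for n in self.names if self.names.count(n) > 1)
            raise FormatError(f"duplicate chromosome name {dup!r}")
        for name, length in zip(self.names, self.lengths):
            if length <= 0:
                raise FormatError(f"non-positive length for chromosome {name!r}")


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Parse a two-column ``name<TAB>length`` chrom.sizes file.

    Chromosome order follows file order. Malformed lines, duplicate names
    and non-positive lengths raise :class:`FormatError` naming the offender.
    """
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name, length_s = parts
            try:
                length = int(length_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: length {length_s!r} is not an integer") from None
            if name in names:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome name {name!r}")
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for chromosome {name!r}")
            names.append(name)
            lengths.append(length)
    if not names:
        raise FormatError(f"{path}: no chromosomes")
    return ChromSizes(tuple(names), tuple(lengths))


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(sizes.names, sizes.lengths):
            fh.write(f"{name}\t{length}\n")


@dataclass
class BinnedGenome:
    """Chromosomes cut into fixed-size bins with a macro/micro classification.

    Bins are 0-based half-open intervals ``[start, end)`` of width
    ``bin_size``; the last bin of each chromosome may be shorter and is kept
    (not dropped). Global bin indices are contiguous, ordered by chromosome
    order then start. A chromosome is ``micro`` iff its length is strictly
    below ``micro_threshold_bp``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: np.ndarray  # int64 bp, one per chromosome
    bin_size: int
    micro_threshold_bp: int

    # derived in __post_init__
    chrom_class: np.ndarray = field(init=False)  # "macro"/"micro" per chromosome
    chrom_nbins: np.ndarray = field(init=False)
    chrom_offsets: np.ndarray = field(init=False)  # first global bin per chromosome
    bin_chrom: np.ndarray = field(init=False)  # chromosome index per global bin
    bin_start: np.ndarray = field(init=False)
    bin_end: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.micro_threshold_bp <= 0:
            raise ValueError("micro_threshold_bp must be positive")
        if np.any(self.chrom_lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        self.chrom_class = np.where(
            self.chrom_lengths < self.micro_threshold_bp, MICRO, MACRO
        )
        self.chrom_nbins = np.array(
            [math.ceil(length / self.bin_size) for length in self.chrom_lengths],
            dtype=np.int64,
        )
        self.chrom_offsets = np.concatenate([[0], np.cumsum(self.chrom_nbins)])
        starts, ends, chroms = [], [], []
        for ci, (length, nb) in enumerate(zip(self.chrom_lengths, self.chrom_nbins)):
            s = np.arange(nb, dtype=np.int64) * self.bin_size
            e = np.minimum(s + self.bin_size, length)
            starts.append(s)
            ends.append(e)
            chroms.append(np.full(nb, ci, dtype=np.int64))
        self.bin_start = np.concatenate(starts)
        self.bin_end = np.concatenate(ends)
        self.bin_chrom = np.concatenate(chroms)
        self._chrom_index = {n: i for i, n in enumerate(self.chrom_names)}

    # -- sizes -----------------------------------------------------------
    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def n_bins(self) -> int:
        return int(self.chrom_offsets[-1])

    def chrom_index(self, name: str) -> int:
        try:
            return self._chrom_index[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def bins_of(self, chrom: int | str) -> slice:
        ci = chrom if isinstance(chrom, (int, np.integer)) else self.chrom_index(chrom)
        return slice(int(self.chrom_offsets[ci]), int(self.chrom_offsets[ci + 1]))

    def bin_index(self, chrom: str, start: int) -> int:
        """Global bin index of the bin starting at ``start`` on ``chrom``."""
        ci = self.chrom_index(chrom)
        if start < 0 or start >= self.chrom_lengths[ci]:
            raise ValueError(f"start {start} outside chromosome {chrom!r}")
        if start % self.bin_size != 0:
            raise ValueError(
                f"start {start} on {chrom!r} is not a multiple of bin_size {self.bin_size}"
            )
        return int(self.chrom_offsets[ci] + start // self.bin_size)

    @property
    def is_micro(self) -> np.ndarray:
        """Boolean per chromosome."""
        return self.chrom_class == MICRO

    @property
    def is_micro_bin(self) -> np.ndarray:
        """Boolean per global bin."""
        return self.is_micro[self.bin_chrom]

    @property
    def bin_lengths(self) -> np.ndarray:
        return self.bin_end - self.bin_start

    def bin_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": np.asarray(self.chrom_names)[self.bin_chrom],
                "start": self.bin_start,
                "end": self.bin_end,
            }
        )

    def sizes(self) -> ChromSizes:
        return ChromSizes(self.chrom_names, tuple(int(x) for x in self.chrom_lengths))


def bin_genome(
    sizes: ChromSizes,
    bin_size: int,
    micro_threshold_bp: int = 30_000_000,
) -> BinnedGenome:
    """Bin a genome and class chromosomes as macro/micro by a length threshold.

    The default threshold (30 Mb) matches the avian convention; for non-avian
    reptiles a 50 Mb break is typically used.
    """
    return BinnedGenome(
        chrom_names=tuple(sizes.names),
        chrom_lengths=np.asarray(sizes.lengths, dtype=np.int64),
        bin_size=int(bin_size),
        micro_threshold_bp=int(micro_threshold_bp),
    )


@dataclass
class ContactMap:
    """Symmetric sparse Hi-C contact matrix over the bins of a genome.

    Entries are stored once with ``bin1 <= bin2``; querying (i, j) and
    (j, i) through :meth:`to_csr`/:meth:`to_dense` yields the same value.
    ``balancing_weights`` (if present) are per-bin multipliers ``w`` such
    that the balanced value is ``w_i * count_ij * w_j``; masked-out bins
    have weight 0.
    """

    genome: BinnedGenome
    bin1: np.ndarray
    bin2: np.ndarray
    counts: np.ndarray
    balancing_weights: np.ndarray | None = None
    bin_mask: np.ndarray | None = None  # True = valid bin
    balance_converged: bool | None = None

    def __post_init__(self) -> None:
        if self.bin_mask is None:
            self.bin_mask = np.ones(self.genome.n_bins, dtype=bool)

    @classmethod
    def from_entries(
        cls,
        genome: BinnedGenome,
        bin1: Sequence[int],
        bin2: Sequence[int],
        counts: Sequence[float],
    ) -> "ContactMap":
        """Build from (i, j, value) entries; duplicates (in either
        orientation) are summed; storage is canonicalized to i <= j."""
        i = np.asarray(bin1, dtype=np.int64)
        j = np.asarray(bin2, dtype=np.int64)
        v = np.asarray(counts, dtype=np.float64)
        n = genome.n_bins
        if i.size and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
            raise ValueError("entry references a bin outside the genome")
        if np.any(v < 0):
            raise ValueError("contact counts must be non-negative")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        m = sp.coo_matrix((v, (lo, hi)), shape=(n, n)).tocsr()  # sums duplicates
        m.eliminate_zeros()
        coo = m.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return cls(genome, coo.row[order], coo.col[order], coo.data[order])

    @property
    def n_entries(self) -> int:
        return len(self.counts)

    def values(self, balanced: bool = True) -> np.ndarray:
        """Per-entry values, balanced if weights are available."""
        if balanced and self.balancing_weights is not None:
            w = self.balancing_weights
            return self.counts * w[self.bin1] * w[self.bin2]
        return self.counts.copy()

    @property
    def is_trans(self) -> np.ndarray:
        """Boolean per entry: True where the two bins lie on different chromosomes."""
        bc = self.genome.bin_chrom
        return bc[self.bin1] != bc[self.bin2]

    def to_csr(self, balanced: bool = False) -> sp.csr_matrix:
        """Full symmetric CSR matrix (diagonal entries counted once)."""
        n = self.genome.n_bins
        v = self.values(balanced=balanced)
        upper = sp.coo_matrix((v, (self.bin1, self.bin2)), shape=(n, n))
        off = self.bin1 != self.bin2
        lower = sp.coo_matrix(
            (v[off], (self.bin2[off], self.bin1[off])), shape=(n, n)
        )
        return (upper + lower).tocsr()

    def to_dense(self, balanced: bool = False) -> np.ndarray:
        return self.to_csr(balanced=balanced).toarray()

    def total(self, balanced: bool = False) -> float:
        return float(self.values(balanced=balanced).sum())

    def with_weights(
        self, weights: np.ndarray, mask: np.ndarray, converged: bool
    ) -> "ContactMap":
        return replace(
            self,
            balancing_weights=weights,
            bin_mask=mask,
            balance_converged=converged,
        )


@dataclass
class GCTrack:
    """Per-bin GC fraction in [0, 1]; NaN marks missing bins."""

    genome: BinnedGenome
    gc: np.ndarray

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=np.float64)
        if self.gc.shape != (self.genome.n_bins,):
            raise ValueError("GC track length does not match genome bin count")
        finite = self.gc[np.isfinite(self.gc)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("GC fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# sparse triplet text
# ---------------------------------------------------------------------------

def read_contacts_triplet(path: str | Path, genome: BinnedGenome) -> ContactMap:
    """Read whitespace-separated sparse contacts.

    Two dialects are auto-detected by column count:

    * 3 columns — ``bin_i bin_j value`` with global bin indices;
    * 7 columns — ``chrom1 start1 end1 chrom2 start2 end2 value`` with
      genomic coordinates that must align to bin boundaries.

    Duplicate entries (in either orientation) are summed.
    """
    ncols = None
    i_list: list[int] = []
    j_list: list[int] = []
    v_list: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if ncols is None:
                if len(parts) not in (3, 7):
                    raise FormatError(
                        f"{path}:{lineno}: expected 3 or 7 columns, got {len(parts)}"
                    )
                ncols = len(parts)
            elif len(parts) != ncols:
                raise FormatError(
                    f"{path}:{lineno}: inconsistent column count ({len(parts)} vs {ncols})"
                )
            try:
                if ncols == 3:
                    bi, bj = int(parts[0]), int(parts[1])
                    value = float(parts[2])
                    if bi < 0 or bj < 0 or bi >= genome.n_bins or bj >= genome.n_bins:
                        raise FormatError(
                            f"{path}:{lineno}: bin index outside genome (n_bins={genome.n_bins})"
                        )
                else:
                    c1, s1 = parts[0], int(parts[1])
                    c2, s2 = parts[3], int(parts[4])
                    value = float(parts[6])
                    try:
                        bi = genome.bin_index(c1, s1)
                        bj = genome.bin_index(c2, s2)
                    except (KeyError, ValueError) as exc:
                        raise FormatError(f"{path}:{lineno}: {exc}") from None
            except FormatError:
                raise
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from None
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative contact value")
            i_list.append(bi)
            j_list.append(bj)
            v_list.append(value)
    return ContactMap.from_entries(genome, i_list, j_list, v_list)


def write_contacts_triplet(cmap: ContactMap, path: str | Path) -> None:
    """Write the bin-index triplet dialect; integer counts stay integers so
    the write → read round trip is lossless."""
    with open(path, "w") as fh:
        for i, j, v in zip(cmap.bin1, cmap.bin2, cmap.counts):
            if float(v).is_integer():
                fh.write(f"{i} {j} {int(v)}\n")
            else:
                fh.write(f"{i} {j} {v!r}\n")


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------

def read_bedgraph_gc(path: str | Path, genome: BinnedGenome) -> GCTrack:
    """Read a per-bin GC bedGraph (chrom, start, end, fraction).

    Every interval must coincide with one genome bin; misaligned intervals
    and out-of-range fractions are collected and reported together.
    """
    gc = np.full(genome.n_bins, np.nan)
    offenders: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start_s, end_s, val_s = parts
            try:
                start, end, value = int(start_s), int(end_s), float(val_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from None
            try:
                b = genome.bin_index(chrom, start)
            except (KeyError, ValueError) as exc:
                offenders.append(f"line {lineno}: {exc}")
                continue
            if end != genome.bin_end[b]:
                offenders.append(
                    f"line {lineno}: interval end {end} != bin end {genome.bin_end[b]}"
                )
                continue
            if not (0.0 <= value <= 1.0):
                offenders.append(f"line {lineno}: GC fraction {value} outside [0, 1]")
                continue
            gc[b] = value
    if offenders:
        raise FormatError(f"{path}: {len(offenders)} bad interval(s): " + "; ".join(offenders[:5]))
    return GCTrack(genome, gc)


def write_bedgraph(track: GCTrack, path: str | Path, precision: int = 6) -> None:
    g = track.genome
    names = np.asarray(g.chrom_names)
    with open(path, "w") as fh:
        for b in range(g.n_bins):
            if np.isfinite(track.gc[b]):
                fh.write(
                    f"{names[g.bin_chrom[b]]}\t{g.bin_start[b]}\t{g.bin_end[b]}\t"
                    f"{track.gc[b]:.{precision}f}\n"
                )


def write_bed(
    genome: BinnedGenome,
    path: str | Path,
    names: Sequence[str],
    scores: np.ndarray | None = None,
) -> None:
    """Write one BED4(+5) row per bin: chrom, start, end, name[, score]."""
    chroms = np.asarray(genome.chrom_names)
    with open(path, "w") as fh:
        for b in range(genome.n_bins):
            row = (
                f"{chroms[genome.bin_chrom[b]]}\t{genome.bin_start[b]}\t{genome.bin_end[b]}"
                f"\t{names[b]}"
            )
            if scores is not None:
                row += f"\t{scores[b]:.6g}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def balance(
    cmap: ContactMap,
    max_iter: int = 500,
    tol: float = 1e-5,
    mask_quantile: float = 0.02,
) -> ContactMap:
    """Balance a contact map by iterative correction toward uniform marginals.

    Bins whose raw marginal is zero, or at/below the ``mask_quantile``
    quantile of the nonzero marginals, are masked (weight 0) and excluded
    from the convergence check. On the unmasked submatrix, per-bin weights
    are iterated until every row sum of ``w_i C_ij w_j`` agrees with the
    mean unmasked row sum within ``tol`` (relative). Weights are rescaled at
    the end so the balanced total equals the raw total, keeping balanced
    values on the scale of the input counts.

    Non-convergence sets ``balance_converged = False`` on the result instead
    of raising.
    """
    if not 0 <= mask_quantile < 1:
        raise ValueError("mask_quantile must lie in [0, 1)")
    n = cmap.genome.n_bins
    m = cmap.to_csr(balanced=False)
    marginals = np.asarray(m.sum(axis=1)).ravel()
    mask = marginals > 0
    nz = marginals[mask]
    if nz.size and mask_quantile > 0:
        cutoff = np.quantile(nz, mask_quantile)
        mask &= marginals > cutoff
    w = np.where(mask, 1.0, 0.0)
    converged = False
    if mask.sum() == 0:
        return cmap.with_weights(w, mask, False)
    for _ in range(max_iter):
        s = w * (m @ w)  # row sums of the reweighted matrix
        mean_s = s[mask].mean()
        if mean_s == 0:
            break
        rel = np.abs(s[mask] / mean_s - 1.0).max()
        if rel < tol:
            converged = True
            break
        adj = np.ones(n)
        adj[mask] = np.sqrt(s[mask] / mean_s)
        w = np.where(mask, w / adj, 0.0)
    # rescale so the balanced total matches the raw total on unmasked bins
    bal_total = cmap.with_weights(w, mask, converged).total(balanced=True)
    raw_total = cmap.counts[mask[cmap.bin1] & mask[cmap.bin2]].sum()
    if bal_total > 0:
        w = w * math.sqrt(raw_total / bal_total)
    return cmap.with_weights(w, mask, converged)
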