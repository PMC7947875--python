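"""3D interpretation of contact maps by multidimensional scaling.

Contacts are converted to dissimilarities by a power law d = c^(−alpha)
and embedded in 3D by metric MDS (classical-scaling initialization followed
by SMACOF stress majorization). The embedding is an *interpretation* of the
2D contact pattern, defined only up to rigid motion and reflection; every
statistic reported here (radial centrality, territory overlap) is invariant
to those transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .contact_io import BinnedGenome, ContactMap
from .trans_interaction import GroupComparison, compare_groups

__all__ = [
    "Embedding3D",
    "contacts_to_distances",
    "classical_mds",
    "mds_embed",
    "centrality_stats",
    "territory_overlap",
    "class_overlap_means",
]


@dataclass
class Embedding3D:
    """Per-bin 3D coordinates (centroid at origin) plus embedding diagnostics.

    ``stress`` is normalized (Kruskal stress-1): sqrt(Σ(d−d̂)² / Σd²) over
    the embedded bin pairs. ``bin_indices`` maps embedding rows back to
    global genome bins (masked bins are excluded from embedding).
    """

    genome: BinnedGenome
    coords: np.ndarray
    bin_indices: np.ndarray
    stress: float
    stress_history: np.ndarray
    n_iter: int

    def radial_distance(self) -> np.ndarray:
        return np.linalg.norm(self.coords - self.coords.mean(axis=0), axis=1)

    def chrom_of_row(self) -> np.ndarray:
        return self.genome.bin_chrom[self.bin_indices]

    def chromosome_centroids(self) -> pd.DataFrame:
        rows = []
        chroms = self.chrom_of_row()
        for ci, name in enumerate(self.genome.chrom_names):
            pts = self.coords[chroms == ci]
            if len(pts) == 0:
                continue
            centroid = pts.mean(axis=0)
            rog = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
            rows.append(
                {
                    "chrom": name,
                    "class": self.genome.chrom_class[ci],
                    "n_bins": len(pts),
                    "cx": centroid[0],
                    "cy": centroid[1],
                    "cz": centroid[2],
                    "radius_of_gyration": rog,
                    "mean_radial_distance": float(
                        np.linalg.norm(pts - self.coords.mean(axis=0), axis=1).mean()
                    ),
                }
            )
        return pd.DataFrame(rows)

    def coordinates_table(self) -> pd.DataFrame:
        g = self.genome
        names = np.asarray(g.chrom_names)
        return pd.DataFrame(
            {
                "chrom": names[g.bin_chrom[self.bin_indices]],
                "start": g.bin_start[self.bin_indices],
                "end": g.bin_end[self.bin_indices],
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )


def contacts_to_distances(
    cmap: ContactMap,
    alpha: float = 0.5,
    balanced: bool = True,
    zero_fill_factor: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert contacts to a dissimilarity matrix d = c^(−alpha).

    Distances are rescaled so the median finite off-diagonal distance is 1;
    pairs with zero contact are set to the maximum finite distance ×
    ``zero_fill_factor``; the diagonal is 0. Masked bins are dropped.
    Returns (distance matrix, kept global bin indices).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    keep = np.flatnonzero(cmap.bin_mask)
    dense = cmap.to_dense(balanced=balanced)[np.ix_(keep, keep)]
    n = len(keep)
    if n < 2:
        raise ValueError("need at least two unmasked bins")
    with np.errstate(divide="ignore"):
        d = np.where(dense > 0, dense**-alpha, np.inf)
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        raise ValueError("contact map has no positive entries")
    d[finite] /= np.median(d[finite])
    d[off & ~np.isfinite(d)] = d[finite].max() * zero_fill_factor
    # recompute after the median rescale so the fill tracks the final scale
    return d, keep


def classical_mds(distances: np.ndarray, n_dim: int = 3) -> np.ndarray:
    """Classical (Torgerson) scaling: eigendecompose the double-centered
    squared-distance Gram matrix and keep the top ``n_dim`` axes."""
    d2 = np.asarray(distances, dtype=np.float64) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(gram)
    idx = np.argsort(evals)[::-1][:n_dim]
    lam = np.clip(evals[idx], 0.0, None)
    return evecs[:, idx] * np.sqrt(lam)


def _stress1(distances: np.ndarray, coords: np.ndarray) -> float:
    d_hat = pdist(coords)
    d = squareform(distances, checks=False)
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - d_hat) ** 2).sum() / denom))


def mds_embed(
    distances: np.ndarray,
    genome: BinnedGenome | None = None,
    bin_indices: np.ndarray | None = None,
    n_dim: int = 3,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> Embedding3D:
    """Stress-majorizing metric MDS.

    Initializes with classical scaling (plus a tiny seeded jitter to break
    exact degeneracies) and iterates the SMACOF Guttman transform until the
    relative stress decrease falls below ``tol``. Stress is non-increasing
    across iterations by construction. The result is centered at the
    origin; orientation is arbitrary (report only rigid-invariant
    statistics).
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if not np.allclose(d, d.T):
        raise ValueError("distances must be symmetric")
    n = d.shape[0]
    rng = np.random.default_rng(seed)
    x = classical_mds(d, n_dim=n_dim)
    scale = np.abs(x).max()
    x = x + rng.normal(scale=(scale if scale > 0 else 1.0) * 1e-9, size=x.shape)
    history = [_stress1(d, x)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d_hat = squareform(pdist(x), checks=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_hat > 0, d / d_hat, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n  # Guttman transform with uniform weights
        stress = _stress1(d, x)
        history.append(stress)
        prev = history[-2]
        if prev == 0 or (prev - stress) / max(prev, 1e-300) < tol:
            break
    x = x - x.mean(axis=0)
    if genome is None:
        # standalone use: a bare genome is not required for the math
        bin_indices = np.arange(n) if bin_indices is None else bin_indices
        genome = _point_genome(n)
    elif bin_indices is None:
        bin_indices = np.arange(genome.n_bins)
    return Embedding3D(
        genome=genome,
        coords=x,
        bin_indices=np.asarray(bin_indices),
        stress=history[-1],
        stress_history=np.asarray(history),
        n_iter=n_iter,
    )


def _point_genome(n: int) -> BinnedGenome:
    from .contact_io import BinnedGenome as BG

    return BG(("points",), np.array([n]), 1, 2)


def embed_contacts(
    cmap: ContactMap,
    alpha: float = 0.5,
    balanced: bool = True,
    n_dim: int = 3,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> Embedding3D:
    """Contact map → distances → MDS, excluding masked bins."""
    d, keep = contacts_to_distances(cmap, alpha=alpha, balanced=balanced)
    return mds_embed(
        d, genome=cmap.genome, bin_indices=keep, n_dim=n_dim, seed=seed,
        max_iter=max_iter, tol=tol,
    )


def centrality_stats(
    emb: Embedding3D, test: str = "student"
) -> tuple[pd.DataFrame, GroupComparison]:
    """Radial centrality of micro vs macro bins.

    Returns a per-class table (n_bins, mean/sd radial distance from the
    global centroid) and the Student t-test over per-bin radial distances
    (negative statistic: micro closer to the center than macro).
    """
    r = emb.radial_distance()
    is_micro = emb.genome.is_micro_bin[emb.bin_indices]
    classes = np.where(is_micro, "micro", "macro")
    table = pd.DataFrame(
        [
            {
                "class": cls,
                "n_bins": int((classes == cls).sum()),
                "mean_radial_distance": float(r[classes == cls].mean()),
                "sd_radial_distance": float(r[classes == cls].std(ddof=1)),
            }
            for cls in ("macro", "micro")
            if (classes == cls).any()
        ]
    )
    comparison = compare_groups(r, classes, test=test)
    return table, comparison


def territory_overlap(
    emb: Embedding3D, k_neighbors: int = 10
) -> np.ndarray:
    """Pairwise chromosome territory overlap from nearest neighbors.

    For each bin, take its ``k_neighbors`` nearest bins (self excluded);
    overlap(k, l) is the fraction of chromosome k's bins with at least one
    of those neighbors on chromosome l, symmetrized by averaging. Bins of a
    chromosome with a well-isolated territory have same-chromosome nearest
    neighbors only, so overlap ≈ 0 against everything; interdigitating
    chromosomes approach 1.
    """
    chroms = emb.chrom_of_row()
    n_chroms = emb.genome.n_chroms
    d = squareform(pdist(emb.coords), checks=False)
    np.fill_diagonal(d, np.inf)
    n = d.shape[0]
    k = min(k_neighbors, n - 1)
    hit = np.zeros((n_chroms, n_chroms))
    count = np.zeros(n_chroms)
    nn = np.argpartition(d, kth=k - 1, axis=1)[:, :k]
    for row in range(n):
        partners = np.unique(chroms[nn[row]])
        hit[chroms[row], partners[partners != chroms[row]]] += 1
        count[chroms[row]] += 1
    with np.errstate(invalid="ignore"):
        frac = hit / np.maximum(count[:, None], 1)
    overlap = (frac + frac.T) / 2.0
    np.fill_diagonal(overlap, np.nan)
    return overlap


def class_overlap_means(overlap: np.ndarray, genome: BinnedGenome) -> dict[str, float]:
    """Mean overlap within/between chromosome classes (pairs k<l)."""
    is_micro = genome.is_micro
    n = genome.n_chroms
    out: dict[str, list[float]] = {"micro-micro": [], "macro-macro": [], "macro-micro": []}
    for k in range(n):
        for l in range(k + 1, n):
            if is_micro[k] and is_micro[l]:
                key = "micro-micro"
            elif not is_micro[k] and not is_micro[l]:
                key = "macro-macro"
            else:
                key = "macro-micro"
            out[key].append(float(overlap[k, l]))
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in out.items()}
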