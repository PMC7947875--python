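"""Interchromosomal contact statistics at the whole-chromosome level.

Quantities computed here:

* ICF density — the summed trans contact frequency of each chromosome
  divided by its length in Mb, the per-chromosome measure of
  interchromosomal interactivity.
* Micro-involvement — the fraction of a chromosome's trans contact mass
  whose partner chromosome is classed micro.
* Observed vs expected pairwise ICF under a uniform-interaction null,
  with the log2 O/E enrichment matrix and hierarchical clustering of
  chromosomes on its rows.
* Student's t comparisons of macro vs micro groups and an OLS regression
  of ICF density on chromosome length.

The default null distributes the total trans mass T over chromosome pairs
in proportion to the product of their lengths, E_kl = T·L_k·L_l / Σ L_m·L_n
(m<n): what "uniform interaction" means if every pair of genomic positions
on different chromosomes is equally likely to touch. A coverage-controlled
alternative (E_kl ∝ trans_sum_k·trans_sum_l) is available via
``null="marginal"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

from .contact_io import BinnedGenome, ContactMap

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "TransSummary",
    "chrom_pair_observed",
    "icf_density",
    "micro_involvement",
    "expected_icf",
    "oe_log2",
    "cluster_chromosomes",
    "dendrogram_newick",
    "compare_groups",
    "regress_density_on_length",
    "trans_summary",
]


def chrom_pair_observed(cmap: ContactMap, balanced: bool = True) -> np.ndarray:
    """Symmetric n_chrom×n_chrom matrix of summed trans contacts per pair
    (diagonal zero; cis contacts are ignored)."""
    g = cmap.genome
    bc = g.bin_chrom
    ci = bc[cmap.bin1]
    cj = bc[cmap.bin2]
    trans = ci != cj
    v = cmap.values(balanced=balanced)[trans]
    obs = np.zeros((g.n_chroms, g.n_chroms))
    np.add.at(obs, (ci[trans], cj[trans]), v)
    np.add.at(obs, (cj[trans], ci[trans]), v)
    return obs


def icf_density(cmap: ContactMap, balanced: bool = True) -> pd.Series:
    """Per-chromosome trans contact sum divided by chromosome length in Mb."""
    g = cmap.genome
    if g.n_chroms < 2:
        raise ValueError("no trans contacts possible with a single chromosome")
    obs = chrom_pair_observed(cmap, balanced=balanced)
    trans_sum = obs.sum(axis=1)
    length_mb = g.chrom_lengths / 1e6
    return pd.Series(trans_sum / length_mb, index=list(g.chrom_names), name="icf_density")


def micro_involvement(cmap: ContactMap, balanced: bool = True) -> pd.Series:
    """Per chromosome, the fraction of its trans contact mass whose partner
    is a microchromosome (0 where the chromosome has no trans contacts)."""
    g = cmap.genome
    obs = chrom_pair_observed(cmap, balanced=balanced)
    trans_sum = obs.sum(axis=1)
    micro_mass = obs[:, g.is_micro].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(trans_sum > 0, micro_mass / np.maximum(trans_sum, 1e-300), 0.0)
    return pd.Series(frac, index=list(g.chrom_names), name="micro_involvement")


def expected_icf(
    cmap_or_obs: ContactMap | np.ndarray,
    genome: BinnedGenome | None = None,
    null: str = "length",
    balanced: bool = True,
) -> np.ndarray:
    """Expected pairwise trans contacts under a uniform-interaction null.

    ``null="length"``: E_kl = T·(L_k·L_l)/Σ_{m<n}(L_m·L_n).
    ``null="marginal"``: the length products are replaced by products of
    observed per-chromosome trans sums (controls for coverage).
    The null redistributes, never creates, contacts: Σ_{k<l} E = Σ_{k<l} O.
    """
    if isinstance(cmap_or_obs, ContactMap):
        genome = cmap_or_obs.genome
        obs = chrom_pair_observed(cmap_or_obs, balanced=balanced)
    else:
        obs = np.asarray(cmap_or_obs, dtype=np.float64)
        if genome is None:
            raise ValueError("genome required when passing an observed matrix")
    n = genome.n_chroms
    if n < 2:
        raise ValueError("need at least two chromosomes")
    iu = np.triu_indices(n, k=1)
    total = obs[iu].sum()
    if total <= 0:
        raise ValueError("no trans contacts observed; expected ICF undefined")
    if null == "length":
        size = genome.chrom_lengths.astype(np.float64)
    elif null == "marginal":
        size = obs.sum(axis=1)
    else:
        raise ValueError(f"unknown null {null!r}")
    prod = np.outer(size, size)
    denom = prod[iu].sum()
    exp = total * prod / denom
    np.fill_diagonal(exp, 0.0)
    return exp


def oe_log2(
    observed: np.ndarray, expected: np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """log2((O+ε)/(E+ε)) per chromosome pair; diagonal NaN."""
    observed = np.asarray(observed, dtype=np.float64)
    expected = np.asarray(expected, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((observed + pseudocount) / (expected + pseudocount))
    np.fill_diagonal(ratio, np.nan)
    return ratio


def cluster_chromosomes(
    log2_matrix: np.ndarray,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, list[int]]:
    """Agglomerative clustering of chromosomes on rows of the log2 O/E
    matrix (diagonal imputed to 0). Returns the scipy linkage matrix and
    the deterministic leaf order."""
    rows = np.asarray(log2_matrix, dtype=np.float64).copy()
    np.fill_diagonal(rows, 0.0)
    if not np.all(np.isfinite(rows)):
        raise ValueError("log2 O/E matrix contains non-finite off-diagonal values")
    if rows.shape[0] < 2:
        raise ValueError("need at least two chromosomes to cluster")
    with warnings.catch_warnings():
        # rows of the (square, symmetric) log2 O/E matrix are the intended
        # observations; silence scipy's distance-matrix heuristic
        warnings.simplefilter("ignore", sch.ClusterWarning)
        linkage = sch.linkage(rows, method=method, metric=metric)
    leaves = sch.leaves_list(linkage)
    return linkage, [int(x) for x in leaves]


def dendrogram_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of micro vs macro values."""

    statistic: float
    pvalue: float
    mean_micro: float
    mean_macro: float
    n_micro: int
    n_macro: int
    test: str


def compare_groups(
    values: np.ndarray,
    classes: np.ndarray,
    test: str = "student",
) -> GroupComparison:
    """Two-sample t-test of micro vs macro values (positive statistic means
    micro > macro). ``test`` is "student" (pooled variance) or "welch"."""
    values = np.asarray(values, dtype=np.float64)
    classes = np.asarray(classes)
    micro = values[classes == "micro"]
    macro = values[classes == "macro"]
    if len(micro) < 2 or len(macro) < 2:
        raise ValueError(
            f"t-test undefined: {len(micro)} micro and {len(macro)} macro values"
        )
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    res = stats.ttest_ind(micro, macro, equal_var=(test == "student"))
    return GroupComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_micro=float(micro.mean()),
        mean_macro=float(macro.mean()),
        n_micro=len(micro),
        n_macro=len(macro),
        test=test,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float


def regress_density_on_length(
    densities: np.ndarray, lengths_bp: np.ndarray, log10_length: bool = False
) -> RegressionResult:
    """OLS of ICF density on chromosome length in Mb (optionally log10 Mb)."""
    y = np.asarray(densities, dtype=np.float64)
    x = np.asarray(lengths_bp, dtype=np.float64) / 1e6
    if log10_length:
        x = np.log10(x)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if np.isnan(r2) and np.ptp(y) == 0:
        r2 = 0.0  # constant response: nothing to explain
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        pvalue=float(res.pvalue),
    )


@dataclass
class TransSummary:
    """All chromosome-level trans statistics for one contact map."""

    genome: BinnedGenome
    per_chromosome: pd.DataFrame  # chrom, length, class, trans_sum, icf_density, micro_involvement
    observed: np.ndarray
    expected: np.ndarray
    log2_ratio: np.ndarray
    linkage: np.ndarray
    leaf_order: list[int]
    density_test: GroupComparison | None
    involvement_test: GroupComparison | None
    regression: RegressionResult
    regression_log10: RegressionResult

    def pairwise_table(self) -> pd.DataFrame:
        names = list(self.genome.chrom_names)
        rows = []
        for k in range(len(names)):
            for l in range(k + 1, len(names)):
                rows.append(
                    {
                        "chrom1": names[k],
                        "chrom2": names[l],
                        "observed": self.observed[k, l],
                        "expected": self.expected[k, l],
                        "log2_ratio": self.log2_ratio[k, l],
                    }
                )
        return pd.DataFrame(rows)

    def stats_table(self) -> pd.DataFrame:
        rows = [
            {
                "test": "icf_density_micro_vs_macro",
                "statistic": self.density_test.statistic if self.density_test else np.nan,
                "pvalue": self.density_test.pvalue if self.density_test else np.nan,
            },
            {
                "test": "micro_involvement_micro_vs_macro",
                "statistic": self.involvement_test.statistic if self.involvement_test else np.nan,
                "pvalue": self.involvement_test.pvalue if self.involvement_test else np.nan,
            },
            {
                "test": "density_vs_length_regression",
                "statistic": self.regression.slope,
                "pvalue": self.regression.pvalue,
            },
        ]
        return pd.DataFrame(rows)

    def newick(self) -> str:
        return dendrogram_newick(self.linkage, list(self.genome.chrom_names))


def trans_summary(
    cmap: ContactMap,
    balanced: bool = True,
    null: str = "length",
    pseudocount: float | None = None,
    linkage_method: str = "average",
    linkage_metric: str = "euclidean",
    test: str = "student",
) -> TransSummary:
    """Compute the full chromosome-level trans summary.

    ``pseudocount=None`` picks 0 for balanced input and 1 for raw counts
    (sparse raw toys can have empty pairs).
    """
    g = cmap.genome
    obs = chrom_pair_observed(cmap, balanced=balanced)
    exp = expected_icf(obs, g, null=null)
    if pseudocount is None:
        pseudocount = 0.0 if (balanced and cmap.balancing_weights is not None) else 1.0
    log2r = oe_log2(obs, exp, pseudocount=pseudocount)
    linkage, leaves = cluster_chromosomes(log2r, method=linkage_method, metric=linkage_metric)
    dens = icf_density(cmap, balanced=balanced)
    invol = micro_involvement(cmap, balanced=balanced)
    classes = g.chrom_class
    density_test = involvement_test = None
    if (classes == "micro").sum() >= 2 and (classes == "macro").sum() >= 2:
        density_test = compare_groups(dens.to_numpy(), classes, test=test)
        involvement_test = compare_groups(invol.to_numpy(), classes, test=test)
    per_chrom = pd.DataFrame(
        {
            "chrom": g.chrom_names,
            "length": g.chrom_lengths,
            "class": classes,
            "trans_sum": obs.sum(axis=1),
            "icf_density": dens.to_numpy(),
            "micro_involvement": invol.to_numpy(),
        }
    )
    return TransSummary(
        genome=g,
        per_chromosome=per_chrom,
        observed=obs,
        expected=exp,
        log2_ratio=log2r,
        linkage=linkage,
        leaf_order=leaves,
        density_test=density_test,
        involvement_test=involvement_test,
        regression=regress_density_on_length(dens.to_numpy(), g.chrom_lengths),
        regression_log10=regress_density_on_length(dens.to_numpy(), g.chrom_lengths, log10_length=True),
    )
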