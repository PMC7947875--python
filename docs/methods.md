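# Methods

## Data model and conventions

Genomes are binned at a fixed resolution with 0-based half-open bins; the
last bin of each chromosome may be short and is kept rather than dropped,
so toy genomes lose no sequence. A chromosome is classed *micro* iff its
length is strictly below a threshold (default 30 Mb, the avian convention;
a 50 Mb "reptile" preset reflects the natural length break seen in
non-avian reptile karyotypes). Contact maps are symmetric and stored
upper-triangular; all file formats are plain text (chrom.sizes TSV, sparse
triplets in bin-index or 7-column genomic form, bedGraph, BED), and
write→read round trips are lossless for integer counts.

## Balancing

Coverage bias is removed by iterative correction: per-bin weights
w are updated by w ← w / √(s/s̄), where s is the current reweighted row
sum, until all unmasked row sums agree within `tol` (default 1e-5) of
their mean, or `max_iter` (500) is reached — non-convergence is flagged,
not raised. Bins with zero marginal, or at/below the 0.02 quantile of
nonzero marginals, are masked with weight 0. For strictly positive
matrices this has the same fixed point (uniform marginals) as
Knight–Ruiz-style balancing; it is a balancing-target equivalent, not a
bit-exact reimplementation of any particular tool. Weights are finally
rescaled so the balanced total equals the raw total, keeping balanced
values on the scale of the input counts. Balancing weights transform as
w → w/c under a symmetric scaling of one bin's contacts by c (verified by
test), so the balanced matrix is invariant to per-bin coverage distortion.

## Interchromosomal statistics

Per-chromosome trans sums use balanced values by default (raw counts
remain available via `balanced=False`; the pseudocount for log₂ O/E
defaults to 0 on balanced maps and 1 on raw counts to avoid −∞ on sparse
toys). The uniform-interaction null distributes the total trans mass in
proportion to chromosome length products,
E_kl = T·L_k·L_l / Σ_{m<n} L_m·L_n. This is the literal meaning of
"uniform interaction" at the scale of genomic positions; an alternative
marginal-product null (E_kl ∝ trans_k·trans_l), which controls for
per-chromosome coverage, is available via `null="marginal"`. Both conserve
the total: Σ E = Σ O over pairs, exactly.

Chromosomes are clustered by average-linkage agglomeration on Euclidean
distances between rows of the log₂ O/E matrix (diagonal imputed to 0);
scipy's deterministic tie-breaking fixes the leaf order. Group comparisons
default to the pooled-variance Student *t*-test, with Welch available;
the regression of ICF density on length is OLS on length in Mb, with a
log10-length variant reported alongside for scale robustness.

## Compartment calling

Compartments are inferred from trans contacts only: cis blocks are masked
throughout. The trans observed/expected model matters. A single global
mean (available as `expected="global"`) leaves both chromosome-level
enrichment (micro–micro proximity) and per-bin radial coverage in the
signal; on territory-structured genomes the leading eigenvector then
tracks geometry, not chromatin state. The default `expected="chrom-pair"`
therefore models E_ij = m_i·m_j·B_kl, where m_i is bin i's mean trans
contact over valid partners and B_kl matches each chromosome-pair block's
expected total to its observed total. Note the full-map balance does not
make this term redundant: balancing equalizes cis+trans marginals, so
trans-only marginals still carry structure.

The O/E rows (centered by subtracting the null value 1) are correlated
over pairwise-complete observations; bins with fewer than 20 complete
pairs (relaxed automatically on tiny inputs) are dropped as NA, and at
least 10 usable bins are required. E1 is the eigenvector of the largest
eigenvalue of the correlation matrix, deterministically signed ("first
nonzero component positive") before orientation. Orientation flips E1 if
corr(E1, GC) < 0; when |corr| < 0.1 the sign is kept and the track is
flagged `orientation_ambiguous` — with an uninformative reference track
the A/B polarity is genuinely undecidable. Labels follow the sign of the
oriented E1; exact zeros and masked bins are NA. Per-chromosome A
proportions exclude NA bins from both numerator and denominator by
default (a `denominator="all"` variant divides by every bin), since on
sparse inputs NA-heavy chromosomes would otherwise be biased toward 0.

## 3D embedding

Contacts map to dissimilarities d_ij = c_ij^(−α) with α = 0.5 (a common
contact-to-distance exponent; configurable), rescaled so the median
finite distance is 1; zero-contact pairs are imputed at 1.5× the maximum
finite distance, which keeps never-touching bin pairs far apart without
dominating the stress. Embedding is metric MDS: classical (Torgerson)
scaling initializes, then SMACOF Guttman-transform iterations minimize
raw stress, which is non-increasing per iteration by construction (a
property the tests assert directly, alongside a cross-check against an
independent SMACOF implementation). A seeded 1e-9-scale jitter on the
initialization breaks exact symmetric degeneracies deterministically.
Reported stress is Kruskal stress-1. Coordinates are defined only up to
rigid motion and reflection; every downstream statistic (radial distance
from the centroid, per-chromosome centroids and radii of gyration,
territory overlap) is invariant to those transforms.

Territory overlap between chromosomes k and l is the fraction of k's bins
whose `k_neighbors` (default 10) nearest bins — among all bins, self
excluded — include at least one bin of l, symmetrized by averaging. With
neighbors drawn from all bins, a chromosome whose territory is isolated
has same-chromosome nearest neighbors only and overlap ≈ 0 against
everything, while interdigitating chromosomes approach 1; restricting
neighbors to other-chromosome bins would instead force every chromosome
to "overlap" whatever happens to be nearest, making isolation
unmeasurable.

## Synthetic nucleus

The generator is the package's ground-truth instrument. Geometry: macro
territory centers uniform on a shell at 0.75× the nucleus radius, micro
centers uniform in a ball of 0.35× the radius — planting "micro central,
macro peripheral"; each chromosome's bins follow a Gaussian random walk
(step SD = territory radius / 4) reflected at the territory boundary
(radius 0.5·L_Mb^(1/3) length units), giving intrachromosomal distance
decay without polymer dynamics. Compartments: A/B labels planted in
blocks of 10 bins, A with probability 0.9 on micros and 0.45 on macros;
A–A pairs get a ×1.5 contact boost (affinity s = 0.5). GC:
0.40 + 0.08·[A] + N(0, 0.01), clipped to [0,1]. Contacts: 2×10⁶ draws
from a multinomial over all bin pairs with propensity
(d+d₀)^(−γ), γ = 1, d₀ = 0.5. The default karyotype is two 80 Mb
macrochromosomes and six microchromosomes of 10–20 Mb at 1 Mb bins
(250 bins), chosen to keep the dense O(n²) propensity computation and the
full pipeline desk-scale (seconds) while leaving enough chromosomes per
class for group t-tests. All randomness flows through one seeded
generator; a fixed seed reproduces the output files byte for byte.

What the generator does *not* emulate: loops/TADs, cis compartment
checkerboards, restriction-site and mappability bias, cell-to-cell
variability, or any real karyotype. Passing recovery tests therefore
demonstrates that the statistics detect territory geometry and planted
compartment structure under distance-decay sampling noise — not that they
are robust to every artifact of real Hi-C libraries. One known
model-vs-nature gap: with this karyotype the fraction of a chromosome's
trans contacts involving a micro partner comes out slightly *higher* for
macros than micros (micros cannot partner with themselves and the micro
class is only ~36% of the genome), so the micro-involvement group
comparison is not a recovery target here, only a reported quantity.

## Pipeline

`run_pipeline` composes simulate-or-load → balance → trans statistics →
compartments (skipped with a warning if no GC track) → embedding →
summary. Every threshold appears as a named config key; the config is
echoed into the report for provenance, outputs are plain TSV/BED/Newick,
and a failed stage leaves partial outputs plus a `FAILED` marker naming
the stage. Determinism: the same config and seed reproduce all report
tables byte-identically (asserted in tests). Analysis runs at the input's
single binning; the 50 kb resolution used for compartment work on real
genomes is just the `bin_size` parameter — synthetic demos use 1 Mb to
stay O(n²)-friendly.
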