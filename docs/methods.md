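# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Kendall co-variation screen

Candidate partner genes are screened against each seed with Kendall's
tau-b over all samples.  The joint threshold is `tau > r_min` **and**
`p <= p_max` with defaults `r_min = 0.6`, `p_max = 1e-3`, where p is the
one-sided upper-tail null probability.

For tie-free data and `n <= 60` the null is exact.  Under H0 every ranking
of one variable against the other is equally likely, so the number of
discordant pairs D follows the inversion-count distribution: the number of
permutations of n items with exactly k inversions, computed by the
prefix-sum recurrence `c(n, k) = sum_{j=0..n-1} c(n-1, k-j)` in exact
integer arithmetic.  Since tau = 1 - 2D/m with m = n(n-1)/2,
`P(T >= t) = (# permutations with D <= floor((1-t) m / 2)) / n!`.
At the default design (n = 18) the tail at the screening threshold is
P(T >= 0.6) = 1.13e-4, i.e. the tau-screen already implies the p-screen
unless n is small.  Tied data fall back to the tie-corrected normal
approximation with a one-unit continuity correction on the S = C - D
scale; the exact path assumes distinct ranks, which FPKM data satisfy
almost surely.

The screen is one-sided (positive co-variation): the neighborhood concept
pairs a positive correlation threshold with a single p bound.  Correlations
are computed on FPKM as stored; Kendall is invariant to any strictly
monotone transform, so the choice only matters for the Pearson paths, which
keep raw FPKM as the default (matching how printed correlation matrices of
FPKM profiles are usually produced) with a `log2` switch.

## Pearson matrices and significance classification

Pairwise Pearson r across all samples for a gene set, classified by the
two-sided t test `t = r sqrt(df) / sqrt(1 - r^2)`.  `df = n - 2` is the
standard convention; a `df = n - 1` compatibility mode exists because
published worked examples sometimes quote n - 1 degrees of freedom for n
samples.  At n = 18 and alpha = 0.05 the critical |r| is 0.4555 (df 16)
vs 0.4438 (df 17); on the built-in 8-gene circadian example both
conventions produce the identical mask, which the suite asserts as a
regression property.  Per-gene *partner counts* are the number of
significant off-diagonal entries in the gene's row.

## Min/max neighborhood expansion

Given seeds S, evidence network E (scored, undirected) and co-variation
network C, the admissible non-seed nodes are:

* *covariation-supported*: a qualifying C-edge to at least one seed;
* *family-included* (optional, default on): same gene family as a seed or
  supported gene — family = fixed-length symbol prefix (default 3) or an
  explicit map.  Family mates never count toward coverage; they exist to
  keep biologically coherent paralogs available as connectors.
* *connectors*: within `max_path_len` (default 3) evidence hops of a seed.
  If no covariation support exists and family inclusion is off, only the
  seeds themselves are admissible and the result degrades to the largest
  seed-only evidence component.

The objective is lexicographic: maximize seeds inside one connected
component of the returned subgraph; then minimize node count; then edge
count; then sorted-node-name order.  Uncoverable seeds are reported
uncovered rather than allowed to break connectivity.  Two solvers:

* an exhaustive search over all connected node subsets (bitmask BFS),
  provably optimal, capped at 18 admissible nodes — also the test oracle;
* a Kruskal-style heuristic for larger instances: every seed starts as a
  component and the two components joined next are those connected by the
  cheapest path, cost = (new nodes, then edges) found by 0/1-weight
  Dijkstra; non-seed leaves are pruned afterwards.

Whenever the admissible instance has at most `exact_solver_node_limit`
nodes (default 14) the heuristic result is replaced by the exhaustive
optimum.  On random instances the heuristic matches the optimal
(coverage, size) in >= 95% of cases (measured by the acceptance suite);
the returned edges always form a deterministic lexicographic spanning
tree, so edge count equals node count - 1 and reruns are reproducible.
A weighted scalarization of the two objectives is deliberately not
offered: the lexicographic reading of "minimal connected neighborhood
with the maximum target genes" keeps results reproducible and
parameter-free.

## Enrichment

PPI edge enrichment uses a density null: expected internal edges =
(pairs in the set) x (global edge density), p = upper-tail Poisson.  This
is computable from the local edge file alone and is deliberately *not* a
degree-corrected null, so its p-values are not comparable to services that
condition on node degrees.  Term over-representation is the standard
hypergeometric upper tail with BH adjustment across tested terms.

## PCA, cluster assignment and half-plane tests

PCA is computed from the genes' Pearson correlation matrix, never the
covariance matrix: FPKM scale becomes irrelevant and the eigenvalues sum
to the gene count (asserted at run time).  Sample scores are standardized
expression projected on eigenvectors; each axis is sign-fixed so its
largest-magnitude loading is positive.

Seed genes are assigned to sample groups by correlating their
log2(FPKM+1) profile with each group's 0/1 indicator.  The log scale is
used because indicator tracking is a location effect and linear FPKM
correlations are dominated by single extreme samples under multiplicative
noise.  A gene whose top-two indicator correlations differ by less than
`margin` (default 0.35) receives the joint label of both groups
("A20/AD"-style).  The default margin is roughly 1.5x the sampling sd of
a correlation difference at an 18-sample design: below it, the top two
groups are statistically indistinguishable.

The half-plane test splits samples by the sign of their score on a chosen
axis (exact zeros go to the positive half and are flagged).  Variant
`binomial_per_sample` (default): p = P(Binomial(g, 1/2) >= m) for the
majority count m of a size-g group — e.g. all 6 of a group on one side
gives p = 2^-6 = 0.015625.  Variant `hypergeometric_split` conditions on
the observed half sizes: all 6 in one half of a 9/9 split of 18 gives
p = C(9,6)/C(18,6) ~ 4.52e-3.  Published bounds for such plots are often
ambiguous between constructions, which is why both are implemented and the
variant is always recorded in the result; the half is defined by the axis
score sign, not a fitted separating line, for reproducibility.

Agglomerative hierarchical clustering uses average linkage on
dissimilarity 1 - r (scipy linkage backend).

## Stand-in DEG caller

Welch's t on log2(FPKM + pseudocount), pseudocount 1.0 (stabilizes
fold changes of low expressors; configurable), two-sided, BH-adjusted over
all tested genes; genes all-zero in both groups are skipped; zero-variance
ties resolve to p = 1 when means are equal.  Welch rather than a rank test
because at n = 6 per group rank tests cannot reach the granularity BH
needs at FDR 0.05.  This caller exists for synthetic validation and as a
transparent fallback — it is *not* a reimplementation of count-model DE
tools, whose tables should be ingested via `iofmt.read_deg_table`.  A
table-wide minimum attainable q in an ingested table (a permutation-
resolution artifact of the producing tool) is treated as input data and
never recomputed.

## Synthetic data generator

Log2-FPKM of gene g in sample s:

    x_gs = mu_g + s_g a_g f_{m(g),s} + s_g delta_{g,G(s)} 1[s active] + eps_gs

one standard-normal latent factor f per module per sample, noise sd
sigma_g, FPKM = 2^x.  Antiphase members (sign s_g = -1) flip both loading
and shift, producing two anticorrelated sub-blocks.  Two same-phase
members of a shift-free module have population Pearson correlation
a^2/(a^2 + sigma^2).  The default sigma = 0.7 (log2) is a conventional
dispersion for bulk FPKM at this depth; the generator does not model
counts, library-size or batch effects — all downstream statistics are
correlation/rank/location-based and consume FPKM, so the count layer would
add parameters without exercising any additional code path.  Consequently,
passing recovery tests demonstrate correctness of the statistics under the
stated model, not robustness to count noise, outlier samples or
normalization artifacts in real data.

The default study fixture (scale 0.1, 3 groups x 6 samples, ~2000
background genes) plants:

* a 12-gene seed TF set split 6/3/3: a control-up cluster (a = 2), a
  subset-active AD-up cluster (active in 4 of 6 AD samples, a = 1) and a
  joint A20/AD-up cluster (a = 0.5), all with group shift delta = 4 log2
  units.  The shift was chosen once, by design, so that indicator-profile
  assignment separates the clusters reliably at n = 6 per group
  ("generator guarantees separability"); smaller shifts make the joint
  cluster statistically indistinguishable from its single-group neighbors
  at this sample size.
* an asymmetric pair of DEG modules at the 170:839 up:down shape (scaled),
  |delta| = 2, a = 0: these emulate a transcriptome-wide direction split
  spanning many unrelated pathways, not one co-expressed module, so no
  shared factor is planted.  A-priori power analysis at these conditions
  (Welch, n = 6, BH at 0.05 over ~2100 genes) gives per-gene power ~0.73,
  and the false-discovery share at FDR 0.05 inflates the minority (up)
  side by ~12% in expectation — the recovered ratio is therefore compared
  at a 15% tolerance.
* an 8-gene antiphase "circadian" structure (two anticorrelated 4-gene
  blocks, a = 1.5, contrast +-2.5 between control and affected groups)
  plus a maximum-score evidence hub from its first gene, emulating a
  curated local interactome for top-k neighborhood recovery;
* two marker genes at baseline log2(1000) and log2(800) FPKM (log-normal
  noise puts their expected sample means ~12% above those medians).

The evidence network is a planted partition: within-module pairs with
p_in = 0.9, background pairs with p_out = 5e-4, scores Uniform(0.4, 1).
All randomness derives from one integer seed via fixed offsets;
identical seeds give bit-identical bundles.

## Pipeline and determinism

Stages run in a fixed order (DEG filtering; direction/family summaries;
seed cluster assignment; per-cluster expansion requiring both evidence
connectivity and co-variation support; PPI/term enrichment; projections
with half-plane tests; report).  The order "assignment -> expansion ->
enrichment" is fixed by design where a figure-driven narrative could be
read either way.  Reports are JSON with sorted keys and explicit float
rounding at the boundaries, so identical config + seed reproduces the
bundle byte for byte.  Any stage failure aborts with the stage name; a
missing evidence network disables expansion/enrichment without touching
earlier statistics; an empty seed set completes the DEG stages and skips
the rest with an explicit notice.

## Problem sizes used in validation

The acceptance suite runs the fixture at scale 0.1 (~2100 genes) with 20
independent draws for recovery statistics, 200 random instances for the
expansion heuristic-vs-oracle sweep, full permutation enumeration of the
Kendall null up to n = 8, and 50 background-only draws of 2000 genes for
the null false-positive fraction.  These sizes give stable Monte-Carlo
estimates (binomial se < 2% on every rate) while keeping the whole suite
fast on one CPU.

## Known limitations

* The exact Kendall path requires tie-free data; heavy ties (e.g. many
  zero-FPKM genes) route to the normal approximation, which is less
  accurate in the far tail at small n.
* The min/max heuristic is not optimal above the exact-solver limit;
  measured size agreement is ~98% on random instances but adversarial
  graphs can do worse.
* The Poisson PPI null ignores degree structure; hub-heavy sets will look
  more enriched than under a degree-corrected null.
* Family = fixed-length prefix is a heuristic for curated family
  abbreviations; an explicit family map should be supplied when available.
* The q-value floor of ingested DEG tables is metadata, not a statistic
  this package can verify.
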