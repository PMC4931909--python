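# Methods

This note documents the models, the tunable parameters, the synthetic-data
generators, and the numerical and design choices behind `tcellsig`.

## The principal-axis model of activation

The expression input is a genes × samples matrix of RPKM values with an
ordered set of condition labels (increasing nominal TCR signal strength) and
replicate groupings. The working model is that across such a series the
dominant mode of variation is a single activation axis: genes respond with
approximately proportional (graded) changes, so the sample cloud is close to
a line in gene space.

`fit_pc1` computes that axis as the first right-singular direction of the
gene-wise mean-centered matrix, with samples as observations. Two choices
are deliberate:

* **Untransformed RPKM, no unit-variance scaling** (a `scale` switch
  exists). On raw RPKM the axis is dominated by highly expressed genes,
  which is what makes the downstream reference-expression floor (below)
  meaningful rather than redundant. Log-transforming or standardizing would
  change the gene weighting entirely; neither is assumed.
* **Sign convention:** the mean PC1 score of the reference (first) condition
  must not exceed that of the highest-signal condition, so scores increase
  with activation; an exact tie falls back to making the largest-magnitude
  loading positive. This makes fits deterministic and comparable.

`variance_explained` is the PC1 share of total centered variance. On
noiseless rank-1 data it is exactly 1; on the default synthetic series it is
≈ 0.95 because the digital gene class adds a second, correlated mode.

## Variable-gene filter

`filter_variable_genes` keeps genes whose maximum condition mean exceeds
10 RPKM (strict) and whose max/min condition-mean ratio is at least 2. The
ratio uses a pseudocount of 1 RPKM in the denominator — below the expression
floor, so it only matters for near-zero genes, which it keeps finite.
Replicates are collapsed to condition means before filtering.

## Signature derivation

`derive_signature(replicates, combined)` proceeds:

1. Fit PC1 on each replicate dataset and on the combined dataset over the
   shared gene universe.
2. Remove genes with reference-condition expression below `min_ref_rpkm`
   (default 100 RPKM, measured in the combined matrix) or whose
   reference-condition level varies across the replicate datasets with a
   standard deviation above `max_ref_cv` (default 0.20) times the reference
   level. This is the only reading of the replicate-consistency rule that is
   computable from the stated inputs; with two replicates the std estimate
   is itself noisy (see Limitations).
3. Take the top and bottom `fraction` (default 0.10) of the *remaining*
   genes in every fit — filter first, deciles of the remainder — and
   intersect the k+1 decile sets (each replicate plus the combined fit).

Decile extraction sorts by loading with lexicographic gene-id tie-break, and
caps each set at `min(ceil(fraction·n), n // 2)` so top and bottom sets are
disjoint for any fraction ≤ 0.5. An empty intersection is a warning, not an
error.

## Activation scoring

`score_samples` restricts the model to genes present in the scored matrix
(missing genes are dropped and reported, never imputed; > 50% missing is an
error), mean-centers gene-wise, and takes the dot product with the loadings.
Centering defaults to the mean **of the samples being scored**, because the
score is routinely applied to external datasets (other platforms) whose
absolute levels are not comparable to the training data; `center="model"`
uses the stored training means, and `center="none"` accepts pre-centered
input. Scaled scores divide by the maximum absolute raw score, so the most
extreme sample sits at ±1 and all scores lie in [−1, 1]. Consequently the
score ranks samples within one invocation only; `rank_experiment_groups`
refuses nothing but should be called once per experiment.

A numerical detail: projections are computed with an explicit axis
reduction, not a BLAS matrix product, because BLAS blocking can give
bit-different results for bit-identical samples and thereby break exact ties
that the rank-based contracts rely on.

## Permutation trend test

For a gene group G and conditions a, b, the statistic is the mean over G of
(condition-b mean − condition-a mean) per gene. The null redraws
`n_permutations` (default 10,000) gene groups of size |G| uniformly without
replacement from the full gene universe, a normal is fitted to the null
statistics, and the two-tailed p is 2·Φ(−|z|), floored at the smallest
positive float; the empirical permutation rank p is reported alongside.
Sampling is without replacement because the object being randomized is a
gene *group*. On an 8-gene universe with size-2 groups the null has only 28
support points; the documented accuracy of the normal approximation there is
0.2 absolute on the two-tailed p (≈ 1/√28), and the test suite holds it to
that bound against exact enumeration. Under a signal-free synthetic matrix
the fraction of p < 0.05 over random groups is 0.05 to within ±0.02.

`compare_group_expression` is the paired companion for two matched datasets
(e.g. with and without MEK inhibition): per-gene means are compared with a
paired two-sided Student's t test, optionally repeated within RPKM strata
(`stratify_by_expression` bins by mean RPKM with half-open bins).

## Enhancer analytics

House conventions, applied uniformly: 0-based half-open coordinates;
*overlap* means ≥ 1 shared bp; promoter and gene-body windows are
strand-aware; a peak belongs to the gene with the nearest TSS measured from
the peak midpoint, equidistant ties going to the smaller coordinate.

* `threshold_peaks`: keeps peaks with ≥ 40 normalized tags (inclusive).
* `overlap_table`: thresholds every set, then counts, for each ordered pair
  (i, j), the set-i peaks overlapping any set-j peak (each counted once);
  the diagonal holds thresholded totals. The matrix is directional — both
  conventions of "overlap of i with j" are present as (i, j) and (j, i).
* `classify_fold_change`: up iff (tags_b + 1)/(tags_a + 1) > fold
  (strict, default 2); down mirrored. The pseudocount of one normalized tag
  keeps zero denominators finite.
* `aggregate_tags_at_sites`: sums per-base coverage in ±1,000 bp (default)
  around site centers, per condition, reporting totals, per-site means and
  the site-aligned mean profile.
* `spreading_ratio`: body density / promoter density, with promoter =
  TSS ± 1,000 bp and body = TSS+1,000…TSS+4,000 bp downstream (truncated at
  the gene end with a warning; an empty promoter gets pseudo-density 1e-6).
  Densities are per-bp, so uniform coverage gives exactly 1 and the ratio is
  invariant to depth scaling. A profile spread uniformly over the first
  4,000 bp of the gene scores ≈ 2 (its promoter window is only half
  covered), a focal TSS peak scores ≪ 1.
* `proximity_enrichment`: assigns every peak to its nearest TSS, forms the
  2×2 table (peak in subset?) × (nearest gene in signature?), and applies
  Pearson's chi-squared without continuity correction (df = 1); an expected
  cell below 1 is an error recommending an exact test rather than a silent
  approximation.
* `classify_digital_analog`: *digital* = minimum treated-condition mean at
  least `induction_fold` (default 4) times the reference mean (pseudocount 1
  when the reference is 0) **and** coefficient of variation across treated
  means ≤ `max_treated_cv` (default 0.15); *analog* = treated means strictly
  monotone in condition order with total fold ≥ 2; digital wins ties. The
  published description of the digital cluster is qualitative; these two
  thresholds are this package's own operationalization and are exposed as
  parameters. The ranking score `induction_fold × (1 − treated_cv)` orders
  genes for a "top N most induced / most consistent" cluster.

## Super-enhancer calling

`stitch_peaks` merges same-chromosome peaks transitively when the gap is
≤ `stitch_distance` (12,500 bp by default — the conventional stitching
distance of rank-based super-enhancer calling; exposed as a flag), summing
tags per condition. Stitching is idempotent and conserves tag totals.

`find_se_threshold` sorts region scores ascending, min-max normalizes both
axes to [0, 1], and finds the point where a line of slope 1 is tangent to
the curve from below: the (last) global minimum of y − x. On a convex curve
this is exactly where the discrete tangent crosses one. The global-minimum
form is used instead of a local slope scan deliberately: single-step slopes
are noisy, and either a tied pair of scores inside the super-enhancer block
or one large order-statistic gap in the background tail can move a local
rule by many ranks, while the global contact point is stable. Analytic
checks: on y = x² the threshold lands within ±1 rank of the tangent point at
x = 0.5 (and converges to (1/k)^(1/(k−1)) on y = x^k); an exactly linear
curve has y − x ≡ 0 and, by the last-minimum tie-break, yields zero
super-enhancers; all-equal scores yield zero with a warning.

`call_super_enhancers` ranks regions descending by total tags (coordinate
tie-break, fully deterministic), applies the threshold, and flags
`is_super = rank ≤ threshold_rank`. No TSS exclusion is applied by default;
`exclude_tss_window` (with a gene annotation) removes promoter-proximal
peaks before stitching. `compare_se_sets` marks a super region *shared* when
it overlaps (≥ 1 bp) a super region of the other call, reporting counts from
both sides, and `se_group_gain` splits shared regions by nearest-gene
membership in the signature set and compares per-region tag gains with a
two-sided Welch t test (refused, with gains still reported, when a split has
a single region).

## Synthetic data: what it emulates, and what it does not

`generate_expression` plants four gene classes over an ordered condition
series with per-condition signal strengths s_c ∈ [0, 1] (default
(0, 0.45, 0.55, 0.60, 1.0) — the middle near-tie mimics a high-dose/
low-affinity vs low-dose/high-affinity pair that reaches similar activation):

| class        | mean in condition c                | default share |
|--------------|------------------------------------|---------------|
| analog_up    | b·(1 + (e−1)·s_c)                  | 10% |
| analog_down  | b·(1 + (e−1)·(1−s_c))              | 10% |
| digital      | b in reference, b·e elsewhere      | 5% |
| null         | b                                  | 75% |

with per-gene baseline b log-uniform on (100, 1000) RPKM — the matrix
emulates the highly expressed, variable part of a transcriptome, which is
where the signature lives — except digital genes, which draw b from
(5, 50) RPKM because digital-response genes start from a low, off-like level
in the unstimulated control. Effect sizes e are log-uniform on (2, 8).
Noise is multiplicative log-normal with mean 1 and coefficient of variation
`noise_cv` (default 0.10); replicate columns are independent draws. With
`noise_cv = 0` the matrix equals the closed-form means exactly. A log-normal
noise model was chosen because expression is positive with roughly
mean-proportional dispersion; no particular noise law is assumed by the
downstream methods.

`generate_peaks` lays peaks on a 30 kb grid (with a 13 kb end margin) so
that distinct elements never overlap and background peaks never stitch
together; background tags are log-normal (median 60, σ_log 0.4) hard-clipped
at 120, gain peaks multiply the capped base by `gain_fold` (> 2 enforced) in
the stimulated condition, and each planted super-enhancer region receives 10
peaks with log-normal tags (median 250) within an 8 kb span — under the
12.5 kb stitch distance, so each planted region stitches to exactly one
region with total tags far above the background. The clip and the
no-stitch margin are requirements of a planted-truth test bed: an unbounded
background upper tail, or occasionally stitched background pairs, is itself
steep enough on the normalized rank curve to cross the slope-1 tangent —
faithful to real landscapes, but it would make "false positive" undefined
for recovery testing.

`generate_tag_profile` returns TSS-anchored Poisson coverage for three
shapes: `uniform` (rate = depth everywhere), `focal_tss` (Gaussian, sd
250 bp, > 95% of expected tags within ±500 bp), and `spread_body` (uniform
over the first 4,000 bp downstream).

Deliberately **not** emulated: per-cell (responder-frequency) structure —
the digital class is planted at the population level, which conflates
responder frequency with per-cell level; library-size or GC biases;
correlated gene modules beyond the planted classes; input-subtracted or
replicate-discordant peaks. Passing tests therefore demonstrate correctness
of the computations under the stated statistical structure, not robustness
to every artifact of real sequencing data.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the standard series at 3,000
genes × 10 samples (100 seeds for axis recovery, 20 for signature
recovery), 1,000-interval oracle comparisons, a 2,020-region super-enhancer
landscape, and 10,000-permutation nulls — sizes at which every stochastic
summary is stable to well under its asserted tolerance while the whole suite
completes in well under a minute of compute. Every generator and test takes
an explicit seed (`numpy.random.default_rng`, one stream per call, no global
state); CLI runs write a JSON manifest (parameters, seed, versions, no
timestamps) and rerun byte-identically.

## Known limitations

* **Signature recovery is capped by the decile arithmetic.** With planted
  analog fractions equal to the decile fraction (10% each), the top/bottom
  sets of the *filtered* universe contain ~271 slots for 300 planted genes,
  and the two-replicate consistency filter falsely drops ~4.5% of genes
  (the sample std of two draws exceeds twice the true σ with probability
  P(|Z| > 2) ≈ 4.6% when `max_ref_cv` is twice the noise CV). Median
  recovery of planted analog genes therefore plateaus near 86–88%, a
  property of the filter-then-decile design at these proportions, not of
  the implementation; planting rarer signal classes or adding replicates
  raises it.
* The normal-approximation p of the trend test is unreliable for very small
  gene universes (documented bound 0.2 at 28 support points); use the
  reported empirical p there.
* Tag counts are trusted as depth-normalized; only an explicit helper
  (`rescale_tags`) rescales raw counts.
* Super-enhancer comparison counts depend on the ≥ 1 bp sharing rule; when
  regions split or merge between conditions the two shared counts differ,
  and both are reported rather than reconciled.
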