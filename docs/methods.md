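# Methods

This note records the models, conventions and design choices behind each
stage of cistrio, and what the synthetic-data tests do and do not
establish about real data.

## Coordinates and overlap arithmetic

All intervals are 0-based half-open `[start, end)` (BED convention); the
center of a site is the floor midpoint. Chromosome names match by
literal string equality — `chr1` and `1` are different until explicitly
normalized. Two intervals overlap when they share at least `min_bp`
basepairs (default 1). The default is deliberate: published overlap
analyses rarely state their threshold, so the predicate is a parameter
rather than a constant. Overlap counting uses a per-chromosome sorted
sweep (candidate windows bounded by a start-sorted array and a prefix
maximum of ends); the test suite holds it to an all-pairs brute-force
oracle on hundreds of random instances.

The cofactor screen reports both overlap-coefficient conventions found
in practice: `count / |anchor|` (asymmetric, the default sort key) and
`|merged peaks touched by both| / |merged union|` (symmetric). Ties in
the ranking are broken by factor label so output order is deterministic.

## Binned density

`binned_density` extends each site ±`flank` (default 2,000 bp) from its
center and splits the window into `2*flank/bin_width` half-open bins
(default 40 × 100 bp). A "tag" is a single basepair position per read
(5′ end, optionally shifted at load time; shift and extension are not
modeled because the fragment model of the source libraries is unknown —
the shift is a recorded parameter instead). Counts are scaled by
`1e7 / total_mapped`: reads per 10 million mapped reads per bin. Two
invariances pin the unit down: doubling tags and library size together
changes nothing, and at fixed tags the density is linear in
`1e7 / total_mapped`. Windows running below position 0 are clipped with
zero-filled bins (logged, not an error). bedGraph input is supported by
treating step values as expected tags per bp (coverage × overlap);
exact tag input is preferred.

## S-codes and NMF

`classify_combinations` assigns each anchor site one binary code over
the caller's factor order; the order is echoed in every output to
prevent silent bit reordering. Membership is Boolean — two overlapping
peaks of the same factor set the bit once. Codes partition the anchor
set; coverage by cardinality (how many sites are bound by 0, 1, …, k
factors) always sums to 1, and the per-factor marginals of the codes
must equal independent overlap counts (tested).

`nmf_binding` is a multiplicative-update Frobenius NMF written in-house
because the surrounding analysis relies on a per-iteration error history
with guaranteed monotone non-increase, which library implementations do
not expose. Initialization is seeded nonnegative-random, scaled by
`sqrt(mean(V)/rank)`; `n_init` restarts guard against poor local minima
and the best factorization is returned, so results are deterministic
given the seed. The default rank (3, the number of factors in the
motivating analysis) and the input scaling are exposed parameters, not
claims about the original analysis, which did not state them.

## Super-enhancer screen

Stitching merges constituents within 12,500 bp; constituents whose
center lies within ±2,000 bp of a TSS can be excluded first. Both
numbers follow the cited ROSE convention and are config-exposed. Region
signal is the summed normalized signal over constituents (not the
stitched span), with optional control subtraction floored at zero.

The cutoff: signals are rank-sorted, rank and signal are min-max scaled
to [0, 1], and the super-enhancer boundary is where a line of slope 1 is
tangent to the curve. We compute the tangency point as the argmax of
`scaled_rank − scaled_signal` — the point farthest below the diagonal.
For a convex curve this is identical to "the first point whose slope
exceeds 1" (on `y = x²` both give cutoff 0.25 at rank 0.5), but the
global form is robust on empirical curves, where a single large spacing
between consecutive order statistics near either end of the
distribution can fire a local slope scan spuriously. Ties take the
last (highest-signal) index; flags are invariant under positive affine
rescaling of the signals. Curves that never dip below the diagonal
(linear or concave — no elbow) return an empty super set with a
warning; all-equal signals are an error.

Nearest-gene assignment is by region center to TSS distance, ties
broken by lexicographic gene name; regions on chromosomes absent from
the TSS table are left unassigned and logged.

## Perturbation classification

Per-site signal is computed over each site's own span (a fixed-window
mode exists). `log2fc = log2((kd + pc) / (ctrl + pc))` with pseudocount
0.5; sites are weaker below −log2(1.5), stronger above +log2(1.5),
unchanged between. The threshold and pseudocount are not taken from any
published split — they are defaults that produce a three-way partition
with a wide unchanged band, and both are stamped into every output.
Exact symmetry under condition swap and monotonicity of the weaker and
stronger fractions in the threshold are tested invariants. Peak-level
loss between conditions is computed on self-merged sets so counts refer
to non-redundant peaks.

## Survival stratification

E-codes: bit = 1 iff expression is strictly above the cohort mean for
that gene (a tie codes 0). Groups below `min_group_size` (default 5)
are flagged for exclusion and logged, never silently dropped — the
threshold is an assumption, as published analyses typically remove
"too small" strata without stating a rule. Kaplan–Meier estimation and
the log-rank test are delegated to lifelines behind this package's
interface; a permutation-mode log-rank (label shuffling, add-one
p-value) is available for small samples where the χ² approximation is
doubtful. The product-limit output is checked against a hand-worked
5-subject table, and the asymptotic p-value against permutation nulls
and a uniformity KS test under a null generator.

## The synthetic-data generator

The generator is the package's study design, not a convenience fixture.
Defaults (chosen once, as the designed conditions):

* genome: 3 chromosomes, 200 Mb total; 20,000 latent sites, uniform
  with a 1 kb minimum gap (so emitted peaks of distinct sites cannot
  overlap by accident); peak widths ≈ N(300, 60²) bp, floored at 50;
  per-factor center jitter N(0, 30²) bp.
* co-occurrence over (GATA3, NR2F2, FOXA1):
  `111=.25, 110=.22, 101=.08, 011=.06, 100=.15, 010=.07, 001=.02,
  000=.15` — cardinality split 25 / 36 / 24 / 15 % with factor marginals
  70 / 60 / 41 %.
* tags: background 0.05 per bp genome-wide plus Poisson site
  enrichment, mean 30 tags per site at multiplier 1, placed with a
  truncated-normal kernel (sd = quarter site width; any unimodal kernel
  satisfies the recovery tests). Anchor enrichment is graded by
  cardinality (1×, 2×, 4×, 8×), so co-bound classes carry stronger
  central signal. `total_mapped` is the realized tag count, as in a
  real library; the dominant background keeps the library-size shift
  between conditions small (≈ 0.1 in log₂), as in real ChIP-seq where
  most reads are not in peaks.
* knockdown: anchor tag rate ×0.25 at every site whose code sets the
  NR2F2 bit (60% of sites under the default design).
* activity-mark intensity: gamma body (shape 20, scale 0.1) for 95% of
  sites and a Pareto tail (shape 2, scale 15) truncated at 60 for the
  rest. The truncation is deliberate: with an unbounded heavy tail the
  slope-1 tangency lands *inside* the tail whenever the realized
  maximum is extreme, so no cutoff rule of this family can recover the
  full planted tail; a bounded dynamic range (as a finite genome
  imposes) keeps the elbow at the body–tail junction.
* cohort: 400 patients, fair-coin bits per gene, expression = 8 + 3·bit
  + N(0, 0.5²) (mean-threshold encoding then recovers planted codes for
  ≥ 99% of patients); exponential event times with hazard
  0.1 · 3^(low bits / 3) — hazard ratio 3 between the all-low and
  all-high codes — and independent exponential censoring at rate 0.05.

What the generator does **not** emulate: mappability and blacklist
artifacts, GC and fragment-length biases, copy-number variation,
correlated replicate structure, peak-width/intensity coupling,
non-exponential hazards, and covariate-dependent censoring. Passing the
recovery tests therefore shows the analysis code reads back what its
own model plants at realistic scales — it does not certify performance
on any real cistrome.

## Problem sizes and determinism

The default test and acceptance runs use the design's own scales:
20,000 sites for classification and screening, 10,000 for the knockdown
comparison, 30,000 for peak loss, 6,000 regions for the super-enhancer
screen, 5,000 sites for cross-condition correlation, 500/200 cohort
replicates for null calibration and power. The end-to-end demo defaults
to 2,000 sites on a 75 Mb genome. All randomness flows through
`numpy.random.SeedSequence` children of a single seed; identical
config + seed reproduces every output byte-for-byte (timestamps are
confined to run manifests).

## Known limitations

* Overlap counting is exact but O(candidates) per anchor interval in
  the worst case; for whole-genome inputs far beyond ~10⁶ intervals an
  indexed backend would be preferable.
* The bedGraph pathway computes expected counts, so Poisson-level
  statements (e.g. fold-change noise) are only exact for tag input.
* The NMF is a plain Frobenius factorization; no sparsity or
  orthogonality regularization.
* The log-rank test is asymptotic by default; use the permutation mode
  below ~30 events per group.
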