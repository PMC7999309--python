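# Methods

## Scope and data model

The pipeline analyses a nonnegative protein x sample abundance matrix
(label-free LC-MS quantification: summed MS1 peak areas), a binary sample
grouping (case vs. control), and optionally a scored protein/cytokine
interaction edge list. Missing matrix entries represent proteins not
quantified in a sample; they are carried as absent values (NaN) end to
end, except where a stage's mathematics requires a complete vector (see
ordination). All exchange formats are plain tab-delimited text or JSON so
runs are diff-able.

## Two-step normalization

Step 1 divides each protein row by `f_i = mean_i / median_over_i(mean_i)`;
step 2 divides each sample column of the adjusted matrix by
`g_j = median_j / overall_median`. Both statistics are taken over present
values only. The steps are exact projections: after step 1 every protein
mean equals the original median of protein means, after step 2 every
sample median equals the pre-step overall median, and the whole map is
equivariant under global rescaling. These identities are the invariants
the tests assert (relative tolerance 1e-9; the looseness only absorbs
floating-point rounding).

Choices worth stating because results depend on them:

* Means and medians **skip missing values**. Treating absences as zeros
  would drag protein means and sample medians toward zero for
  sparsely-observed proteins and distort every factor; skipping is the
  conservative reading when the upstream handling is unknown.
* Zeros are legitimate measurements and do enter the statistics. A protein
  or sample whose factor would be undefined (all-missing, zero mean/median)
  aborts the run with the offending identifier — degenerate input should be
  visible, not silently dropped.
* Even-length medians are midpoints of the central pair (the conventional
  definition); factor values depend on this.

## Differential abundance and pi-score

Per protein with at least two present values per group (those with fewer
are reported in a skipped list, since the variance estimate needs two
points): Welch's two-sided unequal-variance *t*-test on normalized
abundances, and the effect size `log2FC = log2(mean_case / mean_control)`
using arithmetic group means (ratio-of-means, the common label-free
convention; an optional pseudocount guards against zero means, default 0).
The pi-score `pi = log2FC * (-log10 p)` ranks proteins by joint effect and
significance; classification uses a strict threshold, `|pi| > 1` by
default. Degenerate tests are resolved deterministically: two constant
equal groups give (t=0, p=1); constant unequal groups give an infinite
statistic with p clamped to the smallest positive float, with a warning.
A Benjamini–Hochberg q column is included for reference but deliberately
never used for classification — the pi-score operates on raw p-values and
adding a correction would change the method being implemented. The volcano
export flags the top-k (default 10) proteins per class by |pi|, ties broken
by smaller p then identifier order.

## Ordination and PERMANOVA

Bray–Curtis dissimilarity is computed over proteins with missing values
**as zeros** (the single supported policy: a dissimilarity needs complete
vectors, and absence-of-quantification maps naturally to absence of
signal). PCoA is classical scaling — Gower-center `-d^2/2`, symmetric
eigendecomposition, coordinates scaled by the square root of positive
eigenvalues. Negative eigenvalues (Bray–Curtis is non-Euclidean) are
reported untouched; no Cailliez/Lingoes correction is applied, so the
eigenvalue spectrum is transparent. Explained proportions are over the
positive-eigenvalue total.

PERMANOVA uses the one-way pseudo-F
`F = (SS_between/(a-1)) / (SS_within/(N-a))` with sums of squared
distances. For two groups, when `C(N, n1)` distinct relabelings fit in the
permutation budget the null is enumerated exhaustively and
`p = (#relabelings with F >= F_obs) / #relabelings` (the observed labeling
is one of them, so p >= 1/#relabelings and the test is exact). Otherwise
relabelings are sampled uniformly with a seeded generator and
`p = (1 + #extreme) / (1 + n_permutations)`, which never returns zero. An
infinite observed F (zero within-group scatter) counts only infinite
permuted F values as extreme. At the default design — 12 samples, 5 vs. 7,
999 permutations — `C(12,5) = 792 <= 999`, so default runs are exhaustive
and their p-values are deterministic.

## Cytokine inference

The panel specification (`TGFb, TNF, IFN, IL1-40, CXCL1-16, CCL1-27`)
expands to 86 identifiers; node matching is case-insensitive with an
optional alias table (e.g. TGFB1 -> TGFb), and `IFN` is treated as a
single identifier rather than an interferon family. Edges must exceed
combined score 0.4 strictly; cytokines need at least five filtered
connections to significant proteins. The per-class enrichment is the
double ratio `e_d(c) = (k_d(c)/T_d) / (k_total(c)/T_total)`: the
cytokine's connection share of class d, normalized by its share of all
significant proteins. Two class-total definitions are offered behind one
switch because either is defensible: `protein_count` (T_d = number of
significant class-d proteins; the default, which makes the fold-connection
ratio a class-size-normalized connection ratio) and `edge_count`
(T_d = filtered protein-protein edges incident to the class). The
fold-connection ratio `e_case/e_control` is reported as +inf when a
cytokine has case connections but no control connections — capping it
would hide exactly the behavior the ranking looks for, so raw counts are
emitted alongside. Network decoration sizes significant proteins by |pi|
and colors proteins `pro` if they touch any pro-inflammatory enriched
cytokine, `anti` if they touch only anti-inflammatory ones (pro takes
precedence on mixed wiring). The default classification table ships with
IL6 and TNF pro-inflammatory and IL10 anti-inflammatory and is meant to be
overridden per study.

## Synthetic data generator

The generator emulates the target study design, not any particular
dataset: `log2 a_ij = base + b_i + s_i g_j + eps_ij` with per-protein
baselines `b_i ~ N(0, protein_sd)`, planted signed effects `s_i` on
`round(frac_diff * n_proteins)` proteins (half up in cases, half down, odd
counts favoring up), and noise `eps ~ N(0, noise_sd)`. Defaults: 2000
proteins, 5 cases vs. 7 controls, 5% differential at |log2FC| = 2,
`base_log2_mean = 20` (raw MS1 areas of ~1e6), `protein_sd = 2` (several
orders of magnitude between proteins), `noise_sd = 0.5` (~40% CV,
realistic for label-free quantification of small cohorts), 10% missing.
Missingness is Bernoulli per cell in `random` mode; in
`intensity_dependent` mode the missing probability is a logistic function
of log2 abundance with its midpoint calibrated by bisection so the
marginal rate matches — the missing-not-at-random regime typical of LC-MS.
If masking would empty a row or column, the brightest cell is restored so
every protein and sample stays observable.

The network generator wires each (cytokine, protein) pair independently:
probability `p_planted` (default 0.8) for planted-cytokine-to-case-protein
pairs, `p_base` (default 0.05) otherwise, with uniform scores on
(0.15, 0.999), mimicking STRING combined-score ranges. Planted defaults
are IL6/TNF (pro-) and IL10 (anti-inflammatory).

What the simulation does **not** emulate: peptide-to-protein roll-up and
shared peptides, correlated protein modules (all proteins are independent
given the group), batch/run-order drift, heavy-tailed contamination, or
real interaction topology (no protein-protein edges, no degree
heterogeneity beyond the planting). Passing recovery tests therefore shows
the chain is correct and well-calibrated under its stated model, not that
real studies of this size have comparable power; in particular the
false-discovery proportion at |pi| > 1 with 5 vs. 7 samples sits near 0.25
even in simulation, a property of thresholding raw-p pi-scores in small
cohorts.

## Numerical and reproducibility choices

* One run seed feeds named `SeedSequence` substreams per stage
  (abundance simulation, network simulation, PERMANOVA), so stages re-run
  in isolation match the full run; derived seeds stay below 2^31.
* `run_pipeline` re-reads each intermediate file it writes before passing
  data downstream: the text file is the source of truth, making
  stage-at-a-time and run-all outputs byte-identical (in-memory floats and
  their shortest-decimal round-trips can differ in the last ulp).
* p-values of 0 (underflow) are clamped to the smallest positive float
  with a warning before entering `-log10`.
* PCoA's positive-eigenvalue cutoff is `max|eig| * n * eps`, scaling the
  tolerance with the spectrum.
* Validation problem sizes (e.g. 400 effect-free datasets of 80 proteins
  for the PERMANOVA null calibration; 1000-protein recovery runs) were
  chosen to make the Monte-Carlo tolerances tight while keeping the whole
  suite fast on a laptop.

## Known limitations

* Only two-group designs; no covariates, no paired tests, no multivariate
  dispersion test accompanying PERMANOVA.
* Only Bray–Curtis; other dissimilarities would need their own missing-value
  policy.
* The enrichment score's denominator semantics are a documented
  interpretation (two variants provided) rather than a canonical formula.
* No live STRING queries; the edge list is an input.
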