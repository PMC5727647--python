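# Methods

## Statistical model and procedure

The unit of analysis is a *coordination profile*: for a panel of G genes in
one sample group (a tissue × condition cell), the vector of all C(G, 2)
pairwise Pearson correlation coefficients, in canonical (panel-index) order.
For the default 7-gene DNA methylation enzyme panel this is 21 values.

**Pairwise correlation.** Each pair's r is the sample Pearson coefficient on
pairwise-complete observations (missing values are dropped per pair, so n
may differ across pairs within a panel). The two-sided p-value comes from
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. A pair with fewer than 3
complete observations, or a constant series, is an *error*, never r = 0:
silently reporting zero correlation would fabricate evidence of no
association.

**Multiple testing.** Benjamini–Hochberg step-up adjustment is applied
within one group's C(G, 2) pairs — the family is the panel in that group,
not a global family across tissues, matching how per-tissue correlation
tables are corrected in practice. The implementation delegates to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`; the test suite
cross-checks it against an independent hand-written step-up oracle on
random p-vectors.

**Significance convention.** A pair is called *significantly positive* when
r > `r_threshold` (default 0.3) **and** its adjusted p < `alpha` (default
0.05). The conjunction of an effect-size cue and an FDR-controlled p-value
is this package's explicit choice; both thresholds are overridable, and the
call can be switched to raw p-values (`use_adjusted=False`) since correlation
tables are sometimes screened that way.

**Differential coordination.** With matched panels for the same tissues
under two conditions, each pair contributes per-tissue difference values
d_i = r_normal,i − r_tumor,i. The summary test is a two-sided paired t on
the d_i (df = N−1), applied to the correlations themselves rather than
Fisher-z transforms — the transform variant (`fisher_z=True`) exists but is
not the default because r is the quantity displayed and compared downstream,
and at panel sizes of interest the transform changes little while making
effect sizes harder to read. Significance tiers use strict cutoffs
0.05/0.01/0.001 (`*`, `**`, `***`). The connectivity map counts, per pair,
the tissues where r_normal *strictly* exceeds r_tumor; ties contribute
nothing. "Most divergent" pairs are ranked by descending mean(d_i) with ties
broken by smaller p, then canonical pair order — a deterministic total
order.

**Clustering.** Coordination profiles (rows = tissue × condition, columns =
pairs) are clustered agglomeratively with Euclidean distance and average
linkage — both configurable, since no single convention is canonical for
correlation profiles — with deterministic scipy dendrogram leaf ordering.

**Clinical stratification.** Three grouping rules per cancer type:

* *recurrence*: patients who died or recurred within the window (default 3
  years = 1095 days, boundary inclusive) form the early group; **all**
  remaining patients form the non-early group. Patients censored event-free
  before the window therefore land in the non-early group — a known bias of
  the rule, accepted because the rule is defined on observed events, not on
  survival estimates.
* *TNM stage*: I/II vs III/IV. Labels are normalized by stripping a leading
  "stage", upper-casing and truncating sub-stage suffixes ("IIIA" → III);
  unparseable or unknown stages are excluded and logged, never guessed.
* *lymph nodes*: positive vs negative; unknown excluded.

For each pair and stratifier the two strata get independent correlation
panels and the pair is flagged when |r₁ − r₂| exceeds `delta_threshold`
(default 0.15) *strictly*; the comparison tolerates float representation
error (1e-12) so a difference that is exactly the threshold never flags.
The absolute value is used — the sign is retained in the output — because
flags mark pairs, not directions. No p-value accompanies the delta by
default; a two-sample Fisher-z test (`fisher_z_test`) is provided as a
clearly separate extension. Cells where either stratum has fewer than
`min_group_n` (default 10) samples are skipped and logged: Pearson r on
fewer samples is too unstable to compare at a 0.15 resolution.

**qPCR normalization.** Relative expression is 2^(Ct_ref − Ct_gene). The
sign convention is fixed in one place (exponent = reference minus gene), so
a target amplifying five cycles after the reference reports 2⁻⁵ = 0.03125.
Missing target Ct values propagate as missing; a sample lacking the
reference Ct is rejected by name. Re-normalizing an existing expression
matrix to a reference gene requires the caller to declare the input scale
(`linear` or `log2p1`); there is no auto-detection, because silently
guessing the scale corrupts every downstream correlation. Zero reference
values drop the sample (logged) rather than receiving a pseudocount.

**Tissue retention.** Multi-tissue surveys drop tissues with fewer than
`min_samples` samples (default 15 — chosen between the largest excluded
count seen in practice, 11, and the smallest retained, 27) plus an a-priori
exclusion list defaulting to testis and ovary, whose gametic methylation
programs make them outliers for this panel.

## Synthetic-study generator

The generator produces the structure the analysis assumes, with known
ground truth:

* Expression is multivariate log-normal: a Gaussian draw with the target
  correlation matrix and per-gene log-moments, exponentiated (Gaussian
  copula — correlation is imposed on the natural-log scale). Default
  marginal log-sd is 0.25: at this dispersion the Pearson correlation of
  the exponentiated values differs from the log-scale target by less than
  0.01 across the range used (bivariate-lognormal attenuation), so planted
  correlations survive on whichever scale downstream correlation is
  computed. `output_scale="log"` returns the Gaussian values directly for
  analyses that correlate log expression.
* Target matrices must be symmetric, unit-diagonal and positive
  semi-definite (eigenvalue tolerance 1e-8); invalid matrices are an error
  naming the offending group — no silent nearest-PSD repair, which would
  change the experiment's ground truth.
* Control genes (ADH1A/CYP4B1 analogues) are appended as extra dimensions
  uncorrelated with the panel block.
* Clinical cohorts draw each latent patient group under its own correlation
  matrix; clinical fields are assigned deterministically consistent with the
  latent group (group 1: event within the 3-year window, stage III/IV,
  node-positive; group 2: event-free past the window, stage I/II,
  node-negative), so each of the three stratifiers recovers the planted
  partition exactly.
* All generation is a pure function of (config, seed): each group's random
  stream derives from the config seed plus a CRC32 of the group label, so
  output is byte-identical across runs and independent of generation order.
* Three years is realized as 1095 days — an unambiguous integer convention.

What the generator does **not** emulate: library-size and batch effects,
tissue-composition heterogeneity, count noise (the marginals are continuous,
not negative-binomial), censoring-time distributions, or any correlation
between clinical covariates beyond the planted latent group. Passing tests
therefore demonstrate the pipeline's statistical behavior under its own
model assumptions, not robustness to the artifacts of real RNA-seq or
registry data.

## Numerical choices

* Paired differences that are exactly zero (within 1e-15) give the null
  identity t = 0, p = 1; constant *non-zero* differences raise a
  degenerate-test error rather than fabricating a p-value.
* BH inputs outside [0, 1] and correlation values outside [−1, 1] are
  rejected.
* All ranking ties break deterministically (stable mergesort; canonical
  pair order last).
* TSV output uses pandas' shortest-roundtrip float formatting, so write →
  read is lossless and reruns are byte-identical; missing values serialize
  as `NA`.

## Reference problem sizes

The test suite and the acceptance script exercise the pipeline at the
study conditions used throughout: n = 500 for correlation recovery against
the 3(1−r²)/√n bound; identity-null calibration at n = 100 with 500
Monte-Carlo replicates; differential power on 12 matched tissues at
n = 200 per group with 200 replicate studies; clinical flag recovery at
Δr = 0.7 and n = 200 per stratum with 200 replicates; 1,000 random
instances per oracle comparison.

## Known limitations

* Pearson correlation is the only coordination measure in the core
  contract; rank-based or robust alternatives are deliberately out of
  scope.
* Correlations are compared across groups without accounting for their
  sampling variance unless the optional Fisher-z test is invoked; the 0.15
  flag is a fixed-effect-size rule, not an inference.
* The recurrence rule conflates censoring with non-early outcomes (see
  above).
* Tissue matching for the differential stage is by label only; no attempt
  is made to pair individual samples across conditions.
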