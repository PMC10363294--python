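# Methods

## The statistical problem

A cohort provides, for each subject *i*, a sample of per-cell signal
intensities {*x*<sub>*ij*</sub>, 1 ≤ *j* ≤ *n<sub>i</sub>*} for one protein
marker, plus a clinical outcome — here mainly right-censored
progression-free survival (time, 0/1 event), but binary and continuous
outcomes are supported throughout. The conventional summary is the
per-subject mean intensity (ccMSI). `qmarker` instead treats the values of
the per-subject empirical quantile function as a family of candidate
predictors and selects, among a pre-specified grid of probabilities, the
quantile whose dichotomized value is most prognostic.

## Empirical quantiles

For a sample of size *n* and probability *p* ∈ (0, 1), the empirical
quantile is the *k*-th order statistic with *k* = ⌈*np*⌉ — the inverse of
the empirical CDF, with no interpolation, so every feature value is an
actually observed cell intensity. The defining inequality
(*k*−1)/*n* < *p* < *k*/*n* leaves lattice points *p* = *k*/*n*
undetermined; ⌈*np*⌉ resolves them downward (the lower median at even *n*),
preserving the order-statistic property. A 10⁻¹² slack guards ⌈·⌉ against
floating-point round-off in *np*. The implementation is property-tested
against numpy's `method="inverted_cdf"`.

Default grid: 0.05, 0.10, …, 0.95, 0.99 — 20 candidate predictors.
Subjects contribute only if they pass quality control (≥ 20 cells by
default). Intensities are used on the raw scale; an optional `log1p`
transform can be applied before feature computation and is recorded in the
run manifest. Exact duplicate rows in the cell table are retained (a
repeated row is more plausibly a second cell with identical measured value
than an ingestion artifact); the duplicate count is logged so callers can
de-duplicate upstream when their pipeline warrants it.

## Optimal cutpoint (depth-1 split)

Candidate cutoffs are midpoints between consecutive distinct marker
values, constrained to leave at least `min_per_side` subjects strictly on
each side, with default `max(7, ⌈0.05 n⌉)` (the usual minimum-bucket rule
of recursive-partitioning software). The split criterion is the two-sample
log-rank chi-square for survival outcomes, the Pearson chi-square of the
2×2 table for binary outcomes, and the between-group sum of squares for
continuous outcomes; the search is exhaustive, deterministic, and breaks
criterion ties toward the smallest cutoff. Only a single binary split is
implemented — the method dichotomizes, it does not grow trees.

The criteria are evaluated for all candidates simultaneously: with
subjects ordered by marker value, each threshold corresponds to a prefix
of the High group, and the log-rank O−E and variance terms (or cell
counts, or group sums) for every prefix are cumulative sums. A fitted
`CutpointSearcher` therefore costs one sort plus a handful of array
operations regardless of the number of candidates, which is what makes
100 splits × 20 quantiles × 200 bootstraps affordable on one CPU.

The searcher has an opt-in `require_estimable` mode that restricts
candidates to splits whose dichotomized effect is finite (at least one
event on each side for survival; all four 2×2 cells positive for binary).
The default search does not apply it — `optimal_cutpoint` is exactly the
argmax of the split statistic over the candidate set — but the optimism
corrector enables it, since its apparent performance must be a finite log
effect and, under a null marker, the unconstrained argmax occasionally
concentrates all events on one side.

## Effect estimation

All effects are carried internally as log effects; exponentiation happens
only in reports. For a dichotomized marker:

- **Survival** — univariable Cox proportional hazards with Efron tie
  handling (the default of mainstream survival software; ties are common
  with coarse follow-up). The one-covariate-binary case is solved by a
  damped Newton iteration on the Efron partial likelihood (steps clipped
  to ±2, divergence declared at |β| > 15), cross-checked against
  lifelines' `CoxPHFitter` in the test suite. Monotone likelihood (all
  events in one group) is flagged invalid rather than raised, so the split
  layers can record and skip it.
- **Binary** — the saturated univariable logistic model, whose MLE is the
  closed-form log cross-product ratio ln(*ad*/*bc*) with SE
  √(1/*a*+1/*b*+1/*c*+1/*d*); a zero interior cell flags the estimate
  invalid (no continuity correction, because upstream selection treats
  invalid splits as missing).
- **Continuous** — the High−Low mean difference with the pooled-variance
  t-based SE (the OLS slope on the indicator).

Intervals are 95% Wald on the log scale. Multivariable and stratified Cox
fits (low call volume) go through lifelines; non-numeric covariates are
one-hot encoded, singular designs are rejected naming the offending
column, and fewer than five events per coefficient triggers a warning,
not an error. Rubin's rule pools estimates across multiply-imputed
datasets (pooled = mean; total variance *T* = *W* + (1+1/*m*)*B*); the
imputation engine itself is out of scope — the pipeline accepts
pre-imputed or complete-case data.

## Repeated split-sample selection

Each of `n_splits` (default 100) partitions assigns round(0.8·stratum
size) subjects to training within the event and non-event strata
separately (round-half-to-even; both sides forced non-empty), and the
identical partitions are shared by all quantiles so their comparison is
fair. Per-split randomness comes from
`SeedSequence(master_seed, spawn_key=(split_index,))`: adding splits never
reshuffles earlier ones, and the entire screen is a deterministic function
of the data and the master seed.

Per split and quantile, the cutoff is fitted on the training subjects only
and the log effect of 1{value > cutoff} is measured on the test subjects
only. Degeneracies (no admissible training cutoff, one-sided test
dichotomy, monotone likelihood, non-convergence) become flagged records
with reason codes. Each quantile is summarized by the median of its valid
test-set log effects; quantiles with fewer than 50% valid splits
(configurable) are excluded from ranking and listed with a reason
histogram — a median over very few splits is unstable. Ranking is by
|median log effect|, so protective markers (HR < 1) compete on equal
footing and keep their sign in reports. Ties go to the smallest
probability. The top three quantiles are reported, and the selected one's
exponentiated median is HR\*.

## Bootstrap optimism correction

For a fixed quantile, `n_boot` (default 200) subject-level resamples are
drawn with replacement. In each resample the cutoff is re-searched; its
log effect in the resample is the bootstrap performance and its log effect
applied back to the original sample is the test performance; their
difference is that resample's optimism. The corrected estimate is the
apparent log effect minus the **median** optimism — an exact identity
asserted in the report itself. Invalid resamples are dropped and counted;
more than 50% invalid aborts with a reason histogram. The 95% interval for
the corrected effect is the apparent Wald interval shifted by the median
optimism on the log scale — a documented convention, since no exact
interval for an optimism-corrected estimate exists. This procedure
corrects the cutoff selection for a *given* quantile; the selection of the
quantile itself is validated externally, not by the bootstrap.

## External validation

Two frozen cutoff types are derived from the screening cohort: the
apparent cutoff (full-sample search) and the median of the per-split
training cutoffs over the same partitions used in selection; for stable
markers the two coincide. In the external cohort the marker is recomputed
from external cell data, averaged across multiple tissue samples of the
same subject, and dichotomized at the frozen cutoff — never re-fitted
(the frozen-cutoff file carries a SHA-256 checksum that `run_validate`
verifies). Evaluation comprises a univariable Cox fit, a parsimonious
multivariable Cox fit (covariates backward-eliminated at p < 0.05 *before*
the marker is added, eliminating whole covariates largest-p-first; the
marker is never eliminated; complete cases only, with logged exclusions),
and Kaplan–Meier product-limit curves with at-risk counts per group. A
frozen cutoff outside the external marker range is a per-marker error;
other markers in the same run still process. The ccMSI comparator runs
through the identical pathway, enabling the quantile-vs-mean comparison.

## Synthetic cohorts

The generator exists so every stage is testable without patient data. Its
defaults are the package's reference study conditions and were frozen
before the acceptance experiments were finalized.

**Cell intensities.** Subject *i*'s cells are drawn from a two-component
log-normal mixture: a dim background component and a bright expressing
component, mixed with subject weight *w<sub>i</sub>* ~ Beta(160, 240)
(mean 0.4, tightly concentrated). Subject-level parameters deliberately
separate roles:

- the **dim-component center** carries the outcome signal. The cohort
  contains two equally mixed latent expression subtypes at
  μ<sub>low</sub> ± 0.18 (log scale) with ±40% uniform jitter — a bounded,
  bimodal risk distribution. Bimodality reflects the common biological
  situation of low- vs high-expressing tumor subgroups and means the
  dichotomy the method searches for genuinely exists in the population;
  boundedness keeps optimal cutpoints interior (with an unbounded
  signal and a log-linear hazard, the log-rank optimum drifts to extreme
  tail splits whose test groups are too small to evaluate).
- the **component spreads** vary widely and uniformly across subjects
  (σ<sub>low</sub> ∈ [0.15, 1.25], σ<sub>high</sub> ∈ [0.5, 1.1]),
  producing the matched-center / different-tail diversity that motivates
  quantile markers and, importantly, decorrelating neighbouring quantiles
  so the driving probability is identifiable among its grid neighbours.
- the **bright-component center** varies (SD 0.3) but is independent of
  the signal, making upper-tail quantiles uninformative controls.

With weight mean 0.4, the default driving probability *p*\* = 0.30 sits at
the dim component's median, where the location signal dominates.
`make_matched_pair` additionally constructs subject pairs with *exactly*
equal theoretical means and visibly different upper quantiles by trading
expressing fraction against expressing brightness.

**Outcome.** The true marker is the analytic *p*\*-quantile of each
subject's own mixture (numeric CDF inversion). The hazard is
λ₀·exp(β·*z*) with *z* the cohort-standardized **log** true quantile —
the natural scale for log-normal intensities; raw-scale standardization
would let a few extreme subjects dominate the risk distribution. Survival
times are inverse-transform exponential draws; censoring combines an
administrative cutoff (240 months) with an independent exponential time
whose rate is solved analytically so the expected event fraction matches
the target (default 30% events). An unreachable target (e.g. a short
administrative cutoff) is a configuration error. Binary outcomes use a
logistic link with the intercept solved for the target prevalence;
continuous outcomes add unit Gaussian noise to β·*z*. Defaults: 200
subjects, 100–500 cells each, β = 1, λ₀ = 0.005/month.

The ground-truth record (per-subject true quantiles, *p*\*, β) is emitted
separately and never read by the analysis path.

**What the generator does not emulate.** Spatial structure, segmentation
error, batch effects, non-proportional hazards, correlated multi-marker
panels, and informative censoring. Passing tests on this generator show
the algorithm recovers a signal *of the assumed form*; they do not certify
performance on real tissue data, where the prognostic quantile and effect
size must always be validated on an independent cohort.

## Problem sizes used in the checks

The test suite and the acceptance script run the method at the reference
conditions: quantile recovery uses 20 replicate cohorts of 200 subjects ×
300 cells with 100 splits each (recovery of *p*\* within one grid step was
measured at ≈83% over 60 independent seeds during development); the null
optimism study uses 100 cohorts of 150 subjects with 200 bootstrap
resamples (50 cohorts in the acceptance script); censoring calibration
uses 1,000 subjects. The reproducibility check diffs two complete
file-level screening runs byte for byte.

## Numerical choices and degenerate inputs

- Quantile lattice points: ⌈*np*⌉ with 10⁻¹² slack (above).
- Criterion ties in the cutpoint search: smallest cutoff, for
  reproducibility across platforms.
- Quantile-ranking ties: all tied quantiles reported; the smallest
  probability is designated selected for downstream defaults.
- Newton convergence: |score| < 10⁻¹⁰ or step < 10⁻¹², 60 iterations,
  steps damped to ±2; |β| > 15 is declared monotone.
- Constant markers, one-sided dichotomies, zero-event strata and empty QC
  results all fail fast with named errors at the pipeline boundary, and
  become flagged records inside the split/bootstrap loops.
- Reports are strict JSON (NaN → null), written with sorted keys and no
  timestamps, so identical runs are byte-identical.

## Known limitations

- Only depth-1 dichotomization is provided; multi-way splits and
  cross-validated tree complexity are out of scope.
- The survival split criterion is the log-rank chi-square; recursive-
  partitioning software using other survival split rules may place
  cutoffs differently on the same data.
- The corrected-effect interval is a shifted Wald interval, not a
  bootstrap percentile interval.
- Proportional-hazards diagnostics are not included; stratification
  decisions (e.g. by histological grade) are taken as configuration.
- The bootstrap corrects cutoff selection only, not the quantile
  selection — that requires external data by design.
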