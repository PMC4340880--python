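# Methods

This note documents the models, algorithms, numerical choices and
limitations of `macetools`, in the spirit of a statistical package's
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement model

Every MACE subscale is treated as a dichotomous Rasch scale. The
probability that person *n* endorses item *i* is
`expit(θ_n − b_i)`, with θ the person's latent exposure (logits) and
b_i the item's severity. The model's two structural consequences drive
the whole package:

* the raw endorsement count r is sufficient for θ, so person scoring
  needs only the count and the item bank;
* conditioning on r removes θ from the likelihood entirely, so item
  severities can be estimated without assumptions about the population
  (conditional maximum likelihood, CML).

Two- and three-parameter IRT models are deliberately out of scope: for
exposure data every item is taken as an equally good discriminator, and
there is no guessing process to absorb a third parameter.

## Item calibration

**Conditional ML (default).** The conditional likelihood is expressed
through elementary symmetric functions γ_r of ε_i = exp(−b_i), computed
by the summation algorithm entirely in log space (`logaddexp`
recursion), which is stable for any realistic bank size. Persons are
grouped by their observed-item pattern; within a pattern the sufficient
statistics are the per-item totals and the raw-score counts. The score
function uses leave-one-out symmetric functions to form the conditional
expectations E[x_i | r]. Optimization is L-BFGS-B on k−1 free
parameters with the sum-zero gauge built into the parameterization;
difficulties are re-centered (Σb_i = 0) on output, matching the
published banks. Standard errors come from the observed information
(finite differences of the analytic gradient, mapped through the gauge
constraint); simulation in the test suite checks that the reported SEs
match the empirical sampling spread and that nominal 2-SE coverage is
attained.

**Joint ("unconditional") ML.** Alternating Newton steps for person and
item parameters, persons with extreme raw scores dropped, difficulties
re-centered each sweep. JML is provided because it is the estimation
family named in the instrument's development; it carries the classic
outward bias of order k/(k−1), which the tests acknowledge rather than
correct, and the conditional estimates are the ones that reproduce the
published banks.

**Degenerate inputs.** Items with no variance among non-extreme persons
have divergent ML severities and are rejected by name before
optimization. Missing responses are skipped in every sum — the per-person
item count k becomes the observed count — and never imputed; the
published per-subscale observation counts differ for exactly this
reason.

**Convergence policy.** Relative log-likelihood tolerance 1e−10 with a
500-iteration cap; person-equation root finding uses Brent's method at
tolerance 1e−8 with brackets expanding geometrically from [−10, 10].

## Person parameters

For 0 < r < k, θ(r) solves Σ_i expit(θ − b_i) = r; the SE is
1/√(test information). Extreme scores have no finite ML estimate. When a
bank carries published anchors (the instrument's printed "no items / all
items selected" logits), those are used verbatim so that scoring stays
bit-compatible with the released instrument; freshly calibrated banks
fall back to the conventional r → r ± 0.25 adjustment, and the choice is
recorded on the estimate (`convention` field). The exact extrapolation
behind the published anchor values is not derivable from the printed
material, which is why anchors are data, not computation, here.

## Item fit

With P_ni evaluated at the pooled-calibration ML θ for the person's raw
score, W = P(1−P) clamped at 1e−10, and z² = (x − P)²/W:
outfit is the unweighted mean of z² per item, infit the W-weighted
mean. Persons with extreme raw scores are excluded (their responses are
determined by the score). Flagging: max(infit, outfit) ≥ 1.3 is misfit,
≥ 1.5 unacceptable, min < 0.7 with max < 1.3 is overfit — flagged but
retainable, since redundancy understates rather than threatens validity.

A property worth knowing: because θ is estimated from the same response
vector, residuals sum to zero within a person, and both mean squares
center near (k−1)/k rather than 1 on perfectly model-conforming data
(≈0.83 for k = 6). This matches the behaviour of the standard IRT
tooling this computation mirrors, and the published fit tables skew
below 1 accordingly. The test suite asserts the simulation-derived
bands for this statistic — not an idealized expectation of 1 — and the
misfit flags sit far above the conforming band either way.

## Andersen likelihood-ratio test

Groups defined by a person partition (default: median split on an age
covariate, ties to the lower group) are calibrated separately and
pooled; LR = 2(Σ_g logL_g − logL_pooled) on the conditional
likelihoods, df = (groups−1)(k−1), upper-tail χ² p. The statistic is
invariant to group relabeling and person order; a group in which an
item is constant is reported by group and item rather than silently
dropped. Null calibration (rejection rate at α = 0.05) and power
against a 1.5-logit planted shift are checked by simulation in the
suite.

## Subscale construction

`build_subscale` mirrors the instrument's development procedure:
calibrate, compute fits, eliminate the single worst item with
max(infit, outfit) ≥ 1.3, recalibrate, repeat. Ties break on larger
outfit, then lexical item id — the elimination order is otherwise
underdetermined. Protected items (high-severity events retained for
content reasons even when redundant) are never eliminated. If the pool
reaches the floor with misfit remaining, the trace reports failure
instead of raising, because a partial trace is the useful diagnostic.
An exhaustive best-subset search (`best_subset`) is provided as an
oracle for small pools; the greedy path reproduces it in the tests.
Andersen failure after elimination is reported, never acted on
automatically. The information window reports the contiguous θ interval
(0.01 grid on [−6, 6]) where test information stays above a fraction
(default half) of its maximum, rounded outward to whole logits to match
the instrument's "most informative between X–Y" reporting style.

## The shipped instrument

`data/mace_v1.json` carries the ten subscales: item membership
(partitioning items 1–52), reverse-scored items (42, 43, 52 in
emotional neglect; 44, 45, 51 in physical neglect), calibrated
difficulties with SEs, extreme-score anchors, raw and scaled exposure
thresholds, and the 4-item interpolation table. Load-time validation
checks the partition, the mean-centering of each bank, and — as a
self-test — that rescaling each threshold logit with the anchors
reproduces the stated integer threshold. The severity rescale is pinned
as `10·(θ(r) − θ(0))/(θ(k) − θ(0))`: this is the unique linear form
consistent with every printed (logit, scaled) pair. Severities are kept
continuous to 2 decimals internally; integer rounding (half away from
zero) exists only for report columns. The 4-item subscales (parental
verbal abuse, witnessing violence to siblings) cannot be logit-scored
with stable anchors and use the fixed 0/3/5/8/10 interpolation.

## Scoring

Reverse-scoring happens exactly once, inside `score_subscale`, driven
by the instrument definition. Partial missingness prorates the observed
count by k/observed and floors, with an explicit flag — a conservative
convention chosen because the development material is silent; analysts
can filter flagged rows. The witnessing-siblings subscale is scored as
missing for respondents without siblings and contributes zero to the
totals, flagged, so that multiplicity remains a count over assessable
types. Chronology: for each age 1–18, the subscale is re-scored on the
indicator "endorsed at this age" with the same banks (no per-age
recalibration — one instrument, one calibration). A reverse item's
deficit carries no age information (one cannot check the ages at which
love was *not* felt), so an endorsed deficit applies across all ages;
directly worded items count only at their checked ages. Consequences
asserted in tests: per-year severity never exceeds the overall subscale
severity, with equality when all endorsements share one age. Exposure
flags and multiplicity depend only on integer raw counts versus
thresholds, never on floating-point severities.

## Validity statistics

* **Bland–Altman**: mean difference t-test plus the ±2·SD limits;
  "repeatable" requires p > 0.05 and ≥95% of differences inside the
  limits. All-identical differences are repeatable by convention
  (p = 1). The 2·SD convention (not 1.96) follows the instrument's
  reliability analysis.
* **Pearson/Fisher-z CIs**; **Williams test** in the Hotelling–Williams
  form with df = n−3 for two dependent correlations sharing a variable —
  the determinant form of the trivariate correlation matrix, type-I
  calibrated by simulation in the suite.
* **ROC AUC** via the Mann–Whitney identity (ties half-weighted), CI by
  Hanley–McNeil.
* **Odds ratios**: the sample cross-product ratio (Haldane 0.5
  correction on zero cells, flagged) *and* the conditional-MLE estimate
  with exact conditional CI, which is what R's `fisher.test` prints and
  what reproduces the instrument's published ratios and intervals to
  their stated precision; Woolf CI reported alongside. Fisher's exact p
  is two-sided by hypergeometric tail summation.
* **LMG decomposition** by the exact subset formulation (weights
  |S|!(p−|S|−1)!/p!), equivalent to averaging sequential R² increments
  over all p! orderings; R² per subset comes from the correlation-matrix
  linear solve, so shares sum to the model R² at 1e−10. Capped at
  p = 10 regressors (1024 subsets); rank-deficient designs are rejected
  with the offending columns named. Bonferroni adjustment is exposed as
  a utility for cross-comparison families.

## Synthetic populations

The generator emulates the development study's data shapes so the whole
pipeline is testable offline. Per-subscale latent exposures come from a
Gaussian copula with exchangeable correlation 0.32 (the published
cross-subscale regime); responses are Bernoulli draws from the shipped
banks; reverse items are emitted in raw coding. Defaults are the study
conditions: n = 1051; latent SD 1.5 with per-subscale means obtained by
inverting the model-implied exposure probability against each type's
published prevalence (5.8%–33.2%) — this, not tuning, is what makes the
simulated prevalence, the decreasing multiplicity histogram and the
attenuated between-subscale severity correlations land in the reported
regime; ~80% sibling fraction (the witnessing-siblings subsample);
1% stray item non-response; 5% per-cell retest flip noise, which puts
simulated total-severity test-retest correlation in the high-0.8s to
mid-0.9s band at n = 75; symptoms linear in total severity (slope 0.5,
noise SD 15 → correlations near 0.35). Age checkboxes follow triangular
profiles (peer maltreatment peaking in early adolescence, parental in
mid-childhood, sexual abuse later) — enough to exercise chronology
scoring, with no claim to reproduce empirical trajectories.

What the generator does **not** emulate: response styles and recall
bias, item-level local dependence within subscales (the copula is
between subscales only), non-exchangeable correlation structure,
age-varying latent severity (the latent θ is one number per subscale),
and systematic retest drift. Passing tests therefore demonstrate that
the machinery is correct and calibrated under the stated model, not
that the model captures every feature of real questionnaire data.

A single integer seed drives named SeedSequence substreams (order:
responses, ages, missing, siblings, retest, symptoms), so each stage is
independently reproducible.

## Problem sizes in the test suite

Simulation-based checks use n = 400–1051 persons and 100–1000
replicates (10,000 for the Williams null, where each replicate is a
single correlation matrix); these sizes give the assertions comfortable
margins over their sampling noise while keeping the full suite around
half a minute. Seeds are fixed; each seeded statistical check was
verified against its sampling distribution before freezing.

## Known limitations

* CML standard errors use a finite-difference Hessian of the analytic
  gradient; exact second derivatives would be marginally cleaner but
  the tests show the SEs already match the empirical spread.
* JML is uncorrected for its finite-k bias (documented, tested for
  ordering consistency only).
* The deposited study data are not redistributable, so the tests that
  recalibrate them (`TestDepositedDataReproduction`) fail with an
  explanatory message unless the CSVs are placed under `data/`.
* The inline age-annotated CSV convention cannot distinguish a plain
  endorsement from "endorsed at age 1 only" for the bare token `1`;
  the writer emits `1;` for the latter and the parser honours it.
* Exact-conditional OR confidence intervals and the conditional MLE
  come from scipy's contingency machinery; only the surrounding
  reconstruction, Haldane handling and Woolf interval are local code.
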