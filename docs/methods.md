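# Methods

## Problem and model

`rbcscore` derives a pre-operative risk score for red-blood-cell (RBC)
transfusion in invasive spine surgery. The outcome is binary — transfusion
of one or more RBC units during surgery or the post-operative course — and
is modelled by logistic regression on pre-operative covariates:

    logit P(transfusion) = β₀ + Σ βⱼ xⱼ

Eighteen candidate predictors are considered: patient characteristics (sex,
age, height, weight, ASA class, anticoagulant premedication, number of
prior spine surgeries), pre-operative laboratory values (Hb, Quick, INR,
PTT, thrombocytes) and surgical planning details (fracture, tumor, surgery
type, incision, vertebral body replacement, operated stages). Categorical
variables are dummy-coded against fixed reference levels; continuous
variables enter untransformed. Missing data are handled by complete-case
analysis *per candidate model*: each model only drops records missing one
of its own covariates.

## Best-subset selection by repeated stratified resampling

To keep roughly ten events per coefficient at the study's size, models are
limited to at most four predictors. The candidate set M is the exhaustive
enumeration of all subsets of size 0–4 (4048 models for the 18-predictor
pool, null model included), ordered by size then lexicographically so model
indices are reproducible.

Selection works on J stratified train/test splits (default J = 100,
training fraction 0.8). Stratification fixes per-class training counts at
round(0.8·n_class) (round-half-to-even), so every training cohort carries
the same event/non-event ratio as the full cohort. Every model is fitted on
every training part and scored on the matching test part by ROC AUC; the
winner maximizes the mean test AUC. Exact ties are broken toward fewer
predictors, then enumeration order, and all tied models are reported.

Split/model cells that cannot be evaluated (empty or single-class partition
after complete-case filtering, fit failure) are flagged with an explicit
reason and excluded from that model's mean rather than imputed; a model
with more than 50% flagged cells is disqualified from selection and listed.
Both choices are configurable. The alternative complete-case policy —
filter once on the union of the pool's predictors before splitting — is
available as `complete_case_mode="pre_split"`.

### Nested internal validation

Selection optimism is quantified by nesting: each of K outer iterations
(default K = 100) holds out a stratified 20% validation cohort, reruns the
entire selection (J inner splits) on the remaining 80% derivation cohort,
refits the inner winner on the whole derivation cohort, and records AUC(k)
on the held-out part. The mean [min, max] of AUC(k) measures the selection
*procedure*. Because AUC(k) is computed on data untouched by the inner
selection, it is free of the optimism carried by the winner's own inner
mean AUC (which is also reported, as `inner_mean_auc`). Under a no-signal
simulation the held-out AUC(k) averages 0.5 while the non-nested selected
mean AUC sits visibly above 0.5 — the optimism the nesting removes. Inner
split seeds derive deterministically from (master seed, k) via numpy's
`SeedSequence`, so the whole pipeline is bit-reproducible given (seed, J,
K, cohort).

## Logistic fitting

Fitting is Newton/IRLS with step-halving, so the deviance path is
non-increasing. Convergence: max |score| < 1e-8 or relative deviance change
< 1e-10, within 50 iterations. Small training splits of a ~250-record
cohort can separate; a non-convergent or runaway fit (|β| > 30) is refitted
with a small L2 penalty (1e-3, intercept unpenalized) and flagged
`stabilized` instead of being discarded, so every (model, split) pair can
still yield an AUC. Dummy columns constant in a training part (a category
absent from that split) are dropped for that fit and predict with
coefficient 0. Rank-deficient designs and single-class outcomes are errors.
Standard errors from the observed information matrix are exposed for the
parameter-recovery checks only; no further inference is offered.

AUC is the Mann–Whitney estimator — the fraction of (event, non-event)
pairs where the event scores higher, tied pairs counted ½ — computed via
average ranks, and verified in tests against an independent O(n²)
pair-counting oracle.

## The integer point system

The fitted model is converted to a Sullivan-style point system:

1. Every categorical factor is re-expressed against its lowest-risk
   category (the minimum coefficient is shifted to zero and absorbed into
   the intercept), a pure reparameterization that leaves all predicted
   probabilities unchanged.
2. A constant B — log-odds per point — is set to the coefficient of a
   designated binary term; here the vertebral-body-replacement coefficient
   (0.841 in the published model), so one point equals the risk increment
   of implanting a vertebral body replacement. B must come from a
   single-dummy binary factor.
3. Categorical points are round(β / B). Hemoglobin is banded into <8,
   [8;12), [12;16] and >16 g/dL with representative values W = 7.5, 10, 14
   and a reference value W_ref = 16 for the lowest-risk band (>16); band
   points are round(β·(W − W_ref)/B). Rounding is nearest integer, half
   away from zero. With the published coefficients this reproduces the
   published points column exactly (surgery 0/0/1/2, vbr 0/1, stages
   0/1/2/3/3, Hb 7/5/2/0; maximum total 13).
4. The look-up table maps each total P ∈ {0..max} to
   expit(β₀ + β_hb·W_ref + B·P); successive logits differ by exactly B, so
   it is strictly increasing.

The representative-value convention (midpoints for interior bands, the
near-boundary 7.5 for the open "<8" band given the observed minimum 7.0,
the boundary 16 for the reference band) is the simple reconstruction that
reproduces the published points; it is configurable via `BandSpec`.

Because the publication prints the final point system and its look-up table
but not the fitted intercept, those printed artifacts are also shipped
verbatim (`published_score_fixture`); pipelines run on synthetic data build
their own look-up table from their own fitted intercept.

## Synthetic cohorts

Real patient records are not public, so every stage is exercised on a
synthetic generator that emulates the published cohort description:

- Categorical marginals equal the published overall relative frequencies
  (e.g. surgery type 28.2/12.7/41.7/17.5%, stages 41.3/12.7/22.6/9.5/13.9%).
- Continuous variables are truncated normals with the published mean/SD,
  truncated at the published observed [min, max] (Hb 12.7 (2.32) on
  [7.0, 19.1]; age 62.6 (17.3) on [14, 89]; ...), sampled exactly via the
  inverse CDF so no probability mass piles up at the bounds.
- Missingness is missing-completely-at-random at the published per-variable
  rates (e.g. vbr 0.4%, ASA 10.3%); the real mechanism is unknown.
- Outcomes are Bernoulli draws from a ground-truth logistic model on
  {surgery type, vbr, stages, Hb} with the published coefficient values
  (Hb per g/dL −0.665, vbr 0.841, ...), computed before missingness is
  applied. The intercept is calibrated by one-dimensional root finding
  (brentq on a 400 000-draw fixed-seed Monte-Carlo expectation) so the mean
  event probability equals 61/252 ≈ 24.2%; the solved default intercept is
  4.7592.

Covariates are drawn independently: only marginals are published, so no
correlation structure is asserted. Consequently passing tests demonstrate
that the algorithms behave correctly under the published marginal
conditions — they cannot show robustness to the real data's correlations,
within-patient clustering of the 38 repeated-surgery patients, or
informative missingness, none of which the generator emulates.

## Problem sizes used in tests

The packaged test suite runs the statistical checks at deliberately modest
sizes: selection recovery on n = 800 cohorts with an 8-predictor pool
(163 models), J = 25 splits and 20 seeds, requiring ≥ 3 of the 4 true
covariates in ≥ 80% of runs; nested-null behaviour on n = 400 no-signal
cohorts with a 16-model space, K = 10, J = 25 and 3 seeds; parameter
recovery and score calibration at n = 20 000. The analysis drivers default
to the full J = 100 selection and accept `--outer 100 --inner 100` for
full-scale nested validation.

## Known limitations

- Independence of synthetic covariates (above) is the main gap between the
  simulation and any real cohort.
- The stabilized-refit policy trades a small bias on separated splits for
  completeness of the AUC matrix; stabilized fits are flagged.
- The look-up table is exact on the score scale (outcomes drawn from the
  score system itself are calibrated to binomial noise, which is what the
  calibration test checks) but only approximate against the underlying
  continuous model: banding replaces each Hb value by its band
  representative and point rounding perturbs each term's log-odds, so on
  covariate-level simulations the per-stratum observed rates can drift
  below the table in the upper strata. The score-distribution report makes
  this visible rather than hiding it.
- The published look-up probabilities cannot be re-derived exactly because
  the fitted intercept was never printed; back-solving the printed table
  gives per-point logit increments in [0.80, 0.88], consistent with
  B = 0.841 under two-decimal rounding, and the package preserves the
  printed values rather than guessing an intercept.
- No external validation, machine-learning comparators, or within-patient
  correlation modelling; prior surgeries enter only as a counted covariate.
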