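# Methods

## Staging

Decisions are made at the start of ICU days 1, 3 and 5. Stage k covers
times [2(k−1), 2k) days from ICU entry, with stage 3 open-ended (no
follow-up truncation). The stage survival time T_k runs from the stage
start to the next boundary or to the outcome, whichever comes first; death
exactly at a boundary counts as an event of the closing stage. A patient
enters stage k+1 only if still in the ICU strictly after the boundary, so
stage times over entered stages always sum to the observed time exactly.

The daily fluid strategy is liberal iff total intake ≥ 40 ml/kg/day; the
threshold is inclusive. The stage treatment a_k is the decision-day
strategy (days 1, 3, 5); the strategies of days 2 and 4 enter only as
history covariates of later stages. Patients discharged alive are censored
at discharge and never re-enter. Missing covariates demanded by a model
specification are a hard error naming patient, day and variable — silent
imputation would corrupt the recovery experiments that validate the
estimator.

A sepsis screen (suspected infection plus ≥ 2 systemic inflammatory
response criteria: temperature ≤ 36 or ≥ 38 °C; heart rate ≥ 90/min;
respiratory rate ≥ 20/min or PaCO₂ < 32 mmHg; white cells > 12,000 or
< 4,000 /mm³ or > 10% bands) is provided for cohort construction; missing
laboratory values degrade the corresponding criterion to not-met.

## Estimator

Each stage fits a weighted least-squares regression of log remaining
survival time on the concatenated design [h_β | a·h_ψ]. Weights are
|a − π̂(h)| · δ/K̂(h): π̂ and K̂ are unpenalized logistic models (on the blip
covariate set) of treatment and of the probability that the patient's
remaining survival was fully observed (final status died); censored
patients get weight zero. Fitted probabilities are clipped to [0.01, 0.99]
to bound the weights. Standard errors are HC0 sandwich estimates; 95%
intervals can alternatively be obtained by a percentile bootstrap that
resamples whole patients and reruns the full backward induction.

Numerical/contract choices:

- A blip score of exactly zero recommends the restricted strategy (the
  optimality indicator is strict).
- The treatment-free term list defaults to the blip covariate pool plus
  the blood-pressure term. Keeping h_ψ inside h_β is what makes the
  balancing weights deliver double robustness: with it, the blip estimate
  is consistent when either the treatment-free outcome model or the
  propensity model is correctly specified (both directions are exercised
  in the test suite).
- Rank deficiency of the weighted design raises a collinearity error
  listing the aliased terms (QR with pivoting) rather than silently
  dropping columns.
- Backward elimination (optional) removes one non-forced blip term per
  round — the largest p-value above α = 0.05 — refitting after each
  removal; the intercept and, by default, age and mean blood pressure are
  never removed. Terms consumed by a product term are kept while the
  product survives. Selection is per stage.
- Backward induction replaces the outcome of stage k < 3 by the
  counterfactual remaining time T_k + T_{k+1..} · exp(ψ̂ᵀh_ψ [a^opt − a]),
  so each earlier fit is performed under optimal continuation. The
  adjustment never shrinks a time, with equality exactly under concordant
  treatment — this dominance is asserted cohort-wide in the tests.
- A cohort in which nobody reaches day 3 degrades gracefully to a
  single-stage fit; a stage with all patients in one arm is a hard
  degenerate-treatment error.
- All randomness flows through explicit integer seeds; bootstrap
  replicates derive per-replicate resamples from one `numpy` Generator.

## Synthetic cohorts

The generator reproduces the statistical structure the estimator assumes,
not ICU physiology. Per patient: age ~ Normal(65, 15) years (clipped to
18–95), one of eight unit types with a Med-Surg-dominant mix, and daily
vitals following patient-centred AR(1) processes (autocorrelation 0.6)
with population means/SDs chosen to resemble a large sepsis cohort (heart
rate 109/15 bpm, mean blood pressure 57/10 mmHg, respiratory rate 29/6
/min, temperature 37.3/0.6 °C, urine 800/400 ml/day); mechanical
ventilation and vasopressor flags are daily Bernoulli draws (rates 0.25
and 0.35). The behaviour policy assigns the daily liberal strategy by a
logistic rule in centred current covariates and the previous day's
strategy, calibrated to a ~50% day-1 liberal rate so both arms are well
populated.

Stage times are drawn from the AFT model above with Normal(0, 0.4) errors
on the log scale; the generating blips mirror the structure of the
published rules (concave quadratic blood pressure at stage 1 with vertex
near 64 mmHg, prior urine output and prior strategy at stage 2, a
day-3 × day-4 strategy interaction at stage 3) at magnitudes that leave
roughly balanced optimal actions. Death occurs within stage k when the
drawn T_k is shorter than the two-day span (stage 3 always ends in death
unless discharged); stage times have a floor of 0.04 days so logs are
always defined. Treatment-free intercepts are set so that roughly a third
of each stage's entrants die within the stage — substantial within-stage
mortality is what makes the stage-specific effects identifiable at the
cohort sizes used in the tests.

Alive discharge is modelled as a per-stage Bernoulli event given current
covariates (log-odds −2.4 in stages 1–2 and −1.6 in stage 3, lower by 0.7
if ventilated), with the discharge instant placed uniformly within the
stage before the latent death time, and never before day 1. Drawing the
censoring *status* from covariates — rather than racing an independent
discharge clock against death — makes censoring conditionally independent
of the survival time given the modelled covariates, which is precisely the
regime in which a cell-probability censoring weight δ/K̂(h) is correctly
specified. Under a competing continuous clock, censoring status correlates
with the survival time within covariate cells and no covariate-based
weight removes that selection; we verified that such a mechanism leaves a
systematic ~0.02 bias in stage-3 blip coefficients while the mechanism
used here leaves none.

What the generator does not emulate — and hence what passing tests do not
establish about real data: physiologic feedback (fluid given today does
not move tomorrow's vitals), informative discharge beyond the modelled
covariates, measurement error, missingness, and the earlier-stage
subtlety below.

## Known approximations and limitations

- For stages 1 and 2 the regression outcome is the *remaining* survival
  time under optimal continuation, while the generator's blip acts on the
  *within-stage* time only; the two coincide exactly at stage 3. Fitted
  stage-1/2 coefficients therefore estimate a remaining-time blip that is
  a distorted (empirically, nearly proportional) version of the generating
  stage-time blip. Recovery is asserted quantitatively at stage 3 and, at
  stages 1–2, through the agreement of recommended actions with the sign
  of the generating blip away from the decision boundary.
- The intercept of the stage-3 blip has sampling SD ≈ 0.22 at n = 2000,
  so single-cohort estimates of it are loose; bias assertions average 100
  replicates and the point-recovery example pins its seed.
- Probability clipping at [0.01, 0.99] caps weights at ~100; with the
  default generator the bounds are rarely active except for the
  no-censoring case, where K̂ sits at the upper clip by construction.
- The published-rule fixture is data, not an estimate: its coefficients
  are reproduced at equation precision (4–5 significant figures), with
  the companion table's 3-decimal printings used as a cross-check. The
  day-3 temperature coefficient (−0.0037) is applied to °C as printed;
  its original covariate scale is not documented. Day-5 heart rate and
  blood pressure enter unscaled, unlike day 1's per-20 scaling — scaling
  is therefore declared per term, never globally.
- Cross-table percentages are taken over the per-stage entered total, the
  convention under which the published day-1 table is internally
  consistent (its four cells sum to 22,841).
- The observed-vs-counterfactual survival comparison uses a paired
  Wilcoxon signed-rank test on nonzero differences (the source analysis
  names no test); with every pair tied the report flags a degenerate
  p = 1.

## Problem sizes used by the test suite

Recovery bias runs 100 cohorts of n = 2000; bootstrap coverage runs a
20-replicate tier at n = 1000 with B = 200 resamples, pooling coverage
over the stage-3 coefficients; regime value and sign-agreement checks use
single cohorts of n = 2000–5000. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the full suite
in the minutes range on one CPU.
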