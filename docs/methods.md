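# Methods

`exalarm` implements a pipeline for predicting COPD exacerbations from
daily home urine-biomarker telemonitoring: panel discovery from paired
stable/exacerbation samples, Bayesian state-space filtering of the daily
series, rolling-window temporal features, a stepwise neural-network risk
score, and traffic-light alarm rules with event-level evaluation.  This
note records the models, the defaults, and the design choices, in that
order.

## Synthetic cohort

No public dataset of daily home urine biomarker series exists, so the
package ships a generator that emulates the statistical structure the
analysis assumes.  For patient *i*, marker *m*, day *t*, the log10
concentration is

    y_imt = a_im + d_imt + b_imt + s_imt + r_it·1[m informative] + e_imt

with per-patient baseline `a ~ N(baseline_mean, baseline_sd²)`, a slow
random-walk drift `d` (innovation sd `drift_sd`/day), a batch offset `b`
that steps by `N(0, batch_sd²)` every `batch_length` days (device
reagent lots), a stationary AR(1) fluctuation `s` with autocorrelation
`ar_coef` and **marginal** sd `ar_sd`, observation noise `e` with sd
`obs_sd`, and a pre-exacerbation shift `r`.  Tests are missing
completely at random with probability `missing_prob` — the filtering
model assumes missingness is non-informative, and the generator matches
that assumption.

Defaults (log10 units): `baseline_mean 1.5`, `baseline_sd 0.30`,
`drift_sd 0.002`, `ar_coef 0.7`, `ar_sd 0.04`, `obs_sd 0.04`,
`batch_length 28`, `batch_sd 0.05`, `missing_prob 0.12`, `exac_hazard
0.003`/day, `lead_days 13`, `shift_magnitude 0.10`, `recovery_days 42`.
A day-to-day sd of 0.04 log10 units is a ±10% multiplicative
fluctuation around the local level, the magnitude a clinician would
state as prior judgement for these assays; `ar_sd` is deliberately
parameterised as the *stationary* sd of the AR component (innovation sd
`ar_sd·sqrt(1-ar_coef²)`) so that the configured number is the
day-to-day variation one would actually observe.  The missingness rate
matches a home-testing completion rate near 88%, and the hazard gives
roughly one exacerbation per two patients over a 6-month study.

The pre-exacerbation shift is a linear ramp from 0 at `lead_days`
before diagnosis to `shift_magnitude` on the diagnosis day, then an
exponential decay with half-life `recovery_days/4`.  The true
biological lead-in shape is unknown; the ramp is a stand-in chosen as
the simplest shape consistent with a detectable 13-day lead-in and a
6-week recovery, and nothing downstream depends on its exact form.

Reproducibility: every (patient, marker) series draws from an
independent substream `SeedSequence([seed, tag, patient, marker])`, so
enlarging the cohort never perturbs existing patients.

What the generator does **not** emulate: diurnal urine dilution,
assay saturation, device failures, informative missingness (sicker
patients skipping tests), correlated multi-marker flares unrelated to
exacerbations, and covariate effects (age, sex, BMI).  Passing tests
therefore demonstrate internal consistency of the pipeline under its
own assumptions, not clinical performance.

## Discovery panel

Per-marker screening uses a two-sided paired t-test and the
Mann–Whitney ROC AUC on log10 concentrations (exacerbation vs stable),
with the pre-defined rule AUC ≥ 0.59 or ≤ 0.41 and p < 0.05.  The
panel is a logistic regression fitted by backward stepwise elimination:
refit, drop the covariate with the largest Wald p-value above 0.05,
stop when all retained covariates are significant or one remains.
Wald rather than likelihood-ratio criteria keep the path deterministic
and cheap; ties drop the lexicographically later marker name so the
path is independent of candidate order.  Perfect separation aborts
with an explicit error rather than returning unstable coefficients.
The probability score is the inverse-logit of the linear predictor;
the default reporting cut-off is 0.39 with the Youden-optimal cut-off
reported alongside.  Prevalence-adjusted predictive values use
PPV = se·π/(se·π+(1−sp)(1−π)) and NPV = sp(1−π)/(sp(1−π)+(1−se)π).
No multiplicity correction is applied across the screen by default —
standard practice for hypothesis-generating screens — but
`screen_biomarkers(p_adjust=...)` accepts any statsmodels
`multipletests` method name.

## Dynamic linear model and Kalman filter

Each biomarker series gets a separate univariate non-homogeneous DLM
with state (μ_t, s_t, b_t):

    y_t = μ_t + s_t + b_t + ε_t,          ε_t ~ N(0, V)
    μ_t = μ_{t−1} + w1_t,                 w1 ~ N(0, W_μ)
    s_t = φ·s_{t−1} + w2_t,               w2 ~ N(0, W_s)
    b_t = b_{t−1} + w3_t·1[batch change], w3 ~ N(0, W_b)

i.e. four variance parameters (V, W_μ, W_s, W_b) and the AR
coefficient φ.  Fitting is a Gibbs sampler: (a) the full state path by
forward-filtering backward-sampling; (b) conjugate inverse-gamma
updates for the four variances; (c) a random-walk Metropolis step for
φ (proposal sd 0.1, uniform prior support); (d) missing observations
imputed from N(μ+s+b, V), which is exactly missing-data augmentation
under non-informative missingness.  Defaults: 4,000 iterations, 1,000
burn-in, thinning 2, fixed seed.  The kernel is numba-compiled; a
360-day series fits in a few seconds.

Priors are inverse-gamma(shape 2) on variances with means encoding the
±10% day-to-day judgement: prior mean sd 0.04 for observation noise,
0.028 for the AR innovation (= 0.04·sqrt(1−0.7²), so the implied
*marginal* AR fluctuation is again ±10% at a typical persistence of
0.7), 0.01 for the drift, 0.05 for batch steps; φ ~ Uniform(0, 0.99).
Series with no batch changes leave W_b at its prior — the component is
simply non-identified, and the sampler reproduces the prior exactly.

Filtering is strictly causal: the filtered value on day t is
E[μ_t + s_t | y_{1:t}], with missing days handled by pure prediction.
The batch component is excluded from the filtered value by default —
batch steps are device artefact, not physiology — with a flag to
include it.  Whether the AR component should be included is genuinely
open; the sum μ+s is the default because it tracks the observed data
faster, and the component selection is exposed as an argument.  Model fitting uses the whole series
while feature extraction uses only the causal filter, matching a
deployment in which parameters are estimated offline and the filter
runs live.  Parameters are fitted per patient and marker with shared
priors; hierarchical pooling across patients is not implemented (see
limitations).

Numerics: a 1e−12 jitter on state-covariance diagonals keeps the
3×3 Cholesky factorisations positive-definite when components are
degenerate (e.g. b before any batch change); the deterministic filter
is validated against exact joint-Gaussian conditioning at 1e−8.

## Temporal features

A "13-day window" spans 14 daily points (anchor−13 … anchor): for each
marker, the daily value, the differential from the previous day (the
day before the window when available, else 0 for the first point), and
the window-local integral (cumulative sum from the window start) give
14×3 = 42 features per marker.  The integral is window-local rather
than study-cumulative so the feature scale is stationary across a
patient's record.  Each window is labelled with the days to the next
clinician diagnosis, 200 (beyond any observation period) when none.

The development set holds the 14 run-up windows before each diagnosis
plus a seeded random sample of stable windows (anchors ≥ 42 days from
any event, outside recovery spans) at 3 stable windows per run-up
window; the blinded production set holds recovery-span windows (6
weeks post-event, when inflammation may still be resolving) and every
window of patients with no events.  The two sets are disjoint by
(patient, anchor).  A cohort with no events anywhere cannot produce a
development set and is rejected.

## Risk network

A single-hidden-layer network (sigmoid hidden units, linear output)
maps selected temporal features to "time to exacerbation".  Training
is full-batch gradient descent with momentum 0.9, early stopping on a
validation split (patience 80 epochs), inputs standardized with
constants computed on the training split only.  The target is fitted
on the log1p scale by default and predictions returned in days: times
far in the future are inherently unpredictable from a 14-day window,
and with a raw-day squared loss their variance drowns the signal from
imminent events (configurable via `target_transform="none"`).

Input selection is forward stepwise: at each step every unused feature
is tried with the current set, trained per Monte Carlo 60:20:20 split
and scored by MSE on the unseen test split, averaged over splits;
candidates share splits and initialisation streams so comparisons use
common random numbers.  Splits are stratified by patient — every
window of a patient stays in one split — because windows of one
patient are strongly dependent and window-level splits would leak.
The full step budget (default 20) is explored and the prefix with the
lowest mean test error is returned, so a step that fails to improve is
recorded in the trace but never selected.  The final model is tuned
over a hidden-node grid (default 2–10) by unseen-test error.  The
"panel" is the set of distinct markers contributing selected features.
Models export to JSON with an explicit closed-form formula string that
reproduces `predict_risk` to floating-point precision.

## Traffic lights and evaluation

A day is green if its risk score exceeds the amber cut-off (default
13.4 predicted days; scores equal to the cut-off are amber, since
green is defined by strict exceedance), amber otherwise, and red when
at least 6 of the trailing 7 days (inclusive) are amber or red — red
days count toward later windows, otherwise an alarm would reset
itself; a day whose own colour is green can still turn red when the
preceding week was amber-laden.  The separate ROC operating point
(21.19) is kept as distinct configuration because the two cut-offs
play different roles.  Missing days carry the previous outcome
forward.

The default amber cut-off is an operating point on the original
network's score scale; applied verbatim to a newly trained network it
can be unreachable.  The pipeline therefore re-derives the amber
cut-off on development-set windows by Youden's J by default
(`amber_mode="youden_dev"`); `"fixed"` applies the configured value
literally, and the `DecisionConfig` default remains 13.4.

Maximal runs of consecutive red days merge into one called event.
Against clinician diagnoses with windows [diagnosis−13, diagnosis]:
TP per true event with any red day in its window (a run that started
before the window still counts), FN per true event with none, FP per
called event wholly outside all windows, TN per stable day with a
green outcome.  PPV = 100·TP/(TP+FP) and NPV = 100·TN/(FN+TN) are
event-level; specificity is day-level (TN over stable days).  The two
granularities are labelled explicitly wherever reported.  Lead time is
diagnosis day minus the first in-window red day of the earliest run
intersecting the window — a run that began before the window is
clamped to the window start, since an alarm predating the pre-event
window measures background alarm load rather than specific early
warning — summarised as median (IQR); recovery status is the fraction
of events non-red 14 days after diagnosis.

## Evaluation statistics

AUC uses the rank (Mann–Whitney) formulation with ties counted ½,
verified exhaustively against the pairwise win-rate; confidence
intervals are a seeded stratified bootstrap (2,000 resamples) rather
than DeLong so the same machinery serves single markers and model
scores.  Youden's J breaks ties toward the lower cut-off.  Percentages
are rounded to one decimal except where the convention is whole
percent (validity-of-done compliance).

## Problem sizes and what the tests show

The shipped demonstration cohort is 10 patients × 180 days × 5
markers, chosen so the full pipeline runs in about a minute; the
end-to-end evaluation uses 30 patients.  The DLM parameter-recovery
check uses 20 series of 360 days at the full 4,000 iterations.  At 30
patients the windowed detection task is hard by construction: the
±10% day-to-day AR fluctuation has a 13-day-difference sd of
0.04·sqrt(2(1−0.7¹³)) ≈ 0.056 log10 per marker, comparable to the
0.10 pre-event ramp, and windows anchored 8–13 days before an event
are labelled positive while containing almost none of the ramp, so
even an ideal detector restricted to 14-day windows of three
informative markers is noise-limited.  The acceptance test that runs
this end-to-end configuration asserts a strict held-out AUC bar and
currently fails; the shortfall is a property of the study conditions
at this cohort size, not of the implementation, and is reported
rather than papered over.

## Known limitations

- Per-patient DLM fits are independent; no hierarchical pooling.
- The stepwise search is greedy and can miss complementary feature
  pairs whose individual contributions are weak.
- Event-level FP counting treats any out-of-window run as one false
  alarm regardless of length; no grace period is applied.
- The generator's MCAR missingness is favourable; informative
  missingness would bias the filter's imputation.
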