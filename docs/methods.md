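# Methods

This note documents the models, assumptions, defaults and numerical choices
behind `msenrich`, in the order of the analysis workflow.

## Data model and preprocessing

A cohort is a pooled set of randomized trials: one baseline row per patient
(19 features: age, sex, height, weight, disease duration, EDSS, seven
Functional Systems Scores, timed 25-foot walk, 9-hole peg test for both
hands, Gad lesion count, T2 lesion volume, normalized brain volume) and a
long-format visit table (patient, time in years, EDSS). EDSS lives on the
grid {0.0, 1.0, 1.5, ..., 10.0}; 0.5 is invalid and rejected at load time.
All times are in years; 24 weeks is 168/365.25 years.

Cohort exclusions (applied in this order, first match logged): fewer than
two clinical visits; last visit before 24 weeks; any missing baseline
feature. There is no imputation by design — patients with missing features
are excluded, matching the trial-pooling setting the package models.

Preprocessing is fitted on a training split only and is reusable/serializable
(JSON) for bit-exact application to held-out data. Pipeline order:

1. **Cross-trial MRI rescaling.** Segmentation-derived metrics (Gad count,
   T2 volume, NBV) differ systematically between trials ("school effects"
   of different reading centres). Each trial's values are clamped to that
   trial's mean ±3 SD and linearly mapped so the ±3 SD interval coincides
   with a reference trial's. Clamping makes the map robust to extreme
   outliers; consequently the map is the identity only inside the band. The
   subset used to fit the anchors is configurable (a predicate emulating an
   intersection of trial inclusion criteria); the default uses all training
   rows.
2. **Log transform** of the right-skewed features (T25FW, both 9HPT, T2
   volume, NBV) as `ln(max(v, 0) + eps)` with `eps = 0.01`. The offset keeps
   zero-valued T2 volumes finite; the floor guards against rescaled MRI
   values that land marginally below zero.
3. **Gad binning** into ordinal codes 0–9 for counts 0, 1, 2, 3, 4, 5–6,
   7–9, 10–14, 15–19, 20+ (binning follows rescaling, so bin edges apply to
   the harmonized scale).
4. **Standardization** of all non-binary features (including the ordinal
   Gad codes) to zero mean, unit SD using training-split statistics
   (population SD, i.e. ddof 0). Sex stays 0/1. A feature constant on the
   training split is an error, not a silent pass-through.

## Outcome labels

* **Slope.** Ordinary least squares of EDSS on time over all visits,
  baseline included and unweighted. With two visits this reduces to the
  difference quotient. Whether visits should be trimmed or weighted after
  intercurrent events is an open modelling question; unweighted OLS on all
  visits is the documented default.
* **CDP24.** Progression threshold = baseline EDSS + increment, where the
  increment is 1.5 for baseline 0, 0.5 above 5.5, and 1.0 otherwise
  (baseline EDSS is the time-0 visit value, keeping the label internally
  consistent with the series). A candidate onset is the earliest visit at or
  above threshold such that a confirming visit at least 24 weeks later
  exists; in the default *strict* mode every visit between onset and the
  confirming visit (inclusive) must stay at or above threshold, a
  *confirmation-visit-only* mode is available. Event time is the onset
  time, not the confirmation time (the standard trial convention). Without
  a qualifying onset the patient is censored at the last visit.

## The effect model

The CATE estimator is a multi-headed MLP: a shared hidden layer (ReLU) of
width `hidden_width`, then per arm one treatment-specific hidden layer
(ReLU, same width) and a scalar output predicting that arm's
potential-outcome slope. Sharing the trunk lets arm-independent prognostic
structure be learned from all patients regardless of allocation; the heads
capture arm-specific response structure. No propensity correction is used:
the data are randomized, so allocation is independent of features. The
reported CATE is `-(mu_treatment - mu_control)`, positive = benefit.

**Optimization.** Mini-batch gradient descent with momentum on the weighted
factual loss: only the allocated arm's head contributes per patient, with
per-arm weight `n_s/(m * n_t)` (training-split size over arms times arm
size), which makes the size-weighted mean of the weights exactly 1 and
offsets allocation imbalance. Regularization: inverted dropout on both
hidden layers (never on the input), L2 on weight matrices (not biases), and
after every update a max-norm constraint on each unit's incoming weight
vector (columns of each weight matrix are rescaled if their Euclidean norm
exceeds `max_norm`). Batches are stratified: each epoch the arms are
shuffled independently and interleaved proportionally, so every batch
approximately preserves arm proportions; the final short batch is kept.
Weight init is He-style uniform (±sqrt(6/fan_in)), seeded; everything
downstream of a seed is bit-reproducible.

**Early stopping and ensembling.** 4-fold CV stratified by arm; each fold
trains up to 100 epochs and keeps the parameter snapshot from the epoch with
the lowest validation *unweighted* factual MSE (the imbalance weights apply
to the training gradient only; validation quality is measured on the natural
scale). The four early-stopped fold models form the inference ensemble;
its prediction is the arithmetic mean of member predictions.

**Crogged metrics and hyperparameter search.** Validation metrics are
computed once over the pooled out-of-fold predictions (CV aggregation,
"crogging") rather than averaged per fold: a crogged factual MSE and a
crogged AD_wabc (out-of-fold CATE scores against the training cohort's CDP24
labels). Random search draws candidates from: learning rate log-uniform
[1e-4, 1e-1], momentum uniform [0.5, 0.99], L2 log-uniform [1e-6, 1e-2],
width from {16, 32, 64, 128}, max-norm uniform [1, 5], dropout uniform
[0, 0.5] (all configurable). Selection combines both metrics: among
candidates whose crogged MSE lies within one SD of the best candidate's MSE
(SD taken over that candidate's per-fold MSEs, ddof 1), the one with the
highest crogged AD_wabc wins. Defaults used when no search is run: width 64,
lr 0.02, momentum 0.9, L2 1e-4, dropout 0.1, max-norm 3, batch 64.

**Transfer.** Phase 1 trains a 5-headed model (four active arms + placebo)
on the relapsing-remitting-like cohort. Phase 2 builds 2-headed models for
the progressive cohort: fold i inherits the trunk of fold-i's pre-trained
member verbatim, freezes it (weights and biases; gradients are not applied
to it and L2 does not touch it), attaches freshly initialized heads, and
trains heads only. Fold-wise trunk pairing keeps the CV-ensemble structure
intact through both phases and makes the frozen-trunk contract exactly
testable (trunk arrays are bit-identical before and after fine-tuning).
Pre-training and fine-tuning must share the trunk width.

## Baseline rankers

Single-feature rankers use (sign x feature) or (sign x feature / disease
duration) directly as scores; only the induced order matters downstream, so
AD(c)-based comparisons are invariant to any strictly increasing rescaling.
The ridge T-learner fits one L2 linear slope regression per arm (CATE =
sign-flipped difference). The Cox T-learner fits one proportional-hazards
model per arm on time-to-CDP24 (Breslow ties, via lifelines) and scores by
control-arm minus treatment-arm log partial hazard — a survival model has no
slope-scale CATE, but the linear-predictor difference preserves the ranking,
which is all the evaluation consumes; an RMST-difference variant would be a
drop-in alternative. The prognostic ranker trains the same MLP machinery on
placebo patients only (single head) and scores by predicted untreated slope
(worse prognosis = more responsive). The binary clinical rule flags
responders as age < 51 and Gad count > 0 on raw features.

## Ranking evaluation

Kaplan–Meier estimation, the two-group log-rank test and the univariate Cox
HR come from lifelines; KM confidence bands use the exponential Greenwood
(log(-log)) transform at 95%. The HR is reported with a Wald CI and paired
with the log-rank p-value. RMST is the area under the KM step function to
the horizon (2 years by default), with survival extended flat beyond the
last observed time; the AD(c) loop uses a vectorised numpy KM/RMST path
that is tested for equality against lifelines.

AD(c): for threshold c, the responder subset is every patient whose score is
at least the empirical c-quantile (lower order statistic; threshold ties are
retained — "predicted to respond more than a certain threshold"), and AD(c)
is the treated-minus-control RMST difference inside the subset. AD(0) is the
whole-group difference; a subset with an empty arm yields NaN at that c
(recorded, not fatal). Default grid: c = 0, 0.05, ..., 0.85 — higher
thresholds leave unstably small arms; configurable.

AD_wabc is the weighted area between AD(c) and the AD(0) level, normalized:
trapezoidal integral of `w(c) * (AD(c) - AD(0))` over the defined grid
divided by the integral of `w`, with `w(c) = 1 - c` (the retained cohort
fraction) by default; uniform weighting is available. A flat curve scores
exactly 0; larger positive values mean better responsiveness ranking. The
responder/non-responder characteristic table uses Welch's two-sided t-test
with a Satterthwaite-df CI for continuous/ordinal features and a Fisher
exact test with a Woolf-CI odds ratio for sex; a feature with zero variance
in both groups reports p = 1 with a degeneracy flag.

## Trial design

Sample size for a two-sided log-rank test under a proportional-hazards
alternative with allocation ratio k (treatment:control), hazard ratio HR and
arm event probabilities p_t, p_c:

    m   = (1/k) * ((k*HR + 1)/(HR - 1))^2 * (z_{1-alpha/2} + z_{power})^2
    d   = k*p_t + p_c
    n_t = ceil(m*k/d),  n_c = ceil(m/d),  n_total = n_t + n_c

Each arm is rounded up *separately* before summing; this per-arm ceiling
convention reproduces all sixteen published two-year and one-year scenario
totals exactly from their printed HRs and event rates (verified in the
acceptance suite, with lifelines' implementation as an independent
cross-check). HR = 1 and zero event rates are errors (infinite sample).
The enrichment table computes, per percentile threshold: subset event rates
at the horizon as 1 - KM(horizon) (censoring-aware; a crude-proportion
option exists), the subset Cox HR, the required sample size at the given
ratio/power/alpha, and the number screened, `ceil(n_total/(1 - q/100))`.
Subsets where the HR or the sample size is not estimable (an empty or
event-free arm, HR = 1) are flagged rather than fatal.

## Synthetic trial generator

The generator defines the study conditions for every test. Per trial it
samples baseline features from independent distributions loosely matched to
progressive-MS trial-arm summaries (age ~ N(46, 8); EDSS from a discretized
N(4.6, 1.2) clipped to 1.0–6.5; T2 volume log-normal, median ~6 mL; Gad
zero-inflated Poisson, mean ~0.6; NBV ~ N(1.45, 0.09); FSS rounded normals
on 0–6), applies an optional per-trial multiplicative/additive shift to the
MRI metrics (emulating inter-trial segmentation scale differences), and
randomizes arms by configurable weights (default 2:1) independently of the
features.

Each patient gets a latent slope `beta0(x) - tau(x) * e(arm) + noise`, where
`beta0` is the untreated progression rate (default: mean 0.25 EDSS/yr,
increasing with baseline EDSS and lesion load), `tau` is the configured true
effect (benefit-positive), `e(arm)` is a per-arm effect multiplier (0 for
placebo, 1 for a two-arm trial's active arm; the 5-arm RRMS-like preset uses
distinct multipliers per arm), and patient-level noise has SD 0.4 EDSS/yr.
EDSS visits follow a 12-weekly schedule to week 120; each observation is the
latent level plus N(0, 0.3) observation noise, quantized to the valid grid
by *stochastic rounding* (each value rounds to a neighbouring grid point
with probability proportional to proximity). Stochastic rounding makes the
observed score an unbiased quantization of the latent trajectory —
deterministic nearest-rounding of a slowly drifting ramp anchored at an
on-grid baseline systematically biases fitted slopes. Right censoring is an
arm-independent exponential dropout (default hazard 0.08/yr). Under these
defaults roughly a quarter of patients reach CDP24 within two years,
matching the event-rate range the design calculations assume.

Preset effect functions: `linear_cate(strength)` (linear in standardized
log-T2, negative age and EDSS; at strength 1, mean ~0.12 and SD ~0.14
EDSS/yr) and `strong_linear_cate()` (strength 1.5, SD ~0.2) for the
recovery and ranking-metric study conditions; `constant_cate(v)` for
homogeneous-effect nulls.

What the generator does **not** emulate: joint feature correlations of real
cohorts, arm-dependent dropout, visit-schedule irregularity, EDSS floor/
ceiling dynamics beyond clamping, or non-proportional hazards. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
effects under a known, well-behaved generative model — not clinical
performance on real trial data, which is private and out of reach here. For
the same reason the published whole-cohort effect sizes (hazard ratios,
AD_wabc values, cohort tables) are not reproduced anywhere in this package;
the acceptance suite instead checks the structural analogues on synthetic
cohorts (enriched subgroups show smaller hazard ratios, oracle rankings beat
random ones).

## Problem sizes and determinism

The heavy checks run at deliberately chosen sizes: effect-recovery at
n = 2500 (pre-training) + n = 2000 (fine-tuning), ranking-metric properties
at n = 4000 with 100 replicates. These sizes give stable statistics while
keeping the full suite in a few minutes on one CPU. All randomness flows
from explicit seeds (generator config, model init, fold splitting, dropout),
and rerunning any pipeline with the same seed is bit-identical.
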