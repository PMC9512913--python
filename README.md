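# msenrich

Predictive-enrichment toolkit for disability-progression trials in multiple
sclerosis (MS).

Disability progression in progressive MS has no good short-term biomarker, so
phase-2 trials are large, long and risky. One way out is *predictive
enrichment*: estimate each patient's expected treatment benefit from baseline
characteristics, and preferentially randomize the patients predicted to be
most responsive, which concentrates the treatment effect and shrinks the
required sample size. `msenrich` implements that workflow end to end:

* **Effect model.** An ensemble of multi-headed multilayer perceptrons
  estimates the conditional average treatment effect (CATE). Under the
  potential-outcomes framework the individual effect is
  `tau_i = Y_i(1) - Y_i(0)`; the network is a T-learner variant with a shared
  ReLU trunk and one hidden-layer-plus-output head per treatment arm, each
  head predicting the potential-outcome EDSS slope `mu_t(x)` (EDSS change per
  year, fitted by OLS over a patient's visits). The reported estimate is the
  sign-flipped difference `tau_hat(x) = -(mu_1(x) - mu_0(x))`, so positive
  values mean predicted benefit. Training uses mini-batch SGD with momentum
  on a weighted factual loss (weights `n_s / (m * n_t)` offset allocation
  imbalance), dropout, L2 and max-norm regularization, 4-fold CV with
  per-fold early stopping, "crogged" (pooled out-of-fold) validation
  metrics, a random hyperparameter search with a one-SD selection rule, and
  a pretrain-freeze-finetune transfer scheme (5-headed pre-training on a
  relapsing-remitting cohort, then 2-headed fine-tuning with a frozen trunk
  on a primary-progressive cohort).
* **Outcome labels.** EDSS slope (regression target) and time to 24-week
  confirmed disability progression, CDP24 (evaluation target), with the
  standard baseline-dependent progression increment (1.5 from EDSS 0, 0.5
  above 5.5, 1.0 otherwise).
* **Ranking evaluation.** The average-difference curve AD(c) — the
  ground-truth restricted-mean-survival-time (RMST, 2-year horizon)
  difference between arms among patients whose predicted effect exceeds the
  c-th percentile — and its scalar summary AD_wabc, a (1-c)-weighted area
  between AD(c) and its unenriched level. Kaplan–Meier estimation with
  exponential-Greenwood CIs, log-rank tests and Cox hazard ratios are
  delegated to `lifelines`.
* **Trial design.** Rosner-style log-rank sample sizes under a proportional
  hazards alternative at a 2:1 allocation, per-percentile enrichment tables
  (event rates, HR, required n, number screened).
* **Synthetic trials.** A generator producing multi-trial randomized cohorts
  with known ground-truth `tau(x)`, used by the whole test suite in place of
  the (private) clinical-trial data.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import msenrich as me
from msenrich import cate_mlp as cm, outcome_labels as ol, synthetic_trials as st
from msenrich import survival_eval as se

def prepare(cfg, ref):
    ds, truth = st.generate_dataset(cfg)
    ds, _ = me.apply_exclusions(ds)
    _, M = me.fit_transform(ds, reference_trial_id=ref)
    lab = ol.label_dataset(ds)
    base = ds.baseline_frame()
    return truth.loc[M.index], M, lab.loc[M.index], base.loc[M.index]

_, RM, rlab, rbase = prepare(st.rrms_config(n=2500, cate=st.linear_cate(1.0), seed=11), "RRMS_A")
ptruth, PM, plab, pbase = prepare(st.ppms_config(n=2000, cate=st.strong_linear_cate(), seed=12), "TRIAL_A")

hp = cm.HyperParams(seed=3)
res = cm.pretrain_and_finetune(
    (RM.to_numpy(), rlab["slope"].to_numpy(), rbase["arm_id"].to_numpy()),
    (PM.to_numpy(), plab["slope"].to_numpy(), pbase["arm_id"].to_numpy()),
    hp, hp, k=4,
)
pred = res.ensemble.predict_cate(PM.to_numpy(), "treatment", "placebo")
print("Spearman(pred, true tau):", round(spearmanr(pred, ptruth["true_cate"]).statistic, 3))

treated = pbase["arm_id"].to_numpy() == "treatment"
times, events = plab["ttcdp24_years"].to_numpy(), plab["event"].to_numpy(bool)
curve = se.ad_curve(pred, times, events, treated)
print("AD_wabc:", round(se.ad_wabc(curve), 4))
print("whole-group HR:", round(se.cox_hr(times, events, treated).hr, 3))
```

prints

```
Spearman(pred, true tau): 0.744
AD_wabc: 0.112
whole-group HR: 0.505
```

i.e. the fine-tuned ensemble ranks the (known) individual effects well
(Spearman 0.74), the positive AD_wabc confirms that enriching on the model's
scores raises the between-arm RMST difference, and the whole-group hazard
ratio is the unenriched effect against which enriched subgroups can be
compared. Sample-size design for an enriched trial:

```python
>>> me.sample_size_cph(hr=0.49, p_event_treatment=0.20, p_event_control=0.33, ratio=2.0)
(163, 82, 245)
>>> me.number_screened(245, 50)
490
```

A 2:1 two-year trial run in the most-responsive 50% (HR 0.49) needs 245
randomized patients from 490 screened, against 1374 randomized without
enrichment (HR 0.74, rates 0.24/0.30).

A `msenrich` command-line interface mirrors the workflow
(`simulate -> label -> preprocess -> train -> rank -> evaluate -> enrich`);
run `msenrich --help`.

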