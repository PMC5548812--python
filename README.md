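# infarctgrowth

Modelling and prediction of infarct growth in malignant middle-cerebral-artery
(MMCA) stroke from serial non-contrast CT.

Patients evaluated for decompressive hemicraniectomy typically have three CT
scans before surgery, giving three (volume, time) pairs per patient:
V₁@t₁, V₂@t₂, V₃@t₃ (volumes in cm³, times in hours since symptom onset).
Anticipating the third-scan volume V₃ from the first two scans would let
tissue-based markers, rather than clinical deterioration alone, guide the
timing of surgery. This package implements and compares four predictors of
V₃, together with the training protocol and the evaluation statistics needed
to judge them, and ships a 26-patient clinical test table against which the
whole evaluation battery is reproduced exactly.

## Models

Growth rates are finite differences, with the infarct assumed absent at
onset:

    IGR₁ = V₁ / t₁,    IGR₂ = (V₂ − V₁)/(t₂ − t₁),    IGR₃ = (V₃ − V₂)/(t₃ − t₂)

Three fixed closed forms extrapolate V₃ directly:

* **linear** V₃ = V₂ + [(V₂ − V₁)/(t₂ − t₁)] (t₃ − t₂)
* **logarithmic** V₃ = V₂ + (V₂/t₂) ln(t₃ − t₂)
* **exponential** V₃ = V₂ + V₂ exp[ −(t₃ − t₁) / (100 ln((V₂ − V₁)/(t₂ − t₁))) ]

The fourth predictor is a first-order Sugeno **ANFIS** (adaptive neuro-fuzzy
inference system) mapping (IGR₁, IGR₂) → IGR₃. Each input is fuzzified by
three Gaussian membership functions G₁–G₃; the default rule base is the three
diagonal rules "if IGR₁ is Gₖ and IGR₂ is Gₖ then IGR₃ = pₖ·IGR₁ + qₖ·IGR₂ + rₖ";
the crisp output is the firing-strength-weighted average of the rule outputs,
and predicted volume follows as V₃ = V₂ + IGR₃ (t₃ − t₂). Parameters are
fitted by Jang's hybrid rule — exact linear least squares for the consequents
(forward pass), normalized gradient descent for the membership parameters
(backward pass) — inside a Monte-Carlo resampling loop: 30 random 60/40
train/validation splits, keeping the model with the lowest validation MSE.

Evaluation statistics follow clinical-reporting conventions: Pearson
correlation at lag zero (CRR), *population* skewness m₃/m₂^{3/2} and
*non-excess* kurtosis m₄/m₂², sample SD (n−1), and a two-tailed paired
t-test against the measured volumes.

## Worked example

```bash
$ infarctgrowth reproduce-table2
              n     mean       sd    crr  skewness  kurtosis  p_value        mse
method
original     26 332.0112 112.2124 1.0000    0.5700    4.0336   1.0000     0.0000
anfis        26 319.0558  94.5795 0.8190    0.6869    4.4860   0.3151  4160.8197
linear       26 251.7715 154.4578 0.4843    0.9624    3.3170   0.0073 25343.7749
logarithmic  26 259.6835  88.7617 0.7009   -0.1333    2.9240   0.0001 11489.9860
exponential  26 157.7969  84.0489 0.6310    0.1348    2.5953   0.0000 37805.8320
all printed summary values reproduced at 2 dp
```

Reading the block: the measured third volumes average 332.01 ± 112.21 cm³;
the ANFIS predictions correlate 0.82 with them (versus 0.48/0.70/0.63 for
the linear/logarithmic/exponential forms), their distribution shape matches
the measurements (skewness 0.69 vs 0.57, kurtosis 4.49 vs 4.03), they are
the only predictions not significantly different from the measurements
(paired p = 0.32), and their mean squared error is the smallest by a factor
of ~3.

The same pipeline from Python, on synthetic data:

```python
import infarctgrowth as ig

cohort = ig.generate_cohort(ig.CohortConfig(n_patients=67, seed=7))
result = ig.run_mcs(cohort.records, ig.MCSConfig(repetitions=30, seed=7))
print(result.best_repetition, round(result.best_mse, 3))
# 3 4.19   <- best of 30 repetitions, validation MSE in (cm^3/h)^2
ev = ig.evaluate_holdout(result.best_model, cohort.records)
print(round(ev.mse_iv3, 1))
# 8792.0   <- volume-scale MSE, cm^6
```

Shell equivalents: `infarctgrowth simulate | train | predict | evaluate`
(each writes a `.manifest.json` with the seed and versions needed to
reproduce its output bit-identically).

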