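# Methods

## Setting and quantities

Each patient contributes three CT measurements of infarct volume,
(V₁, t₁), (V₂, t₂), (V₃, t₃), with times in hours since stroke onset and
volumes in cm³ (1 ml is treated as identical to 1 cm³ throughout). The
infarct is assumed to have zero volume at onset, so the first growth rate is
IGR₁ = V₁/t₁; later rates are finite differences between consecutive scans.
Growth rates after the first may be negative — lesions occasionally measure
smaller on a later scan — and the package accepts that for rate computation,
while the exponential predictor (below) treats a non-growing lesion as a
domain error.

A record whose third volume is unmeasured is a valid *prediction target*
(the third scan time must still be present, since every predictor needs the
prediction horizon); such records are rejected by training and evaluation.

## Closed-form predictors

The three analytic models are fixed formulas, not fitted curves:

* Linear: V₃ = V₂ + [(V₂−V₁)/(t₂−t₁)](t₃−t₂). Exact for affine
  trajectories; invariant to shifting all times by a constant.
* Logarithmic: V₃ = V₂ + (V₂/t₂)·ln(t₃−t₂). The ln argument is the raw
  hour gap, which is dimensionally informal but is implemented literally as
  published. For gaps under one hour the increment is negative; the
  prediction is returned with a `subhour_gap` flag rather than raising,
  since the formula remains well defined. Not time-shift invariant (t₂
  appears absolutely).
* Exponential: V₃ = V₂ + V₂·exp[−(t₃−t₁)/(100·ln s)] with inter-scan slope
  s = (V₂−V₁)/(t₂−t₁). Implemented exactly as published, including the
  constant 100 and the (t₃−t₁) numerator. s ≤ 0 raises a log-domain error
  and s = 1 a division-by-zero (ln s = 0). Algebraically this form *is*
  time-shift invariant: it depends only on the differences t₃−t₁ and t₂−t₁.

Every predictor also reports the growth rate it implies, so that
predicted_iv3 = V₂ + predicted_igr3·(t₃−t₂) holds identically.

## ANFIS

The neuro-fuzzy predictor is a first-order Takagi–Sugeno system on the two
inputs (IGR₁, IGR₂):

1. **Fuzzification.** Each input has three Gaussian membership functions
   μ(x) = exp(−(x−c)²/2σ²). Initialization places centers at the min,
   midpoint and max of the training range; widths are (max−min)/(2(n_mf−1)),
   floored at 10⁻⁶ (the floor also bounds gradient updates away from
   degenerate widths).
2. **Rules.** Default rule base: the three diagonal rules (Gₖ, Gₖ) → fₖ.
   A full 3×3 grid is available (`rule_base="grid"`); the decision surface
   over the input rectangle is obtainable either way, the diagonal base
   simply ties the cluster index across inputs. Firing strength is the
   product T-norm of the two memberships.
3. **Consequents and defuzzification.** Rule outputs are linear,
   fₖ = pₖ·IGR₁ + qₖ·IGR₂ + rₖ (a zero-order option fixes pₖ = qₖ = 0), and
   the crisp output is Σ w̄ₖ fₖ with normalized firings w̄ₖ. This weighted
   average is the centroid of the singleton rule outputs; it confines every
   prediction to the envelope [min fₖ, max fₖ] — the "stretched sheet"
   bound, which is also why the model cannot extrapolate beyond the span of
   its training data. A query at which no rule fires numerically raises an
   out-of-support error instead of returning 0/0.
4. **Hybrid learning.** Per epoch: (forward) with premises fixed, the
   consequents solve the linear least-squares problem in the
   normalized-firing design matrix — `numpy.linalg.lstsq`, with a ridge
   term ε = 10⁻⁸ on the normal equations plus a warning when the system is
   rank-deficient (e.g. a rule that never fires; its coefficients then
   collapse to ≈0); (backward) all centers and widths take one gradient
   step against the squared prediction error. The update is Jang's
   normalized step, Δθ = −η·g/‖g‖ with η the step size, so `step_size=0`
   is exactly a no-op and the raw analytic gradient is exposed separately
   (`premise_gradients`) for verification against finite differences.
   Step-size policy: start at 0.01, ×1.1 after four consecutive error
   decreases, ×0.9 after two consecutive up/down oscillation pairs.
   Training runs 50 epochs by default with early stopping when the relative
   RMSE improvement falls below 10⁻⁶ or the RMSE itself falls below 10⁻¹²
   (an exact fit, where the normalized step would otherwise keep perturbing
   converged premises). After a full epoch budget the consequents are refit
   once so they are always least-squares-optimal for the final premises.

Because the least-squares pass is exact, one hybrid epoch can never end
with a worse training RMSE than the consequent fit alone — a property the
test suite asserts.

Models serialize to versioned JSON; doubles survive the round trip
bit-exactly (Python's `json` emits `repr`-faithful floats), so a reloaded
model predicts identically.

## Monte-Carlo training protocol

Training resamples the cohort: per repetition (30 by default) the records
are randomly split 60/40, a fresh ANFIS is hybrid-trained on the 60% and
scored by validation MSE of IGR₃ on the 40%, and the incumbent model is
replaced only by a strictly lower MSE (ties keep the earlier model), making
the retained-MSE trace non-increasing by construction. The split rounds the
training side up, so 67 patients split 41/26; a round-half-up option gives
40/27. MSE is computed on the trained quantity (IGR₃, units (cm³/h)²), with
the volume-scale MSE reported alongside by the holdout evaluator.

Each repetition draws its generator from a spawned `SeedSequence` child of
the root seed, so a single repetition is reproducible in isolation and the
whole run is bit-deterministic. Repetitions that diverge (non-finite
validation error) are discarded with a warning rather than poisoning the
incumbent.

When run standalone the protocol resamples whatever cohort it is given; the
`train` CLI command first holds out a fixed final test fraction (40% by
default) and resamples only within the remaining pool, so the reported
held-out performance never touches training data. Both modes exist because
either reading of a 60/40-inside-resampling protocol is defensible; the
leakage-free one is the default pipeline.

## Synthetic cohorts

The generator emulates the marginal structure of a hemicraniectomy cohort:

* **Times.** t₁ and the two inter-scan gaps are log-normal, parameterized
  directly by target mean/SD — defaults 6.39 ± 6.76 h, 30.87 ± 23.53 h and
  36.85 ± 48.55 h. Log-normals guarantee positivity and the right skew;
  the gap targets are chosen so the implied second- and third-scan
  marginals have means 37.26 and 74.11 h and SDs ≈ 24.5 and 54.4 h (SDs of
  independent gaps add in quadrature). Times are therefore calibrated by
  construction and are what the calibration test checks against 3 standard
  errors at n = 2000.
* **Volumes.** A latent per-patient saturating-exponential law
  V(t) = Vmax(1−e^(−kt)), Vmax ~ log-normal(450, 120) cm³ and
  k ~ log-normal(0.030, 0.012) h⁻¹, chosen once by coarse moment matching:
  on the default time grid the noiseless marginals land near 71/263/351 cm³
  (large-n values 70.98/262.94/350.76), close to the 73/251/353 cm³ of real
  cohorts of this kind. A bounded law was chosen because infarcts plateau
  as the lesion fills the arterial territory; unbounded linear and logistic
  laws are selectable for stress tests. Volumes are *emergent*, not
  directly parameterized, so their test compares realized means against the
  generator's own large-n reference rather than against external targets.
* **Noise.** Multiplicative Gaussian measurement noise (default SD 5%),
  floored at zero volume. Records rendered non-monotone by noise are kept
  (real lesions occasionally measure smaller later) but flagged in the
  truth table.
* **Planted truth.** Either a planted Sugeno model for IGR₃ inside the
  cohort generator (the third volume is rebuilt as V₂ + g(IGR₁,IGR₂)(t₃−t₂)),
  or bare (IGR₁, IGR₂, IGR₃) triples drawn uniformly over a rate rectangle
  (defaults 0.5–12 × 0.5–25 cm³/h, bracketing clinically observed rates).
  Recovery tests plant a truth model whose premises coincide with the
  fitter's own initialization geometry, so noiseless data admit an exact
  in-class solution and the noisy-data holdout RMSE should approach the
  injected noise SD.

What the generator does **not** emulate: correlations between scan timing
and lesion size (times and growth parameters are drawn independently; real
cohorts are scanned sooner when deterioration is faster), covariate effects
(age, risk factors, collateral status), and the abrupt volume jumps of
collateral failure. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the marginals, not clinical performance on
real cohorts.

## The packaged 26-patient table

The package ships the published test table of 26 patients (measured third
volume, four per-method predictions, time to third CT, demographics) exactly
as printed, including integer-valued cells. The evaluation battery
recomputes its entire summary block — mean 332.01, sample SD 112.21 cm³,
CRR 0.82/0.48/0.70/0.63, skewness 0.57/0.69/0.96/−0.13/0.13, kurtosis
4.03/4.49/3.32/2.92/2.60 — at two decimal places, which pins down the
statistic conventions: CRR must be the *centered* (Pearson) correlation,
the moments must be population moments (biased, non-excess), and the
summary SD the n−1 sample SD. The printed per-method P values
(0.32/0.01/0.00/0.00) are reproduced by a two-tailed paired t-test, which
is therefore the default comparison. Comparisons against printed values
round half away from zero, matching how such tables are typeset.

The per-patient linear/logarithmic/exponential predictions in that table
cannot be *re-derived* from it: the required per-patient V₁, V₂, t₁, t₂ are
not published, and inverting the formulas from the predictions alone is
underdetermined. The table is therefore a fixture for the evaluation
statistics, not for the predictors.

## Numerical and design notes

* Test-suite problem sizes: planted recovery uses 500 rate triples
  (300/200 train/test), Monte-Carlo checks 67-patient cohorts with 30
  repetitions, generator calibration 2000 patients; each was chosen as the
  smallest size at which the statistical assertions are stable.
* The published narrative describes output "clusters" and a "centroid",
  which reads Mamdani-style, but the described learning rule (least squares
  + backpropagation) is exactly Sugeno-type hybrid learning; this package
  implements the Sugeno reading, with the zero-order option as the nearest
  Mamdani-like variant.
* Whether the original MATLAB model used 3 or 9 rules, zero- or first-order
  consequents, or fed scan times directly into the network is not recorded;
  here times enter only through rate computation and the IGR₃→V₃
  conversion, per the two-input network structure.
* Known limitations: the ANFIS cannot extrapolate beyond its training
  envelope (by construction); the three-rule diagonal base cannot represent
  targets requiring independent cluster indices per input (use the grid
  base); sub-hour third-scan gaps make the logarithmic model's increment
  negative (flagged); and the exponential model is undefined for
  non-growing lesions.
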