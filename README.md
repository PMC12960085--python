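# ventcost

Predicting the **oxygen cost of ventilation** (V̇O2VENT) during
ramp-incremental cycle exercise, and correcting whole-body oxygen uptake
for it.

During a maximal ramp test, the respiratory muscles consume an increasing —
and near exhaustion, disproportionate — share of whole-body V̇O2. Measuring
that share directly requires ventilation-mimicking trials with added CO₂,
which most exercise-testing laboratories cannot run. `ventcost` implements
a six-predictor composite regression model that estimates peak V̇O2VENT
from quantities every cardiopulmonary exercise test already produces, and
applies it breath by breath to obtain ventilation-corrected V̇O2
trajectories (V̇O2VCORR = V̇O2 − V̇O2VENT). It is aimed at exercise
physiologists and sports scientists analysing ramp-test gas-exchange data.

## The model

With V̇E the peak expired ventilation (L·min⁻¹, STPD), W weight (kg), H
height (cm), A age (years), V̇O2peak (L·min⁻¹) and HRmax (beats·min⁻¹):

```
V̇O2VENT = c + v₁·V̇E + v₂·V̇E² + v₃·V̇E³
         + w₁·W + w₂·W² + w₃·W³
         + s·exp(k·H)
         + a₁·A + p₁·V̇O2peak + h₁·HRmax
```

The published coefficient set ships with the package
(`ventcost.published_composite()`), as do the six single-predictor
relationships it was assembled from (`ventcost.published_submodels()`) and
the 42-participant derivation cohort. The model is linear in every
parameter except the height rate k, so refitting is solved as a
one-dimensional profile over k with an exact linear least-squares solve at
each candidate — no unstable 16-parameter black-box optimisation.

Also included:

* **Validation** — leave-one-out cross-validation, seeded bootstrap
  resampling with percentile CIs, calibration (predicted-on-observed OLS),
  residual diagnostics, and collinearity screening (Pearson matrix + VIF).
* **Application** — breath averaging, V̇O2VENT/V̇O2VCORR trajectories,
  %Wpeak intensity tables, final-30 s slopes, paired slope tests, and
  one-/two-way within-subject repeated-measures ANOVA with
  Greenhouse–Geisser correction.
* **Gas volumes** — BTPS → STPD conversion.
* **Synthetic data** — a seeded generator of physiologically structured
  ramp tests and model-true cohorts, so the whole pipeline is testable
  without any external data.

## Worked example

```python
import ventcost as vc
from ventcost.composite import predict_record
from ventcost.synthetic import SimParams, generate_subject

cohort = vc.derivation_cohort()                 # packaged n = 42 table
fit = vc.fit_composite(cohort)
report = vc.loocv(cohort)
rec = cohort.records[0]
print(f"composite refit: R2 = {fit.r2:.3f}, RSS = {fit.rss:.3f}")
print(f"in-sample RMSE = {report.apparent.rmse:.3f}, held-out RMSE = {report.rmse:.3f}")
print(f"subject 1 predicted VO2VENT = {predict_record(vc.published_composite(), rec):.3f}")

rec, series = generate_subject(SimParams(seed=7))     # synthetic ramp test
res = vc.apply_correction(vc.published_composite(),
                          vc.rie.average_breaths(series, 7), rec)
print(f"VO2VENT at max = {res.percent_vent_at_max:.1f}% of VO2peak")
print(f"final-30s slopes: VO2 {res.slope_vo2:.3f} vs VO2VCORR {res.slope_vo2vcorr:.3f}")
```

prints

```
composite refit: R2 = 0.814, RSS = 0.673
in-sample RMSE = 0.127, held-out RMSE = 0.172
subject 1 predicted VO2VENT = 0.415
VO2VENT at max = 22.7% of VO2peak
final-30s slopes: VO2 0.371 vs VO2VCORR 0.068
```

Reading these numbers: the refit composite model explains 81.4% of the
variance in measured peak V̇O2VENT across the 42 derivation subjects, with
a residual sum of squares of 0.673 (L·min⁻¹)². The in-sample RMSE (0.127
L·min⁻¹) is the optimistic apparent error; honest leave-one-out prediction
error is larger (0.172 L·min⁻¹) because 12 parameters are fit to 42
subjects — the package always reports both. Subject 1's predicted cost
(0.415 L·min⁻¹) sits next to the measured 0.42. On the synthetic ramp
test, breathing costs ~23% of V̇O2 at peak, and subtracting it flattens
the final-30 s V̇O2 slope from 0.371 to 0.068 L·min⁻¹ per minute — the
end-test V̇O2 rise is largely ventilatory.

A `ventcost` console script exposes the same pipeline
(`ventcost summarize|convert|fit|predict|validate|correct|simulate`);
see `ventcost --help`.

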