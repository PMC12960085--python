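# Methods

This note records the modelling assumptions, numerical choices and design
decisions behind `ventcost`, and what the synthetic-data tests do and do
not demonstrate about real ramp-test data.

## The composite model

Peak oxygen cost of ventilation (V̇O2VENT, L·min⁻¹) is modelled as an
additive combination of fixed single-predictor forms: a cubic in peak
expired ventilation V̇E (L·min⁻¹, STPD), a cubic in body weight (kg), an
exponential `s·exp(k·H)` in height (cm), and linear terms in age (years),
V̇O2 peak (L·min⁻¹) and maximal heart rate (beats·min⁻¹). The functional
forms are treated as given — they were chosen in the original analysis by
lowest standard error per predictor — and are not re-searched here; a
user can compare candidate forms per predictor with `submodels.fit_submodel`.

The published coefficient set distributes the intercept over five additive
constants. Only their sum is identifiable; predictions are invariant to
redistributing mass among them (property-tested), and refits return a
single effective intercept.

Assumptions worth stating explicitly: predictors enter additively (no
interactions), measurement error lives in V̇O2VENT only, and the model is
a population-level description of healthy, largely trained adults — the
packaged derivation cohort spans V̇E 58–190 L·min⁻¹, age 20–44, weight
38–95 kg, height 152–196 cm. Evaluations outside those ranges warn rather
than fail.

## Refitting: profiled linear least squares

The model is linear in all parameters except the height rate `k`. Refits
therefore profile `k`: for each candidate the remaining 11 coefficients
are solved exactly by column-scaled `lstsq`, and the profile is minimised
over a coarse grid on [−0.06, 0.06] (61 points, plus any rates suggested
by the initialisation) followed by bounded scalar refinement
(`xatol = 1e−9`). Over heights of 150–200 cm a rate of |k| = 0.06 already
spans enormous curvature; beyond it the exponential column is numerically
a step function. Convergence is declared when the refinement can no longer
reduce the residual sum of squares (relative criterion 10⁻⁸).

Two facts shape everything downstream:

* **The height term is weakly identified.** Near `k ≈ 0` (the published
  rate is 6.3·10⁻⁵ per cm), `s·exp(k·H) ≈ s + s·k·H`, so the intercept,
  scale and rate trade off along a ridge: only the height *profile* they
  jointly define is determined by data. Refits on equally plausible
  cohorts legitimately return very different raw (intercept, s, k)
  triples with near-identical predictions. Tests of coefficient recovery
  therefore check the nine separably identifiable coefficients (V̇E and
  weight polynomials, age, V̇O2peak, HRmax), not the raw trio.
* **Apparent vs held-out performance differ materially.** Twelve
  identifiable parameters fit to 42 subjects give an average leverage of
  ~0.29, so honest leave-one-out errors run ~35% above in-sample errors.
  The published performance figures (RMSE 0.128, MAE 0.098, calibration
  slope 0.81 = R²) coincide exactly with the in-sample identities of the
  converged fit — RMSE = √(RSS/n) and slope = R² — so the package computes
  and reports *both* layers everywhere: `loocv()` returns held-out metrics
  plus an `apparent` block, and the acceptance script reports the
  in-sample quantities (the published ones) while printing the held-out
  figures beside them. On the packaged cohort the refit gives
  R² = 0.814 / RSS = 0.673, in-sample RMSE 0.127 / MAE 0.097, and honest
  LOOCV RMSE 0.172 / MAE 0.137.

Negative predictions are physiologically impossible and are clamped to
zero with a warning; the raw value remains available
(`clip_negative=False`) for diagnostics.

## Validation battery

**LOOCV** refits the composite model n times on n−1 subjects; pooled
held-out predictions give RMSE/MAE/R², with adjusted R² using k = 6
predictors and the full n. Folds that fail to converge are excluded and
counted; more than 10% failures aborts.

**Calibration** regresses predicted on observed. For in-sample OLS fitted
values the identities slope = R², intercept = (1−R²)·mean(observed) hold
exactly and are asserted as such.

**Bootstrap** resamples subjects with replacement (seeded,
bit-reproducible) and refits per resample. The default per-iteration
metric pipeline records the *apparent* metrics of each refit, with the
95% percentile interval of adjusted R² as the headline interval — this is
the pipeline whose intervals match the published (0.68, 0.90). An honest
alternative (`metric="loocv"`) runs grouped LOOCV inside each resample,
holding all duplicates of a subject out together to prevent
self-prediction; on n = 42 it is far more pessimistic, because a resample
contains only ~27 unique subjects against 12 parameters, and it is not
the default for that reason. Percentile (not BCa) intervals throughout;
no multiplicity adjustment within diagnostics.

**Collinearity** reports the 6×6 Pearson matrix and VIFs from the
regression definition (statsmodels), which equals the diagonal of the
inverse correlation matrix — asserted as an oracle equivalence. Perfect
collinearity raises rather than returning infinite VIFs.

## Application to breath-by-breath data

Only V̇E varies within a test, so the default trajectory convention slides
the instantaneous (block-averaged) V̇E through the model with the other
five predictors fixed at the subject's values. How the original LabVIEW
implementation produced submaximal values is undocumented; a
peak-anchored mode (peak prediction × V̇E(t)/V̇E_peak) is provided behind
a flag, as is an optional rest-offset mode that subtracts the prediction
at the pre-ramp baseline V̇E (off by default — resting V̇O2VENT is an
acknowledged open problem).

Numerical conventions: breath averaging uses non-overlapping blocks
(default seven breaths) with the trailing partial block dropped; %Wpeak
values interpolate the channels *in power*, using the last crossing if
power is non-monotone, because ramp intensities are defined by power;
final-window slope membership is by time stamp, inclusive of both
endpoints, and slopes are reported per minute. V̇O2VENT is stored as the
rounded complement of V̇O2VCORR so that the two reconstruct measured V̇O2
bit-exactly, samplewise (the stored value is within 1 ulp of the raw
prediction).

The repeated-measures ANOVA (one-way over conditions, or two-way
fully-within such as measure × intensity) is implemented directly from the
sums-of-squares decomposition, with Greenhouse–Geisser epsilon estimated
from the sample covariance of the repeated measures through orthonormal
contrast spaces (`ε = tr(CSC′)²/(d·ΣᵢⱼM²ᵢⱼ)`, clipped to [1/d, 1]); the
test suite cross-checks F, ε and GG-corrected p-values against pingouin
and against loop-written oracles, exhaustively on small integer designs.
Effect sums of squares within float noise of zero are snapped to zero so
degenerate designs yield F = 0 (no condition effect) or F = ∞ (zero error
SS) deterministically. Pairwise follow-ups are paired t-tests with
Bonferroni adjustment within each comparison family.

## Gas volumes

BTPS→STPD conversion is the product of a temperature ratio and a pressure
ratio, `273/(273+T) · PB/760`, with defaults T = 37 °C and PB = 635 mmHg
(the site conditions of the source V̇E trials; PB is configurable). No
saturated water-vapor correction is applied by default because the source
conversion did not include one; `subtract_water_vapor=True` enables the
textbook PB−47 form.

## Synthetic data generator

`synthetic.generate_subject` emulates the structure the application stage
assumes: linear power ramp (36 W·min⁻¹), V̇O2 as the exact first-order
response to the ramp demand (gain 0.010 L·min⁻¹·W⁻¹, τ = 35 s), V̇E
linear in V̇O2 (24 L per L) below a gas-exchange threshold at 60% of
end-test V̇O2 and gaining an exponential excess (rate 2.0 per L·min⁻¹
V̇O2) above it, tidal volume saturating at 2.6 L via a tanh profile while
breathing frequency rises to supply V̇E (ve = fr·vt exactly), breath
intervals shortening as frequency rises, and 3% multiplicative Gaussian
noise per breath on V̇O2 and V̇E. Baseline: 30 W, V̇O2 0.9 L·min⁻¹, 16
breaths·min⁻¹; duration 600 s. These defaults were chosen once as typical
for a trained adult on a 36 W·min⁻¹ ramp and produce peak values (V̇O2
~4.8 L·min⁻¹, V̇E ~150 L·min⁻¹, Wpeak ~390 W) inside the derivation
cohort's ranges.

`synthetic.generate_cohort` is deliberately *model-true*: "measured"
V̇O2VENT is drawn from the composite family plus Gaussian noise (default
σ = 0.13 L·min⁻¹, the derivation cohort's residual scale), with
anthropometrics sampled uniformly and independently within the derivation
ranges. This gives validation properties a known ground truth but means
the generator does **not** emulate: correlated anthropometrics (tall
people having higher V̇O2peak), model mis-specification, CO₂ kinetics or
hyperventilation trials, V̇O2 plateaus, or non-Gaussian breath noise.
Passing tests on synthetic data therefore demonstrate the *pipeline* —
conservation, slope attenuation under an exponential V̇E end-spurt,
estimator consistency and calibration of the inferential machinery — not
external validity of the model on new human cohorts.

## Sub-model fitting

Linear and cubic forms are exact linear least squares; cubics are solved
on numpy's mapped-domain basis and reported in raw powers, since raw
cubics on V̇E ~ 50–190 are badly conditioned. The exponential height form
is optimised from two starts (log-linear, and the published pair) keeping
the best RSS. The published V̇E-cubic constants carry enough printed
rounding that an exact refit of the packaged cohort reproduces their curve
(maximum divergence < 0.05 L·min⁻¹ over the observed range) but not every
raw coefficient to tight relative tolerance; tests assert curve agreement
for that form and coefficient agreement for the others.

## Known limitations

* The model's applicability is bounded by its derivation cohort: healthy,
  mostly trained adults on ramp cycle protocols. Step or constant-work
  protocols, clinical populations and extremes of body size are
  extrapolations.
* Held-out predictive error (~0.17 L·min⁻¹) is materially larger than the
  apparent error (~0.13); at an average peak cost of ~0.86 L·min⁻¹ that
  is a ±20% individual-level uncertainty. The two layers are never
  conflated in reports.
* The intercept/height-scale/height-rate trio is only jointly identified;
  refit values of those three coefficients should not be interpreted
  individually.
* Resting V̇O2VENT is unresolved; trajectories include the model's
  baseline-V̇E cost unless the rest-offset mode is enabled.
* The two-level "measure" factor in the two-way ANOVA (V̇O2 vs V̇O2VCORR)
  compares quantities that differ by a model-derived term; its p-values
  inherit the model's prediction uncertainty, which the ANOVA does not
  propagate.
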