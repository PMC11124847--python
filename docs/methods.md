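# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the limitations of `otterlab`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Physical model

### Homogeneous decay

A pulsed laser deposits heat at the surface of a semi-infinite sample; the
detector sees blackbody emission weighted by the sample's emission
absorption coefficient β at the detection wavelength. With the 1-D
instantaneous-surface-heating temperature field
`T(z,t) ∝ exp(−z²/4Dt)/√(πDt)` and emission weight `β·exp(−βz)`, the
detected transient is

    S(t) = A · e^(t/τ) · erfc(√(t/τ)),    τ = 1/(β²D).

`A` absorbs pulse energy, emissivity and detector coupling and carries
detector units. The kernel is evaluated as `erfcx(√(t/τ))` — the scaled
complementary error function — because forming `e^(t/τ)` explicitly
overflows for `t ≫ τ`. The kernel is strictly decreasing on [0, ∞),
bounded in (0, 1], and behaves as `1/√(π t/τ)` at long times; the test
suite checks it against a 30-digit `mpmath` evaluation over
`t/τ ∈ [1e−8, 1e8]`.

### Graded-absorption decay

For `β(z) = β₀ + w_β·z`, carrying the same emission integral through
(attenuation `exp(−β₀z − w_β z²/2)`, Gaussian temperature kernel) gives in
closed form

    S(t) = A [ 2W√(tτ/π)/(2Wt+1)
               + (2Wt+1)^(−3/2) e^((t/τ)/(2Wt+1)) erfc(√(t/τ)/√(2Wt+1)) ]

with the **effective gradient** `W = w_β·D`. `W` carries units of 1/s so
that every group `2Wt` is dimensionless; `τ = 1/(β₀²D)` is the *surface*
lifetime. Two identities pin the form down and are enforced at tight
tolerances: `W → 0` reduces pointwise to the homogeneous decay, and
`S(0) = A` for every `W` (no heat has diffused at t = 0, so only the
surface emits). The closed form is additionally verified against direct
numerical quadrature of the emission integral (relative agreement at the
1e−9 level in the tests), including negative gradients.

For `W < 0` the expression is only defined while `2Wt + 1 > 0`; beyond
that time the linear profile has crossed β = 0 inside the probed depth
and the model is unphysical, so the implementation raises a domain error
rather than returning a value.

### Hydration mapping

Water content is obtained by placing the fitted β between two reference
coefficients: `H = (β_w − β)/(β_w − β_d)`. The formula is implemented in
exactly this orientation — which assigns H = 1 to the dry reference and
H = 0 to water — because that is how the inversion is specified upstream
of this package; the physically conventional orientation
`(β − β_d)/(β_w − β_d)` is available via an `orientation` switch but is
not the default, and the two are exact inverses of their respective
mappings. Values outside [0, 1] are returned unclipped so callers can
flag out-of-range fits. Default references (β_w = 2.5·10⁵ 1/m,
β_d = 5·10⁴ 1/m) and diffusivity (D = 10⁻⁷ m²/s) are skin-like package
constants, configurable everywhere they appear.

## Inversion

All estimators are model/results objects. Fits use scipy's trust-region
reflective least squares with positivity bounds on `A` and `τ`, cost
tolerance 1e−10 and at most 200 function evaluations; the `converged`
flag reports the optimizer's own success criterion, never a silent bad
fit. Standard errors come from the Jacobian at the optimum
(`σ² (JᵀJ)⁻¹`). Initial guesses: `A₀` = first windowed sample; `τ₀` = the
time at which the record first falls to `erfcx(1)·A₀ ≈ 0.428·A₀` (grid
lookup), falling back to a third of the window length. The gradient fit
starts from the homogeneous guess with `W = 0` (nudged off the bound) and
bounds `W` below so `2Wt + 1` stays positive on the window. All fits run
on window-relative time (t = 0 at the detected start).

**Window detection**: the start is the global-maximum sample (earliest on
ties — the laser-pulse peak); the end is the first sample after the start
where a moving-average-smoothed copy (width 5 samples) falls below 2% of
the peak above baseline, or the last sample if the floor is never
reached. The baseline is the median of pre-peak samples when at least 4
exist, else zero (records are assumed dark-level subtracted).

**Segmented least squares (SLS)**: the window is cut into `n_slices`
(default 10) equal-duration slices; for k = 1..n the homogeneous model is
fitted to slices 1..k cumulatively, seeded by a whole-window fit. Each
β_k is assigned the probing depth `z_k = √(D·t_k)` at the slice's end
time — the thermal diffusion length, the standard photothermal
probing-depth estimate. The depth formula is a package convention (a
multiplicative `depth_prefactor` is exposed); it sets the z-axis scale
but not the ordering of the β_k. Equal-duration slicing is used because
it is the plainest reading of "divide the signal into N slices"; the
whole-window fit is used only as initialization for the slice fits.
Non-converged slice fits are flagged in the profile, not fabricated.
`linearize_profile` summarises a profile by an ordinary least-squares
line `(β₀, w_β)`.

## Synthetic data

No measured transients ship with the package, so a seeded generator
emulates the three study designs; every generated dataset is a pure
function of (spec, acquisition config, seed).

* **Hydration regression** (default 97 signals): hydration drawn
  uniformly from [0.2, 0.9] — a wide span of stratum-corneum states —
  mapped to β through the inverse of the hydration formula (printed
  orientation, so labels round-trip exactly), to τ = 1/(β²D), and to a
  homogeneous decay. Amplitudes are drawn from [0.9, 1.1] because
  detector coupling varies between measurements.
* **Gradient regression**: additionally draws a hydration-vs-depth slope
  from ±1.5·10³ fraction/m (a few percent change across the probed
  depth), converts it to `w_β` and `W`, and synthesises the graded decay.
  The range keeps `|2Wt| < 1` on the default grid, inside the graded
  model's domain of validity.
* **Subject classification** (default 4 subjects × 5 repeats): subjects
  differ in mean lifetime (ratios ≈ 1.5, i.e. distinct hydration states)
  and mean amplitude (emissivity/coupling), with 2% within-subject
  relative scatter — visually separable traces, deliberately an easy
  design.

Acquisition model: 512 samples uniform in t from 0 to 20·τ_ref, where
τ_ref is the median generated lifetime — all rows of a dataset share one
grid because the ML stage uses raw samples as features. Noise is additive
i.i.d. Gaussian with sd = 1% of each row's amplitude (detector/amplifier
noise); no multiplicative, 1/f or jitter components are modelled. These
digitiser numbers are engineering choices: real acquisition hardware
publishes none of them.

What passing tests therefore show: the pipeline is exact on its own
forward models, unbiased at the percent level under additive white noise,
and reproduces the qualitative benchmark findings on separable synthetic
subjects. What they do not show: robustness to real-world artefacts
(trigger jitter, detector nonlinearity, filter leakage, baseline drift),
or the actual accuracy attainable on volunteer measurements.

## Benchmark harness

Features are the raw signal samples (one column per time point). Splits
are 75/25 with `|train| = round(0.75·n)` (so 97 → 73/24) and are
stratified by class for classification (with 20 rows and 4 classes an
unstratified split can drop a class from training; a flag disables
stratification). Features are standardised inside each model pipeline by
default; a flag disables scaling.

Model registries use library defaults with fixed seeds — no tuning loop
is shipped, only a config override hook — with two documented exceptions:

* the "deep learning" entry is a fully connected network (two hidden
  layers of 64 and 32 rectified-linear units, early stopping on a
  validation split) since a specific architecture is not prescribed;
* the AdaBoost classifier uses depth-2 base trees: a depth-1 stump has
  two leaves, fewer than the number of classes, so a stump-based
  multi-class ensemble cannot represent the partition at all (it
  plateaus far below 100% even on perfectly separated training data).

"Gradient boosting" and "extreme gradient boosting" are distinct entries
(sklearn and xgboost respectively) even though the learners are related.
Multi-target regression wraps estimators without native multi-output
support per target. R² on the test partition uses the test-set mean as
baseline, and a constant target scores R² = 0 by convention (the 0/0
case). Accuracies are reported in percent, rendered to one decimal.
A model that raises is recorded in the report with its failure reason
rather than aborting the suite — e.g. LDA on data with exactly zero
within-class scatter, where the discriminant is ill-posed.

Embeddings: PCA (full SVD solver; coordinates agree with a brute-force
eigendecomposition of the centred covariance up to per-component sign)
and LDA (at most `n_classes − 1` components). The PCA→classifier chain
fits PCA on training rows only and projects test rows with the training
transform.

Feature attribution: permutation importance (sklearn, mean absolute
importance over repeats) is the default; a Monte-Carlo
permutation-sampling Shapley estimator (marginal contributions along
sampled feature orderings, background rows drawn from the data, feature
independence assumed) is provided for Shapley-value attributions. For
classifiers the attributed output is the predicted-class probability,
falling back to the decision-function margin.

## Problem sizes and determinism

The acceptance script measures: kernel accuracy on a 200-point log grid;
lifetime recovery on 200 signals at 1% noise; SLS flatness on a 512-sample
noiseless decay; the regression benchmark on the full 97-signal design
(linear-model median over 10 generation seeds; all 13 models once); the
classification benchmark, permutation null (20 shuffles), PCA chain and
importance locality over 10 generation seeds of the 20-signal design.
These sizes match the study designs the generator emulates; Monte-Carlo
repeat counts are chosen to give stable medians. All randomness flows
from explicit integer seeds; rerunning any stage with the same seed and
configuration reproduces its reports exactly (byte-identical files, which
is why resolved configs omit absolute paths and timestamps).

## Known limitations

* Single-layer, 1-D, semi-infinite heat diffusion only; no multi-layer
  models, finite pulse width, detector bandwidth or filter transmission.
* The graded model assumes β stays positive over the probed depth; steep
  negative gradients leave its domain (raised as errors, not clipped).
* The SLS depth axis depends on the √(Dt) convention; published probing
  ranges (~20 µm for skin) are a qualitative sanity check only.
* The printed hydration orientation (H = 1 dry) is kept for fidelity;
  users wanting the conventional scale must opt in.
* Benchmark numbers on synthetic subjects are analogs, not reproductions
  of any measured dataset: the separable class design makes 100%
  accuracies expected, and chance-level nulls confirm they are not
  leakage artefacts.
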