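# otterlab

Analysis tools for **opto-thermal transient emission radiometry (OTTER)** —
a pulsed-laser photothermal technique used to measure skin hydration and
hydration depth profiles in the stratum corneum, the outermost ~10–20 µm of
skin. A short mid-infrared laser pulse heats the sample surface; the
transient increase in blackbody emission is recorded by a fast infrared
detector, and the shape of that decay encodes the sample's optical and
thermal properties.

The package is written for researchers who analyse such transients: it
provides the physical forward models, statsmodels-style fitting objects,
segmented least-squares (SLS) depth profiling, a seeded synthetic-signal
generator, and a benchmarking harness that trains a registry of regression
and classification models on signal collections.

## The model

For a semi-infinite, optically homogeneous sample the emission transient is

```
S(t) = A · e^(t/τ) · erfc(√(t/τ)),          τ = 1 / (β² D)
```

with amplitude `A` (detector units), emission absorption coefficient `β`
(1/m) at the detection wavelength, and thermal diffusivity `D` (m²/s).
The kernel is evaluated via the scaled complementary error function
`erfcx(√x)`, so it never overflows even for `t ≫ τ`. The fitted `β` maps to
water content by placing it between reference coefficients of water (β_w)
and of the dry sample (β_d):

```
H = (β_w − β) / (β_w − β_d)
```

(the formula is implemented exactly in this orientation, which assigns
H = 1 to the dry reference; an `orientation="conventional"` switch selects
(β − β_d)/(β_w − β_d)).

For an absorption coefficient that varies linearly with depth,
`β(z) = β₀ + w_β·z`, integrating the emission kernel over the 1-D
surface-heating temperature field gives the graded-sample decay

```
S(t) = A · [ 2W√(tτ/π)/(2Wt+1)
             + (2Wt+1)^(−3/2) · e^((t/τ)/(2Wt+1)) · erfc(√(t/τ)/√(2Wt+1)) ]
```

with effective gradient `W = w_β·D` (1/s) and surface lifetime
`τ = 1/(β₀²D)`. At `W = 0` this reduces exactly to the homogeneous decay,
and `S(0) = A` for every `W`; both identities are enforced by tests, and
the closed form is checked against direct numerical quadrature of the
emission integral.

**SLS depth profiling** fits the homogeneous model to cumulatively growing
early-time windows (10 slices by default); each cumulative fit's `β_k` is
assigned the thermal diffusion length `z_k = √(D·t_k)` of its end time as
probing depth, yielding β(z) and hydration(z) profiles that can be
summarised by a straight line `β(z) = β₀ + w_β·z`.

## Worked example

```python
import numpy as np
from otterlab import (AcquisitionConfig, HomogeneousDecayModel,
                      SegmentedLeastSquares, OpticalPair, RegressionSpec,
                      generate_regression_dataset)

spec = RegressionSpec(n_signals=97)          # 97 hydration-labelled decays
acq = AcquisitionConfig(noise_sd=0.01)       # 512 samples, 1% noise
ds = generate_regression_dataset(spec, acq, seed=0)

res = HomogeneousDecayModel(ds.grid, ds.signals[0]).fit()
print(res.summary())
```

```
Decay fit (HomogeneousParams)
========================================
n obs           512
converged       True
n fev           4
residual RMS    0.011097
----------------------------------------
A              1.09128  (se 0.00611)
tau        0.000687248  (se 1.04e-05)
beta            120627  1/m
```

The fitted lifetime (687 µs against a generating truth of 685 µs, within
the 1%-noise uncertainty) converts to β = 120 627 1/m and, through the
hydration formula with the default skin-like references
(β_w = 2.5·10⁵, β_d = 5·10⁴ 1/m), to a hydration of 0.6469 against a true
label of 0.6459. Depth profiling the same record:

```python
prof = SegmentedLeastSquares(ds.grid, ds.signals[0]).fit()
print(prof.summary(OpticalPair(2.5e5, 5e4)))
```

```
Segmented least-squares depth profile
==============================================
n slices      10
whole-window beta   120627 1/m
----------------------------------------------
    z [um]    beta [1/m]   hydration  conv
    10.880    1.2102e+05      0.6449  True
    15.386    1.2124e+05      0.6438  True
    18.844    1.2124e+05      0.6438  True
    21.760    1.2109e+05      0.6445  True
    24.328    1.2051e+05      0.6474  True
    26.650    1.2073e+05      0.6463  True
    28.785    1.2052e+05      0.6474  True
    30.773    1.2067e+05      0.6466  True
    32.639    1.2073e+05      0.6463  True
    34.405    1.2063e+05      0.6469  True
```

The input is homogeneous, so the profile is flat at the whole-window β to
within fit noise — a graded sample would show a trending β_k sequence,
which `prof.linearize()` summarises as a `(β₀, w_β)` pair.

## Benchmarking suites

`run_regression_suite` trains 13 regressors (lasso, elastic net, decision
tree, SVM, gradient boosting, linear, random forest, k-NN, extreme
gradient boosting, PLS, voting, RidgeCV, and a fully connected network) on
a 75/25 split of a labelled dataset and reports train/test R² and RMSE.
`run_classification_suite` does the same for 9 classifiers (logistic,
naive Bayes, SVC, random forest, bagging, AdaBoost, gradient boosting,
neural network, LDA) with accuracies in percent. 2-component LDA/PCA
embeddings, a PCA→classifier chain and per-feature importance attribution
(permutation importance or a Monte-Carlo Shapley estimate) round out the
harness.

A CLI mirrors the pipeline:

```bash
otterlab simulate --preset paper-regression --seed 1 --out out/sim
otterlab fit       --dataset out/sim --seed 1 --out out/fit
otterlab profile   --dataset out/sim --seed 1 --out out/prof
otterlab bench-reg --seed 1 --out out/reg
otterlab bench-clf --seed 1 --out out/clf
```

Every run writes its fully resolved configuration next to its outputs;
identical config + seed reproduces every report byte for byte.

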