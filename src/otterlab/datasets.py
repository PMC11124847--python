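"""Seeded synthetic OTTER datasets mirroring the three study designs.

No volunteer measurements ship with this package, so every downstream
stage (fitting, depth profiling, the regression and classification
benchmarks) is exercised on synthetic signals generated here:

* a ~97-signal homogeneous-skin collection labelled with hydration,
* the same design labelled with a linear hydration-depth profile
  (surface value + gradient),
* a 20-signal, 4-subject collection (5 repeats each) labelled by subject.

Generation is a pure function of (spec, acquisition config, seed): the
same inputs give bit-identical datasets.  The defaults are the package's
standing study conditions; see docs/methods.md for the rationale behind
each number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .physics import (
    DEFAULT_MATERIAL,
    DEFAULT_OPTICAL,
    GradientParams,
    HomogeneousParams,
    MaterialProps,
    OpticalPair,
    beta_from_hydration,
    signal_gradient,
    signal_homogeneous,
    tau_from_beta,
)

__all__ = [
    "AcquisitionConfig",
    "RegressionSpec",
    "ClassificationSpec",
    "Dataset",
    "add_noise",
    "generate_regression_dataset",
    "generate_classification_dataset",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Digitiser model for synthetic records.

    ``n_points`` samples uniformly spaced from 0 to
    ``t_max_over_tau * tau_ref`` (tau_ref = median generated lifetime, so
    all rows of a dataset share one grid); additive Gaussian noise of
    standard deviation ``noise_sd`` relative to each row's amplitude; a
    constant ``baseline`` offset in detector units.
    """

    n_points: int = 512
    t_max_over_tau: float = 20.0
    noise_sd: float = 0.01
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if self.t_max_over_tau <= 0:
            raise ValueError("t_max_over_tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class RegressionSpec:
    """Design of the hydration-regression collections.

    ``mode="homogeneous"`` draws a hydration level per signal;
    ``mode="gradient"`` draws a (surface hydration, hydration gradient)
    pair, maps it to a linear beta(z) and synthesises the graded decay.
    Hydration uses the printed convention of the inversion formula
    (H = 1 at the dry reference); ``gradient_range`` is dH/dz in 1/m.
    Amplitudes are drawn from ``amplitude_range`` (detector coupling
    varies between measurements).
    """

    n_signals: int = 97
    hydration_range: tuple[float, float] = (0.2, 0.9)
    amplitude_range: tuple[float, float] = (0.9, 1.1)
    optical: OpticalPair = DEFAULT_OPTICAL
    material: MaterialProps = DEFAULT_MATERIAL
    mode: str = "homogeneous"
    gradient_range: tuple[float, float] = (-1.5e3, 1.5e3)

    def __post_init__(self) -> None:
        if self.n_signals < 4:
            raise ValueError("n_signals must be >= 4")
        lo, hi = self.hydration_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("hydration_range must be an interval within [0, 1]")
        if self.mode not in ("homogeneous", "gradient"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for h in self.hydration_range:
            if beta_from_hydration(h, self.optical) <= 0:
                raise ValueError("hydration_range maps to non-positive beta for this optical pair")


# four synthetic subjects: lifetimes spaced by ~1.5x (distinct hydration
# states) and amplitudes offset (skin emissivity/optical coupling differ),
# with small within-subject scatter — mirrors visually separable traces
_DEFAULT_TAU_MEANS = (4.0e-4, 6.0e-4, 9.0e-4, 1.35e-3)
_DEFAULT_A_MEANS = (1.0, 1.15, 0.85, 1.3)


@dataclass(frozen=True)
class ClassificationSpec:
    """Design of the subject-identification collection (n_classes
    subjects, per_class repeats each, labelled by subject id)."""

    n_classes: int = 4
    per_class: int = 5
    tau_means: tuple = _DEFAULT_TAU_MEANS
    a_means: tuple = _DEFAULT_A_MEANS
    tau_rel_sd: float = 0.02
    a_rel_sd: float = 0.02
    material: MaterialProps = DEFAULT_MATERIAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.per_class < 2:
            raise ValueError("per_class must be >= 2")
        if len(self.tau_means) < self.n_classes or len(self.a_means) < self.n_classes:
            raise ValueError("need a (tau, A) mean per class")


@dataclass
class Dataset:
    """A labelled collection of synthetic decays on one shared time grid.

    ``signals`` is (n_signals, n_points); ``labels`` and ``truth`` are
    row-aligned DataFrames (targets and generating parameters); and
    ``provenance`` records the generation spec and seed.
    """

    signals: np.ndarray
    grid: np.ndarray
    labels: pd.DataFrame
    truth: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.signals.shape[0]
        if len(self.labels) != n or len(self.truth) != n:
            raise ValueError("labels/truth must align with signal rows")
        if self.signals.shape[1] != self.grid.size:
            raise ValueError("signal columns must match the grid length")

    @property
    def n_signals(self) -> int:
        return self.signals.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Targets as an array (1-D for a single label column)."""
        arr = self.labels.to_numpy()
        return arr[:, 0] if arr.shape[1] == 1 else arr

    def permute(self, order) -> "Dataset":
        """Row-reordered copy; labels and truth move with their signals."""
        order = np.asarray(order)
        return Dataset(
            signals=self.signals[order],
            grid=self.grid.copy(),
            labels=self.labels.iloc[order].reset_index(drop=True),
            truth=self.truth.iloc[order].reset_index(drop=True),
            provenance=dict(self.provenance),
        )


def add_noise(signal, sd: float, seed: int | np.random.Generator = 0):
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sd``
    (detector units).  ``sd = 0`` returns the input unchanged."""
    signal = np.asarray(signal, dtype=float)
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return signal + rng.normal(0.0, sd, signal.shape)


def _common_grid(taus: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    tau_ref = float(np.median(taus))
    return np.linspace(0.0, acq.t_max_over_tau * tau_ref, acq.n_points)


def generate_regression_dataset(
    spec: RegressionSpec = RegressionSpec(),
    acq: AcquisitionConfig = AcquisitionConfig(),
    seed: int | None = None,
) -> Dataset:
    """Synthesize the hydration-regression collection.

    For each signal a hydration label is drawn uniformly (homogeneous
    mode) or a (surface hydration, gradient) pair (gradient mode); the
    label maps to beta via the inverse of the hydration formula, to the
    lifetime via tau = 1/(beta^2 D), and to a decay via the matching
    forward model, plus additive Gaussian noise.
    """
    if seed is None:
        seed = acq.seed
    rng = np.random.default_rng(seed)
    n = spec.n_signals
    h = rng.uniform(*spec.hydration_range, n)
    amps = rng.uniform(*spec.amplitude_range, n)
    beta0 = beta_from_hydration(h, spec.optical)
    taus = np.array([tau_from_beta(b, spec.material) for b in beta0])
    grid = _common_grid(taus, acq)

    if spec.mode == "gradient":
        dh_dz = rng.uniform(*spec.gradient_range, n)
        # printed-orientation inverse: beta = beta_w - H*(beta_w - beta_d)
        w_beta = -dh_dz * (spec.optical.beta_w - spec.optical.beta_d)
        Ws = w_beta * spec.material.D
        rows = [
            signal_gradient(grid, GradientParams(A=a, tau=tau, W=w))
            for a, tau, w in zip(amps, taus, Ws)
        ]
        labels = pd.DataFrame({"surface_hydration": h, "hydration_gradient": dh_dz})
        truth = pd.DataFrame(
            {"A": amps, "tau": taus, "beta0": beta0, "w_beta": w_beta, "W": Ws,
             "surface_hydration": h, "hydration_gradient": dh_dz}
        )
    else:
        rows = [
            signal_homogeneous(grid, HomogeneousParams(A=a, tau=tau))
            for a, tau in zip(amps, taus)
        ]
        labels = pd.DataFrame({"hydration": h})
        truth = pd.DataFrame({"A": amps, "tau": taus, "beta": beta0, "hydration": h})

    signals = np.vstack(rows) + acq.baseline
    signals = add_noise(signals, 0.0, rng) if acq.noise_sd == 0 else (
        signals + rng.normal(0.0, acq.noise_sd, signals.shape) * amps[:, None]
    )
    return Dataset(
        signals=signals,
        grid=grid,
        labels=labels,
        truth=truth,
        provenance={"kind": "regression", "spec": _spec_dict(spec), "acq": asdict(acq), "seed": int(seed)},
    )


def generate_classification_dataset(
    spec: ClassificationSpec = ClassificationSpec(),
    acq: AcquisitionConfig = AcquisitionConfig(),
    seed: int | None = None,
) -> Dataset:
    """Synthesize the subject-identification collection.

    Each subject has its own mean (A, tau); repeats scatter around the
    means with small relative spread, and all rows get additive noise.
    Overlapping class distributions are allowed — separability is the
    caller's concern.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.n_classes * spec.per_class
    cls = np.repeat(np.arange(spec.n_classes), spec.per_class)
    tau_mu = np.asarray(spec.tau_means[: spec.n_classes])[cls]
    a_mu = np.asarray(spec.a_means[: spec.n_classes])[cls]
    taus = tau_mu * (1.0 + spec.tau_rel_sd * rng.standard_normal(n))
    amps = a_mu * (1.0 + spec.a_rel_sd * rng.standard_normal(n))
    taus = np.maximum(taus, 1e-12)
    amps = np.maximum(amps, 1e-12)
    grid = _common_grid(taus, acq)
    rows = [signal_homogeneous(grid, HomogeneousParams(A=a, tau=tau)) for a, tau in zip(amps, taus)]
    signals = np.vstack(rows) + acq.baseline
    if acq.noise_sd > 0:
        signals = signals + rng.normal(0.0, acq.noise_sd, signals.shape) * amps[:, None]
    labels = pd.DataFrame({"subject": cls + 1})
    truth = pd.DataFrame({"A": amps, "tau": taus, "subject": cls + 1})
    return Dataset(
        signals=signals,
        grid=grid,
        labels=labels,
        truth=truth,
        provenance={"kind": "classification", "spec": _spec_dict(spec), "acq": asdict(acq), "seed": int(seed)},
    )


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
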