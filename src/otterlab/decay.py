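"""Recovering decay parameters from measured transients.

The estimators follow a model/results pattern: a model object is built from
a (time, signal) record, its :meth:`fit` runs a trust-region least-squares
optimisation and returns a results object carrying the point estimates,
their standard errors (from the Jacobian at the optimum), residual
diagnostics and a ``summary()`` table.

Three estimators are provided:

* :class:`HomogeneousDecayModel` — amplitude and lifetime of the
  homogeneous decay; the lifetime converts to an average emission
  absorption coefficient via ``beta = 1/sqrt(tau * D)``.
* :class:`GradientDecayModel` — amplitude, surface lifetime and effective
  gradient ``W`` of the graded-absorption decay (a strict superset of the
  homogeneous model: at ``W = 0`` the two coincide).
* :class:`SegmentedLeastSquares` — depth profiling: the window is split
  into ``n_slices`` equal-duration slices and the homogeneous model is
  fitted to the cumulative data from slice 1 through slice k.  Each
  cumulative fit's beta is assigned the thermal diffusion length
  ``z_k = sqrt(D * t_k)`` of its end time as probing depth, giving a
  beta(z) (and hydration(z)) profile.

All fits operate on window-relative time (t = 0 at the detected start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .physics import (
    GradientParams,
    HomogeneousParams,
    LinearBetaProfile,
    MaterialProps,
    OpticalPair,
    DEFAULT_MATERIAL,
    beta_from_tau,
    hydration_from_beta,
    signal_gradient,
    signal_homogeneous,
)

__all__ = [
    "SignalWindow",
    "detect_window",
    "HomogeneousDecayModel",
    "GradientDecayModel",
    "DecayFitResults",
    "SegmentedLeastSquares",
    "DepthProfileResults",
    "linearize_profile",
]

_MAX_NFEV = 200
_COST_TOL = 1e-10


def _kernel(x):
    """Decay kernel exp(x)*erfc(sqrt(x)) via erfcx; clipped at 0 for optimizer probes."""
    from scipy.special import erfcx

    return erfcx(np.sqrt(np.maximum(x, 0.0)))


@dataclass(frozen=True)
class SignalWindow:
    """Half-open sample-index range [start, end) of the usable decay."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def detect_window(
    t,
    y,
    floor_frac: float = 0.02,
    smooth: int = 5,
    baseline: float | None = None,
) -> SignalWindow:
    """Locate the usable decay inside a raw record.

    The start is the global-maximum sample (the laser-pulse peak; earliest
    index on ties).  The end is the first sample after the start where the
    moving-average-smoothed signal falls below ``baseline +
    floor_frac*(peak - baseline)``, or the last sample if the decay never
    reaches that floor.  ``baseline=None`` estimates the baseline as the
    median of the pre-peak samples; with fewer than 4 pre-peak samples it
    is taken as zero (records are dark-level subtracted).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 32:
        raise ValueError("detect_window: record must hold at least 32 samples")
    if np.ptp(y) == 0:
        raise ValueError("detect_window: flat record, no decay to locate")
    start = int(np.argmax(y))
    if baseline is None:
        baseline = float(np.median(y[:start])) if start >= 4 else 0.0
    peak = float(y[start])
    floor = baseline + floor_frac * (peak - baseline)
    k = max(1, int(smooth))
    kernel = np.ones(k) / k
    ys = np.convolve(y, kernel, mode="same")
    below = np.nonzero(ys[start + 1 :] < floor)[0]
    end = start + 1 + int(below[0]) if below.size else y.size
    return SignalWindow(start, max(end, start + 2))


@dataclass
class DecayFitResults:
    """Estimates and diagnostics of a decay fit.

    ``params`` is a :class:`HomogeneousParams` or :class:`GradientParams`;
    ``bse`` are asymptotic standard errors from the Jacobian at the
    optimum (NaN where the curvature is singular); ``beta`` is the
    absorption coefficient 1/sqrt(tau*D) implied by the fitted lifetime.
    """

    params: HomogeneousParams | GradientParams
    bse: dict = field(default_factory=dict)
    residual_rms: float = np.nan
    converged: bool = False
    n_iter: int = 0
    beta: float = np.nan
    model: object = None

    def predict(self, t=None) -> np.ndarray:
        if t is None:
            t = self.model.t
        if isinstance(self.params, GradientParams):
            return signal_gradient(t, self.params)
        return signal_homogeneous(t, self.params)

    def hydration(self, optical: OpticalPair, orientation: str = "printed") -> float:
        """Water content implied by the fitted beta."""
        return hydration_from_beta(self.beta, optical, orientation)

    def summary(self) -> str:
        kind = type(self.params).__name__
        lines = [
            f"Decay fit ({kind})",
            "=" * 40,
            f"{'n obs':<16}{len(self.model.t) if self.model is not None else 'n/a'}",
            f"{'converged':<16}{self.converged}",
            f"{'n fev':<16}{self.n_iter}",
            f"{'residual RMS':<16}{self.residual_rms:.6g}",
            "-" * 40,
        ]
        for name in ("A", "tau", "W"):
            if hasattr(self.params, name):
                se = self.bse.get(name, np.nan)
                lines.append(f"{name:<8}{getattr(self.params, name):>14.6g}  (se {se:.3g})")
        lines.append(f"{'beta':<8}{self.beta:>14.6g}  1/m")
        return "\n".join(lines)


class _DecayModelBase:
    """Shared construction/validation for the decay estimators."""

    _min_samples = 8

    def __init__(self, t, y, material: MaterialProps = DEFAULT_MATERIAL):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if t.size < self._min_samples:
            raise ValueError(f"need at least {self._min_samples} samples in the window, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time axis must be strictly increasing")
        # window-relative time: fits are defined with t=0 at the pulse peak
        self.t = t - t[0]
        self.y = y
        self.material = material

    @classmethod
    def from_signal(cls, t, y, window: SignalWindow | None = None, material: MaterialProps = DEFAULT_MATERIAL, **detect_kw):
        """Build the model from a raw record, detecting the window if not given."""
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if window is None:
            window = detect_window(t, y, **detect_kw)
        sl = slice(window.start, window.end)
        return cls(t[sl], y[sl], material=material)

    def _initial_guess(self) -> tuple[float, float]:
        a0 = max(float(self.y[0]), 1e-12)
        # tau0: time at which the decay reaches exp_erfc(1)*A ~ 0.4276*A
        target = 0.42758357615580700 * a0
        idx = np.nonzero(self.y <= target)[0]
        if idx.size and self.t[idx[0]] > 0:
            tau0 = float(self.t[idx[0]])
        else:
            tau0 = float(self.t[-1]) / 3.0
        return a0, tau0

    def _least_squares(self, fun, x0, bounds):
        res = optimize.least_squares(
            fun,
            x0,
            bounds=bounds,
            method="trf",
            xtol=1e-12,
            ftol=_COST_TOL,
            gtol=1e-12,
            max_nfev=_MAX_NFEV,
        )
        return res

    @staticmethod
    def _standard_errors(res, names):
        # covariance ~ rms^2 * (J^T J)^-1 at the optimum
        m, n = res.jac.shape
        dof = max(m - n, 1)
        s2 = 2.0 * res.cost / dof
        try:
            cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(n, np.nan)
        return dict(zip(names, se))


class HomogeneousDecayModel(_DecayModelBase):
    """Least-squares fit of the homogeneous decay A*exp(t/tau)*erfc(sqrt(t/tau)).

    Parameters
    ----------
    t, y : arrays
        Windowed time (s) and signal (detector units); time is re-zeroed
        to the first sample.
    material : MaterialProps
        Thermal diffusivity used to convert the fitted lifetime to an
        absorption coefficient.

    Examples
    --------
    >>> from otterlab.physics import HomogeneousParams, signal_homogeneous
    >>> import numpy as np
    >>> t = np.linspace(0, 0.02, 256)
    >>> y = signal_homogeneous(t, HomogeneousParams(1.0, 1e-3))
    >>> res = HomogeneousDecayModel(t, y).fit()
    >>> round(res.params.tau, 6)
    0.001
    """

    param_names = ("A", "tau")

    def fit(self, start_params=None) -> DecayFitResults:
        if start_params is None:
            start_params = self._initial_guess()
        x0 = np.asarray(start_params, dtype=float)

        def resid(x):
            return x[0] * _kernel(self.t / x[1]) - self.y

        res = self._least_squares(resid, x0, bounds=([1e-12, 1e-12], [np.inf, np.inf]))
        params = HomogeneousParams(A=float(res.x[0]), tau=float(res.x[1]))
        rms = float(np.sqrt(np.mean(res.fun**2)))
        return DecayFitResults(
            params=params,
            bse=self._standard_errors(res, self.param_names),
            residual_rms=rms,
            converged=bool(res.success),
            n_iter=int(res.nfev),
            beta=beta_from_tau(params.tau, self.material),
            model=self,
        )


class GradientDecayModel(_DecayModelBase):
    """Least-squares fit of the graded-absorption decay (A, tau, W).

    ``tau`` is the surface lifetime, so the derived ``beta`` is the surface
    absorption coefficient beta0.  The fit keeps ``2*W*t + 1`` positive on
    the window by bounding W below at ``(eps - 1) / (2*t_max)``.
    """

    param_names = ("A", "tau", "W")

    def fit(self, start_params=None) -> DecayFitResults:
        if start_params is None:
            a0, tau0 = self._initial_guess()
            start_params = (a0, tau0, 0.0)
        x0 = np.asarray(start_params, dtype=float)
        t_max = float(self.t[-1])
        w_lo = (1e-6 - 1.0) / (2.0 * t_max) if t_max > 0 else -np.inf

        def resid(x):
            A, tau, W = x
            g = 2.0 * W * self.t + 1.0
            x_eff = (self.t / tau) / g
            model = A * (2.0 * W * np.sqrt(self.t * tau / np.pi) / g + g**-1.5 * _kernel(x_eff))
            return model - self.y

        # nudge W off the boundary of the zero-gradient start
        if x0[2] == 0.0:
            x0 = x0.copy()
            x0[2] = 1e-12
        res = self._least_squares(resid, x0, bounds=([1e-12, 1e-12, w_lo], [np.inf, np.inf, np.inf]))
        params = GradientParams(A=float(res.x[0]), tau=float(res.x[1]), W=float(res.x[2]))
        rms = float(np.sqrt(np.mean(res.fun**2)))
        return DecayFitResults(
            params=params,
            bse=self._standard_errors(res, self.param_names),
            residual_rms=rms,
            converged=bool(res.success),
            n_iter=int(res.nfev),
            beta=beta_from_tau(params.tau, self.material),
            model=self,
        )




@dataclass
class DepthProfileResults:
    """Depth-resolved absorption profile from segmented least squares.

    ``z`` are probing depths in metres (strictly increasing), ``beta`` the
    cumulative-fit absorption coefficients, ``converged`` per-slice flags
    (a non-converged slice keeps its estimate but is flagged, never
    fabricated), ``slice_bounds`` the cumulative end indices into the
    window.
    """

    z: np.ndarray
    beta: np.ndarray
    converged: np.ndarray
    slice_bounds: np.ndarray
    material: MaterialProps
    whole_fit: DecayFitResults

    @property
    def z_um(self) -> np.ndarray:
        return self.z * 1e6

    def hydration(self, optical: OpticalPair, orientation: str = "printed") -> np.ndarray:
        return hydration_from_beta(self.beta, optical, orientation)

    def linearize(self) -> LinearBetaProfile:
        """Straight-line summary beta(z) = beta0 + w_beta*z of the profile."""
        return linearize_profile(self.z, self.beta)

    def to_frame(self, optical: OpticalPair | None = None):
        import pandas as pd

        data = {"z_um": self.z_um, "beta_per_m": self.beta, "converged": self.converged}
        if optical is not None:
            data["hydration"] = self.hydration(optical)
        return pd.DataFrame(data)

    def summary(self, optical: OpticalPair | None = None) -> str:
        lines = [
            "Segmented least-squares depth profile",
            "=" * 46,
            f"{'n slices':<14}{self.z.size}",
            f"{'whole-window beta':<20}{self.whole_fit.beta:.6g} 1/m",
            "-" * 46,
            f"{'z [um]':>10}  {'beta [1/m]':>12}  {'hydration':>10}  conv",
        ]
        h = self.hydration(optical) if optical is not None else [np.nan] * self.z.size
        for zi, bi, hi, ci in zip(self.z_um, self.beta, h, self.converged):
            lines.append(f"{zi:>10.3f}  {bi:>12.5g}  {hi:>10.4f}  {bool(ci)}")
        return "\n".join(lines)

    def plot(self, optical: OpticalPair | None = None, ax=None):
        """Profile vs depth (beta, or hydration when an OpticalPair is given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if optical is not None:
            ax.plot(self.z_um, 100 * self.hydration(optical), "o-")
            ax.set_ylabel("hydration [%]")
        else:
            ax.plot(self.z_um, self.beta, "o-")
            ax.set_ylabel(r"$\beta$ [1/m]")
        ax.set_xlabel(r"depth [$\mu$m]")
        return ax


class SegmentedLeastSquares(_DecayModelBase):
    """Depth profiling by cumulative-window homogeneous fits.

    The windowed decay is split into ``n_slices`` equal-duration slices.
    A whole-window homogeneous fit is performed first (it seeds every
    cumulative fit); then for k = 1..n_slices the homogeneous model is
    fitted to slices 1..k, and the resulting beta_k is assigned the
    probing depth ``z_k = depth_prefactor * sqrt(D * t_k)`` with t_k the
    slice end time measured from the window start.  Early windows see only
    shallow material, so beta_k traces the depth dependence of the
    absorption coefficient.
    """

    def __init__(self, t, y, material: MaterialProps = DEFAULT_MATERIAL, n_slices: int = 10, depth_prefactor: float = 1.0):
        if n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        self._min_samples = max(4 * n_slices, 8)
        super().__init__(t, y, material=material)
        self.n_slices = int(n_slices)
        self.depth_prefactor = float(depth_prefactor)

    def fit(self) -> DepthProfileResults:
        whole = HomogeneousDecayModel(self.t, self.y, material=self.material).fit()
        t_end = self.t[-1]
        edges = t_end * np.arange(1, self.n_slices + 1) / self.n_slices
        bounds = np.searchsorted(self.t, edges, side="right")
        bounds[-1] = self.t.size
        betas = np.empty(self.n_slices)
        conv = np.zeros(self.n_slices, dtype=bool)
        zs = self.depth_prefactor * np.sqrt(self.material.D * edges)
        x0 = (whole.params.A, whole.params.tau)
        for k, b in enumerate(bounds):
            sub = HomogeneousDecayModel(self.t[:b], self.y[:b], material=self.material)
            r = sub.fit(start_params=x0)
            betas[k] = r.beta
            conv[k] = r.converged
        return DepthProfileResults(
            z=zs,
            beta=betas,
            converged=conv,
            slice_bounds=bounds,
            material=self.material,
            whole_fit=whole,
        )


def linearize_profile(z, beta) -> LinearBetaProfile:
    """Ordinary least-squares line beta(z) = beta0 + w_beta*z through a profile."""
    z = np.asarray(z, dtype=float)
    beta = np.asarray(beta, dtype=float)
    ok = np.isfinite(z) & np.isfinite(beta)
    if ok.sum() < 2:
        raise ValueError("linearize_profile: need at least 2 valid profile points")
    slope, intercept = np.polyfit(z[ok], beta[ok], 1)
    return LinearBetaProfile(beta0=float(intercept), w_beta=float(slope))
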