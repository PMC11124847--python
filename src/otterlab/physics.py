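"""Closed-form forward models of the OTTER emission transient.

Opto-thermal transient emission radiometry (OTTER) heats a sample surface
with a short laser pulse and records the decay of the resulting blackbody
emission.  For a semi-infinite, optically homogeneous sample the decay is

    S(t) = A * exp(t/tau) * erfc(sqrt(t/tau)),        tau = 1/(beta**2 * D)

where ``A`` is the signal amplitude (detector units), ``beta`` the emission
absorption coefficient at the detection wavelength (1/m) and ``D`` the
thermal diffusivity (m^2/s).  The fitted ``beta`` is converted to a water
content by interpolating between reference absorption coefficients of water
and of the dry sample.

For a sample whose absorption coefficient varies linearly with depth,
``beta(z) = beta0 + w_beta * z``, integrating the emission kernel over the
1-D surface-heating temperature field gives the graded-sample decay

    S(t) = A * [ 2*W*sqrt(t*tau/pi) / (2*W*t + 1)
                 + (2*W*t + 1)**(-3/2)
                   * exp((t/tau) / (2*W*t + 1))
                   * erfc(sqrt(t/tau) / sqrt(2*W*t + 1)) ]

with the effective gradient ``W = w_beta * D`` (units 1/s, so that
``2*W*t`` is dimensionless) and ``tau`` the *surface* decay lifetime
``1/(beta0**2 * D)``.  At ``W = 0`` this reduces exactly to the homogeneous
decay, and ``S(0) = A`` for every ``W``.

All quantities are SI internally (seconds, metres); depth is rendered in
micrometres only at the presentation layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx

__all__ = [
    "HomogeneousParams",
    "GradientParams",
    "OpticalPair",
    "MaterialProps",
    "LinearBetaProfile",
    "as_time_grid",
    "exp_erfc",
    "signal_homogeneous",
    "signal_gradient",
    "tau_from_beta",
    "beta_from_tau",
    "hydration_from_beta",
    "beta_from_hydration",
    "beta_linear",
    "DEFAULT_MATERIAL",
    "DEFAULT_OPTICAL",
]


@dataclass(frozen=True)
class HomogeneousParams:
    """Parameters of the homogeneous decay: amplitude and lifetime.

    Attributes
    ----------
    A : float
        Signal amplitude, detector units, >= 0 (zero gives the trivial all-zero decay).
    tau : float
        Decay lifetime in seconds, > 0; ``tau = 1/(beta**2 * D)``.
    """

    A: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and self.A >= 0):
            raise ValueError(f"amplitude A must be non-negative and finite, got {self.A}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"lifetime tau must be positive and finite, got {self.tau}")


@dataclass(frozen=True)
class GradientParams:
    """Parameters of the graded-absorption decay.

    ``tau`` is the surface lifetime ``1/(beta0**2 * D)``; ``W = w_beta * D``
    is the effective gradient in 1/s and may be negative (absorption
    decreasing with depth).
    """

    A: float
    tau: float
    W: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and self.A >= 0):
            raise ValueError(f"amplitude A must be non-negative and finite, got {self.A}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"lifetime tau must be positive and finite, got {self.tau}")
        if not np.isfinite(self.W):
            raise ValueError(f"effective gradient W must be finite, got {self.W}")


@dataclass(frozen=True)
class OpticalPair:
    """Reference emission absorption coefficients for hydration inversion.

    beta_w is the coefficient of water, beta_d that of the fully dry
    sample, both in 1/m at the detection wavelength.
    """

    beta_w: float
    beta_d: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta_w) and self.beta_w > 0):
            raise ValueError("beta_w must be positive and finite")
        if not (np.isfinite(self.beta_d) and self.beta_d > 0):
            raise ValueError("beta_d must be positive and finite")
        if self.beta_w == self.beta_d:
            raise ValueError("degenerate optical pair: beta_w == beta_d")


@dataclass(frozen=True)
class MaterialProps:
    """Thermal material properties: diffusivity D in m^2/s."""

    D: float = 1e-7

    def __post_init__(self) -> None:
        if not (np.isfinite(self.D) and self.D > 0):
            raise ValueError(f"thermal diffusivity D must be positive, got {self.D}")


@dataclass(frozen=True)
class LinearBetaProfile:
    """Linear depth dependence of the absorption coefficient.

    ``beta(z) = beta0 + w_beta * z`` with beta0 in 1/m (surface value,
    > 0) and w_beta in 1/m^2 (may be negative).
    """

    beta0: float
    w_beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta0) and self.beta0 > 0):
            raise ValueError(f"surface coefficient beta0 must be positive, got {self.beta0}")
        if not np.isfinite(self.w_beta):
            raise ValueError("gradient w_beta must be finite")


# Skin-like defaults used by examples and the synthetic generator; these are
# engineering constants of this package, configurable everywhere.
DEFAULT_MATERIAL = MaterialProps(D=1e-7)
DEFAULT_OPTICAL = OpticalPair(beta_w=2.5e5, beta_d=5e4)


def as_time_grid(t) -> np.ndarray:
    """Validate and return a time grid: 1-D, length >= 2, finite,
    non-negative, strictly increasing (seconds)."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(t)):
        raise ValueError("time grid contains non-finite values")
    if t[0] < 0:
        raise ValueError("time grid contains negative times")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    return t


def exp_erfc(x):
    """Evaluate ``exp(x) * erfc(sqrt(x))`` for x >= 0 without overflow.

    This is the dimensionless kernel of the homogeneous decay, with
    ``x = t/tau``.  Evaluated as ``erfcx(sqrt(x))`` (the scaled
    complementary error function) so that arbitrarily large ``x`` is safe;
    the value lies in (0, 1] and decays like ``1/sqrt(pi*x)``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("exp_erfc: x must be finite")
    if np.any(x < 0):
        raise ValueError("exp_erfc: x must be non-negative")
    out = erfcx(np.sqrt(x))
    return out if out.ndim else float(out)


def signal_homogeneous(t, params: HomogeneousParams) -> np.ndarray:
    """Homogeneous decay ``S(t) = A * exp(t/tau) * erfc(sqrt(t/tau))``."""
    t = as_time_grid(t)
    return params.A * exp_erfc(t / params.tau)


def signal_gradient(t, params: GradientParams) -> np.ndarray:
    """Graded-absorption decay for ``beta(z) = beta0 + w_beta*z``.

    Reduces pointwise to :func:`signal_homogeneous` at ``W = 0`` and gives
    ``S(0) = A`` for every ``W``.  Raises if ``2*W*t + 1`` vanishes or goes
    negative anywhere on the grid (the linear profile would cross zero
    within the probed depth there).
    """
    t = as_time_grid(t)
    g = 2.0 * params.W * t + 1.0
    if np.any(g <= 0):
        raise ValueError(
            "signal_gradient: 2*W*t + 1 <= 0 on the grid "
            f"(W={params.W:g}, t_max={t[-1]:g}); the graded model is undefined there"
        )
    x = t / params.tau
    term1 = 2.0 * params.W * np.sqrt(t * params.tau / np.pi) / g
    term2 = g ** -1.5 * erfcx(np.sqrt(x / g))
    return params.A * (term1 + term2)


def tau_from_beta(beta: float, mat: MaterialProps) -> float:
    """Decay lifetime from the absorption coefficient: tau = 1/(beta^2 D)."""
    beta = float(beta)
    if not (np.isfinite(beta) and beta > 0):
        raise ValueError(f"beta must be positive and finite, got {beta}")
    return 1.0 / (beta * beta * mat.D)


def beta_from_tau(tau: float, mat: MaterialProps) -> float:
    """Absorption coefficient from the decay lifetime: beta = 1/sqrt(tau D)."""
    tau = float(tau)
    if not (np.isfinite(tau) and tau > 0):
        raise ValueError(f"tau must be positive and finite, got {tau}")
    return 1.0 / np.sqrt(tau * mat.D)


def hydration_from_beta(beta, opt: OpticalPair, orientation: str = "printed"):
    """Water content from the fitted absorption coefficient.

    ``orientation="printed"`` uses ``H = (beta_w - beta)/(beta_w - beta_d)``,
    which assigns H = 1 to the dry reference and H = 0 to water.
    ``orientation="conventional"`` uses ``(beta - beta_d)/(beta_w - beta_d)``
    (H = 1 for water).  No clipping: values outside [0, 1] are returned
    as-is so the caller can flag them.
    """
    beta = np.asarray(beta, dtype=float)
    denom = opt.beta_w - opt.beta_d
    if orientation == "printed":
        h = (opt.beta_w - beta) / denom
    elif orientation == "conventional":
        h = (beta - opt.beta_d) / denom
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return h if h.ndim else float(h)


def beta_from_hydration(h, opt: OpticalPair, orientation: str = "printed"):
    """Exact inverse of :func:`hydration_from_beta`."""
    h = np.asarray(h, dtype=float)
    denom = opt.beta_w - opt.beta_d
    if orientation == "printed":
        beta = opt.beta_w - h * denom
    elif orientation == "conventional":
        beta = opt.beta_d + h * denom
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return beta if beta.ndim else float(beta)


def beta_linear(z, prof: LinearBetaProfile):
    """Absorption coefficient at depth z (m): beta0 + w_beta * z."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be non-negative")
    out = prof.beta0 + prof.w_beta * z
    return out if out.ndim else float(out)
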