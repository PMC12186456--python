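"""Closed-form numerical- and functional-response model families.

The numerical response (NR) relates the predator's per-capita growth
rate r to prey density P through a threshold-Monod (saturating) form

    r(P) = rmax · (P − P′) / (k2 + (P − P′)),

where P′ is the threshold prey density (x-intercept, r = 0) and k2 a
half-saturation-like constant in the same units as P.  Below the
threshold the same expression is returned, i.e. growth is negative.

The functional response (FR) relates per-capita ingestion I to prey
density through the generalized Holling disk equation

    I(P) = a · P^θ / (1 + a·h·P^θ),

with space clearance rate a (volume predator⁻¹ time⁻¹ for θ = 1),
handling time h (days per prey item, Imax = 1/h) and Hill exponent
θ ≥ 1.  θ = 1 is the hyperbolic type II, θ = 2 the classical sigmoidal
type III, and h = 0 with θ = 1 degenerates to the linear type I,
I = a·P.  The Michaelis–Menten form I = Imax·P/(k + P) is the θ = 1
case re-parameterized with Imax = 1/h and k = 1/(a·h).

The clearance-rate curve C(P) = I(P)/P is the model-discrimination
diagnostic: monotone decreasing for type II, unimodal for any θ > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NRParams",
    "FRParams",
    "SingularModelError",
    "HandlingTimeZeroError",
    "nr_predict",
    "fr_predict",
    "fr_predict_mm",
    "clearance_curve",
    "imax_from_handling",
]


class SingularModelError(ValueError):
    """Raised when a parameter set makes the model expression singular."""


class HandlingTimeZeroError(ValueError):
    """Raised when Imax = 1/h is requested for h = 0 (unbounded type I)."""


@dataclass(frozen=True)
class NRParams:
    """Threshold numerical-response parameters.

    Attributes
    ----------
    rmax : float
        Maximum specific growth rate (d⁻¹), > 0.
    p_prime : float
        Threshold prey density (x-intercept, same units as the prey
        axis: cells mL⁻¹ or mg C L⁻¹), ≥ 0.
    k2 : float
        Half-saturation-like constant, same units as the prey axis, > 0.
    """

    rmax: float
    p_prime: float
    k2: float

    def __post_init__(self) -> None:
        if not self.rmax > 0:
            raise ValueError(f"rmax must be > 0, got {self.rmax}")
        if not self.p_prime >= 0:
            raise ValueError(f"p_prime must be >= 0, got {self.p_prime}")
        if not self.k2 > 0:
            raise ValueError(f"k2 must be > 0, got {self.k2}")


@dataclass(frozen=True)
class FRParams:
    """Generalized Holling disk-equation parameters.

    Attributes
    ----------
    a : float
        Space clearance rate (mL^θ predator⁻¹ d⁻¹ on a cells mL⁻¹ prey
        axis), > 0.
    h : float
        Handling time (d per prey item), ≥ 0; h = 0 is the type I limit.
    theta : float
        Hill exponent, ≥ 1. 1 → type II, > 1 → sigmoidal type III.
    """

    a: float
    h: float
    theta: float = 1.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if not self.h >= 0:
            raise ValueError(f"h must be >= 0, got {self.h}")
        if not self.theta >= 1:
            raise ValueError(f"theta must be >= 1, got {self.theta}")

    @property
    def imax(self) -> float:
        """Maximum ingestion rate, 1/h (prey predator⁻¹ d⁻¹)."""
        return imax_from_handling(self.h)

    @property
    def half_saturation(self) -> float:
        """Prey density at I = Imax/2: k = (1/(a·h))^(1/θ)."""
        if self.h == 0:
            raise HandlingTimeZeroError("type I response (h = 0) never saturates")
        return (1.0 / (self.a * self.h)) ** (1.0 / self.theta)

    @classmethod
    def from_imax_k(cls, imax: float, k: float, theta: float = 1.0) -> "FRParams":
        """Build from the saturation parameterization (Imax, k, θ)."""
        if not (imax > 0 and k > 0):
            raise ValueError("imax and k must be > 0")
        h = 1.0 / imax
        a = imax / k**theta
        return cls(a=a, h=h, theta=theta)


def nr_predict(P, params: NRParams):
    """Predator growth rate r (d⁻¹) at prey density P.

    Passes exactly through (P′, 0); asymptote rmax for P → ∞.  The
    denominator k2 + (P − P′) must stay positive over the requested
    densities, otherwise the model is singular there.
    """
    p = np.asarray(P, dtype=float)
    x = p - params.p_prime
    denom = params.k2 + x
    if np.any(denom <= 0):
        raise SingularModelError(
            "k2 + (P - p_prime) <= 0 for some densities; the threshold-Monod "
            "expression is singular below P = p_prime - k2"
        )
    out = params.rmax * x / denom
    return float(out) if np.isscalar(P) else out


def fr_predict(P, params: FRParams):
    """Per-capita ingestion rate I (prey predator⁻¹ d⁻¹) at prey density P."""
    p = np.asarray(P, dtype=float)
    if np.any(p < 0):
        raise ValueError("prey density must be >= 0")
    ap = params.a * p**params.theta
    out = ap / (1.0 + params.h * ap)
    return float(out) if np.isscalar(P) else out


def fr_predict_mm(P, imax: float, k: float):
    """Type II ingestion in the Michaelis–Menten form Imax·P/(k + P).

    Algebraically identical to :func:`fr_predict` with θ = 1,
    h = 1/Imax, a = Imax/k.
    """
    if not (imax > 0 and k > 0):
        raise ValueError("imax and k must be > 0")
    p = np.asarray(P, dtype=float)
    out = imax * p / (k + p)
    return float(out) if np.isscalar(P) else out


def clearance_curve(P, params: FRParams):
    """Clearance rate C(P) = I(P)/P = a·P^(θ−1)/(1 + a·h·P^θ).

    Strictly decreasing for θ = 1 (maximum C = a as P → 0); for θ > 1
    the curve rises to an interior maximum and then declines — the
    type III signature.
    """
    p = np.asarray(P, dtype=float)
    if np.any(p <= 0):
        raise ValueError("prey density must be > 0 for a clearance rate")
    num = params.a * p ** (params.theta - 1.0)
    out = num / (1.0 + params.a * params.h * p**params.theta)
    return float(out) if np.isscalar(P) else out


def imax_from_handling(h: float) -> float:
    """Maximum ingestion rate Imax = 1/h (prey predator⁻¹ d⁻¹)."""
    if h < 0:
        raise ValueError(f"handling time must be >= 0, got {h}")
    if h == 0:
        raise HandlingTimeZeroError(
            "h = 0 is the linear type I regime; ingestion is unbounded"
        )
    return 1.0 / h
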