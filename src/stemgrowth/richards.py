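"""The four-parameter Richards (generalized logistic) growth function.

The curve

    y(x) = a * (1 + b * exp(-c * x)) ** (-1 / d)

describes a monotone sigmoid rising from 0 (as x -> -inf) to the asymptote
``a``.  ``x`` is the explanatory variable: day of year ("Julian day") or
accumulated thermal time in degree days.  ``b`` locates the curve on the x
axis, ``c`` sets the intrinsic rate and ``d`` the asymmetry of the sigmoid;
``d = 1`` recovers the ordinary logistic.

Everything here is exact closed-form calculus on the curve.  With the
substitution ``u = b * exp(-c * x)`` (``u`` is positive and decreasing in x):

* first derivative      y' = (a c / d) * u * (1 + u)^(-(d+1)/d)
* second derivative     y'' = (a c^2 / d^2) * u (u - d) (1 + u)^(-(2d+1)/d)
* y' is maximal at u = d, i.e. the inflection x* = ln(b/d) / c
* y'' has its extrema (zeros of y''') at the roots of
      u^2 - d (3 + d) u + d^2 = 0
  i.e. u = (d/2) * ((3 + d) ± sqrt((3 + d)^2 - 4)).

The larger root maps to the earlier x (start of the near-linear "logarithmic"
growth phase), the smaller to the later x (its end).  The product of the two
roots is d^2, which makes the phase exactly symmetric around the inflection
on the x axis — the midpoint identity (start + end) / 2 = x* holds for every
valid parameter set.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .exceptions import ParameterDomainError, UnreachableHeightError

__all__ = [
    "Domain",
    "RichardsParams",
    "richards_value",
    "richards_deriv1",
    "richards_deriv2",
    "richards_deriv3",
    "day_of_max_growth",
    "max_growth_rate",
    "log_phase_bounds",
    "auc",
    "day_at_height",
]


class Domain(str, enum.Enum):
    """Explanatory-variable domain of a fitted curve."""

    julian_day = "julian_day"
    thermal_time = "thermal_time"


@dataclass(frozen=True)
class RichardsParams:
    """Parameters of the Richards growth function.

    Parameters
    ----------
    a : float
        Asymptotic stem length (cm).
    b : float
        Dimensionless offset parameter locating the curve on the x axis.
    c : float
        Rate parameter (per day, or per °Cd on a thermal-time axis).
    d : float
        Dimensionless shape (asymmetry) parameter; ``d = 1`` is the logistic.
    domain : Domain
        Whether x is day of year or accumulated degree days.
    """

    a: float
    b: float
    c: float
    d: float
    domain: Domain = Domain.julian_day

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterDomainError(
                    f"Richards parameter {name} must be finite and > 0, got {v!r}"
                )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def _u(params: RichardsParams, x):
    return params.b * np.exp(-params.c * np.asarray(x, dtype=float))


def richards_value(params: RichardsParams, x):
    """Evaluate the Richards curve at ``x`` (vectorized)."""
    a, _, _, d = params.as_tuple()
    return a * (1.0 + _u(params, x)) ** (-1.0 / d)


def richards_deriv1(params: RichardsParams, x):
    """First derivative dy/dx (growth rate, cm per x-unit)."""
    a, _, c, d = params.as_tuple()
    u = _u(params, x)
    return (a * c / d) * u * (1.0 + u) ** (-(d + 1.0) / d)


def richards_deriv2(params: RichardsParams, x):
    """Second derivative d²y/dx² (curvature of the growth curve)."""
    a, _, c, d = params.as_tuple()
    u = _u(params, x)
    return (a * c**2 / d**2) * u * (u - d) * (1.0 + u) ** (-(2.0 * d + 1.0) / d)


def richards_deriv3(params: RichardsParams, x):
    """Third derivative d³y/dx³; its roots are the curvature extrema."""
    a, _, c, d = params.as_tuple()
    u = _u(params, x)
    poly = u * u - d * (3.0 + d) * u + d * d
    return -(a * c**3 / d**3) * u * poly * (1.0 + u) ** (-(3.0 * d + 1.0) / d)


def day_of_max_growth(params: RichardsParams) -> float:
    """x at which the growth rate is maximal (the inflection), ln(b/d)/c."""
    return math.log(params.b / params.d) / params.c


def max_growth_rate(params: RichardsParams) -> float:
    """Maximum growth rate, a·c·(1+d)^(-(d+1)/d), attained at the inflection."""
    a, _, c, d = params.as_tuple()
    return a * c * (1.0 + d) ** (-(d + 1.0) / d)


def _curvature_roots_u(d: float) -> tuple[float, float]:
    # roots of u^2 - d(3+d)u + d^2 = 0; discriminant is positive for d > 0
    s = math.sqrt((3.0 + d) ** 2 - 4.0)
    u_hi = 0.5 * d * ((3.0 + d) + s)
    u_lo = 0.5 * d * ((3.0 + d) - s)
    return u_hi, u_lo


def log_phase_bounds(params: RichardsParams) -> tuple[float, float]:
    """(start, end) of the logarithmic growth phase.

    Start and end are the maximum and minimum of the second derivative,
    i.e. the zeros of the third derivative, mapped back from u-space by
    x = ln(b/u)/c.  The larger u root gives the earlier x.
    """
    u_hi, u_lo = _curvature_roots_u(params.d)
    start = math.log(params.b / u_hi) / params.c
    end = math.log(params.b / u_lo) / params.c
    return start, end


def auc(params: RichardsParams, window: tuple[float, float]) -> float:
    """Integral of the fitted curve over ``window`` (cm·x-units).

    Adaptive quadrature; exact to quadrature tolerance for any d.  The
    integrand is smooth and bounded by a, so this is cheap and reliable.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"AUC window must satisfy lo < hi, got {window!r}")
    val, _ = quad(lambda x: richards_value(params, x), lo, hi, limit=200)
    return val


def day_at_height(params: RichardsParams, h: float) -> float:
    """Invert the curve: the x at which stem length equals ``h`` cm.

    Closed form x = -(1/c) · ln(((a/h)^d - 1)/b).  The curve approaches its
    asymptote a but never attains it, so h must lie strictly in (0, a).
    """
    a, b, c, d = params.as_tuple()
    if h <= 0:
        raise ParameterDomainError(f"height must be > 0, got {h!r}")
    if h >= a:
        raise UnreachableHeightError(
            f"height {h} cm is at or above the asymptote a={a} cm and is never reached"
        )
    return -math.log(((a / h) ** d - 1.0) / b) / c
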