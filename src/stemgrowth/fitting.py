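"""Fitting the Richards curve to per-plant stem-elongation series.

The public surface follows the model/results idiom: build a
:class:`RichardsModel` from one plant's (x, length) data, call
:meth:`~RichardsModel.fit`, and read estimates, uncertainties and derived
growth traits off the returned :class:`RichardsResults`.

Richards fits are initialization-sensitive, so the fitter combines a
data-driven starting point (asymptote from the largest observation, rate from
a log-linearized logistic slope) with bounded multi-start restarts under
log-uniform jitter.  Convergence failures are reported on the results object
(``converged=False``), never raised, so population-scale loops can log and
move on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InsufficientDataError, InternalConsistencyError
from .richards import (
    Domain,
    RichardsParams,
    auc,
    day_at_height,
    day_of_max_growth,
    log_phase_bounds,
    max_growth_rate,
    richards_deriv3,
    richards_value,
)

__all__ = [
    "StemSeries",
    "FitConfig",
    "GrowthTraits",
    "RichardsModel",
    "RichardsResults",
    "derive_traits",
    "fit_richards",
    "fit_stem_table",
]


@dataclass(frozen=True)
class StemSeries:
    """One plant-year of stem-elongation measurements.

    ``x`` is day of year (1-based) or accumulated °Cd depending on ``domain``;
    lengths are the longest-stem length in cm at each visit.
    """

    plant_id: str
    year: int
    x: np.ndarray
    length: np.ndarray
    domain: Domain = Domain.julian_day

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "length", np.asarray(self.length, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.length.shape:
            raise ValueError("x and length must be 1-D arrays of equal size")
        if len(self.x) < 2:
            raise InsufficientDataError(
                f"series {self.plant_id}/{self.year}: need >= 2 points, got {len(self.x)}"
            )
        if np.any(np.diff(self.x) <= 0):
            raise ValueError(f"series {self.plant_id}/{self.year}: x must be strictly increasing")
        if np.any(self.length < 0):
            raise ValueError(f"series {self.plant_id}/{self.year}: lengths must be >= 0")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class FitConfig:
    """Settings for the bounded multi-start nonlinear least-squares fit.

    ``min_points`` is the fewest visits accepted per plant-year;
    ``r2_accept`` is the goodness-of-fit floor a fit must clear to enter
    downstream analyses; ``max_restarts`` bounds the jittered restarts tried
    after the data-driven start; restarts stop early once r² exceeds
    ``early_stop_r2`` (further restarts almost never improve such fits).
    """

    min_points: int = 6
    max_restarts: int = 20
    min_restarts: int = 3
    r2_accept: float = 0.8
    early_stop_r2: float = 0.995
    jitter_scale: float = 0.5
    seed: int = 0


# ---------------------------------------------------------------------------
# derived growth characteristics


@dataclass(frozen=True)
class GrowthTraits:
    """The six growth characteristics derived from a fitted curve.

    All in x-units of the fit's domain: MaxGR (cm/x-unit) and its timing
    DayMaxGR; start/end/duration of the logarithmic growth phase from the
    curvature extrema; AUC, the integral of the curve over the season window;
    and the x at which the stem first reaches 15 cm (NaN if the asymptote is
    below 15 cm).  ``in_window`` records whether the whole logarithmic phase
    fell inside the window used for AUC.
    """

    max_gr: float
    day_max_gr: float
    start_logg: float
    end_logg: float
    duration: float
    auc: float
    day_at_15cm: float
    in_window: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "max_gr": self.max_gr,
            "day_max_gr": self.day_max_gr,
            "start_logg": self.start_logg,
            "end_logg": self.end_logg,
            "duration": self.duration,
            "auc": self.auc,
            "day_at_15cm": self.day_at_15cm,
        }


_REFERENCE_HEIGHT_CM = 15.0


def derive_traits(
    params: RichardsParams,
    window: tuple[float, float] = (0.0, 365.0),
    check: bool = True,
) -> GrowthTraits:
    """Derive the six growth characteristics from Richards parameters.

    Closed forms are used for the inflection and the curvature extrema; with
    ``check=True`` each closed-form location is verified to be a root of the
    relevant derivative (third derivative at the phase bounds, second-
    derivative sign change at the inflection) and an
    :class:`InternalConsistencyError` is raised on disagreement.  AUC is
    adaptive quadrature over ``window``.  Phase bounds outside the window are
    flagged via ``in_window``, not clipped.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"window must be ordered, got {window!r}")
    x_star = day_of_max_growth(params)
    gr_max = max_growth_rate(params)
    start, end = log_phase_bounds(params)

    if check:
        # the phase bounds are zeros of y'''; scale the residual by the local
        # magnitude of y''' a quarter-phase away to make the check unitless
        span = max(end - start, 1e-9)
        scale = max(
            abs(richards_deriv3(params, start - 0.25 * span)),
            abs(richards_deriv3(params, end + 0.25 * span)),
        )
        for root in (start, end):
            if abs(richards_deriv3(params, root)) > 1e-6 * scale + 1e-300:
                raise InternalConsistencyError(
                    f"curvature-extremum closed form fails the y'''=0 check at x={root}"
                )
        if not (start < x_star < end):
            raise InternalConsistencyError("inflection not bracketed by phase bounds")

    area = auc(params, window)
    try:
        x15 = day_at_height(params, _REFERENCE_HEIGHT_CM)
    except Exception:
        x15 = float("nan")
    return GrowthTraits(
        max_gr=gr_max,
        day_max_gr=x_star,
        start_logg=start,
        end_logg=end,
        duration=end - start,
        auc=area,
        day_at_15cm=x15,
        in_window=bool(lo <= start and end <= hi),
    )


# ---------------------------------------------------------------------------
# the model / results pair


class RichardsModel:
    """Richards growth curve for one plant-year of stem-elongation data.

    Parameters
    ----------
    x, length : array-like
        Measurement x-values (strictly increasing) and stem lengths (cm).
    domain : Domain
        Day-of-year or thermal-time axis.

    Examples
    --------
    >>> model = RichardsModel([100, 120, 140, 160, 180, 200, 220, 240],
    ...                       [2, 8, 30, 90, 180, 250, 280, 292])
    >>> res = model.fit()
    >>> res.converged
    True
    """

    def __init__(self, x, length, domain: Domain = Domain.julian_day):
        self.series = StemSeries("<anon>", 0, np.asarray(x, float), np.asarray(length, float), domain)
        self.domain = domain

    @classmethod
    def from_series(cls, series: StemSeries) -> "RichardsModel":
        m = cls.__new__(cls)
        m.series = series
        m.domain = series.domain
        return m

    # -- starting values -----------------------------------------------------

    def _start_values(self) -> np.ndarray:
        x, y = self.series.x, self.series.length
        a0 = 1.05 * float(np.max(y))
        d0 = 1.0
        # log-linearized logistic on interior points: ln(y/(a0-y)) ~ c*x
        mask = (y > 0.02 * a0) & (y < 0.98 * a0)
        if mask.sum() >= 2:
            z = np.log(y[mask] / (a0 - y[mask]))
            slope = np.polyfit(x[mask], z, 1)[0]
            c0 = float(np.clip(slope, 1e-3, 1.0))
        else:
            c0 = 3.0 / max(np.ptp(x), 1.0)
        # solve b from the first positive observation
        ipos = np.flatnonzero(y > 0)
        x1, y1 = (x[ipos[0]], y[ipos[0]]) if len(ipos) else (x[0], a0 / 2)
        b0 = ((a0 / y1) ** d0 - 1.0) * math.exp(c0 * x1)
        b0 = float(np.clip(b0, 1e-5, 1e5))
        return np.array([a0, b0, c0, d0])

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        max_obs = float(np.max(self.series.length))
        lo = np.array([max_obs * (1 + 1e-9), 1e-6, 1e-4, 0.05])
        hi = np.array([10.0 * max_obs, 1e6, 1.0, 20.0])
        return lo, hi

    # -- fitting -------------------------------------------------------------

    def fit(self, config: FitConfig | None = None) -> "RichardsResults":
        """Bounded multi-start nonlinear least squares.

        Raises :class:`InsufficientDataError` below ``config.min_points`` or
        when at most one length is positive; returns a results object with
        ``converged=False`` (never raises) when all restarts diverge.
        """
        cfg = config or FitConfig()
        x, y = self.series.x, self.series.length
        if len(x) < cfg.min_points:
            raise InsufficientDataError(
                f"series {self.series.plant_id}/{self.series.year}: "
                f"{len(x)} points < minimum {cfg.min_points}"
            )
        if np.count_nonzero(y > 0) < 2:
            raise InsufficientDataError(
                f"series {self.series.plant_id}/{self.series.year}: "
                "fewer than two positive lengths"
            )

        lo, hi = self._bounds()
        theta0 = np.clip(self._start_values(), lo, hi)
        rng = np.random.default_rng(cfg.seed)

        def residuals(theta):
            a, b, c, d = theta
            return a * (1.0 + b * np.exp(-c * x)) ** (-1.0 / d) - y

        def jacobian(theta):
            a, b, c, d = theta
            u = b * np.exp(-c * x)
            base = (1.0 + u) ** (-1.0 / d)
            inner = (1.0 + u) ** (-1.0 / d - 1.0)
            return np.column_stack([
                base,
                -(a / d) * inner * u / b,
                (a / d) * inner * u * x,
                a * base * np.log1p(u) / d**2,
            ])

        tss = float(np.sum((y - y.mean()) ** 2))
        best = None
        n_tried = 0
        stall = 0
        for k in range(cfg.max_restarts + 1):
            if k == 0:
                start = theta0
            else:
                jit = np.ones(4)
                jit[1:] = np.exp(rng.uniform(-cfg.jitter_scale, cfg.jitter_scale, 3) * math.log(10))
                start = np.clip(theta0 * jit, lo, hi)
            n_tried += 1
            try:
                sol = least_squares(residuals, start, jac=jacobian, bounds=(lo, hi),
                                    method="trf", max_nfev=2000)
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            if best is None or sol.cost < best.cost * (1.0 - 1e-3):
                best, stall = sol, 0
            else:
                stall += 1
            # stop early only after a few restarts have confirmed the basin:
            # either the fit is essentially exact or restarts stopped helping
            if best is not None and k >= cfg.min_restarts:
                if tss > 0 and 1 - 2 * best.cost / tss >= cfg.early_stop_r2:
                    break
                if stall >= 3:
                    break

        if best is None or not best.success:
            converged = best is not None and best.status > 0
        else:
            converged = True
        if best is None:
            # every restart blew up; report the starting point, unconverged
            return RichardsResults(self, RichardsParams(*theta0, domain=self.domain),
                                   rss=float(np.sum(residuals(theta0) ** 2)),
                                   converged=False, n_restarts_used=n_tried, bse=None)

        params = RichardsParams(*best.x, domain=self.domain)
        rss = float(2 * best.cost)
        bse = self._param_se(best, rss)
        return RichardsResults(self, params, rss=rss, converged=bool(converged),
                               n_restarts_used=n_tried, bse=bse)

    @staticmethod
    def _param_se(sol, rss: float) -> np.ndarray | None:
        # Gauss-Newton covariance from the Jacobian at the solution
        n, p = sol.jac.shape
        if n <= p:
            return None
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
            return np.sqrt(np.diag(jtj_inv) * rss / (n - p))
        except np.linalg.LinAlgError:
            return None


class RichardsResults:
    """Results of a Richards fit: estimates, fit quality, derived traits."""

    _names = ("a", "b", "c", "d")

    def __init__(self, model: RichardsModel, params: RichardsParams, rss: float,
                 converged: bool, n_restarts_used: int, bse: np.ndarray | None):
        self.model = model
        self.params = params
        self.rss = rss
        self.converged = converged
        self.n_restarts_used = n_restarts_used
        self.bse = bse
        self.n_points = len(model.series)
        y = model.series.length
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r_squared = 1.0 - rss / tss if tss > 0 else float("nan")

    def predict(self, x) -> np.ndarray:
        return richards_value(self.params, x)

    @property
    def resid(self) -> np.ndarray:
        return self.model.series.length - self.predict(self.model.series.x)

    def derive_traits(self, window: tuple[float, float] = (0.0, 365.0),
                      check: bool = True) -> GrowthTraits:
        if not self.converged:
            raise RuntimeError("cannot derive traits from a non-converged fit")
        return derive_traits(self.params, window=window, check=check)

    def plot(self, ax=None, window: tuple[float, float] | None = None):
        """Plot the measurements, the fitted curve and the growth phases."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        lo, hi = window or (float(s.x.min()) - 10, float(s.x.max()) + 10)
        xs = np.linspace(lo, hi, 400)
        ax.plot(s.x, s.length, "o", label="measured", color="k", ms=4)
        ax.plot(xs, self.predict(xs), "-", label="Richards fit")
        if self.converged:
            t = self.derive_traits(window=(lo, hi), check=False)
            ax.axvspan(t.start_logg, t.end_logg, alpha=0.15,
                       label="logarithmic phase")
            ax.axvline(t.day_max_gr, ls="--", lw=0.8)
        unit = "day of year" if self.params.domain == Domain.julian_day else "thermal time (°Cd)"
        ax.set_xlabel(unit)
        ax.set_ylabel("stem length (cm)")
        ax.legend(frameon=False)
        return ax

    def accepted(self, config: FitConfig | None = None) -> bool:
        """Does this fit pass the downstream acceptance filter?"""
        cfg = config or FitConfig()
        return bool(self.converged and self.n_points >= cfg.min_points
                    and np.isfinite(self.r_squared) and self.r_squared >= cfg.r2_accept)

    def summary(self) -> str:
        lines = [
            "Richards growth fit",
            "=" * 46,
            f"domain: {self.params.domain.value}   n = {self.n_points}",
            f"converged: {self.converged}   restarts used: {self.n_restarts_used}",
            f"RSS = {self.rss:.4g} cm^2   R^2 = {self.r_squared:.4f}",
            "-" * 46,
            f"{'param':>6} {'estimate':>12} {'std err':>12}",
        ]
        for i, name in enumerate(self._names):
            se = f"{self.bse[i]:.4g}" if self.bse is not None else "--"
            lines.append(f"{name:>6} {getattr(self.params, name):>12.5g} {se:>12}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        a, b, c, d = self.params.as_tuple()
        return (f"<RichardsResults a={a:.4g} b={b:.4g} c={c:.4g} d={d:.4g} "
                f"r2={self.r_squared:.3f} converged={self.converged}>")


def fit_richards(series: StemSeries, config: FitConfig | None = None) -> RichardsResults:
    """Functional wrapper: fit a :class:`StemSeries`, return the results."""
    return RichardsModel.from_series(series).fit(config)


# ---------------------------------------------------------------------------
# population-scale driver


def fit_stem_table(
    series_list: Iterable[StemSeries],
    config: FitConfig | None = None,
    window: tuple[float, float] = (0.0, 365.0),
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Fit every series; return (fits, traits, exclusions).

    ``fits`` has one row per plant-year with parameters and diagnostics;
    ``traits`` holds the derived growth characteristics for fits passing the
    acceptance filter (converged, enough points, r² at or above the
    configured floor).  ``exclusions`` is a list of dicts with a
    machine-readable reason for every plant-year that did not make it.
    """
    cfg = config or FitConfig()
    fit_rows, trait_rows, exclusions = [], [], []
    for i, series in enumerate(series_list):
        try:
            res = fit_richards(series, replace(cfg, seed=cfg.seed + i))
        except InsufficientDataError as err:
            exclusions.append({"plant_id": series.plant_id, "year": series.year,
                               "reason": "insufficient_data", "detail": str(err)})
            continue
        fit_rows.append({
            "plant_id": series.plant_id, "year": series.year,
            "a": res.params.a, "b": res.params.b, "c": res.params.c, "d": res.params.d,
            "rss": res.rss, "r_squared": res.r_squared, "converged": res.converged,
            "n_points": res.n_points, "n_restarts_used": res.n_restarts_used,
        })
        if not res.converged:
            exclusions.append({"plant_id": series.plant_id, "year": series.year,
                               "reason": "not_converged", "detail": ""})
            continue
        if not res.accepted(cfg):
            exclusions.append({"plant_id": series.plant_id, "year": series.year,
                               "reason": "low_r_squared",
                               "detail": f"r2={res.r_squared:.4f} < {cfg.r2_accept}"})
            continue
        traits = res.derive_traits(window=window)
        row = {"plant_id": series.plant_id, "year": series.year}
        row.update(traits.as_dict())
        if series.domain == Domain.julian_day:
            # reporting convention: timing of peak growth to the nearest day
            row["day_max_gr_reported"] = int(round(traits.day_max_gr))
        trait_rows.append(row)
    return pd.DataFrame(fit_rows), pd.DataFrame(trait_rows), exclusions
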