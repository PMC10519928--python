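"""Time-course statistics for the healing monitoring pipeline.

Covers the three longitudinal questions the monitoring data answer:

- when the force partition overturns (callus force first exceeds the
  fixator force: the load-share crossover, reported to fractional-day
  precision by linear interpolation);
- when a quantity stabilizes (stays inside a tolerance band for a hold
  period, e.g. the fixator force settling around zero);
- how well gait recovery tracks callus mineralization (OLS regression of
  body-weight-normalized GRF on BMD, with the significance criterion
  R^2 > 0.5 and p < 0.005 on the two-sided slope test).

Trend curves are fitted with one of three families: exponential
saturation ``A - B exp(-t/tau)``, a four-parameter logistic, or a
monotone spline (isotonic regression smoothed by a shape-preserving
cubic interpolant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

DEFAULT_STABILITY_BAND_FRACTION = 0.05  # of the mean internal force
DEFAULT_STABILITY_HOLD_DAYS = 14.0

#: Fig.-style significance rule for the GRF-BMD association.
SIGNIFICANCE_R2 = 0.5
SIGNIFICANCE_P = 0.005


class FitError(RuntimeError):
    """Raised when a trend-curve fit fails to converge."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS slope/intercept with fit quality and the significance flag."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared!r}")


def detect_crossover_day(
    days: Sequence[float],
    f_f: Sequence[float],
    f_c: Sequence[float],
) -> Optional[float]:
    """First day the callus force exceeds the fixator force.

    Linearly interpolates between the bracketing samples to fractional-day
    precision.  Returns ``None`` (with a logged reason) if the series never
    crosses.  Invariant to common positive rescaling of both forces.
    """
    d = np.asarray(days, dtype=float)
    diff = np.asarray(f_c, dtype=float) - np.asarray(f_f, dtype=float)
    ok = np.isfinite(diff)
    d, diff = d[ok], diff[ok]
    if d.size < 2:
        logger.warning("crossover: need >= 2 days with both forces, got %d", d.size)
        return None
    if np.any(np.diff(d) <= 0):
        raise ValueError("days must be strictly increasing")
    above = np.flatnonzero(diff > 0)
    if above.size == 0:
        logger.warning("crossover: callus force never exceeds fixator force")
        return None
    i = above[0]
    if i == 0:
        return float(d[0])
    d0, d1 = d[i - 1], d[i]
    y0, y1 = diff[i - 1], diff[i]
    return float(d0 + (0.0 - y0) * (d1 - d0) / (y1 - y0))


def detect_stabilization(
    days: Sequence[float],
    values: Sequence[float],
    band: float,
    hold_days: float = DEFAULT_STABILITY_HOLD_DAYS,
) -> Optional[float]:
    """First day after which ``|value| <= band`` holds for ``hold_days``.

    The candidate day must have in-band samples throughout the hold window
    and the series must cover the full window; otherwise ``None``.
    """
    d = np.asarray(days, dtype=float)
    v = np.abs(np.asarray(values, dtype=float))
    if d.size == 0 or d[-1] - d[0] < hold_days:
        logger.warning("stabilization: series shorter than the hold window")
        return None
    in_band = v <= band
    for i in range(d.size):
        if d[i] + hold_days > d[-1]:
            break
        window = (d >= d[i]) & (d <= d[i] + hold_days)
        if in_band[window].all():
            return float(d[i])
    return None


@dataclass
class FittedCurve:
    """A fitted trend curve: parameters, fit quality and an evaluator."""

    family: str
    params: dict[str, float]
    rmse: float
    predict: Callable[[np.ndarray], np.ndarray]

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.predict(np.asarray(t, dtype=float))


def _exp_saturation(t, a, b, tau):
    return a - b * np.exp(-t / tau)


def _logistic(t, base, span, t0, scale):
    return base + span / (1.0 + np.exp(-(t - t0) / scale))


def fit_recovery_curve(
    days: Sequence[float],
    values: Sequence[float],
    family: str = "exp_saturation",
) -> FittedCurve:
    """Least-squares trend fit in one of three families.

    ``family`` is ``"exp_saturation"`` (``A - B exp(-t/tau)``),
    ``"logistic"`` (4-parameter) or ``"monotone_spline"`` (isotonic
    regression followed by a shape-preserving cubic through the isotonic
    values; direction chosen by the sign of the overall trend).
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError(f"need >= 4 points to fit a trend, got {t.size}")

    if family == "exp_saturation":
        p0 = [y[-1], max(y[-1] - y[0], 1e-6), max((t[-1] - t[0]) / 3.0, 1e-3)]
        try:
            popt, _ = curve_fit(_exp_saturation, t, y, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"exp_saturation fit failed on n={t.size}: {exc}") from exc
        params = dict(zip(("a", "b", "tau"), map(float, popt)))
        predict = lambda tt: _exp_saturation(tt, *popt)  # noqa: E731
    elif family == "logistic":
        p0 = [y.min(), y.max() - y.min() or 1.0, float(np.median(t)), max((t[-1] - t[0]) / 6.0, 1e-3)]
        try:
            popt, _ = curve_fit(_logistic, t, y, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"logistic fit failed on n={t.size}: {exc}") from exc
        params = dict(zip(("base", "span", "t0", "scale"), map(float, popt)))
        predict = lambda tt: _logistic(tt, *popt)  # noqa: E731
    elif family == "monotone_spline":
        increasing = bool(np.polyfit(t, y, 1)[0] >= 0)
        iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
        y_iso = iso.fit_transform(t, y)
        t_u, idx = np.unique(t, return_index=True)
        interp = PchipInterpolator(t_u, y_iso[idx], extrapolate=False)
        lo, hi = float(y_iso[idx][0]), float(y_iso[idx][-1])

        def predict(tt, _f=interp, _lo=lo, _hi=hi, _t0=t_u[0], _t1=t_u[-1]):
            tt = np.asarray(tt, dtype=float)
            out = _f(np.clip(tt, _t0, _t1))
            return np.where(tt < _t0, _lo, np.where(tt > _t1, _hi, out))

        params = {"increasing": float(increasing)}
    else:
        raise ValueError(f"unknown family {family!r}")

    rmse = float(np.sqrt(np.mean((np.asarray(predict(t)) - y) ** 2)))
    return FittedCurve(family=family, params=params, rmse=rmse, predict=predict)


def grf_bmd_regression(
    grf: Sequence[float],
    bmd: Sequence[float],
    r2_threshold: float = SIGNIFICANCE_R2,
    p_threshold: float = SIGNIFICANCE_P,
) -> RegressionResult:
    """OLS of body-weight-normalized GRF on BMD with the significance rule.

    Fits ``GRF = intercept + slope * BMD`` by ordinary least squares over
    paired observations and tests the slope (two-sided).  The association
    is flagged significant when R^2 exceeds ``r2_threshold`` *and* the
    slope p-value falls below ``p_threshold``.  No multiple-testing
    adjustment: a single pre-specified regression.
    """
    y = np.asarray(grf, dtype=float)
    x = np.asarray(bmd, dtype=float)
    if y.size != x.size:
        raise ValueError("grf and bmd must be paired")
    if y.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {y.size}")
    if np.ptp(x) < 1e-12:
        raise ValueError("BMD has zero variance; regression is degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(model.rsquared)
    p = float(model.pvalues[1])
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=r2,
        p_value=p,
        n=int(y.size),
        significant=bool(r2 > r2_threshold and p < p_threshold),
    )
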