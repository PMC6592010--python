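"""Exponential and linear regression of gas-exchange channels.

The central model is the exponential trend y = b * a**x fitted to a channel
(VCO2 or VE) against VO2 over the ramp phase. With VO2 in mL/min inside the
exponent, the base ``a`` sits numerically just above 1 (typically 1.0010 to
1.0020 for human ramp tests); keep the units straight or ``a`` degenerates.

The default fit is ordinary least squares of ln(y) on x (the log-linear fit
used by spreadsheet exponential trendlines). A true nonlinear least-squares
fit on the original scale is available and is initialized from the log-linear
solution. Fit quality is summarized as the Pearson correlation between the
observed and fitted values on the original (not log) scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitError, InsufficientDataError


@dataclass(frozen=True)
class ExpFit:
    """Coefficients of y = b * a**x with fit diagnostics."""

    a: float
    b: float
    r_fit: float
    n: int
    x_name: str = "vo2"
    y_name: str = "y"
    method: str = "log-linear"

    def predict(self, x) -> np.ndarray:
        return self.b * self.a ** np.asarray(x, dtype=float)

    def derivative(self, x) -> np.ndarray:
        """dy/dx = b * a**x * ln(a) of the fitted curve."""
        return self.predict(x) * np.log(self.a)


@dataclass(frozen=True)
class LinFit:
    slope: float
    intercept: float
    r: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _as_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D sequences")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("x and y must be finite")
    return x, y


def _safe_pearson(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return float("nan")
    return float(stats.pearsonr(u, v).statistic)


def fit_exponential(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "log-linear",
    *,
    x_name: str = "vo2",
    y_name: str = "y",
    n_min: int = 10,
) -> ExpFit:
    """Fit y = b * a**x.

    method "log-linear" (default): OLS of ln(y) on x; a = exp(slope),
    b = exp(intercept). method "nonlinear": least squares on the original
    scale started from the log-linear solution. On noise-free exponential
    data both recover (a, b) exactly.
    """
    x, y = _as_xy(x, y)
    if len(x) < n_min:
        raise InsufficientDataError(f"need >= {n_min} points, got {len(x)}")
    if np.any(y <= 0):
        raise DomainError("exponential fit requires all y > 0")
    if np.ptp(x) == 0:
        raise FitError("x has zero variance; exponential fit undefined")

    slope, intercept = np.polyfit(x, np.log(y), 1)
    a, b = float(np.exp(slope)), float(np.exp(intercept))

    if method == "nonlinear":
        def model(xv, av, bv):
            return bv * np.power(av, xv)

        try:
            (a, b), _ = optimize.curve_fit(
                model, x, y, p0=[a, b], maxfev=10000
            )
            a, b = float(a), float(b)
        except RuntimeError as exc:  # pragma: no cover - pathological data
            raise FitError(f"nonlinear fit failed to converge: {exc}") from exc
    elif method != "log-linear":
        raise DomainError(f"unknown method {method!r}")

    fitted = b * a ** x
    r_fit = _safe_pearson(y, fitted)
    return ExpFit(a=a, b=b, r_fit=r_fit, n=len(x),
                  x_name=x_name, y_name=y_name, method=method)


def fit_linear(x: Sequence[float], y: Sequence[float], *, n_min: int = 3) -> LinFit:
    """Ordinary least-squares line with Pearson r of (x, y)."""
    x, y = _as_xy(x, y)
    if len(x) < n_min:
        raise InsufficientDataError(f"need >= {n_min} points, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError("x has zero variance; line fit undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return LinFit(slope=float(slope), intercept=float(intercept),
                  r=_safe_pearson(x, y), n=len(x))


def slope_shape_percent_peak(
    x: Sequence[float],
    channels: dict[str, Sequence[float]],
    method: str = "log-linear",
) -> dict[str, dict[str, float]]:
    """Compare exponential slopes across channels of different units.

    Each channel is rescaled to percent of its own peak (100*y/max(y)),
    refitted, and summarized as the refitted exponential base ("slope
    (%peak)") together with the root-mean-square deviation of observed minus
    fitted values in %peak units. Rescaling makes VCO2 (mL/min) and VE
    (L/min) shapes directly comparable.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not channels:
        raise InsufficientDataError("need samples and at least one channel")
    out: dict[str, dict[str, float]] = {}
    for name, y in channels.items():
        y = np.asarray(y, dtype=float)
        y_pct = 100.0 * y / np.max(y)
        fit = fit_exponential(x, y_pct, method=method, y_name=f"{name}_pct_peak")
        resid = y_pct - fit.predict(x)
        out[name] = {
            "a_pct_peak": fit.a,
            "b_pct_peak": fit.b,
            "rmsd_pct_peak": float(np.sqrt(np.mean(resid ** 2))),
            "r_fit": fit.r_fit,
        }
    return out
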