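"""Quality control and method-agreement statistics.

Covers the statistics used around the threshold estimators: iterative
Smirnov-Grubbs screening of fit-quality values, the pre-threshold V-slope
validity check, Bland-Altman limits of agreement, Williams's test for two
dependent correlations sharing a variable, and pairwise-complete correlation
matrices for cohorts with missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import BreathSample
from .errors import DomainError, InsufficientDataError
from .fitting import fit_linear


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of iterative Grubbs screening.

    excluded_indices refer to positions in the original input, ordered by
    exclusion step; g_statistics holds each step's G alongside its critical
    value as (G, G_crit) pairs.
    """

    excluded_indices: tuple[int, ...]
    g_statistics: tuple[tuple[float, float], ...]
    alpha: float
    side: str

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_indices)


def _grubbs_critical(n: int, alpha: float, side: str) -> float:
    """Critical value of the Grubbs statistic from the t distribution.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/n (one-sided) or alpha/(2n) (two-sided) quantile of t_{n-2}.
    """
    p = alpha / n if side in ("lower", "upper") else alpha / (2 * n)
    t = sps.t.ppf(1 - p, n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(
    values: Sequence[float],
    alpha: float = 0.001,
    side: str = "lower",
) -> GrubbsResult:
    """Iterative Smirnov-Grubbs outlier screening.

    Repeatedly tests the most extreme value on the chosen tail ("lower",
    "upper" or "two-sided") against the Grubbs critical value at level
    ``alpha``, removing it while the test rejects. The default lower tail
    suits fit-quality screening: poor exponential fits depress r.

    With zero spread no value is ever excluded.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 3:
        raise InsufficientDataError("Grubbs screening needs n >= 3")
    if not np.all(np.isfinite(vals)):
        raise DomainError("values must be finite")
    if side not in ("lower", "upper", "two-sided"):
        raise DomainError(f"unknown side {side!r}")

    remaining = list(range(len(vals)))
    excluded: list[int] = []
    steps: list[tuple[float, float]] = []
    while len(remaining) >= 3:
        sub = vals[remaining]
        sd = np.std(sub, ddof=1)
        if sd == 0:
            break
        mean = np.mean(sub)
        if side == "lower":
            pos = int(np.argmin(sub))
            g = (mean - sub[pos]) / sd
        elif side == "upper":
            pos = int(np.argmax(sub))
            g = (sub[pos] - mean) / sd
        else:
            pos = int(np.argmax(np.abs(sub - mean)))
            g = abs(sub[pos] - mean) / sd
        crit = _grubbs_critical(len(sub), alpha, side)
        if g > crit:
            steps.append((float(g), float(crit)))
            excluded.append(remaining.pop(pos))
        else:
            break
    return GrubbsResult(
        excluded_indices=tuple(excluded),
        g_statistics=tuple(steps),
        alpha=alpha,
        side=side,
    )


def pre_vat_slope_check(
    samples: Sequence[BreathSample],
    threshold: float = 1.105,
) -> dict:
    """Linear V-slope validity check over a data segment.

    Fits VCO2 on VO2 linearly and compares the slope with ``threshold``
    (default 1.105, the pre-threshold slope mean + 2 SD, 0.901 + 0.204).
    A slope below the threshold over a whole test indicates the metabolic
    threshold was likely never reached, so an exponential threshold estimate
    should not be trusted.
    """
    if len(samples) < 10:
        raise InsufficientDataError("slope check needs >= 10 points")
    fit = fit_linear([s.vo2 for s in samples], [s.vco2 for s in samples])
    return {"slope": fit.slope, "valid": bool(fit.slope >= threshold)}


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman style agreement between two paired measurements."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_half_width: float  # always 1.96 * sd_diff
    pearson_r: float
    williams_t: float | None = None
    williams_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_half_width": self.loa_half_width,
            "pearson_r": self.pearson_r,
            "williams_t": self.williams_t,
            "williams_p": self.williams_p,
        }


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementReport:
    """Limits of agreement between paired measurements.

    Pairs with a missing member are dropped. Differences d = x - y are
    summarized as mean and sample SD (n-1 denominator); the half-width of
    the limits of agreement is 1.96*SD. Pearson r of (x, y) accompanies the
    report; it is NaN when either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("paired inputs must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError("agreement needs >= 3 complete pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(sps.pearsonr(x, y).statistic)
    return AgreementReport(
        n=len(x),
        mean_diff=float(np.mean(d)),
        sd_diff=sd,
        loa_half_width=1.96 * sd,
        pearson_r=r,
    )


def williams_test(r12: float, r13: float, r23: float, n: int) -> dict:
    """Williams's t for comparing two dependent correlations sharing variable 1.

    Tests H0: rho(1,2) = rho(1,3) given the correlation r23 between the two
    competing variables, on n subjects:

        t = (r12 - r13) * sqrt( (n-1)(1+r23) /
              ( 2*((n-1)/(n-3))*|R| + rbar^2*(1-r23)^3 ) )

    with |R| = 1 - r12^2 - r13^2 - r23^2 + 2*r12*r13*r23 (the determinant of
    the 3x3 correlation matrix) and rbar = (r12+r13)/2. Two-sided p from the
    t distribution with n-3 degrees of freedom.
    """
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise DomainError("correlations must lie strictly inside (-1, 1)")
    if n < 5:
        raise DomainError("Williams's test needs n >= 5")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det <= 0:
        raise DomainError(
            "correlation triplet is not positive definite (|R| <= 0)"
        )
    rbar = (r12 + r13) / 2.0
    denom = 2 * ((n - 1) / (n - 3)) * det + rbar**2 * (1 - r23) ** 3
    t = (r12 - r13) * math.sqrt((n - 1) * (1 + r23) / denom)
    df = n - 3
    p = 2 * sps.t.sf(abs(t), df)
    return {"t": t, "p": p, "df": df}


def correlation_matrix(columns: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix with per-pair n.

    Missing values (None/NaN) are dropped pair by pair, so every cell uses
    the maximal available n — the convention for cohorts where a visual
    threshold was not detected in some subjects. Returns a DataFrame whose
    cells are (r, n) tuples; r is NaN when fewer than 3 complete pairs or a
    degenerate column.
    """
    if len(columns) < 2:
        raise DomainError("need at least 2 columns")
    df = pd.DataFrame(
        {k: pd.to_numeric(pd.Series(v, dtype=float), errors="coerce")
         for k, v in columns.items()}
    )
    names = list(df.columns)
    out = pd.DataFrame(index=names, columns=names, dtype=object)
    for i in names:
        for j in names:
            u, v = df[i].to_numpy(), df[j].to_numpy()
            keep = np.isfinite(u) & np.isfinite(v)
            u, v = u[keep], v[keep]
            n = len(u)
            if n < 3 or np.std(u) == 0 or np.std(v) == 0:
                out.loc[i, j] = (float("nan"), n)
            else:
                out.loc[i, j] = (float(sps.pearsonr(u, v).statistic), n)
    return out
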