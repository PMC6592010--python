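"""Closed-form ventilatory anaerobic threshold (VAT) estimators.

Two objective VAT estimates are derived from exponential fits of ramp data
against VO2 (x, mL/min):

* expVAT(VCO2): on the fitted V-slope y = b*a**x (VCO2 vs VO2), the VO2 at
  which the tangent is parallel to the R = 1 line, i.e. where the fitted
  instantaneous dVCO2/dVO2 equals exactly 1. Closed form
  x0 = ln(1 / (b*ln a)) / ln a, defined for a > 1 and b*ln(a) < 1.

* expVAT(VE): on the fitted VO2-VE curve, the VO2 at which the tangent
  passes through the origin. Closed form x0 = 1/ln(a), independent of b.
  This point is also the minimizer of the fitted ventilatory equivalent
  (b*a**x)/x over x > 0 — the VE/VO2 nadir.

In both, a smaller base ``a`` (a shallower exponential) yields a higher
threshold. The oxygen uptake efficiency slope (OUES) is the companion
submaximal index: the OLS slope of VO2 on log10(VE) (or log10(VCO2)), in
mL/min per decade of the ventilatory channel.

Batch workflows need per-subject missingness rather than exceptions, so
undefined estimates come back as None together with explanatory QC flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import BreathSample, CpxTest, highest_values, moving_average, require_ramp
from .errors import DomainError, InsufficientDataError
from .fitting import ExpFit, LinFit, fit_exponential, fit_linear

# QC flags attached to a VatEstimates record
FLAG_A_NOT_GT_1 = "a_not_gt_1"
FLAG_POOR_FIT = "poor_fit_outlier"
FLAG_PRE_VAT_SLOPE = "pre_vat_slope_below_threshold"
FLAG_INSUFFICIENT = "insufficient_data"
FLAG_IMPLAUSIBLE = "implausible_expvat"

#: linear V-slope below which the threshold was likely never reached
#: (pre-threshold slope mean + 2 SD, 0.901 + 0.204)
PRE_VAT_SLOPE_THRESHOLD = 1.105


def expvat_vco2(fit: ExpFit) -> float | None:
    """VO2 (mL/min) where the fitted V-slope tangent is parallel to R = 1.

    x0 = ln(1/(b*ln a)) / ln a. At x0 the derivative b*a**x0*ln(a) is
    exactly 1. Returns None when undefined: a <= 1 (no accelerating CO2
    output) or tangent point at x <= 0.
    """
    if not (fit.a > 1.0) or not (fit.b > 0):
        return None
    la = math.log(fit.a)
    arg = fit.b * la
    if arg >= 1.0:  # tangency at x <= 0
        return None
    x0 = math.log(1.0 / arg) / la
    if not (math.isfinite(x0) and x0 > 0):
        return None
    return x0


def expvat_ve(fit: ExpFit) -> float | None:
    """VO2 (mL/min) where the fitted VO2-VE curve's tangent crosses the origin.

    x0 = 1/ln(a); equals the fitted VE/VO2 nadir. Independent of b.
    Returns None when a <= 1.
    """
    if not (fit.a > 1.0):
        return None
    return 1.0 / math.log(fit.a)


def oues(samples: Sequence[BreathSample], channel: str = "ve") -> LinFit:
    """Oxygen uptake efficiency slope: OLS of VO2 on log10(channel).

    channel "ve" uses VE in L/min; channel "vco2" uses VCO2 in mL/min. The
    slope (mL/min per decade) is invariant to the channel's unit scale,
    since rescaling only shifts the logarithm.
    """
    if channel not in ("ve", "vco2"):
        raise DomainError(f"channel must be 've' or 'vco2', got {channel!r}")
    if len(samples) < 10:
        raise InsufficientDataError(
            f"OUES needs >= 10 ramp samples, got {len(samples)}"
        )
    x = np.array([getattr(s, channel) for s in samples], dtype=float)
    y = np.array([s.vo2 for s in samples], dtype=float)
    if np.any(x <= 0):
        raise DomainError(f"non-positive {channel} value in OUES input")
    return fit_linear(np.log10(x), y)


@dataclass(frozen=True)
class VatEstimates:
    """Per-test derived indices with QC flags.

    All estimates are optional; every missing value is explained by at least
    one flag in ``qc_flags``. Thresholds in mL/min; OUES in mL/min per
    decade; relative values in percent.
    """

    subject_id: str = ""
    expvat_vco2: float | None = None
    expvat_ve: float | None = None
    a_vslope: float | None = None
    b_vslope: float | None = None
    r_vslope: float | None = None
    a_ve: float | None = None
    b_ve: float | None = None
    r_ve: float | None = None
    oues_ve: float | None = None
    oues_vco2: float | None = None
    pre_vat_slope: float | None = None
    highest_vo2: float | None = None
    highest_hr: float | None = None
    highest_r: float | None = None
    relative_vat_vco2_pct: float | None = None
    relative_vat_ve_pct: float | None = None
    pct_predicted_hr: float | None = None
    expvat_vco2_per_kg: float | None = None
    expvat_ve_per_kg: float | None = None
    highest_vo2_per_kg: float | None = None
    qc_flags: frozenset = field(default_factory=frozenset)

    #: estimator fields reported in batch/paired tables
    INDEX_FIELDS = (
        "expvat_vco2", "expvat_ve", "oues_ve", "oues_vco2",
        "a_vslope", "a_ve", "highest_vo2",
    )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "qc_flags"}
        d["qc_flags"] = sorted(self.qc_flags)
        return d


def summary_metrics(est: VatEstimates, test: CpxTest) -> VatEstimates:
    """Complete an estimate record with peak-relative and per-kg metrics.

    relative VAT (%) = 100 * expVAT / highest VO2 for each estimator;
    %predicted HR = 100 * highest HR / (220 - age); per-kg values divide by
    body weight. Fields whose inputs (age, weight, HR) are missing stay None.
    """
    peaks = highest_values(test)
    hv, hh = peaks["highest_vo2"], peaks["highest_hr"]
    upd: dict = {
        "highest_vo2": hv,
        "highest_hr": hh,
        "highest_r": peaks["highest_r"],
        "highest_vo2_per_kg": peaks["highest_vo2_per_kg"],
    }
    if hv:
        if est.expvat_vco2 is not None:
            upd["relative_vat_vco2_pct"] = 100.0 * est.expvat_vco2 / hv
        if est.expvat_ve is not None:
            upd["relative_vat_ve_pct"] = 100.0 * est.expvat_ve / hv
    age, weight = test.meta.age, test.meta.weight
    if hh is not None and age is not None and age < 220:
        upd["pct_predicted_hr"] = 100.0 * hh / (220.0 - age)
    if weight:
        if est.expvat_vco2 is not None:
            upd["expvat_vco2_per_kg"] = est.expvat_vco2 / weight
        if est.expvat_ve is not None:
            upd["expvat_ve_per_kg"] = est.expvat_ve / weight
    return replace(est, **upd)


def evaluate_cohort(
    tests: Sequence[CpxTest],
    *,
    method: str = "log-linear",
    grubbs_alpha: float = 0.001,
) -> list[VatEstimates]:
    """Evaluate a cohort and screen out poorly fitted subjects.

    After per-test evaluation, the fit-quality correlations of each
    exponential fit (V-slope and VO2-VE) are screened with the iterative
    lower-tail Grubbs test at ``grubbs_alpha``; subjects excluded on either
    channel get the poor-fit flag. Set ``grubbs_alpha`` to 0 to skip
    screening.
    """
    from .stats import grubbs_screen  # local import: stats does not need us

    ests = [evaluate_test(t, method=method) for t in tests]
    if grubbs_alpha > 0 and len(ests) >= 3:
        for attr in ("r_vslope", "r_ve"):
            vals = [getattr(e, attr) for e in ests]
            idx = [i for i, v in enumerate(vals)
                   if v is not None and math.isfinite(v)]
            if len(idx) < 3:
                continue
            res = grubbs_screen([vals[i] for i in idx], alpha=grubbs_alpha,
                                side="lower")
            for j in res.excluded_indices:
                i = idx[j]
                ests[i] = replace(
                    ests[i],
                    qc_flags=frozenset(ests[i].qc_flags | {FLAG_POOR_FIT}),
                )
    return ests


def evaluate_test(
    test: CpxTest,
    *,
    method: str = "log-linear",
    slope_threshold: float = PRE_VAT_SLOPE_THRESHOLD,
    smooth_window: int = 1,
) -> VatEstimates:
    """Compute every derived index for one CPX test.

    Fits the exponential V-slope (VCO2 vs VO2) and VO2-VE relation over the
    ramp phase, evaluates both closed-form thresholds, both OUES variants,
    the whole-ramp linear V-slope validity check, and the peak-relative
    summary metrics. Never raises for estimator-level problems: undefined or
    implausible estimates are returned as None/flagged.
    """
    flags: set[str] = set()
    sid = test.meta.subject_id
    try:
        ramp = require_ramp(test, 10)
    except InsufficientDataError:
        return VatEstimates(subject_id=sid,
                            qc_flags=frozenset({FLAG_INSUFFICIENT}))
    if smooth_window > 1:
        ramp = moving_average(ramp, smooth_window)

    vo2 = [s.vo2 for s in ramp]
    vslope = fit_exponential(vo2, [s.vco2 for s in ramp], method=method,
                             y_name="vco2")
    vefit = fit_exponential(vo2, [s.ve for s in ramp], method=method,
                            y_name="ve")

    vat_v = expvat_vco2(vslope)
    vat_e = expvat_ve(vefit)
    if vat_v is None or vat_e is None:
        flags.add(FLAG_A_NOT_GT_1)

    lin = fit_linear(vo2, [s.vco2 for s in ramp])
    if lin.slope < slope_threshold:
        # whole-test V-slope never steepened past the pre-threshold band:
        # the threshold was probably not reached and expVAT is unreliable
        flags.add(FLAG_PRE_VAT_SLOPE)

    est = VatEstimates(
        subject_id=sid,
        expvat_vco2=vat_v,
        expvat_ve=vat_e,
        a_vslope=vslope.a, b_vslope=vslope.b, r_vslope=vslope.r_fit,
        a_ve=vefit.a, b_ve=vefit.b, r_ve=vefit.r_fit,
        oues_ve=oues(ramp, "ve").slope,
        oues_vco2=oues(ramp, "vco2").slope,
        pre_vat_slope=lin.slope,
        qc_flags=frozenset(flags),
    )
    est = summary_metrics(est, test)

    # sanity bound: extrapolated thresholds far above the observed peak are
    # flagged (not erased) — exponential fitting misbehaves most in subjects
    # with high exercise tolerance
    hv = est.highest_vo2
    if hv is not None:
        for v in (est.expvat_vco2, est.expvat_ve):
            if v is not None and v > 1.5 * hv:
                flags.add(FLAG_IMPLAUSIBLE)
    return replace(est, qc_flags=frozenset(flags))
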