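"""Seeded breath-by-breath ramp-test simulator with a known true threshold.

The generative model is deliberately NOT the exponential the estimators fit:
the noise-free V-slope is two-segment linear — slope s1 (< 1) below the true
metabolic threshold and s2 (> 1) above, continuous at the knot — so the
estimators are exercised the way they are used on real tests: as an
exponential summary of threshold-shaped data, not a self-fulfilling fit.

* VO2 rises linearly through the ramp from its resting level.
* VCO2 = vco2_intercept + s1*VO2 below the threshold, continuing with slope
  s2 above it.
* VE = ve_intercept + ve_per_vco2 * VCO2. The positive VE intercept makes
  the ventilatory equivalent VE/VO2 fall before the threshold and rise after
  it, putting its nadir at the knot — the geometry the VE-based threshold
  estimator relies on.
* Breath-to-breath variability is multiplicative lognormal noise with a
  given coefficient of variation, independently per gas channel and breath
  (physiological scatter scales with the signal).

Ground truth (the knot location) accompanies every simulated test; no
estimator ever reads it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import BreathSample, CpxTest, Protocol, SubjectMeta
from .errors import ValidationError


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one simulated ramp test.

    Defaults describe a healthy adult: resting VO2 300 mL/min rising ~185
    mL/min per minute over a 550 s ramp (peak just under 2000 mL/min),
    threshold at 1100 mL/min (~55% of peak), pre/post-threshold V-slope
    0.90/1.40, VE tracking VCO2 with ratio 28 over a 3 L/min intercept,
    breaths every ~2 s, 4% multiplicative noise per channel.
    """

    vo2_rest: float = 300.0
    vo2_rise_rate: float = 185.0  # mL/min per minute of ramp
    ramp_duration: float = 550.0  # s
    warmup_duration: float = 120.0  # s
    true_vat: float = 1100.0  # mL/min
    s1: float = 0.90
    s2: float = 1.40
    vco2_intercept: float = 0.0  # mL/min
    ve_intercept: float = 3.0  # L/min
    ve_per_vco2: float = 28.0  # L/min VE per L/min VCO2
    breath_interval_mean: float = 2.0  # s
    noise_cv: float = 0.04
    hr_rest: float = 70.0
    hr_peak: float = 165.0
    ramp_rate_w: float = 15.0  # W/min, cosmetic work-rate channel
    seed: int = 0

    @property
    def vo2_peak(self) -> float:
        """Noise-free end-ramp VO2, mL/min."""
        return self.vo2_rest + self.vo2_rise_rate * self.ramp_duration / 60.0

    def validate(self) -> None:
        problems = []
        if not 0 < self.s1 < 1:
            problems.append(f"s1 must be in (0, 1), got {self.s1}")
        if not self.s2 > 1:
            problems.append(f"s2 must be > 1, got {self.s2}")
        if not self.vo2_rest > 0:
            problems.append(f"vo2_rest must be > 0, got {self.vo2_rest}")
        if not self.vo2_rest < self.true_vat < self.vo2_peak:
            problems.append(
                f"true_vat must lie inside (vo2_rest, vo2_peak) = "
                f"({self.vo2_rest}, {self.vo2_peak:.0f}), got {self.true_vat}"
            )
        if self.noise_cv < 0:
            problems.append(f"noise_cv must be >= 0, got {self.noise_cv}")
        for name in ("vo2_rise_rate", "ramp_duration", "warmup_duration",
                     "breath_interval_mean", "ve_per_vco2"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0")
        if problems:
            raise ValidationError("; ".join(problems))


def _noiseless_channels(params: SimParams, t_ramp: np.ndarray):
    """Piecewise-linear noise-free VO2/VCO2/VE at ramp times (s from ramp start)."""
    vo2 = params.vo2_rest + params.vo2_rise_rate * t_ramp / 60.0
    knot_vco2 = params.vco2_intercept + params.s1 * params.true_vat
    vco2 = np.where(
        vo2 <= params.true_vat,
        params.vco2_intercept + params.s1 * vo2,
        knot_vco2 + params.s2 * (vo2 - params.true_vat),
    )
    ve = params.ve_intercept + params.ve_per_vco2 * vco2 / 1000.0
    return vo2, vco2, ve


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, n)


def simulate_subject(
    params: SimParams,
    meta: SubjectMeta | None = None,
    *,
    vvat_cv: float | None = None,
) -> CpxTest:
    """Simulate one breath-by-breath ramp test.

    Breaths arrive at intervals jittered +-20% around the mean. The warmup
    phase holds resting values; the ramp follows the piecewise model above
    with per-breath multiplicative noise. Deterministic for a fixed seed.

    ``vvat_cv``, when given, attaches a noisy reading of the true threshold
    to the metadata as a synthetic stand-in for a visually determined
    threshold (useful for agreement demonstrations).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    total = params.warmup_duration + params.ramp_duration

    times = []
    t = 0.0
    while True:
        t += params.breath_interval_mean * rng.uniform(0.8, 1.2)
        if t > total:
            break
        times.append(t)
    times = np.asarray(times)
    in_ramp = times >= params.warmup_duration
    t_ramp = times[in_ramp] - params.warmup_duration

    n_w = int((~in_ramp).sum())
    n_r = int(in_ramp.sum())
    vo2 = np.empty_like(times)
    vco2 = np.empty_like(times)
    ve = np.empty_like(times)
    vo2[~in_ramp] = params.vo2_rest
    knot = params.vco2_intercept + params.s1 * params.vo2_rest
    vco2[~in_ramp] = knot
    ve[~in_ramp] = params.ve_intercept + params.ve_per_vco2 * knot / 1000.0
    vo2[in_ramp], vco2[in_ramp], ve[in_ramp] = _noiseless_channels(params, t_ramp)

    frac = (vo2 - params.vo2_rest) / max(params.vo2_peak - params.vo2_rest, 1.0)
    hr = params.hr_rest + (params.hr_peak - params.hr_rest) * np.clip(frac, 0, 1)
    work = np.where(in_ramp, params.ramp_rate_w * (times - params.warmup_duration) / 60.0, 0.0)

    n = len(times)
    vo2 = vo2 * _lognormal_factors(rng, params.noise_cv, n)
    vco2 = vco2 * _lognormal_factors(rng, params.noise_cv, n)
    ve = ve * _lognormal_factors(rng, params.noise_cv, n)

    meta = meta or SubjectMeta(subject_id=f"sim-{params.seed}")
    if vvat_cv is not None and vvat_cv > 0:
        vvat = float(params.true_vat * _lognormal_factors(rng, vvat_cv, 1)[0])
        meta = replace(meta, vvat=vvat)
    elif vvat_cv == 0.0:
        meta = replace(meta, vvat=float(params.true_vat))

    samples = tuple(
        BreathSample(
            t=float(times[i]),
            vo2=float(vo2[i]),
            vco2=float(vco2[i]),
            ve=float(ve[i]),
            hr=float(hr[i]),
            work_rate=float(work[i]),
            phase="ramp" if in_ramp[i] else "warmup",
        )
        for i in range(n)
    )
    protocol = Protocol(ramp_rate=params.ramp_rate_w, warmup_s=params.warmup_duration)
    return CpxTest(meta=meta, protocol=protocol, samples=samples)


@dataclass(frozen=True)
class CohortSpread:
    """Per-subject heterogeneity around base simulation parameters.

    true thresholds are drawn uniformly over ``vat_range``; each subject's
    peak VO2 is set so the threshold sits at a normally distributed fraction
    of the peak (matching the ~57% relative threshold typical of ramp
    cohorts); slopes, resting VO2, ramp duration and noise get normal
    jitter, clipped to physiological bounds.
    """

    vat_range: tuple[float, float] = (450.0, 1400.0)
    rel_vat_mean: float = 0.575
    rel_vat_sd: float = 0.04
    vo2_rest_sd: float = 30.0
    duration_sd: float = 100.0
    s1_sd: float = 0.05
    s2_sd: float = 0.10
    noise_cv_sd: float = 0.0

    def validate(self) -> None:
        problems = []
        lo, hi = self.vat_range
        if not 0 < lo <= hi:
            problems.append(f"vat_range must be non-decreasing positive, got {self.vat_range}")
        for name in ("rel_vat_sd", "vo2_rest_sd", "duration_sd",
                     "s1_sd", "s2_sd", "noise_cv_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not 0 < self.rel_vat_mean < 1:
            problems.append("rel_vat_mean must be in (0, 1)")
        if problems:
            raise ValidationError("; ".join(problems))


def simulate_cohort(
    n: int,
    base: SimParams | None = None,
    spread: CohortSpread | None = None,
    seed: int = 0,
    *,
    vvat_cv: float | None = None,
) -> list[tuple[CpxTest, float]]:
    """Simulate a cohort; returns (test, true threshold) pairs.

    Reproducible for a fixed seed. With ``n = 1`` and a zero-width spread
    the subject reduces to ``simulate_subject(base)`` up to its metadata.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    base = base or SimParams()
    spread = spread or CohortSpread()
    spread.validate()
    rng = np.random.default_rng(seed)
    zero_spread = (
        spread.vat_range[0] == spread.vat_range[1]
        and spread.rel_vat_sd == spread.vo2_rest_sd == spread.duration_sd
        == spread.s1_sd == spread.s2_sd == spread.noise_cv_sd == 0.0
    )
    out = []
    for i in range(n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if zero_spread and spread.vat_range[0] == base.true_vat:
            # degenerate spread: reproduce the base subject exactly
            p = base
        else:
            vat = float(rng.uniform(*spread.vat_range))
            frac = float(np.clip(rng.normal(spread.rel_vat_mean, spread.rel_vat_sd), 0.40, 0.75))
            rest = float(np.clip(rng.normal(base.vo2_rest, spread.vo2_rest_sd), 150.0, min(400.0, 0.8 * vat)))
            dur = float(np.clip(rng.normal(base.ramp_duration, spread.duration_sd), 300.0, 900.0))
            peak = max(vat / frac, vat + 100.0, rest + 200.0)
            rise = (peak - rest) / (dur / 60.0)
            p = replace(
                base,
                true_vat=vat,
                vo2_rest=rest,
                ramp_duration=dur,
                vo2_rise_rate=rise,
                s1=float(np.clip(rng.normal(base.s1, spread.s1_sd), 0.70, 0.99)),
                s2=float(np.clip(rng.normal(base.s2, spread.s2_sd), 1.05, 2.0)),
                noise_cv=float(max(rng.normal(base.noise_cv, spread.noise_cv_sd), 0.0)),
                hr_peak=float(np.clip(rng.normal(base.hr_peak, 15.0), 100.0, 200.0)),
                seed=sub_seed,
            )
        meta = SubjectMeta(
            subject_id=f"sim{i:03d}",
            age=float(np.clip(rng.normal(55.0, 15.0), 20.0, 85.0)),
            sex="female" if rng.uniform() < 0.5 else "male",
            weight=float(np.clip(rng.normal(65.0, 12.0), 40.0, 110.0)),
        )
        test = simulate_subject(p, meta=meta, vvat_cv=vvat_cv)
        out.append((test, p.true_vat))
    return out
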