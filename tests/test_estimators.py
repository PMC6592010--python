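"""Closed-form threshold estimators: tangency identities, nadir equivalence,
OUES conventions and per-test evaluation with QC flags."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import expvat as ev
from expvat.estimators import FLAG_A_NOT_GT_1, FLAG_INSUFFICIENT
from expvat.fitting import ExpFit


def mkfit(a, b, **kw):
    return ExpFit(a=a, b=b, r_fit=1.0, n=100, **kw)


valid_ab = st.tuples(
    st.floats(1.0005, 1.004),  # base: 1/ln(a) spans ~250-2000 mL/min
    st.floats(50.0, 600.0),
)


@given(valid_ab)
def test_vslope_tangent_derivative_is_exactly_one(ab):
    """At expVAT(VCO2) the fitted curve's slope equals the R = 1 line's slope."""
    a, b = ab
    x0 = ev.expvat_vco2(mkfit(a, b))
    if x0 is None:  # b*ln(a) >= 1: tangent point not in the positive domain
        assert b * math.log(a) >= 1.0
        return
    deriv = b * a ** x0 * math.log(a)
    assert deriv == pytest.approx(1.0, rel=1e-10)


@given(valid_ab)
def test_ve_tangent_chord_equals_derivative(ab):
    """At expVAT(VE) the chord from the origin has the curve's own slope."""
    a, b = ab
    x0 = ev.expvat_ve(mkfit(a, b))
    chord = b * a ** x0 / x0
    deriv = b * a ** x0 * math.log(a)
    assert chord == pytest.approx(deriv, rel=1e-10)


def test_expvat_ve_is_independent_of_b():
    assert ev.expvat_ve(mkfit(1.0015, 10.0)) == ev.expvat_ve(mkfit(1.0015, 900.0))
    assert ev.expvat_ve(mkfit(1.0015, 300.0)) == pytest.approx(
        1 / math.log(1.0015))  # ~667.2 mL/min


def test_expvat_worked_value_and_degenerate_base():
    x0 = ev.expvat_vco2(mkfit(1.0020, 154.3))
    assert x0 == pytest.approx(
        math.log(1 / (154.3 * math.log(1.0020))) / math.log(1.0020))
    assert 500 < x0 < 700  # cardiac-range threshold magnitude
    assert ev.expvat_vco2(mkfit(1.0, 300.0)) is None
    assert ev.expvat_ve(mkfit(0.9995, 300.0)) is None


@given(st.floats(1.0006, 1.003), st.floats(1.0006, 1.003), st.floats(100.0, 400.0))
def test_thresholds_strictly_decrease_as_base_increases(a1, a2, b):
    """A steeper exponential (larger a) means a lower threshold, fixed b."""
    if a1 == a2:
        return
    lo, hi = sorted((a1, a2))
    v_lo, v_hi = ev.expvat_vco2(mkfit(lo, b)), ev.expvat_vco2(mkfit(hi, b))
    if v_lo is not None and v_hi is not None:
        assert v_hi < v_lo
    assert ev.expvat_ve(mkfit(hi, b)) < ev.expvat_ve(mkfit(lo, b))


def test_expvat_ve_equals_brute_force_nadir_of_fitted_ve_vo2():
    """1/ln(a) minimizes (b*a**x)/x: check against a 1 mL/min grid scan."""
    rng = np.random.default_rng(12)
    for _ in range(50):
        a = float(rng.uniform(1.0006, 1.003))
        b = float(rng.uniform(3.0, 40.0))
        x0 = ev.expvat_ve(mkfit(a, b))
        grid = np.arange(1.0, 5.0 / math.log(a), 1.0)
        ratio = b * a ** grid / grid
        assert abs(grid[np.argmin(ratio)] - x0) <= 1.0


def test_oues_exact_slope_and_unit_invariance():
    ve = np.linspace(8.0, 80.0, 40)
    vo2 = 2000.0 * np.log10(ve) - 500.0
    samples = [ev.BreathSample(t=i, vo2=v, vco2=0.9 * v, ve=e)
               for i, (v, e) in enumerate(zip(vo2, ve))]
    assert ev.oues(samples, "ve").slope == pytest.approx(2000.0, rel=1e-12)
    # rescaling the channel only shifts log10 -> intercept; slope unchanged
    ml = [ev.BreathSample(t=s.t, vo2=s.vo2, vco2=s.vco2 / 1000 + 1e-9, ve=s.ve)
          for s in samples]
    base = ev.oues(samples, "vco2").slope
    assert ev.oues(ml, "vco2").slope == pytest.approx(base, rel=1e-6)


def test_oues_rejects_too_few_or_nonpositive():
    s = [ev.BreathSample(t=i, vo2=300 + i, vco2=270, ve=10) for i in range(5)]
    with pytest.raises(ev.InsufficientDataError):
        ev.oues(s, "ve")


def test_summary_metrics_arithmetic(noise_free_test):
    meta = ev.SubjectMeta(subject_id="s", age=60.0, weight=70.0)
    test = ev.CpxTest(meta=meta, protocol=noise_free_test.protocol,
                      samples=noise_free_test.samples)
    hv = ev.highest_values(test)["highest_vo2"]
    est = ev.VatEstimates(expvat_vco2=hv / 2.0, expvat_ve=hv / 2.0)
    out = ev.summary_metrics(est, test)
    assert out.relative_vat_vco2_pct == pytest.approx(50.0)
    assert out.expvat_vco2_per_kg == pytest.approx(hv / 140.0)
    # age 60 -> predicted max 160; %predicted = highest HR / 160
    assert out.pct_predicted_hr == pytest.approx(100.0 * out.highest_hr / 160.0)


def test_evaluate_test_full_record(default_test):
    est = ev.evaluate_test(default_test)
    assert est.expvat_vco2 is not None and est.expvat_ve is not None
    assert 1.0005 < est.a_vslope < 1.005
    assert est.r_vslope > 0.97
    assert est.oues_ve > est.oues_vco2 > 0
    assert est.pre_vat_slope > ev.PRE_VAT_SLOPE_THRESHOLD
    assert not est.qc_flags


def test_evaluate_test_flags_flat_vslope():
    """A test that never crosses the threshold: base <= 1 and shallow slope."""
    rng = np.random.default_rng(9)
    vo2 = np.linspace(300, 900, 120)
    vco2 = 0.85 * vo2 * rng.lognormal(0, 0.02, vo2.size)
    samples = tuple(ev.BreathSample(t=i, vo2=v, vco2=c, ve=0.028 * c + 3)
                    for i, (v, c) in enumerate(zip(vo2, vco2)))
    est = ev.evaluate_test(ev.CpxTest(samples=samples))
    assert "pre_vat_slope_below_threshold" in est.qc_flags
    assert est.pre_vat_slope < ev.PRE_VAT_SLOPE_THRESHOLD


def test_evaluate_test_insufficient_data_flag():
    s = tuple(ev.BreathSample(t=i, vo2=300 + i, vco2=280, ve=10, phase="ramp")
              for i in range(5))
    est = ev.evaluate_test(ev.CpxTest(samples=s))
    assert est.qc_flags == {FLAG_INSUFFICIENT}
    assert est.expvat_vco2 is None


def test_evaluate_cohort_grubbs_flags_poor_fit(small_cohort):
    tests = [t for t, _ in small_cohort]
    # corrupt one subject's VCO2 with gross artifacts to wreck its fit r
    bad = tests[0]
    rng = np.random.default_rng(0)
    samples = tuple(
        ev.BreathSample(t=s.t, vo2=s.vo2,
                        vco2=s.vco2 * float(rng.lognormal(0, 0.5)),
                        ve=s.ve, hr=s.hr, work_rate=s.work_rate, phase=s.phase)
        for s in bad.samples)
    tests[0] = ev.CpxTest(meta=bad.meta, protocol=bad.protocol, samples=samples)
    ests = ev.evaluate_cohort(tests)
    assert "poor_fit_outlier" in ests[0].qc_flags
    assert all("poor_fit_outlier" not in e.qc_flags for e in ests[1:])
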