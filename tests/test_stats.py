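"""Outlier screening, validity checks and agreement statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import expvat as ev


def grubbs_crit_oracle(n, alpha):
    """Tabulated-formula one-sided Grubbs critical value, coded independently."""
    t2 = sps.t.ppf(1 - alpha / n, n - 2) ** 2
    return (n - 1) * math.sqrt(t2 / (n * (n - 2 + t2)))


class TestGrubbs:
    def test_single_gross_outlier_excluded(self):
        values = [0.99] * 9 + [0.985] * 5 + [0.992] * 5 + [0.70]
        res = ev.grubbs_screen(values, alpha=0.001, side="lower")
        assert res.excluded_indices == (19,)
        g, crit = res.g_statistics[0]
        n = len(values)
        arr = np.array(values)
        g_oracle = (arr.mean() - arr.min()) / arr.std(ddof=1)
        assert g == pytest.approx(g_oracle, rel=1e-12)
        assert crit == pytest.approx(grubbs_crit_oracle(n, 0.001), rel=1e-10)
        assert g_oracle > crit

    def test_identical_values_never_excluded(self):
        res = ev.grubbs_screen([0.99] * 10)
        assert res.excluded_indices == ()

    def test_exclusions_non_increasing_in_alpha(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0.98, 0.005, 30), [0.9, 0.85]])
        counts = [ev.grubbs_screen(vals, alpha=a).n_excluded
                  for a in (0.05, 0.01, 0.001, 1e-6)]
        assert counts == sorted(counts, reverse=True)

    def test_iterative_removal_of_multiple_outliers(self):
        vals = [0.99] * 25 + [0.75, 0.70]
        res = ev.grubbs_screen(vals, alpha=0.001)
        assert set(res.excluded_indices) == {25, 26}
        # most extreme first
        assert res.excluded_indices[0] == 26

    def test_needs_three_values(self):
        with pytest.raises(ev.InsufficientDataError):
            ev.grubbs_screen([0.9, 0.8])


class TestPreVatSlopeCheck:
    def test_threshold_is_mean_plus_two_sd_of_printed_statistics(self):
        assert 0.901 + 2 * 0.102 == pytest.approx(1.105, abs=5e-4)
        assert ev.PRE_VAT_SLOPE_THRESHOLD == pytest.approx(1.105)

    def test_pure_pre_threshold_segment_is_invalid(self):
        vo2 = np.linspace(300, 900, 60)
        samples = [ev.BreathSample(t=i, vo2=v, vco2=0.9 * v, ve=10)
                   for i, v in enumerate(vo2)]
        out = ev.pre_vat_slope_check(samples)
        assert out["slope"] == pytest.approx(0.9, rel=1e-9)
        assert out["valid"] is False

    def test_full_ramp_crossing_threshold_is_valid(self, noise_free_test):
        ramp = ev.select_ramp(noise_free_test)
        out = ev.pre_vat_slope_check(ramp)
        # direct OLS oracle on the mixture
        x = np.array([s.vo2 for s in ramp]); y = np.array([s.vco2 for s in ramp])
        slope = np.polyfit(x, y, 1)[0]
        assert out["slope"] == pytest.approx(slope, rel=1e-12)
        assert slope > 1.105 and out["valid"] is True

    def test_sub_threshold_segments_flagged_invalid_with_noise(self):
        """Segments wholly below the true threshold fail the check >= 95% of runs."""
        n_invalid = 0
        reps = 200
        for i in range(reps):
            p = ev.SimParams(seed=10_000 + i)
            test = ev.simulate_subject(p)
            below = [s for s in ev.select_ramp(test) if s.vo2 < p.true_vat]
            if not ev.pre_vat_slope_check(below)["valid"]:
                n_invalid += 1
        assert n_invalid / reps >= 0.95


class TestBlandAltman:
    def test_identical_inputs(self):
        rep = ev.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.mean_diff == 0.0 and rep.loa_half_width == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_zero_variance_r_is_flagged_nan(self):
        rep = ev.bland_altman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rep.pearson_r)

    def test_loa_from_constructed_sd(self):
        # differences engineered to have sample SD exactly 140.8
        d = np.array([-1.0, 0.0, 1.0])
        d = d / d.std(ddof=1) * 140.8
        rep = ev.bland_altman(d + 1000.0, np.full(3, 1000.0))
        assert rep.sd_diff == pytest.approx(140.8)
        assert rep.loa_half_width == pytest.approx(276.0, abs=0.05)

    def test_two_pass_oracle_and_missing_pairs(self):
        rng = np.random.default_rng(3)
        x = rng.normal(900, 200, 40)
        y = x + rng.normal(-20, 80, 40)
        x[5] = np.nan
        rep = ev.bland_altman(x, y)
        keep = np.isfinite(x)
        d = x[keep] - y[keep]
        assert rep.n == 39
        assert rep.mean_diff == pytest.approx(d.mean(), rel=1e-12)
        assert rep.sd_diff == pytest.approx(d.std(ddof=1), rel=1e-12)
        assert rep.loa_half_width == pytest.approx(1.96 * d.std(ddof=1), rel=1e-12)

    @given(scale=st.floats(0.1, 50.0))
    def test_loa_scales_linearly(self, scale):
        x = np.array([800.0, 950.0, 1100.0, 1240.0])
        y = np.array([760.0, 990.0, 1050.0, 1300.0])
        r1 = ev.bland_altman(x, y)
        r2 = ev.bland_altman(scale * x, scale * y)
        assert r2.loa_half_width == pytest.approx(scale * r1.loa_half_width,
                                                  rel=1e-9)


def williams_oracle(r12, r13, r23, n):
    """Independent re-derivation of the dependent-correlations t."""
    detR = (1 - r12**2 - r13**2 - r23**2) + 2 * r12 * r13 * r23
    rbar = 0.5 * (r12 + r13)
    num = (r12 - r13) * math.sqrt((n - 1) * (1 + r23))
    den = math.sqrt(2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3)
    return num / den


class TestWilliams:
    def test_equal_correlations_give_t_zero_p_one(self):
        out = ev.williams_test(0.8, 0.8, 0.5, 50)
        assert out["t"] == 0.0 and out["p"] == pytest.approx(1.0)

    def test_antisymmetric_in_the_compared_pair(self):
        a = ev.williams_test(0.9, 0.7, 0.6, 40)
        b = ev.williams_test(0.7, 0.9, 0.6, 40)
        assert b["t"] == pytest.approx(-a["t"], rel=1e-12)
        assert b["p"] == pytest.approx(a["p"], rel=1e-12)

    def test_matches_independent_formula_on_random_psd_triplets(self):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 30:
            m = rng.normal(size=(60, 3))
            c = np.corrcoef(m.T)  # empirical matrices are PSD by construction
            r12, r13, r23 = c[0, 1], c[0, 2], c[1, 2]
            out = ev.williams_test(r12, r13, r23, 60)
            assert out["t"] == pytest.approx(
                williams_oracle(r12, r13, r23, 60), rel=1e-10)
            assert out["df"] == 57
            checked += 1

    def test_rejects_non_psd_triplet(self):
        with pytest.raises(ev.DomainError):
            ev.williams_test(0.9, 0.9, -0.9, 30)


class TestCorrelationMatrix:
    def test_self_and_proportional_columns(self):
        x = [1.0, 2.0, 3.0, 4.0]
        m = ev.correlation_matrix({"a": x, "b": [2 * v for v in x]})
        assert m.loc["a", "a"][0] == pytest.approx(1.0)
        assert m.loc["a", "b"][0] == pytest.approx(1.0)
        assert m.loc["a", "b"][1] == 4

    def test_pairwise_complete_against_direct_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=30)
        b = a + rng.normal(0, 0.5, 30)
        c = rng.normal(size=30)
        b[3] = np.nan
        m = ev.correlation_matrix({"a": a, "b": b, "c": c})
        keep = np.isfinite(b)
        r_oracle = np.corrcoef(a[keep], b[keep])[0, 1]
        r, n = m.loc["a", "b"]
        assert n == 29
        assert r == pytest.approx(r_oracle, rel=1e-12)

    def test_short_pair_flagged_missing(self):
        m = ev.correlation_matrix({"a": [1, 2, np.nan, np.nan],
                                   "b": [1, np.nan, 2, 3]})
        r, n = m.loc["a", "b"]
        assert n < 3 and math.isnan(r)
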