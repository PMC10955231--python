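"""NCA, Guest criteria, GMFE, success bounds, dose linearity, VPC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dabepbpk import errors, metrics


class TestNCA:
    def test_single_exponential_auc(self):
        t = np.linspace(0, 72, 400)
        c = 100.0 * np.exp(-0.1 * t)
        m = metrics.nca(t, c)
        assert m.auc_0_inf == pytest.approx(1000.0, rel=5e-3)
        assert m.cmax == pytest.approx(100.0)
        assert m.lambda_z == pytest.approx(0.1, rel=1e-3)

    def test_all_zero_profile_flagged(self):
        m = metrics.nca([0, 1, 2, 3], [0, 0, 0, 0])
        assert m.auc_0_inf == 0.0
        assert m.flags

    def test_linearity_in_concentration(self):
        t = np.linspace(0, 24, 100)
        c = 50 * t * np.exp(-0.5 * t)
        m1 = metrics.nca(t, c)
        m2 = metrics.nca(t, 2 * c)
        assert m2.cmax == pytest.approx(2 * m1.cmax)
        assert m2.auc_0_inf == pytest.approx(2 * m1.auc_0_inf)

    def test_grid_refinement_converges_to_integral(self):
        # biexponential absorption curve (log-down trapezoids are not exact
        # on the rising limb, so refinement must reduce the error)
        def profile(t):
            return 100.0 * (np.exp(-0.1 * t) - np.exp(-1.0 * t))

        analytic = 100.0 * (1 / 0.1 - 1 / 1.0)
        t1, t2 = np.linspace(0, 96, 25), np.linspace(0, 96, 2000)
        coarse = metrics.nca(t1, profile(t1))
        fine = metrics.nca(t2, profile(t2))
        assert abs(fine.auc_0_inf - analytic) < abs(coarse.auc_0_inf - analytic)
        assert fine.auc_0_inf == pytest.approx(analytic, rel=1e-4)


class TestGuestLimits:
    @pytest.mark.parametrize("robs, lo, hi", [
        (4.57, 2.57, 8.14),
        (1.97, 1.32, 2.94),
    ])
    def test_printed_windows(self, robs, lo, hi):
        g = metrics.guest_limits(robs)
        assert round(g.lower, 2) == lo
        assert round(g.upper, 2) == hi

    def test_unity_collapses(self):
        g = metrics.guest_limits(1.0)
        assert g.lower == pytest.approx(1.0)
        assert g.upper == pytest.approx(1.0)

    def test_reciprocal_mapping_below_one(self):
        g = metrics.guest_limits(0.5)
        h = metrics.guest_limits(2.0)
        assert g.lower == pytest.approx(1 / h.upper)
        assert g.upper == pytest.approx(1 / h.lower)

    @settings(derandomize=True, max_examples=50)
    @given(robs=st.floats(1.01, 50.0))
    def test_log_symmetry_and_twofold_limit(self, robs):
        g = metrics.guest_limits(robs)
        assert g.lower * g.upper == pytest.approx(robs**2, rel=1e-9)
        assert g.upper <= 2.0 * robs + 1e-9  # approaches twofold from below


class TestGMFE:
    def test_identity(self):
        assert metrics.gmfe([(2.0, 2.0), (5.0, 5.0)]).value \
            == pytest.approx(1.0)

    def test_signed_reciprocal_under_swap(self):
        pairs = [(1.0, 2.0), (3.0, 1.5), (4.0, 6.0)]
        fwd = metrics.gmfe(pairs).value
        rev = metrics.gmfe([(s, o) for o, s in pairs]).value
        assert fwd * rev == pytest.approx(1.0)

    def test_absolute_variant_at_least_one(self):
        pairs = [(1.0, 0.5), (1.0, 2.0)]
        assert metrics.gmfe(pairs).value == pytest.approx(1.0)
        assert metrics.gmfe(pairs, signed=False).value == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(errors.InvalidDataError):
            metrics.gmfe([(0.0, 1.0)])


class TestSuccessBounds:
    def test_cv_zero_collapses_to_mean(self):
        lo, hi = metrics.success_bounds(145.0, 0.0, 10)
        assert lo == hi == 145.0

    def test_training_set_window(self):
        # arithmetic mean 145 +- 45 (cv 31%), n = 10 inferred from the
        # printed window
        lo, hi = metrics.success_bounds(145.0, 31.03, 10)
        assert round(lo) == 96
        assert round(hi) == 218

    def test_twofold_fallback(self):
        lo, hi = metrics.success_bounds(0.17, None, None)
        assert lo == pytest.approx(0.085)
        assert hi == pytest.approx(0.34)


class TestDoseLinearity:
    def test_perfectly_linear(self):
        out = metrics.dose_linearity([1, 10, 100], [5, 50, 500], 100)
        assert np.allclose(out["ratio"], 1.0)

    def test_subproportional_deviation_factor(self):
        out = metrics.dose_linearity([0.375, 300], [1.44, 2377], 300)
        idx = list(out["doses"]).index(0.375)
        assert out["deviation_factor"][idx] > 2.0


class TestVPC:
    def test_median_observations_fully_covered(self):
        t = np.linspace(0, 10, 20)
        med = np.exp(-0.3 * t)
        out = metrics.vpc_coverage(t, med, t, med * 0.5, med * 2.0)
        assert out["coverage"] == 1.0
        assert not out["excursions"]

    def test_far_outside_zero(self):
        t = np.linspace(0, 10, 20)
        med = np.exp(-0.3 * t)
        out = metrics.vpc_coverage(t, med * 100, t, med * 0.5, med * 2.0)
        assert out["coverage"] == 0.0

    def test_self_drawn_observations_cover_about_90_percent(self):
        # observations drawn from the same log-normal population as the
        # band: coverage should sit near the nominal 90% within binomial
        # error
        rng = np.random.default_rng(42)
        t = np.linspace(0, 10, 50)
        sigma = 0.4
        med = 10 * np.exp(-0.2 * t)
        lo = med * np.exp(sigma * -1.6449)
        hi = med * np.exp(sigma * 1.6449)
        obs = med * np.exp(sigma * rng.standard_normal(t.size))
        out = metrics.vpc_coverage(t, obs, t, lo, hi)
        assert out["coverage"] == pytest.approx(0.90, abs=0.08)
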