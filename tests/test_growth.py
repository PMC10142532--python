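import numpy as np
import pandas as pd
import pytest

from ensuq.growth import (
    cumulative_curve,
    fit_saturation,
    michaelis_menten,
    permutation_median_curve,
    summarize_saturation,
)
from ensuq.metrics import r_squared
from ensuq.synthetic import make_curve, make_member_matrix


@pytest.fixture
def small_mpm():
    return make_member_matrix(n=80, M=12, tau=(0.2, 1.0), seed=3)


class TestCumulativeCurve:
    def test_size_one_equals_first_member_r2(self, small_mpm):
        mpm, y, _ = small_mpm
        curve = cumulative_curve(mpm, y, metric="r2")
        assert curve.sizes[0] == 1
        assert curve.values[0] == pytest.approx(r_squared(y, mpm.values[:, 0]))

    def test_rho_curve_starts_at_two(self, small_mpm):
        mpm, y, _ = small_mpm
        curve = cumulative_curve(mpm, y, metric="rho")
        assert curve.sizes[0] == 2
        assert len(curve.sizes) == mpm.n_members - 1

    def test_full_size_value_permutation_invariant(self, small_mpm):
        mpm, y, _ = small_mpm
        rng = np.random.default_rng(0)
        base = cumulative_curve(mpm, y, metric="r2").values[-1]
        for _ in range(3):
            perm = rng.permutation(mpm.n_members)
            assert cumulative_curve(mpm, y, metric="r2", order=perm).values[-1] == pytest.approx(
                base, abs=1e-10
            )

    def test_identical_members_flat_r2_undefined_rho(self):
        mpm, y, _ = make_member_matrix(n=50, M=6, tau=1e-12, seed=0)
        mpm.values[:] = mpm.values[:, [0]]  # exactly identical columns
        r2c = cumulative_curve(mpm, y, metric="r2")
        assert np.ptp(r2c.values) == pytest.approx(0.0, abs=1e-12)
        rhoc = cumulative_curve(mpm, y, metric="rho")
        assert np.all(np.isnan(rhoc.values))  # zero spread everywhere

    def test_invalid_order_rejected(self, small_mpm):
        mpm, y, _ = small_mpm
        with pytest.raises(ValueError, match="permutation"):
            cumulative_curve(mpm, y, order=np.zeros(mpm.n_members, dtype=int))


class TestPermutationMedianCurve:
    def test_single_permutation_equals_that_shuffle(self, small_mpm):
        mpm, y, _ = small_mpm
        med = permutation_median_curve(mpm, y, metric="r2", n_permutations=1, seed=7)
        order = np.random.default_rng(7).permutation(mpm.n_members)
        raw = cumulative_curve(mpm, y, metric="r2", order=order)
        np.testing.assert_allclose(med.values, raw.values)

    def test_last_point_equals_full_ensemble_metric(self, small_mpm):
        mpm, y, _ = small_mpm
        full = cumulative_curve(mpm, y, metric="r2").values[-1]
        for seed in (0, 1, 2):
            med = permutation_median_curve(mpm, y, metric="r2", n_permutations=5, seed=seed)
            assert med.values[-1] == pytest.approx(full, abs=1e-10)

    def test_exchangeable_constant_spread_gives_flat_rho_curve(self):
        # i.i.d. member columns with a constant spread: uncertainties carry
        # no rank signal, so the median UQ curve stays near 0 at every size
        mpm, y, _ = make_member_matrix(n=400, M=12, tau=0.3, seed=5)
        med = permutation_median_curve(mpm, y, metric="rho", n_permutations=50, seed=0)
        assert np.nanmax(np.abs(med.values)) < 0.05

    def test_reproducible_given_seed(self, small_mpm):
        mpm, y, _ = small_mpm
        a = permutation_median_curve(mpm, y, n_permutations=8, seed=11)
        b = permutation_median_curve(mpm, y, n_permutations=8, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_mean_center_available(self, small_mpm):
        mpm, y, _ = small_mpm
        mean_c = permutation_median_curve(mpm, y, n_permutations=8, seed=0, center="mean")
        med_c = permutation_median_curve(mpm, y, n_permutations=8, seed=0, center="median")
        assert mean_c.values.shape == med_c.values.shape


class TestFitSaturation:
    def test_noiseless_parameter_recovery_and_m_star(self):
        curve = make_curve(a=0.5, b=0.3, c=5.0, M=200)
        fit = fit_saturation(curve)
        assert fit.a == pytest.approx(0.5, abs=1e-6)
        assert fit.b == pytest.approx(0.3, abs=1e-6)
        assert fit.c == pytest.approx(5.0, abs=1e-5)
        assert fit.m_star == 117  # first step gain b*c/((c+m)(c+m+1)) < 1e-4
        assert fit.flag == "ok"

    def test_constant_curve_flagged_flat(self):
        curve = make_curve(a=0.7, b=0.0, c=5.0, M=50)
        fit = fit_saturation(curve)
        assert fit.flag == "flat"
        assert fit.m_star == 1

    def test_decreasing_curve_flagged_no_size(self):
        curve = make_curve(a=0.8, b=-0.3, c=10.0, M=50)
        fit = fit_saturation(curve)
        assert fit.flag == "decreasing"
        assert fit.m_star is None

    def test_too_few_points_rejected(self):
        curve = make_curve(a=0.5, b=0.3, c=5.0, M=4)
        curve.values[1:] = np.nan
        with pytest.raises(ValueError, match="4 finite"):
            fit_saturation(curve)

    def test_step_gains_strictly_decreasing(self):
        a, b, c = 0.4, 0.5, 8.0
        m = np.arange(1, 100, dtype=float)
        gains = michaelis_menten(m + 1, a, b, c) - michaelis_menten(m, a, b, c)
        assert np.all(np.diff(gains) < 0)

    def test_parameter_bias_shrinks_with_noise(self):
        errs = []
        for sigma in (0.02, 0.002):
            recovered = []
            for seed in range(10):
                fit = fit_saturation(make_curve(0.5, 0.3, 5.0, M=100, sigma=sigma, seed=seed))
                recovered.append([fit.a, fit.b, fit.c])
            errs.append(np.abs(np.mean(recovered, axis=0) - [0.5, 0.3, 5.0]).sum())
        assert errs[1] < errs[0]


class TestSummarize:
    def make_fits(self, rows):
        return pd.DataFrame(rows, columns=["combination", "m_star"])

    def test_single_fit_is_its_own_median(self):
        out = summarize_saturation(self.make_fits([("a", 42)]))
        assert out.loc[0, "median_m_star"] == 42

    def test_odd_group_median(self):
        out = summarize_saturation(self.make_fits([("a", 10), ("a", 20), ("a", 30)]))
        assert out.loc[0, "median_m_star"] == 20

    def test_even_group_half_integer_median(self):
        out = summarize_saturation(self.make_fits([("a", 10), ("a", 20)]))
        assert out.loc[0, "median_m_star"] == 15.0

    def test_undetected_excluded_with_counts(self):
        out = summarize_saturation(self.make_fits([("a", 10), ("a", None), ("b", None)]))
        a = out[out["combination"] == "a"].iloc[0]
        assert (a["median_m_star"], a["n_detected"], a["n_excluded"]) == (10.0, 1, 1)
        b = out[out["combination"] == "b"].iloc[0]
        assert np.isnan(b["median_m_star"]) and b["n_excluded"] == 1
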