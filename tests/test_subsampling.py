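import numpy as np
import pytest

from ensuq.adapters import RegressorSpec
from ensuq.subsampling import (
    MemberPredictionMatrix,
    filter_outlier_predictions,
    make_split_plan,
    run_members,
)


class TestSplitPlan:
    def test_balanced_two_folds(self):
        plan = make_split_plan(10, k=2, n_repetitions=1, seed=0)
        counts = np.bincount(plan.fold_assignments[0], minlength=2)
        assert sorted(counts) == [5, 5]

    def test_odd_n_fold_sizes_differ_by_one(self):
        plan = make_split_plan(11, k=2, n_repetitions=3, seed=0)
        for m in range(3):
            counts = np.bincount(plan.fold_assignments[m], minlength=2)
            assert sorted(counts) == [5, 6]

    def test_each_compound_in_exactly_one_fold(self):
        plan = make_split_plan(37, k=5, n_repetitions=4, seed=1)
        assert plan.fold_assignments.shape == (4, 37)
        assert np.all((plan.fold_assignments >= 0) & (plan.fold_assignments < 5))

    def test_same_seed_identical_plans(self):
        a = make_split_plan(20, k=2, n_repetitions=5, seed=9)
        b = make_split_plan(20, k=2, n_repetitions=5, seed=9)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)

    def test_n_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            make_split_plan(3, k=5, n_repetitions=1)

    def test_planned_fit_count(self):
        assert make_split_plan(50, k=2, n_repetitions=200, seed=0).n_fits == 400
        assert make_split_plan(50, scheme="bootstrap", n_repetitions=7, seed=0).n_fits == 7

    def test_bootstrap_oob_fraction_near_inverse_e(self):
        plan = make_split_plan(500, scheme="bootstrap", n_repetitions=50, seed=2)
        oob = [
            500 - np.unique(plan.bags[m]).size for m in range(plan.n_repetitions)
        ]
        assert np.mean(oob) / 500 == pytest.approx(1.0 / np.e, abs=0.02)


class TestRunMembers:
    @pytest.fixture
    def linear_data(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        return X, y

    def test_fit_count_is_m_times_k(self, linear_data):
        X, y = linear_data
        plan = make_split_plan(40, k=2, n_repetitions=3, seed=0)
        calls = []
        run_members(X, y, RegressorSpec("mean"), plan, fit_callback=lambda m, f: calls.append((m, f)))
        assert len(calls) == 6
        assert sorted(calls) == [(m, f) for m in range(3) for f in range(2)]

    def test_every_compound_predicted_once_per_repetition(self, linear_data):
        X, y = linear_data
        plan = make_split_plan(40, k=2, n_repetitions=4, seed=0)
        mpm = run_members(X, y, RegressorSpec("mean"), plan)
        assert np.all(np.isfinite(mpm.values))
        np.testing.assert_array_equal(mpm.retained_counts(), 4)

    def test_noiseless_linear_data_memorizing_learner(self, linear_data):
        X, y = linear_data
        plan = make_split_plan(40, k=2, n_repetitions=1, seed=0)
        mpm = run_members(X, y, RegressorSpec("linreg"), plan)
        np.testing.assert_allclose(mpm.values[:, 0], y, atol=1e-8)

    def test_reruns_bitwise_identical(self, linear_data):
        X, y = linear_data
        plan = make_split_plan(40, k=2, n_repetitions=2, seed=5)
        spec = RegressorSpec("rf", {"n_estimators": 5})
        a = run_members(X, y, spec, plan)
        b = run_members(X, y, spec, plan)
        np.testing.assert_array_equal(a.values, b.values)

    def test_bootstrap_masks_in_bag_entries(self, linear_data):
        X, y = linear_data
        plan = make_split_plan(40, scheme="bootstrap", n_repetitions=5, seed=1)
        mpm = run_members(X, y, RegressorSpec("mean"), plan)
        for m in range(5):
            in_bag = np.unique(plan.bags[m])
            assert not np.any(mpm.mask[in_bag, m])
            oob = np.setdiff1d(np.arange(40), in_bag)
            assert np.all(mpm.mask[oob, m])

    def test_continue_on_error_records_and_masks(self, linear_data):
        X, y = linear_data
        # constant-y SVR is fine, but an unknown custom factory raising is what we emulate
        from ensuq.adapters import register_technique

        def boom(hp, seed):
            raise RuntimeError("synthetic failure")

        register_technique("boom", boom)
        plan = make_split_plan(40, k=2, n_repetitions=2, seed=0)
        with pytest.raises(RuntimeError, match="repetition 0, fold 0"):
            run_members(X, y, RegressorSpec("boom"), plan)
        mpm = run_members(X, y, RegressorSpec("boom"), plan, continue_on_error=True)
        assert len(mpm.errors) == 4
        assert not mpm.mask.any()


class TestOutlierFilter:
    def make_mpm(self, values, y_min, y_max):
        values = np.asarray(values, dtype=float).reshape(-1, 1)
        n = values.shape[0]
        return MemberPredictionMatrix(
            values=values,
            mask=np.isfinite(values),
            train_ranges=np.array([[[y_min, y_max]]]),
            scheme="kfold",
            fold_of=np.zeros((1, n), dtype=int),
        )

    def test_doubled_range_interval(self):
        # training range [0, 10] -> acceptance interval [-5, 15]
        mpm = self.make_mpm([16.0, 15.0, -5.0, -5.1, 7.0], 0.0, 10.0)
        out = filter_outlier_predictions(mpm)
        np.testing.assert_array_equal(out.mask[:, 0], [False, True, True, False, True])

    def test_boundary_retained_closed_interval(self):
        out = filter_outlier_predictions(self.make_mpm([15.0], 0.0, 10.0))
        assert out.mask[0, 0]

    def test_degenerate_constant_range(self):
        out = filter_outlier_predictions(self.make_mpm([3.0, 3.0001], 3.0, 3.0))
        np.testing.assert_array_equal(out.mask[:, 0], [True, False])

    def test_mask_monotone_never_unmasks(self):
        mpm = self.make_mpm([7.0, 8.0], 0.0, 10.0)
        mpm.mask[0, 0] = False
        out = filter_outlier_predictions(mpm)
        assert not out.mask[0, 0]

    def test_fully_masked_compound_flagged(self):
        out = filter_outlier_predictions(self.make_mpm([100.0], 0.0, 10.0))
        assert any(e[0] == "all_members_masked" for e in out.errors)


def test_member_matrix_csv_roundtrip(tmp_path, rng):
    values = rng.normal(size=(6, 3))
    mpm = MemberPredictionMatrix(
        values=values,
        mask=np.ones((6, 3), dtype=bool),
        train_ranges=np.zeros((3, 2, 2)),
        scheme="kfold",
        fold_of=np.zeros((3, 6), dtype=int),
    )
    path = tmp_path / "members.csv"
    mpm.write(path)
    back = MemberPredictionMatrix.read(path)
    np.testing.assert_array_equal(back.values, mpm.values)
    np.testing.assert_array_equal(back.mask, mpm.mask)
    assert back.scheme == "kfold"
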