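"""Scaler gating, transformer round-trips, feature filtering, stability
selection."""

import numpy as np
import pandas as pd
import pytest

from ganbalance.preprocessing import (POWER, ROBUST, FittedTransformer,
                                      choose_feature_transforms,
                                      filter_top_features, fit_transformer,
                                      stability_select)
from ganbalance.simulate import LabeledMatrix


def _dagostino_skew_z(x):
    """Independent implementation of the D'Agostino skewness normality test
    statistic (transformed sample skewness)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m2 = ((x - x.mean()) ** 2).mean()
    m3 = ((x - x.mean()) ** 3).mean()
    b1 = m3 / m2 ** 1.5
    y = b1 * np.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n ** 2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9))
    w2 = -1 + np.sqrt(2 * (beta2 - 1))
    delta = 1 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1))
    y = np.where(y == 0, 1, y)
    return delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1))


class TestScalerGating:
    def test_symmetric_feature_gets_robust_scaler(self):
        col = np.tile([-2.0, -1.0, 0.0, 1.0, 2.0], 10)
        plan = choose_feature_transforms(col[:, None])
        assert plan.assignments == [ROBUST]
        assert plan.p_values[0] > 0.05

    def test_right_skewed_feature_gets_power_transform(self):
        rng = np.random.default_rng(0)
        col = rng.exponential(size=500)
        plan = choose_feature_transforms(col[:, None])
        assert plan.assignments == [POWER]
        # p-value agrees with the independently computed test statistic
        from scipy.stats import norm
        z = _dagostino_skew_z(col)
        p_oracle = 2 * norm.sf(abs(z))
        assert plan.p_values[0] == pytest.approx(p_oracle, rel=1e-6)

    def test_alpha_zero_disables_power_transform(self):
        rng = np.random.default_rng(1)
        X = rng.exponential(size=(200, 5))
        plan = choose_feature_transforms(X, alpha=0.0)
        assert all(a == ROBUST for a in plan.assignments)

    def test_constant_feature_flagged_not_dropped(self):
        X = np.column_stack([np.ones(50), np.random.default_rng(2).normal(size=50)])
        with pytest.warns(UserWarning, match="constant"):
            plan = choose_feature_transforms(X)
        assert plan.constant_features == [0]
        assert plan.assignments[0] == ROBUST

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            choose_feature_transforms(np.zeros((7, 2)))

    def test_plan_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 6)) ** 2
        a = choose_feature_transforms(X)
        b = choose_feature_transforms(X)
        assert a.assignments == b.assignments
        np.testing.assert_array_equal(a.p_values, b.p_values)


class TestFittedTransformer:
    def test_robust_scaling_formula(self):
        # feature with median 5 and IQR 2 maps to (x - 5) / 2
        x = np.array([3.0, 4.0, 5.0, 6.0, 7.0] * 4)[:, None]
        plan = choose_feature_transforms(np.tile(x, (1, 1)))
        t = fit_transformer(x, plan)
        np.testing.assert_allclose(t.transform(x), (x - 5.0) / 2.0)

    def test_yeo_johnson_lambda_near_one_on_normal_data(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10.0, 2.0, size=(2000, 1))
        from ganbalance.preprocessing import ScalerPlan
        plan = ScalerPlan([POWER], np.array([0.0]))
        t = FittedTransformer(plan).fit(x)
        pt, _ = t._groups[POWER][1]
        assert pt.lambdas_[0] == pytest.approx(1.0, abs=0.15)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.exponential(size=300),
                             rng.normal(size=300),
                             rng.gamma(2.0, 0.5, size=300)])
        plan = choose_feature_transforms(X)
        t = fit_transformer(X, plan)
        back = t.inverse_transform(t.transform(X))
        np.testing.assert_allclose(back, X, rtol=1e-8, atol=1e-8)

    def test_subsampled_fit_uses_requested_rows(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 3))
        plan = choose_feature_transforms(X)
        t1 = fit_transformer(X, plan, n_fit_samples=200,
                             rng=np.random.default_rng(1))
        t2 = fit_transformer(X, plan, n_fit_samples=200,
                             rng=np.random.default_rng(1))
        assert t1.fingerprint == t2.fingerprint
        with pytest.raises(ValueError):
            fit_transformer(X, plan, n_fit_samples=301)

    def test_zero_iqr_warns_and_stays_finite(self):
        X = np.column_stack([np.r_[np.zeros(48), 1.0, 2.0],
                             np.random.default_rng(7).normal(size=50)])
        plan = choose_feature_transforms(X)
        if plan.assignments[0] != ROBUST:  # ensure the robust path is hit
            plan.assignments[0] = ROBUST
        with pytest.warns(UserWarning, match="zero IQR"):
            t = fit_transformer(X, plan)
        assert np.isfinite(t.transform(X)).all()

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([rng.exponential(size=200), rng.normal(size=200)])
        plan = choose_feature_transforms(X)
        t = fit_transformer(X, plan)
        back = FittedTransformer.from_dict(t.to_dict())
        np.testing.assert_allclose(back.transform(X), t.transform(X))
        np.testing.assert_allclose(back.inverse_transform(t.transform(X)), X,
                                   rtol=1e-8, atol=1e-8)

    def test_out_of_domain_inverse_stays_finite(self):
        # generated values can land outside the Yeo-Johnson image; the
        # inverse must clip into the domain rather than produce NaN
        rng = np.random.default_rng(9)
        X = rng.exponential(size=(300, 1))
        plan = choose_feature_transforms(X)
        t = fit_transformer(X, plan)
        wild = np.array([[-50.0], [50.0], [0.0]])
        out = t.inverse_transform(wild)
        assert np.isfinite(out).all()


class TestFilterTopFeatures:
    def _table(self):
        return pd.DataFrame({
            "feature": [f"g{i}" for i in range(10)],
            "adj_p": [0.001, 0.002, 0.003, 0.004, 0.005,
                      0.1, 0.2, 0.3, 0.4, 0.5]})

    def test_takes_k_most_significant(self):
        got = filter_top_features(self._table(), 5)
        assert got == ["g0", "g1", "g2", "g3", "g4"]

    def test_missingness_removes_after_selection(self):
        got = filter_top_features(self._table(), 5, missing_features={"g1", "g3"})
        assert got == ["g0", "g2", "g4"]

    def test_k_larger_than_table_warns_and_takes_all(self):
        with pytest.warns(UserWarning, match="taking all"):
            got = filter_top_features(self._table(), 99)
        assert len(got) == 10

    def test_ties_break_by_feature_name(self):
        table = pd.DataFrame({"feature": ["b", "a", "c"],
                              "adj_p": [0.01, 0.01, 0.01]})
        assert filter_top_features(table, 2) == ["a", "b"]


class TestStabilitySelection:
    def _signal_matrix(self, n=160, p=30, informative=4, effect=2.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = np.repeat([0, 1], n // 2)
        X[:, :informative] += effect * y[:, None]
        names = [f"f{i:02d}" for i in range(p)]
        return LabeledMatrix(X, y, names), names[:informative]

    def test_recovers_planted_signal_features(self):
        matrix, truth = self._signal_matrix()
        result = stability_select(matrix, n_iterations=4, inner_folds=5, seed=1)
        assert set(truth) <= set(result.selected)

    def test_selection_bounded_by_top_fraction_arithmetic(self):
        matrix, _ = self._signal_matrix(n=80, p=8, informative=2, seed=2)
        result = stability_select(matrix, n_iterations=2, inner_folds=4,
                                  top_fraction=0.25, seed=3)
        # ceil(8 * 0.25) = 2 per ranking, so at most 2 survive the intersection
        assert len(result.selected) <= 2

    def test_column_order_invariance(self):
        matrix, _ = self._signal_matrix(n=100, p=10, informative=2, seed=4)
        perm = np.random.default_rng(0).permutation(10)
        shuffled = LabeledMatrix(matrix.values[:, perm], matrix.labels,
                                 [matrix.feature_names[j] for j in perm])
        a = stability_select(matrix, n_iterations=2, inner_folds=4, seed=5)
        b = stability_select(shuffled, n_iterations=2, inner_folds=4, seed=5)
        assert set(a.selected) == set(b.selected)

    def test_single_class_rejected(self):
        m = LabeledMatrix(np.random.default_rng(1).normal(size=(40, 5)),
                          np.zeros(40, dtype=int))
        with pytest.raises(ValueError):
            stability_select(m)
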