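"""Gaussian-kernel SVR and data-based sensitivity-analysis importance."""

import numpy as np
import pytest

from actimem.activities import BASELINE_MEMORY, EDUCATION
from actimem.importance import (SensitivityImportance,
                                combined_activity_importance,
                                importance_distribution, sa_importance)
from actimem.svr import GaussianKernelSVR, SvrGridSpec, holdout_r2
from actimem.types import AgeGroup, AnalysisTable, ImportanceDistribution, RunConfig


class TestGaussianKernelSVR:
    def test_noiseless_linear_high_holdout_r2(self, rng):
        X = rng.standard_normal((300, 4))
        y = 2 * X[:, 0] + X[:, 1]
        mean_r2, vals = holdout_r2(X, y, repeats=10, seed=0)
        assert mean_r2 >= 0.95
        assert vals.shape == (10,)

    def test_seeded_width_selection_deterministic(self, rng):
        X = rng.standard_normal((100, 3))
        y = X[:, 0] + 0.3 * rng.standard_normal(100)
        m1 = GaussianKernelSVR(random_state=5).fit(X, y)
        m2 = GaussianKernelSVR(random_state=5).fit(X, y)
        assert m1.width_ == m2.width_
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_default_grid_has_ten_widths(self, rng):
        X = rng.standard_normal((50, 2))
        m = GaussianKernelSVR(random_state=0).fit(X, X[:, 0] + X[:, 1])
        assert m.widths_.shape == (10,)
        assert np.all(np.diff(m.widths_) > 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SvrGridSpec(n_widths=0)
        with pytest.raises(ValueError):
            GaussianKernelSVR(n_widths=0).fit(np.zeros((20, 2)), np.arange(20.0))

    def test_constant_target_raises(self, rng):
        X = rng.standard_normal((30, 2))
        with pytest.raises(ValueError):
            GaussianKernelSVR().fit(X, np.ones(30))

    def test_predict_matches_libsvm_decision_function(self, rng):
        X = rng.standard_normal((80, 3))
        y = X[:, 0] ** 2 + rng.standard_normal(80)
        m = GaussianKernelSVR(random_state=1).fit(X, y)
        Xn = rng.standard_normal((40, 3))
        ref = m.svr_.predict((Xn - m.mean_) / m.scale_)
        assert np.allclose(m.predict(Xn), ref, atol=1e-10)

    def test_null_target_r2_near_zero(self, rng):
        X = rng.standard_normal((200, 5))
        y = rng.standard_normal(200)
        mean_r2, _ = holdout_r2(X, y, repeats=10, seed=2)
        assert abs(mean_r2) <= 0.15 and mean_r2 <= 0.05


class _Analytic:
    """Stand-in model with a known prediction function."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        return self.fn(np.asarray(X))


class TestSaImportance:
    def test_ignored_feature_gets_zero(self, rng):
        X = rng.standard_normal((60, 3))
        r = sa_importance(_Analytic(lambda X: X[:, 0] + 0.5 * X[:, 1]), X, L=7)
        assert r[2] == 0.0
        assert r.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_active_feature_takes_all(self, rng):
        X = rng.standard_normal((60, 4))
        r = sa_importance(_Analytic(lambda X: X[:, 0]), X, L=5)
        assert r == pytest.approx([1.0, 0, 0, 0], abs=1e-12)

    def test_symmetric_model_splits_evenly(self, rng):
        X = rng.standard_normal((100, 2))
        X[:, 1] = rng.permutation(X[:, 0])  # identical probe grids
        r = sa_importance(_Analytic(lambda X: X[:, 0] + X[:, 1]), X, L=7)
        assert r[0] == pytest.approx(0.5, abs=1e-6)
        assert r[1] == pytest.approx(0.5, abs=1e-6)

    def test_ordinal_feature_probed_on_its_categories(self, rng):
        # a 4-category ordinal column: probe levels are exactly its codes,
        # so a model reacting only to a missing 5th level sees no dispersion
        X = np.column_stack([rng.integers(0, 4, 50), rng.standard_normal(50)])
        r = sa_importance(_Analytic(lambda X: (X[:, 0] == 4.0) * 1.0 + X[:, 1]),
                          X.astype(float), L=7)
        assert r[0] == 0.0

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((80, 3))
        fn = lambda Z: Z[:, 0] + 0.5 * Z[:, 1] ** 2 + 0.2 * Z[:, 2]
        r = sa_importance(_Analytic(fn), X, L=6)
        perm = [2, 0, 1]
        fn_p = lambda Z: fn(Z[:, np.argsort(perm)])
        r_p = sa_importance(_Analytic(fn_p), X[:, perm], L=6)
        assert r_p == pytest.approx(r[perm], abs=1e-10)

    def test_constant_model_flagged_degenerate(self, rng):
        X = rng.standard_normal((30, 2))
        with pytest.raises(ValueError, match="degenerate"):
            sa_importance(_Analytic(lambda X: np.zeros(len(X))), X)

    def test_range_measure_supported(self, rng):
        X = rng.standard_normal((40, 2))
        r = sa_importance(_Analytic(lambda X: X[:, 0]), X, L=5, measure="range")
        assert r == pytest.approx([1.0, 0.0], abs=1e-12)


class TestSensitivityImportance:
    def test_output_shape_rows_sum_to_one(self, rng):
        X = rng.standard_normal((80, 4))
        y = X[:, 0] + 0.5 * rng.standard_normal(80)
        est = SensitivityImportance(n_repeats=8, random_state=0).fit(X, y)
        assert est.importances_.shape == (8, 4)
        assert np.allclose(est.importances_.sum(axis=1), 1.0, atol=1e-9)
        assert (est.importances_ >= 0).all()

    def test_dominant_feature_recovered(self, rng):
        X = rng.standard_normal((150, 5))
        y = 2.0 * X[:, 3] + 0.3 * X[:, 0] + 0.3 * rng.standard_normal(150)
        est = SensitivityImportance(n_repeats=10, random_state=1).fit(X, y)
        assert np.argmax(est.importances_mean_) == 3

    def test_affine_rescaling_of_input_column_invariant(self, rng):
        X = rng.standard_normal((120, 3))
        y = X[:, 0] + 0.5 * X[:, 1] + 0.2 * rng.standard_normal(120)
        a = SensitivityImportance(n_repeats=6, random_state=2).fit(X, y)
        X2 = X.copy()
        X2[:, 1] = 10.0 * X2[:, 1] - 7.0
        b = SensitivityImportance(n_repeats=6, random_state=2).fit(X2, y)
        assert b.importances_mean_ == pytest.approx(a.importances_mean_, abs=5e-2)

    def test_too_small_subsample_raises(self, rng):
        X = rng.standard_normal((11, 2))
        with pytest.raises(ValueError):
            SensitivityImportance(subsample_fraction=0.5).fit(X, X[:, 0])


class TestImportanceDistribution:
    def _table(self, rng, n=80):
        X = np.column_stack([rng.integers(0, 7, n), rng.integers(0, 6, n),
                             rng.integers(8, 21, n), rng.binomial(20, 0.5, n)])
        z = (X - X.mean(0)) / X.std(0)
        y = np.clip(np.rint(1.5 * z[:, 0] + 0.5 * z[:, 3]
                            + 0.5 * rng.standard_normal(n)), -20, 20)
        return AnalysisTable(age_group=AgeGroup.G65_69,
                             feature_names=["ACT_A", "ACT_B", EDUCATION,
                                            BASELINE_MEMORY],
                             X=X.astype(float), y=y)

    def test_distribution_and_combined_identity(self, rng):
        cfg = RunConfig(n_reps_sa=6, seed=0)
        dist = importance_distribution(self._table(rng), cfg)
        assert dist.values.shape == (6, 4)
        comb = combined_activity_importance(dist)
        assert comb == pytest.approx(1.0 - dist.values[:, 2:].sum(axis=1), abs=1e-9)
        assert ((comb >= 0) & (comb <= 1)).all()

    def test_dominant_activity_among_activities(self, rng):
        cfg = RunConfig(n_reps_sa=8, seed=1)
        dist = importance_distribution(self._table(rng, n=150), cfg)
        # ACT_A carries most of the signal variance
        assert dist.mean[0] > dist.mean[1]

    def test_summary_se_matches_definition(self, rng):
        dist = ImportanceDistribution(
            age_group=AgeGroup.G70_74, predictor_names=["a", "e", "b"],
            values=np.array([[0.5, 0.3, 0.2], [0.6, 0.2, 0.2], [0.4, 0.4, 0.2]]))
        assert dist.se == pytest.approx(
            np.std(dist.values, axis=0, ddof=1) / np.sqrt(3))
        assert dist.combined_activity == pytest.approx([0.5, 0.6, 0.4])
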