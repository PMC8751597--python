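"""Stage 1 — per-age-group association screening of the 33 activities.

Two complementary non-linear screens are run within each age group:

* distance correlation between each activity and the memory change, with a
  permutation significance test (:mod:`.dcor`);
* random-forest regression of memory change on all predictors, with a
  permutation test on each feature's impurity importance (the response is
  permuted and the forest refit to build the null).

An activity is kept if it reaches significance in at least one age group by
at least one method (inclusive threshold: a p-value equal to alpha counts).
No multiple-testing correction is applied — the report records the total
number of tests instead.  The union set is used for every group downstream.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_X_y, check_is_fitted

from .dcor import dcor_resample_test
from .seeding import stage_int_seed
from .types import AGE_GROUPS, AgeGroup, AnalysisTable, FeatureSelectionResult, RunConfig

log = logging.getLogger("actimem.screening")


def _check_regression_target(y: np.ndarray) -> None:
    if y.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant target: degenerate regression problem")


def rf_fit_predict(X, y, n_trees: int = 500, min_leaf: int = 5,
                   seed: Optional[int] = None) -> tuple[RandomForestRegressor, np.ndarray]:
    """Fit a seeded regression forest; returns (forest, out-of-bag predictions).

    Conventional regression-forest settings: impurity split rule,
    features-per-split = ceil(p/3), configurable tree count and leaf size.
    """
    X, y = check_X_y(X, y, ensure_min_samples=2)
    _check_regression_target(y)
    p = X.shape[1]
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        max_features=max(1, math.ceil(p / 3)),
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest, forest.oob_prediction_


def rf_permutation_pvalues(X, y, n_perm: int = 300, n_trees: int = 500,
                           min_leaf: int = 5,
                           seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Permutation p-values for each feature's forest importance.

    For each of ``n_perm`` draws, y is permuted and the forest refit; the
    p-value for feature j is (1 + #{null_j >= observed_j}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y = check_X_y(X, y, ensure_min_samples=2)
    _check_regression_target(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _importances(target: np.ndarray) -> np.ndarray:
        fit_seed = int(rng.integers(2**31 - 1))
        forest = RandomForestRegressor(
            n_estimators=n_trees, min_samples_leaf=min_leaf,
            max_features=max(1, math.ceil(X.shape[1] / 3)),
            random_state=fit_seed, n_jobs=1)
        forest.fit(X, target)
        return forest.feature_importances_

    observed = _importances(y)
    exceed = np.zeros(X.shape[1], dtype=int)
    for _ in range(n_perm):
        null = _importances(rng.permutation(y))
        exceed += null >= observed
    return (1 + exceed) / (1 + n_perm)


class DCorScreener(BaseEstimator):
    """Per-feature distance-correlation independence screen.

    Parameters
    ----------
    alpha : significance level (inclusive threshold).
    n_resamples : permutations for each feature's null distribution.
    random_state : seed for the permutation draws.

    Attributes
    ----------
    pvalues_ : ndarray of shape (n_features,)
    statistics_ : observed distance correlations.
    support_ : boolean mask of features with ``pvalues_ <= alpha``.
    """

    def __init__(self, alpha: float = 0.05, n_resamples: int = 300,
                 random_state: Optional[int] = None):
        self.alpha = alpha
        self.n_resamples = n_resamples
        self.random_state = random_state

    def fit(self, X, y):
        from .dcor import distance_correlation

        X, y = check_X_y(X, y, ensure_min_samples=2)
        rng = np.random.default_rng(self.random_state)
        p = X.shape[1]
        self.statistics_ = np.empty(p)
        self.pvalues_ = np.empty(p)
        for j in range(p):
            self.statistics_[j] = distance_correlation(X[:, j], y)
            self.pvalues_[j] = dcor_resample_test(
                X[:, j], y, n_resamples=self.n_resamples, seed=rng)
        self.support_ = self.pvalues_ <= self.alpha
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


class RFPermutationScreener(BaseEstimator):
    """Random-forest permutation-importance significance screen.

    Attributes after fit: ``pvalues_``, ``support_`` as in
    :class:`DCorScreener`.
    """

    def __init__(self, alpha: float = 0.05, n_permutations: int = 300,
                 n_trees: int = 500, min_leaf: int = 5,
                 random_state: Optional[int] = None):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.n_trees = n_trees
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        self.pvalues_ = rf_permutation_pvalues(
            X, y, n_perm=self.n_permutations, n_trees=self.n_trees,
            min_leaf=self.min_leaf, seed=np.random.default_rng(self.random_state))
        self.support_ = self.pvalues_ <= self.alpha
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


def select_features(p_dcor: np.ndarray, p_rf: np.ndarray, alpha: float,
                    activity_names: Sequence[str]) -> FeatureSelectionResult:
    """Union selection: an activity is kept iff its minimum p-value over
    both methods and all age groups is <= alpha (inclusive)."""
    p_dcor = np.asarray(p_dcor, dtype=float)
    p_rf = np.asarray(p_rf, dtype=float)
    if p_dcor.shape != p_rf.shape or p_dcor.shape[0] != len(activity_names):
        raise ValueError("p-value matrices must cover the same activities and groups")
    minp = np.minimum(p_dcor, p_rf).min(axis=1)
    selected = [a for a, mp in zip(activity_names, minp) if mp <= alpha]
    return FeatureSelectionResult(
        activity_names=list(activity_names), p_dcor=p_dcor, p_rf=p_rf,
        alpha=alpha, selected=selected)


def screen_activities(tables: Mapping[AgeGroup, AnalysisTable],
                      cfg: RunConfig) -> FeatureSelectionResult:
    """Run both screens in every age group and take the union selection.

    ``tables`` must contain all 33 activities (plus education and baseline
    memory as the final two columns); only activities are screened —
    education and baseline always enter stage 2.
    """
    first = tables[AGE_GROUPS[0]]
    activity_names = first.activity_names
    n_act = len(activity_names)
    p_dcor = np.ones((n_act, len(AGE_GROUPS)))
    p_rf = np.ones((n_act, len(AGE_GROUPS)))
    for j, g in enumerate(AGE_GROUPS):
        t = tables[g]
        if t.activity_names != activity_names:
            raise ValueError("inconsistent activity columns across groups")
        dc = DCorScreener(alpha=cfg.alpha, n_resamples=cfg.n_resamples_dcor,
                          random_state=stage_int_seed(cfg.seed, f"dcor:{g.label}"))
        dc.fit(t.X[:, :n_act], t.y)
        p_dcor[:, j] = dc.pvalues_
        rf = RFPermutationScreener(
            alpha=cfg.alpha, n_permutations=cfg.n_perm_rf,
            n_trees=cfg.rf_n_trees, min_leaf=cfg.rf_min_leaf,
            random_state=stage_int_seed(cfg.seed, f"rfperm:{g.label}"))
        rf.fit(t.X, t.y)  # forest uses activities + education + baseline
        p_rf[:, j] = rf.pvalues_[:n_act]
        log.info("screened group %s: %d dCor hits, %d RF hits", g.label,
                 int((p_dcor[:, j] <= cfg.alpha).sum()),
                 int((p_rf[:, j] <= cfg.alpha).sum()))
    result = select_features(p_dcor, p_rf, cfg.alpha, activity_names)
    log.info("union selection: %d of %d activities (%d tests, no correction)",
             len(result.selected), n_act, 2 * n_act * len(AGE_GROUPS))
    return result
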