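"""Stage 2 — data-based sensitivity-analysis importance.

A fitted black-box regressor is probed one input at a time: input j is
swept over L levels spanning its observed range (for an ordinal input with
at most L categories, the levels are exactly its categories) while every
other input keeps its observed values; predictions are averaged over the
reference rows at each level.  The dispersion of those level means —
variance by default, range as an option — is input j's sensitivity, and
relative importance is each sensitivity divided by their sum, so
importances are nonnegative and sum to one and can be meaningfully added
across inputs.

Uncertainty comes from repetition: each of R repetitions draws a fresh
subsample (80% without replacement by default), refits the SVR on it, and
computes importances with the subsample as the reference matrix.  The
combined daily-activity importance of a repetition is the arithmetic sum of
its activity importances, which by normalization equals one minus the
education and baseline-memory importances.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_X_y, check_is_fitted

from .seeding import stage_rng
from .svr import GaussianKernelSVR
from .types import AnalysisTable, ImportanceDistribution, RunConfig

log = logging.getLogger("actimem.importance")


def sa_importance(model, X_ref: np.ndarray, L: int = 7,
                  measure: str = "variance") -> np.ndarray:
    """Relative importance of each feature of ``model`` on reference data.

    ``model`` needs only a ``predict`` method over the feature space of
    ``X_ref``.  Returns a nonnegative vector summing to 1; raises if every
    sensitivity is zero (a constant model has no importance to attribute).
    """
    if L < 2:
        raise ValueError("need at least 2 probe levels")
    if measure not in ("variance", "range"):
        raise ValueError("measure must be 'variance' or 'range'")
    X_ref = np.asarray(X_ref, dtype=float)
    n, p = X_ref.shape
    feature_levels: list[np.ndarray] = []
    probes = []
    for j in range(p):
        uniq = np.unique(X_ref[:, j])
        levels = uniq if uniq.size <= L else np.linspace(uniq[0], uniq[-1], L)
        feature_levels.append(levels)
        for lev in levels:
            Xp = X_ref.copy()
            Xp[:, j] = lev
            probes.append(Xp)
    # one batched predict over all probe blocks (cheaper than per-level calls)
    preds = model.predict(np.vstack(probes))
    s = np.empty(p)
    off = 0
    for j in range(p):
        n_lev = feature_levels[j].size
        means = preds[off:off + n_lev * n].reshape(n_lev, n).mean(axis=1)
        off += n_lev * n
        s[j] = means.var() if measure == "variance" else np.ptp(means)
    # snap float-level jitter to an exact zero so an ignored input reports
    # exactly no importance
    scale = max(1.0, float(np.abs(preds).max()))
    tiny = (1e-9 * scale) ** 2 if measure == "variance" else 1e-9 * scale
    s[s < tiny] = 0.0
    total = s.sum()
    if total <= 0:
        raise ValueError("degenerate model: zero sensitivity for every feature")
    return s / total


class SensitivityImportance(BaseEstimator):
    """Repeated subsample-refit-probe importance estimator.

    Parameters
    ----------
    n_repeats : number of subsample repetitions (R).
    subsample_fraction : fraction drawn without replacement per repetition.
    n_levels : probe levels per feature (L).
    measure : 'variance' (default) or 'range' dispersion of level means.
    refit : refit the SVR on each subsample (default) or fit once on the
        full data and only resample the reference matrix.
    n_widths, validation_fraction : forwarded to :class:`GaussianKernelSVR`.
    random_state : master seed for subsampling and SVR fits.

    Attributes
    ----------
    importances_ : ndarray (n_repeats, n_features), rows sum to 1.
    importances_mean_, importances_se_ : per-feature summaries; the SE is
        the standard deviation across repetitions divided by sqrt(R).
    """

    def __init__(self, n_repeats: int = 200, subsample_fraction: float = 0.8,
                 n_levels: int = 7, measure: str = "variance", refit: bool = True,
                 n_widths: int = 10, validation_fraction: float = 0.2,
                 random_state: Optional[int] = None):
        self.n_repeats = n_repeats
        self.subsample_fraction = subsample_fraction
        self.n_levels = n_levels
        self.measure = measure
        self.refit = refit
        self.n_widths = n_widths
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=10)
        n, p = X.shape
        n_sub = int(round(self.subsample_fraction * n))
        if n_sub < 10:
            raise ValueError(f"subsample of {n_sub} rows is too small (< 10)")
        rng = np.random.default_rng(self.random_state)
        full_model = None
        if not self.refit:
            full_model = GaussianKernelSVR(
                n_widths=self.n_widths,
                validation_fraction=self.validation_fraction,
                random_state=int(rng.integers(2**31 - 1))).fit(X, y)
        values = np.empty((self.n_repeats, p))
        for r in range(self.n_repeats):
            idx = rng.choice(n, size=n_sub, replace=False)
            if self.refit:
                model = GaussianKernelSVR(
                    n_widths=self.n_widths,
                    validation_fraction=self.validation_fraction,
                    random_state=int(rng.integers(2**31 - 1))).fit(X[idx], y[idx])
            else:
                model = full_model
            values[r] = sa_importance(model, X[idx], L=self.n_levels,
                                      measure=self.measure)
        self.importances_ = values
        self.importances_mean_ = values.mean(axis=0)
        self.importances_se_ = (values.std(axis=0, ddof=1) / np.sqrt(self.n_repeats)
                                if self.n_repeats > 1 else np.zeros(p))
        return self

    def get_importances(self) -> np.ndarray:
        check_is_fitted(self, "importances_")
        return self.importances_


def importance_distribution(table: AnalysisTable, cfg: RunConfig) -> ImportanceDistribution:
    """Run the repeated sensitivity analysis for one age group's table."""
    est = SensitivityImportance(
        n_repeats=cfg.n_reps_sa, subsample_fraction=cfg.subsample_fraction,
        n_levels=cfg.sa_levels, measure=cfg.sa_measure,
        refit=cfg.refit_per_subsample, n_widths=cfg.svr_n_widths,
        validation_fraction=cfg.svr_validation_fraction,
        random_state=int(stage_rng(cfg.seed, f"sa:{table.age_group.label}")
                         .integers(2**31 - 1)))
    est.fit(table.X, table.y)
    log.info("group %s: %d repetitions over %d predictors",
             table.age_group.label, cfg.n_reps_sa, len(table.feature_names))
    return ImportanceDistribution(
        age_group=table.age_group, predictor_names=list(table.feature_names),
        values=est.importances_)


def combined_activity_importance(dist: ImportanceDistribution) -> np.ndarray:
    """Per-repetition combined importance of all activity features — the
    arithmetic sum of their relative importances (equivalently one minus
    the education and baseline-memory importances)."""
    return dist.combined_activity
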