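"""Stage 3 — across-age-group comparison of importance distributions.

The R repetition-level importances of one series (combined activities,
education, or baseline memory) are compared across the five age groups
with a one-way ANOVA, followed by all-pairs Tukey Honest Significant
Difference tests based on the studentized-range distribution.

The repetitions within a group are subsamples of the same underlying
data, so these p-values characterize the dispersion of the importance
estimator, not population-level inference (pseudo-replication); the
report states this alongside the numbers.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping

import numpy as np
from scipy import stats

from .types import AgeGroup, ImportanceDistribution, TrendTestResult

log = logging.getLogger("actimem.trends")


def _validate_groups(groups: Mapping) -> list:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    vals = []
    for g, v in groups.items():
        v = np.asarray(v, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {g} has fewer than 2 values")
        vals.append(v)
    return vals


def anova_oneway(groups: Mapping) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Raises for fewer than two groups or when the within-group variance is
    zero with equal means (F undefined).
    """
    vals = _validate_groups(groups)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in vals)
    means = [v.mean() for v in vals]
    if ssw == 0 and np.ptp(means) == 0:
        raise ValueError("zero within-group variance with equal means: F undefined")
    f, p = stats.f_oneway(*vals)
    return float(f), float(p)


def tukey_hsd(groups: Mapping) -> list[tuple[str, str, float, float]]:
    """All-pairs Tukey HSD table: (group_a, group_b, mean diff, adjusted p).

    The adjusted p-value is the studentized-range tail probability of
    q = |mean_a - mean_b| / sqrt(MSW/2 * (1/n_a + 1/n_b)) with k groups
    and N-k error degrees of freedom.
    """
    vals = _validate_groups(groups)
    keys = list(groups)
    k = len(vals)
    N = sum(v.size for v in vals)
    msw = sum(((v - v.mean()) ** 2).sum() for v in vals) / (N - k)
    if msw == 0:
        raise ValueError("zero within-group variance: Tukey HSD undefined")
    rows = []
    for (ia, a), (ib, b) in itertools.combinations(enumerate(keys), 2):
        va, vb = vals[ia], vals[ib]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(msw / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, N - k))
        label = getattr(a, "label", str(a)), getattr(b, "label", str(b))
        rows.append((label[0], label[1], diff, min(max(p, 0.0), 1.0)))
    return rows


def trend_summary(series_name: str,
                  series: Mapping[AgeGroup, np.ndarray]) -> TrendTestResult:
    """Monotonicity report for one importance series across the age groups.

    Bundles group means, the rank correlation of mean against group order,
    ANOVA and Tukey results, and the relative change from the youngest to
    the oldest group mean ((oldest - youngest) / youngest).
    """
    ordered = {g: np.asarray(series[g], dtype=float)
               for g in sorted(series, key=lambda g: g.lo)}
    f, p = anova_oneway(ordered)
    tk = tukey_hsd(ordered)
    res = TrendTestResult(series_name=series_name, group_values=ordered,
                          F=f, p_anova=p, tukey=tk)
    log.info("%s: rank corr %+.2f, relative change %+.0f%%, ANOVA p=%.3g",
             series_name, res.rank_correlation, 100 * res.relative_change, p)
    return res


def importance_trends(
        dists: Mapping[AgeGroup, ImportanceDistribution]) -> list[TrendTestResult]:
    """Trend tests for the three headline series: combined activities,
    education, and baseline memory."""
    from .activities import BASELINE_MEMORY, EDUCATION

    series = []
    todo = [("COMBINED_ACTIVITIES",
             {g: d.combined_activity for g, d in dists.items()})]
    for name in (EDUCATION, BASELINE_MEMORY):
        per = {}
        for g, d in dists.items():
            j = d.predictor_names.index(name)
            per[g] = d.values[:, j]
        todo.append((name, per))
    for name, per in todo:
        try:
            series.append(trend_summary(name, per))
        except ValueError as exc:
            # e.g. a predictor with exactly zero importance in every
            # repetition of every group: F undefined, series skipped
            log.warning("trend test for %s skipped: %s", name, exc)
    return series
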