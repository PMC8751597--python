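"""Synthetic-cohort generator: determinism, bounds, presets, and
parameter recovery against a closed-form regression oracle."""

import numpy as np
import pytest

from actimem.activities import ACTIVITY_NAMES
from actimem.preprocess import build_tables, compute_memory_score, preprocess
from actimem.simulate import (DEFAULT_N_PER_GROUP, PRESET_ACTIVE_ACTIVITIES,
                              SyntheticConfig, generate_cohort,
                              generate_null_cohort, null_config, trend_preset)
from actimem.types import AGE_GROUPS


def small_sizes(n=150):
    return {g: n for g in AGE_GROUPS}


class TestGeneration:
    def test_seeded_determinism(self):
        cfg = trend_preset("paper-like", seed=11, n_per_group=small_sizes())
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert [r.activities for r in a] == [r.activities for r in b]
        assert [(r.recall_immediate_w1, r.recall_delayed_w2) for r in a] == \
               [(r.recall_immediate_w1, r.recall_delayed_w2) for r in b]

    def test_group_sizes_match_config(self):
        cfg = SyntheticConfig(seed=0, missing_rate=0.0)
        cfg.n_per_group = {g: 30 + 5 * i for i, g in enumerate(AGE_GROUPS)}
        recs = generate_cohort(cfg)
        counts = {g: 0 for g in AGE_GROUPS}
        for r in recs:
            for g in AGE_GROUPS:
                if g.lo <= r.age_years <= g.hi:
                    counts[g] += 1
        assert counts == cfg.n_per_group

    def test_recall_bounds_and_change_range(self):
        cfg = trend_preset("paper-like", seed=2, n_per_group=small_sizes())
        for r in generate_cohort(cfg):
            for v in (r.recall_immediate_w1, r.recall_delayed_w1,
                      r.recall_immediate_w2, r.recall_delayed_w2):
                assert 0 <= v <= 10
            b = compute_memory_score(r.recall_immediate_w1, r.recall_delayed_w1)
            f = compute_memory_score(r.recall_immediate_w2, r.recall_delayed_w2)
            assert 0 <= b <= 20 and 0 <= f <= 20 and -20 <= f - b <= 20

    def test_degenerate_model_gives_deterministic_change(self):
        cfg = SyntheticConfig(seed=5, noise_sd=1e-9, missing_rate=0.0)
        cfg.n_per_group = small_sizes(100)
        # keep group means off the .5 rounding boundary, where vanishing
        # noise still flips the rounded value
        cfg.mu = {g: -0.8 - 0.4 * i for i, g in enumerate(AGE_GROUPS)}
        for r in generate_cohort(cfg):
            b = compute_memory_score(r.recall_immediate_w1, r.recall_delayed_w1)
            f = compute_memory_score(r.recall_immediate_w2, r.recall_delayed_w2)
            g = next(g for g in AGE_GROUPS if g.lo <= r.age_years <= g.hi)
            mu = round(cfg.mu[g])
            if 0 <= b + mu <= 20:  # away from the clipping bounds
                assert f - b == mu

    def test_missing_rate_applies_to_activities_and_education_only(self):
        cfg = SyntheticConfig(seed=9, missing_rate=0.3)
        cfg.n_per_group = small_sizes(200)
        recs = generate_cohort(cfg)
        cells = np.array([[r.activities[a] is None for a in ACTIVITY_NAMES]
                          for r in recs])
        rate = cells.mean()
        assert 0.27 < rate < 0.33
        assert all(r.recall_immediate_w1 is not None for r in recs)


class TestNullCohort:
    def test_ledger_coefficients_all_zero(self):
        cfg = null_config(trend_preset("paper-like", seed=0))
        led = cfg.ledger()
        for g in led["groups"].values():
            assert g["alpha_baseline_memory"] == 0.0
            assert g["beta_education"] == 0.0
            assert all(v == 0.0 for v in g["gamma_activities"].values())

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(seed=3)
        cfg.n_per_group = small_sizes(50)
        a, b = generate_null_cohort(cfg), generate_null_cohort(cfg)
        assert [r.activities for r in a] == [r.activities for r in b]


class TestTrendPreset:
    def test_paper_like_monotone_coefficients(self):
        cfg = trend_preset("paper-like")
        tot = [sum(abs(v) for v in cfg.gamma[g].values()) for g in AGE_GROUPS]
        assert all(a < b for a, b in zip(tot, tot[1:]))
        al = [abs(cfg.alpha[g]) for g in AGE_GROUPS]
        be = [abs(cfg.beta[g]) for g in AGE_GROUPS]
        assert all(a > b for a, b in zip(al, al[1:]))
        assert all(a > b for a, b in zip(be, be[1:]))

    def test_null_identical_across_groups(self):
        cfg = trend_preset("null")
        first = AGE_GROUPS[0]
        for g in AGE_GROUPS[1:]:
            assert cfg.gamma[g] == cfg.gamma[first]
            assert cfg.alpha[g] == cfg.alpha[first]

    def test_reversed_monotone_decreasing(self):
        cfg = trend_preset("reversed")
        tot = [sum(abs(v) for v in cfg.gamma[g].values()) for g in AGE_GROUPS]
        assert all(a > b for a, b in zip(tot, tot[1:]))

    def test_unknown_direction_raises(self):
        with pytest.raises(ValueError):
            trend_preset("sideways")

    def test_default_sizes_match_study_populations(self):
        assert list(DEFAULT_N_PER_GROUP.values()) == [757, 840, 800, 518, 295]


def _ols_coef_ci(X, y):
    """Closed-form OLS with 95% Wald intervals (the recovery oracle)."""
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    s2 = resid @ resid / (n - p - 1)
    cov = s2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov))
    from scipy.stats import t as tdist

    half = tdist.ppf(0.975, n - p - 1) * se
    return beta[1:], half[1:]


def test_ols_recovers_configured_coefficients():
    """Per-group OLS of memory change on standardized predictors covers the
    configured coefficients at close to the nominal 95% rate."""
    cfg0 = trend_preset("paper-like", n_per_group={g: 500 for g in AGE_GROUPS})
    n_rep = 50
    covered = []  # one row per replicate: coverage indicator per coefficient
    for rep in range(n_rep):
        cfg = trend_preset("paper-like", seed=1000 + rep,
                           n_per_group=cfg0.n_per_group)
        cfg.missing_rate = 0.0
        tables = build_tables(generate_cohort(cfg), list(ACTIVITY_NAMES))
        row = []
        for g in AGE_GROUPS:
            t = tables[g]
            Z = (t.X - t.X.mean(0)) / t.X.std(0)
            beta, half = _ols_coef_ci(Z, t.y)
            truth = np.array([cfg.gamma[g].get(a, 0.0) for a in ACTIVITY_NAMES]
                             + [cfg.beta[g], cfg.alpha[g]])
            row.extend(np.abs(beta - truth) <= half)
        covered.append(row)
    covered = np.asarray(covered)
    assert covered.mean() >= 0.90          # aggregate coverage near nominal
    assert covered.mean(axis=0).min() >= 0.80  # no coefficient badly missed
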