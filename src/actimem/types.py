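"""Domain types for the age-stratified memory-change analysis.

The unit of observation is one survey participant with a 10-word immediate
and delayed recall test at two waves six years apart, years of education,
and 33 ordinal daily-activity engagement codes.  Baseline memory is the
0-20 sum of the two recall counts; the target is the change in that sum
between waves.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional

import numpy as np

from .activities import ACTIVITY_CATEGORIES, ACTIVITY_NAMES, BASELINE_MEMORY, EDUCATION


class AgeGroup(enum.Enum):
    """Five inclusive 5-year age bins covering ages 65-89."""

    G65_69 = (65, 69)
    G70_74 = (70, 74)
    G75_79 = (75, 79)
    G80_84 = (80, 84)
    G85_89 = (85, 89)

    @property
    def lo(self) -> int:
        return self.value[0]

    @property
    def hi(self) -> int:
        return self.value[1]

    @property
    def label(self) -> str:
        return f"{self.lo}-{self.hi}"

    @classmethod
    def from_age(cls, age_years: int) -> "AgeGroup":
        for g in cls:
            if g.lo <= age_years <= g.hi:
                return g
        raise ValueError(f"age {age_years} outside the 65-89 study range")

    @classmethod
    def from_label(cls, label: str) -> "AgeGroup":
        for g in cls:
            if g.label == label:
                return g
        raise ValueError(f"unknown age-group label {label!r}")


AGE_GROUPS: tuple[AgeGroup, ...] = tuple(AgeGroup)


@dataclass
class ParticipantRecord:
    """One subject's raw measurements; ``None`` marks a missing cell.

    Recall components are 0-10 word counts; activity codes are ordinal
    integers 0..K-1 where K is that activity's category count (6 or 7).
    """

    id: str
    age_years: int
    education_years: Optional[int] = None
    recall_immediate_w1: Optional[int] = None
    recall_delayed_w1: Optional[int] = None
    recall_immediate_w2: Optional[int] = None
    recall_delayed_w2: Optional[int] = None
    activities: dict[str, Optional[int]] = field(
        default_factory=lambda: {a: None for a in ACTIVITY_NAMES}
    )

    def __post_init__(self) -> None:
        for name in ACTIVITY_NAMES:
            self.activities.setdefault(name, None)
        extra = set(self.activities) - set(ACTIVITY_NAMES)
        if extra:
            raise ValueError(f"unknown activity keys: {sorted(extra)}")
        for comp in (
            "recall_immediate_w1",
            "recall_delayed_w1",
            "recall_immediate_w2",
            "recall_delayed_w2",
        ):
            v = getattr(self, comp)
            if v is not None and not 0 <= v <= 10:
                raise ValueError(f"{comp}={v} outside 0-10")
        for name, level in self.activities.items():
            if level is not None and not 0 <= level < ACTIVITY_CATEGORIES[name]:
                raise ValueError(
                    f"activity {name!r} level {level} outside "
                    f"0..{ACTIVITY_CATEGORIES[name] - 1}"
                )

    def n_missing(self) -> int:
        """Missing cells among the 36 tracked: 33 activities, education,
        and the two wave memory scores (a score is missing if either of its
        recall components is)."""
        n = sum(v is None for v in self.activities.values())
        n += self.education_years is None
        n += self.recall_immediate_w1 is None or self.recall_delayed_w1 is None
        n += self.recall_immediate_w2 is None or self.recall_delayed_w2 is None
        return n


N_TRACKED_CELLS = 36  # 33 activities + education + 2 wave memory scores


@dataclass
class AnalysisTable:
    """Complete per-age-group design matrix and memory-change target.

    Feature order is fixed: selected activities first, then education,
    then baseline memory.
    """

    age_group: AgeGroup
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if n == 0:
            raise ValueError(f"empty table for group {self.age_group.label}")
        if p != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")
        if self.y.shape != (n,):
            raise ValueError("y length does not match X rows")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("analysis table contains missing values")
        if self.feature_names[-1] != BASELINE_MEMORY or self.feature_names[-2] != EDUCATION:
            raise ValueError("feature order must end with education, baseline memory")
        b = self.X[:, -1]
        if b.min() < 0 or b.max() > 20:
            raise ValueError("baseline memory column outside 0-20")
        if np.abs(self.y).max() > 20:
            raise ValueError("memory change outside [-20, 20]")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def activity_names(self) -> list[str]:
        return self.feature_names[:-2]


@dataclass
class FeatureSelectionResult:
    """Stage-1 output: activity x age-group p-value matrices per method and
    the cross-group, cross-method union of significant activities."""

    activity_names: list[str]
    p_dcor: np.ndarray  # (33, 5)
    p_rf: np.ndarray    # (33, 5)
    alpha: float
    selected: list[str]

    def __post_init__(self) -> None:
        self.p_dcor = np.asarray(self.p_dcor, dtype=float)
        self.p_rf = np.asarray(self.p_rf, dtype=float)
        shape = (len(self.activity_names), len(AGE_GROUPS))
        if self.p_dcor.shape != shape or self.p_rf.shape != shape:
            raise ValueError(f"p-value matrices must have shape {shape}")
        for m in (self.p_dcor, self.p_rf):
            if (m <= 0).any() or (m > 1).any():
                raise ValueError("p-values must lie in (0, 1]")
        if not set(self.selected) <= set(self.activity_names):
            raise ValueError("selected set contains unknown activities")

    def min_p(self) -> np.ndarray:
        return np.minimum(self.p_dcor, self.p_rf)


@dataclass
class ImportanceDistribution:
    """Per-age-group repetition-level relative importances.

    ``values`` is R x p, every row nonnegative and summing to one;
    ``combined_activity`` is the per-repetition sum over activity columns.
    """

    age_group: AgeGroup
    predictor_names: list[str]
    values: np.ndarray
    combined_activity: np.ndarray = field(init=False)
    mean: np.ndarray = field(init=False)
    se: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        R, p = self.values.shape
        if p != len(self.predictor_names):
            raise ValueError("predictor_names length does not match columns")
        if (self.values < -1e-12).any():
            raise ValueError("negative importance")
        rowsum = self.values.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > 1e-9:
            raise ValueError("importance rows must sum to 1")
        n_act = len(self.predictor_names) - 2
        self.combined_activity = self.values[:, :n_act].sum(axis=1)
        self.mean = self.values.mean(axis=0)
        self.se = self.values.std(axis=0, ddof=1) / math.sqrt(R) if R > 1 else np.zeros(p)

    @property
    def n_repetitions(self) -> int:
        return self.values.shape[0]


@dataclass
class TrendTestResult:
    """ANOVA + Tukey HSD comparison of one importance series across groups."""

    series_name: str
    group_values: dict[AgeGroup, np.ndarray]
    F: float
    p_anova: float
    tukey: list[tuple[str, str, float, float]]  # (group_a, group_b, mean_diff, adj_p)
    group_means: dict[AgeGroup, float] = field(init=False)
    rank_correlation: float = field(init=False)
    relative_change: float = field(init=False)

    def __post_init__(self) -> None:
        if self.F < 0 or not 0 <= self.p_anova <= 1:
            raise ValueError("invalid ANOVA result")
        k = len(self.group_values)
        if len(self.tukey) != k * (k - 1) // 2:
            raise ValueError("Tukey table must have C(k,2) rows")
        self.group_means = {g: float(np.mean(v)) for g, v in self.group_values.items()}
        means = [self.group_means[g] for g in sorted(self.group_values, key=lambda g: g.lo)]
        self.rank_correlation = _spearman_vs_index(means)
        youngest, oldest = means[0], means[-1]
        self.relative_change = (oldest - youngest) / youngest if youngest != 0 else math.nan


def _spearman_vs_index(means: Iterable[float]) -> float:
    """Spearman correlation of group means against group order; 0 for a
    flat (zero-variance) series, where the correlation is undefined."""
    m = np.asarray(list(means), dtype=float)
    if np.ptp(m) == 0:
        return 0.0
    from scipy.stats import spearmanr

    rho = spearmanr(np.arange(len(m)), m).statistic
    return float(rho)


@dataclass
class RunConfig:
    """All tunable counts, fractions and model settings for one run."""

    alpha: float = 0.05
    missing_threshold: float = 0.15
    n_resamples_dcor: int = 300
    n_perm_rf: int = 300
    n_reps_sa: int = 200
    sa_levels: int = 7
    sa_measure: str = "variance"  # or "range"
    subsample_fraction: float = 0.8
    refit_per_subsample: bool = True
    r2_split: float = 0.8
    r2_repeats: int = 100
    rf_n_trees: int = 500
    rf_min_leaf: int = 5
    svr_n_widths: int = 10
    svr_validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        for frac in (self.missing_threshold, self.subsample_fraction,
                     self.r2_split, self.svr_validation_fraction):
            if not 0 < frac < 1:
                raise ValueError("fractions must be in (0,1)")
        for count in (self.n_resamples_dcor, self.n_perm_rf, self.n_reps_sa,
                      self.r2_repeats, self.rf_n_trees, self.rf_min_leaf,
                      self.svr_n_widths):
            if count < 1:
                raise ValueError("counts must be positive")
        if self.sa_levels < 2:
            raise ValueError("sa_levels must be >= 2")
        if self.sa_measure not in ("variance", "range"):
            raise ValueError("sa_measure must be 'variance' or 'range'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))


def smoke_config(seed: int = 0) -> RunConfig:
    """Reduced-count profile for quick end-to-end runs."""
    return RunConfig(
        n_resamples_dcor=50, n_perm_rf=50, n_reps_sa=50,
        r2_repeats=10, rf_n_trees=60, seed=seed,
    )
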