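"""Raw records -> per-age-group analysis tables.

Selection and cleaning follow the study protocol: keep ages 65-89 with both
waves' memory assessments, drop participants with more than 15% missing
cells across the 36 tracked variables, replace remaining missing activity /
education cells with the per-variable median over participants (rounded to
the nearest valid ordinal category, half up), then bin into five age
groups.  Memory scores are never imputed: a record without both wave totals
cannot form the change target and is excluded.

Sign convention: change = follow-up - baseline, so negative means decline.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np

from .activities import ACTIVITY_CATEGORIES, ACTIVITY_NAMES, BASELINE_MEMORY, EDUCATION
from .types import AGE_GROUPS, N_TRACKED_CELLS, AgeGroup, AnalysisTable, ParticipantRecord

log = logging.getLogger("actimem.preprocess")


def compute_memory_score(immediate: Optional[int], delayed: Optional[int]) -> Optional[int]:
    """Sum of immediate and delayed 10-word recall counts (0-20); missing
    propagates."""
    if immediate is None or delayed is None:
        return None
    if not (0 <= immediate <= 10 and 0 <= delayed <= 10):
        raise ValueError(f"recall components ({immediate}, {delayed}) outside 0-10")
    return immediate + delayed


def compute_memory_change(score_w1: int, score_w2: int) -> int:
    """Follow-up minus baseline memory score; negative = decline."""
    for s in (score_w1, score_w2):
        if not 0 <= s <= 20:
            raise ValueError(f"memory score {s} outside 0-20")
    return score_w2 - score_w1


def assign_age_group(age_years: int) -> AgeGroup:
    """Inclusive binning into the five 5-year groups; raises outside 65-89."""
    return AgeGroup.from_age(age_years)


def select_eligible(records: Sequence[ParticipantRecord]) -> list[ParticipantRecord]:
    """Keep records aged 65-89 with memory assessments at both waves."""
    kept = []
    for r in records:
        if not 65 <= r.age_years <= 89:
            continue
        if compute_memory_score(r.recall_immediate_w1, r.recall_delayed_w1) is None:
            continue
        if compute_memory_score(r.recall_immediate_w2, r.recall_delayed_w2) is None:
            continue
        kept.append(r)
    log.info("eligibility: kept %d of %d records", len(kept), len(records))
    return kept


def filter_missingness(records: Sequence[ParticipantRecord],
                       threshold: float = 0.15) -> list[ParticipantRecord]:
    """Drop records whose missing fraction over the 36 tracked cells
    exceeds ``threshold``; order preserved."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    kept = [r for r in records if r.n_missing() / N_TRACKED_CELLS <= threshold]
    log.info("missingness filter (> %.0f%%): kept %d of %d",
             100 * threshold, len(kept), len(records))
    return kept


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def impute_median(records: Sequence[ParticipantRecord]) -> list[ParticipantRecord]:
    """Replace missing activity/education cells with the per-variable median
    over the full retained sample, rounded half-up to a valid category.

    Idempotent; raises if any variable has no observed value at all.
    """
    medians: dict[str, int] = {}
    edu = [r.education_years for r in records if r.education_years is not None]
    if records and not edu:
        raise ValueError("variable 'education' has no observed values to impute from")
    if edu:
        medians[EDUCATION] = _round_half_up(float(np.median(edu)))
    for name in ACTIVITY_NAMES:
        vals = [r.activities[name] for r in records if r.activities[name] is not None]
        if records and not vals:
            raise ValueError(f"variable {name!r} has no observed values to impute from")
        if vals:
            med = _round_half_up(float(np.median(vals)))
            medians[name] = int(np.clip(med, 0, ACTIVITY_CATEGORIES[name] - 1))

    out = []
    for r in records:
        out.append(ParticipantRecord(
            id=r.id, age_years=r.age_years,
            education_years=r.education_years if r.education_years is not None
            else medians[EDUCATION],
            recall_immediate_w1=r.recall_immediate_w1,
            recall_delayed_w1=r.recall_delayed_w1,
            recall_immediate_w2=r.recall_immediate_w2,
            recall_delayed_w2=r.recall_delayed_w2,
            activities={name: (v if v is not None else medians[name])
                        for name, v in r.activities.items()},
        ))
    return out


def preprocess(records: Sequence[ParticipantRecord],
               missing_threshold: float = 0.15) -> list[ParticipantRecord]:
    """Full cleaning chain: eligibility, missingness filter, then imputation."""
    return impute_median(filter_missingness(select_eligible(records), missing_threshold))


def build_tables(records: Sequence[ParticipantRecord],
                 selected_activities: Sequence[str]) -> dict[AgeGroup, AnalysisTable]:
    """Assemble the per-group design matrices.

    Columns are the selected activities (ordinal codes as numeric), then
    education, then baseline memory; the target is the memory change.
    Requires complete (imputed) records; raises for an empty group.
    """
    feature_names = list(selected_activities) + [EDUCATION, BASELINE_MEMORY]
    rows: dict[AgeGroup, list[list[float]]] = {g: [] for g in AGE_GROUPS}
    ys: dict[AgeGroup, list[float]] = {g: [] for g in AGE_GROUPS}
    for r in records:
        g = assign_age_group(r.age_years)
        b = compute_memory_score(r.recall_immediate_w1, r.recall_delayed_w1)
        f = compute_memory_score(r.recall_immediate_w2, r.recall_delayed_w2)
        if b is None or f is None or r.education_years is None:
            raise ValueError(f"record {r.id} incomplete; run preprocess() first")
        if any(r.activities[a] is None for a in selected_activities):
            raise ValueError(f"record {r.id} has missing activities")
        feats = [float(r.activities[a]) for a in selected_activities]
        rows[g].append(feats + [float(r.education_years), float(b)])
        ys[g].append(float(compute_memory_change(b, f)))
    tables = {}
    for g in AGE_GROUPS:
        if not rows[g]:
            raise ValueError(f"no records in age group {g.label}")
        tables[g] = AnalysisTable(age_group=g, feature_names=list(feature_names),
                                  X=np.asarray(rows[g]), y=np.asarray(ys[g]))
    return tables
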