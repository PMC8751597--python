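"""Cohort ingestion, report emission, YAML config and logging.

The only ingest format is a comma-separated UTF-8 table with a header row
(survey extracts are distributed as flat tables).  A schema mapping lets
arbitrary export dialects map onto the canonical activity names; cells that
cannot be parsed or fall outside their valid range become missing markers
with a logged warning, never silent zeros.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .activities import ACTIVITY_CATEGORIES, ACTIVITY_NAMES
from .types import (
    AGE_GROUPS,
    FeatureSelectionResult,
    ImportanceDistribution,
    ParticipantRecord,
    RunConfig,
    TrendTestResult,
)

log = logging.getLogger("actimem.io")

#: canonical field -> default CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    "id": "id",
    "age": "age",
    "education": "education",
    "recall_immediate_w1": "recall_immediate_w1",
    "recall_delayed_w1": "recall_delayed_w1",
    "recall_immediate_w2": "recall_immediate_w2",
    "recall_delayed_w2": "recall_delayed_w2",
    **{name: name for name in ACTIVITY_NAMES},
}

_RECALL_FIELDS = (
    "recall_immediate_w1",
    "recall_delayed_w1",
    "recall_immediate_w2",
    "recall_delayed_w2",
)


class SchemaError(ValueError):
    """A required column is absent from the input file."""


def setup_logging(log_file: Optional[Path] = None, level: int = logging.INFO) -> None:
    """Timestamped, stage-tagged lines to stderr and optionally a file."""
    root = logging.getLogger("actimem")
    root.setLevel(level)
    fmt = logging.Formatter("%(asctime)s [%(name)s] %(levelname)s: %(message)s")
    root.handlers = [h for h in root.handlers if not isinstance(h, logging.StreamHandler)]
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        root.addHandler(fh)


def _parse_cell(raw, lo: int, hi: int, where: str) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in ("na", "nan", "none", "."):
        return None
    try:
        v = int(round(float(s)))
    except ValueError:
        log.warning("unparseable cell %r at %s -> missing", raw, where)
        return None
    if not lo <= v <= hi:
        log.warning("out-of-range value %s at %s (valid %d-%d) -> missing", v, where, lo, hi)
        return None
    return v


def read_cohort(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
) -> list[ParticipantRecord]:
    """Read a participant table into records; one record per input row.

    Raises ``FileNotFoundError`` for a missing file and ``SchemaError``
    naming the first required column absent from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for field, col in schema.items():
        if col not in df.columns:
            raise SchemaError(f"input file lacks required column {col!r} (field {field!r})")

    records: list[ParticipantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        where = f"row {i}"
        age = _parse_cell(row_d[schema["age"]], 0, 150, f"{where} age")
        if age is None:
            raise ValueError(f"row {i}: age is missing or unparseable")
        rec = ParticipantRecord(
            id=str(row_d[schema["id"]]),
            age_years=age,
            education_years=_parse_cell(row_d[schema["education"]], 0, 30, f"{where} education"),
            **{
                f: _parse_cell(row_d[schema[f]], 0, 10, f"{where} {f}")
                for f in _RECALL_FIELDS
            },
            activities={
                name: _parse_cell(
                    row_d[schema[name]], 0, ACTIVITY_CATEGORIES[name] - 1, f"{where} {name}"
                )
                for name in ACTIVITY_NAMES
            },
        )
        records.append(rec)
    log.info("read %d records from %s", len(records), path)
    return records


def write_cohort(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write records as CSV under the default schema; missing cells empty."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age": r.age_years,
            "education": r.education_years,
            **{f: getattr(r, f) for f in _RECALL_FIELDS},
            **r.activities,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(
    out_dir: str | Path,
    selection: Optional[FeatureSelectionResult] = None,
    importances: Optional[Mapping] = None,  # AgeGroup -> ImportanceDistribution
    trends: Optional[Sequence[TrendTestResult]] = None,
    config: Optional[RunConfig] = None,
    extra_summary: Optional[dict] = None,
) -> dict[str, str]:
    """Emit delimited-text stage artifacts plus a JSON run summary.

    Returns a manifest mapping artifact names to file paths.  The p-value
    table flags entries at or below alpha (the convention under which a
    printed .05 counts as significant).  Rerunning with identical inputs
    produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise IOError(f"{out_dir} is not a writable directory")
    manifest: dict[str, str] = {}

    def _save(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.10g")
        manifest[name] = str(p)

    labels = [g.label for g in AGE_GROUPS]
    if selection is not None:
        rows = []
        minp = selection.min_p()
        for i, act in enumerate(selection.activity_names):
            row: dict = {"activity": act}
            for j, lab in enumerate(labels):
                row[f"p_dcor_{lab}"] = selection.p_dcor[i, j]
                row[f"p_rf_{lab}"] = selection.p_rf[i, j]
                row[f"p_min_{lab}"] = minp[i, j]
                row[f"significant_{lab}"] = int(minp[i, j] <= selection.alpha)
            row["selected"] = int(act in selection.selected)
            rows.append(row)
        _save("selection_pvalues.csv", pd.DataFrame(rows))
        sel_path = out_dir / "selected_activities.txt"
        sel_path.write_text("".join(f"{a}\n" for a in selection.selected))
        manifest["selected_activities.txt"] = str(sel_path)

    if importances is not None:
        if not importances:
            log.warning("empty importance set; writing empty summary")
            _save("importance_summary.csv", pd.DataFrame(
                columns=["age_group", "predictor", "mean", "se"]))
        else:
            summary_rows = []
            for g, dist in importances.items():
                rep = pd.DataFrame(dist.values, columns=dist.predictor_names)
                rep["COMBINED_ACTIVITIES"] = dist.combined_activity
                rep.insert(0, "repetition", np.arange(dist.n_repetitions))
                _save(f"importance_reps_{g.label}.csv", rep)
                for name, m, s in zip(dist.predictor_names, dist.mean, dist.se):
                    summary_rows.append(
                        {"age_group": g.label, "predictor": name, "mean": m, "se": s})
                summary_rows.append({
                    "age_group": g.label, "predictor": "COMBINED_ACTIVITIES",
                    "mean": float(dist.combined_activity.mean()),
                    "se": float(dist.combined_activity.std(ddof=1)
                                / np.sqrt(dist.n_repetitions))
                    if dist.n_repetitions > 1 else 0.0,
                })
            _save("importance_summary.csv", pd.DataFrame(summary_rows))

    if trends is not None:
        trend_rows, pair_rows = [], []
        for t in trends:
            trend_rows.append({
                "series": t.series_name,
                "F": t.F, "p_anova": t.p_anova,
                "rank_correlation": t.rank_correlation,
                "relative_change": t.relative_change,
                **{f"mean_{g.label}": t.group_means[g] for g in sorted(
                    t.group_means, key=lambda g: g.lo)},
            })
            for a, b, diff, p in t.tukey:
                pair_rows.append({"series": t.series_name, "group_a": a,
                                  "group_b": b, "mean_diff": diff, "p_adj": p})
        _save("trend_summary.csv", pd.DataFrame(trend_rows))
        _save("tukey_pairs.csv", pd.DataFrame(pair_rows))

    summary = {"config": config.to_dict() if config is not None else None,
               "artifacts": sorted(manifest)}
    if extra_summary:
        summary.update(extra_summary)
    sp = out_dir / "run_summary.json"
    sp.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    manifest["run_summary.json"] = str(sp)
    return manifest


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration mirroring :class:`RunConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
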