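"""CSV/JSON serialization for assessments, reports and study output.

CSV schemas (UTF-8, comma-separated, header row):

* numeric assessment — columns ``unit, instance, value`` and optionally
  ``objective`` (a per-row threshold);
* fuzzy assessment — columns ``unit, instance, failed, rank`` with
  ``failed`` in {0, 1} and ``rank`` blank on compliant rows;
* study table — one row per simulated table (see
  :meth:`esindicator.simulate.StudyResult.to_frame`).

An empty ``value`` field marks an unmonitored instance: the row is kept
out of the table (and hence out of every denominator) rather than
treated as a failure. Reports are JSON with display-rounded scores
(1 decimal by default, half away from zero, matching how the scores are
conventionally printed) alongside the raw doubles.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    AssessmentTable,
    ESIReport,
    FuzzyRecord,
    Objective,
    ValidationError,
    validate_table,
)

NUMERIC_COLUMNS = ("unit", "instance", "value")
FUZZY_COLUMNS = ("unit", "instance", "failed", "rank")


def display_round(x: float, decimals: int = 1) -> float:
    """Round half away from zero, as score tables are printed."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _require_columns(frame: pd.DataFrame, required: tuple[str, ...], path: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")


def _check_duplicates(frame: pd.DataFrame, path: str) -> None:
    dup = frame.duplicated(subset=["unit", "instance"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (unit, instance) = ({row['unit']}, {row['instance']})"
        )


def read_assessment_csv(
    path: str | Path, objective_kind: str = "sharp"
) -> tuple[AssessmentTable, dict[tuple[str, str], float] | None]:
    """Read an assessment table; returns (table, per-row thresholds or None)."""
    path = str(path)
    frame = pd.read_csv(path, dtype={"unit": str, "instance": str})
    if objective_kind == "sharp":
        _require_columns(frame, NUMERIC_COLUMNS, path)
        _check_duplicates(frame, path)
        monitored = frame[frame["value"].notna()]
        values = pd.to_numeric(monitored["value"], errors="coerce")
        if values.isna().any():
            bad = monitored.loc[values.isna()].iloc[0]
            raise ValidationError(
                f"{path}: non-numeric value {bad['value']!r} at "
                f"({bad['unit']}, {bad['instance']})"
            )
        obs = {
            (row["unit"], row["instance"]): float(v)
            for (_, row), v in zip(monitored.iterrows(), values)
        }
        table = AssessmentTable.from_numeric(obs)
        thresholds = None
        if "objective" in frame.columns and monitored["objective"].notna().any():
            thresholds = {
                (row["unit"], row["instance"]): float(row["objective"])
                for _, row in monitored.iterrows()
            }
        return table, thresholds
    if objective_kind == "fuzzy":
        _require_columns(frame, FUZZY_COLUMNS, path)
        _check_duplicates(frame, path)
        records: dict[tuple[str, str], FuzzyRecord] = {}
        for _, row in frame.iterrows():
            if pd.isna(row["failed"]):
                continue  # unmonitored instance
            failed = bool(int(row["failed"]))
            key = (row["unit"], row["instance"])
            if failed and pd.isna(row["rank"]):
                raise ValidationError(f"{path}: rank required on failing row {key}")
            if not failed and not pd.isna(row["rank"]):
                raise ValidationError(f"{path}: rank present on compliant row {key}")
            records[key] = FuzzyRecord(
                failed=failed, rank=float(row["rank"]) if failed else None
            )
        return AssessmentTable.from_fuzzy(records), None
    raise ValidationError(f"unknown objective kind: {objective_kind!r}")


def write_assessment_csv(
    table: AssessmentTable,
    path: str | Path,
    thresholds: dict[tuple[str, str], float] | None = None,
) -> None:
    """Write a table in its CSV schema; lossless for raw values."""
    rows = []
    for (unit, instance), payload in table.observations.items():
        if table.kind == "numeric":
            row = {"unit": unit, "instance": instance, "value": repr(float(payload))}
            if thresholds is not None:
                row["objective"] = repr(thresholds[(unit, instance)])
        else:
            assert isinstance(payload, FuzzyRecord)
            row = {
                "unit": unit,
                "instance": instance,
                "failed": int(payload.failed),
                "rank": "" if payload.rank is None else repr(payload.rank),
            }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def report_to_dict(report: ESIReport) -> dict:
    """JSON-ready view of a report: rounded display plus raw doubles."""
    d = report.dimensions
    decimals = report.rounding

    def disp(x: float) -> float:
        return display_round(x, decimals)

    scores: dict[str, dict[str, float]] = {}
    raw_scores: dict[str, dict[str, float]] = {}
    for method, levels in report.method_scores.items():
        key = method.lower()
        scores[key] = {f"esi{lvl}": disp(s) for lvl, s in sorted(levels.items())}
        raw_scores[key] = {f"esi{lvl}": s for lvl, s in sorted(levels.items())}
    return {
        "dimensions": {
            "f1": disp(d.f1),
            "f2": disp(d.f2),
            "nse": d.nse,
            "moe": d.moe,
            "f3_nse": disp(d.f3_nse),
            "f3_moe": disp(d.f3_moe),
            "counts": {
                "n_units": d.n_units,
                "n_failing_units": d.n_failing_units,
                "n_instances": d.n_instances,
                "n_failing_instances": d.n_failing_instances,
            },
        },
        "scores": scores,
        "raw": {
            "f1": d.f1,
            "f2": d.f2,
            "f3_nse": d.f3_nse,
            "f3_moe": d.f3_moe,
            "scores": raw_scores,
        },
        "objective": report.objective_echo,
        "rounding": decimals,
        "tool_version": __version__,
    }


def write_report(report: ESIReport, path: str | Path) -> dict:
    """Serialize a report to JSON; returns the written document."""
    doc = report_to_dict(report)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
    return doc


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_study_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_study_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"discard_reason": str})


def objective_from_config(cfg: dict) -> Objective:
    """Build an objective from its JSON configuration block."""
    kind = cfg.get("kind", "sharp")
    if kind == "sharp":
        return Objective(
            kind="sharp",
            threshold=cfg["threshold"],
            direction=cfg.get("direction", "must_not_fall_short"),
        )
    return Objective(kind="fuzzy")


__all__ = [
    "display_round",
    "read_assessment_csv",
    "write_assessment_csv",
    "report_to_dict",
    "write_report",
    "read_report",
    "write_study_csv",
    "read_study_csv",
    "objective_from_config",
    "validate_table",
]
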