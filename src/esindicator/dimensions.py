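"""Scope, frequency and amplitude of failed ecosystem-service delivery.

The three dimensions descend from the CCME Water Quality Index family:

* scope ``F1`` — what fraction of the study area ever failed;
* frequency ``F2`` — how often instances failed, pooled over units;
* amplitude ``F3`` — how far failing instances fell from the objective,
  summarized either as a normalized sum of excursions (``nse``, divided
  by all monitored instances, so it embeds frequency) or as a mean over
  failing instances only (``moe``), then scaled onto [0, 100) by
  ``100 * x / (x + 1)``.

Boundary policy: a value exactly at the threshold complies. A zero
excursion would otherwise count a "failure" with no supply-demand gap,
which is an artifact rather than a delivery problem.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    AssessmentTable,
    DimensionScores,
    Direction,
    FuzzyRecord,
    Objective,
    ValidationError,
    validate_table,
)

Key = tuple[str, str]


@dataclass(frozen=True)
class ExcursionSet:
    """Per-instance excursions of the failing instances of one table."""

    records: tuple[tuple[str, str, float], ...]
    total_instances: int

    def __post_init__(self) -> None:
        if self.total_instances < 1:
            raise ValidationError("total_instances must be positive")
        if any(ex < 0 for (_, _, ex) in self.records):
            raise ValidationError("excursions must be non-negative")


def classify_failures(table: AssessmentTable, objective: Objective) -> dict[Key, bool]:
    """Flag each monitored instance as failing (True) or compliant.

    Sharp shortfall: fails iff value < threshold. Sharp exceedance:
    fails iff value > threshold (equality complies in both directions).
    Fuzzy: flags are copied from the table.
    """
    validate_table(table, objective)
    flags: dict[Key, bool] = {}
    for key, payload in table.observations.items():
        if objective.kind == "fuzzy":
            assert isinstance(payload, FuzzyRecord)
            flags[key] = payload.failed
        else:
            threshold = objective.threshold_at(key)
            value = float(payload)  # type: ignore[arg-type]
            if objective.direction is Direction.MUST_NOT_FALL_SHORT:
                flags[key] = value < threshold
            else:
                flags[key] = value > threshold
    return flags


def compute_scope(flags: dict[Key, bool]) -> float:
    """F1: percentage of units with at least one failing instance."""
    if not flags:
        raise ValidationError("empty table")
    units: dict[str, bool] = {}
    for (unit, _), failed in flags.items():
        units[unit] = units.get(unit, False) or failed
    return 100.0 * sum(units.values()) / len(units)


def compute_frequency(flags: dict[Key, bool]) -> float:
    """F2: percentage of all monitored instances that failed."""
    if not flags:
        raise ValidationError("empty table")
    return 100.0 * sum(flags.values()) / len(flags)


def excursion(value: float, threshold: float, direction: Direction) -> float:
    """Relative gap of one failing numeric instance.

    Shortfall: ``threshold / value - 1``; exceedance: ``value / threshold
    - 1``. Both are 0 at the threshold and grow with the gap. A
    non-positive value under a shortfall objective has no defined
    relative gap; callers producing such data must floor their values
    first (the simulator applies a configurable ``value_floor``).
    """
    direction = Direction(direction)
    if direction is Direction.MUST_NOT_FALL_SHORT:
        if value <= 0:
            raise ValidationError(
                "shortfall excursion undefined for value <= 0; apply a value "
                "floor before scoring (see the simulator's value_floor)"
            )
        return threshold / value - 1.0
    if threshold <= 0:
        raise ValidationError("exceedance excursion requires a positive threshold")
    return value / threshold - 1.0


def fuzzy_excursion(rank: float) -> float:
    """Excursion of a failing fuzzy instance: the 1-10 rank itself."""
    if not (1.0 <= rank <= 10.0):
        raise ValidationError(f"rank out of range: {rank!r}")
    return float(rank)


def compute_excursions(
    table: AssessmentTable,
    objective: Objective,
    flags: dict[Key, bool] | None = None,
) -> ExcursionSet:
    """Excursions of every failing instance, plus the pooled denominator."""
    if flags is None:
        flags = classify_failures(table, objective)
    records = []
    for key, failed in flags.items():
        if not failed:
            continue
        payload = table.observations[key]
        if objective.kind == "fuzzy":
            assert isinstance(payload, FuzzyRecord) and payload.rank is not None
            ex = fuzzy_excursion(payload.rank)
        else:
            ex = excursion(
                float(payload),  # type: ignore[arg-type]
                objective.threshold_at(key),
                objective.direction,  # type: ignore[arg-type]
            )
        records.append((key[0], key[1], ex))
    return ExcursionSet(records=tuple(records), total_instances=len(flags))


def normalized_sum_excursions(exs: ExcursionSet) -> float:
    """nse: total excursion divided by all monitored instances."""
    return sum(ex for (_, _, ex) in exs.records) / exs.total_instances


def mean_of_excursions(exs: ExcursionSet) -> float:
    """moe: mean excursion over failing instances; 0 when none failed.

    The zero convention lets a fully compliant table flow through to a
    composite score of 100 without special-casing.
    """
    if not exs.records:
        return 0.0
    return sum(ex for (_, _, ex) in exs.records) / len(exs.records)


def scale_amplitude(x: float) -> float:
    """Map a non-negative excursion aggregate onto [0, 100).

    ``100 * x / (x + 1)``: strictly increasing, 0 at 0, asymptote 100.
    """
    if x < 0:
        raise ValidationError("amplitude aggregate must be non-negative")
    return 100.0 * x / (x + 1.0)


def score_dimensions(table: AssessmentTable, objective: Objective) -> DimensionScores:
    """Full dimension pipeline: classify, count, aggregate excursions."""
    flags = classify_failures(table, objective)
    exs = compute_excursions(table, objective, flags)
    nse = normalized_sum_excursions(exs)
    moe = mean_of_excursions(exs)
    units: dict[str, bool] = {}
    for (unit, _), failed in flags.items():
        units[unit] = units.get(unit, False) or failed
    return DimensionScores(
        f1=compute_scope(flags),
        f2=compute_frequency(flags),
        nse=nse,
        moe=moe,
        f3_nse=scale_amplitude(nse),
        f3_moe=scale_amplitude(moe),
        n_units=len(units),
        n_failing_units=sum(units.values()),
        n_instances=len(flags),
        n_failing_instances=sum(flags.values()),
    )
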