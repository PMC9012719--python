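"""Domain model for ecosystem-service delivery assessments.

An assessment asks whether the realized supply of an ecosystem service
(water provision, sediment regulation, ...) met a stated demand across a
set of *spatial units* (sub-basins, stations, municipality-sector pairs)
observed at one or more *instances* (months, annual maps, static layers).

Two data regimes are supported:

* **numeric** — each observation is a measured value compared against a
  quantitative threshold (the *sharp* objective), with a direction: the
  value must not fall short of the objective (e.g. supply reliability)
  or must not exceed it (e.g. soil-erosion rate).
* **fuzzy** — no quantitative threshold exists; each observation carries
  a failure flag and, when it failed, a stakeholder-assigned severity
  rank on a 1-10 scale standing in for the supply-demand gap.

A table is homogeneously one or the other; mixing regimes within a table
is rejected at validation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Union


class ValidationError(ValueError):
    """Raised when a table or objective violates a structural invariant."""


class Direction(str, Enum):
    """Orientation of a sharp objective."""

    MUST_NOT_FALL_SHORT = "must_not_fall_short"
    MUST_NOT_EXCEED = "must_not_exceed"


@dataclass(frozen=True)
class FuzzyRecord:
    """One observation under a fuzzy objective.

    ``rank`` is present iff the instance failed; it grades the gap between
    supply and demand from 1 (barely short) to 10 (severe). Ranks need not
    be integers — stakeholder elicitation may average to fractional values.
    """

    failed: bool
    rank: float | None = None

    def __post_init__(self) -> None:
        if self.failed:
            if self.rank is None:
                raise ValidationError("failing fuzzy record requires a rank")
            if not (1.0 <= self.rank <= 10.0):
                raise ValidationError(
                    f"rank out of range: {self.rank!r} (must lie in [1, 10])"
                )
        elif self.rank is not None:
            raise ValidationError("compliant fuzzy record must not carry a rank")


Payload = Union[float, FuzzyRecord]
Key = tuple[str, str]


@dataclass
class AssessmentTable:
    """Observations of one service over spatial units x instances.

    ``observations`` maps ``(unit, instance)`` to either a finite numeric
    value or a :class:`FuzzyRecord`. Missing (unit, instance) combinations
    are simply absent: unmonitored instances never enter any denominator.
    Instance labels are opaque ordered strings; no calendar semantics are
    imposed, and units may have unequal instance counts.
    """

    kind: str  # "numeric" | "fuzzy"
    observations: dict[Key, Payload] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "fuzzy"):
            raise ValidationError(f"unknown table kind: {self.kind!r}")
        if not self.observations:
            raise ValidationError("table has no observations")
        for key, payload in self.observations.items():
            if self.kind == "numeric":
                if isinstance(payload, FuzzyRecord):
                    raise ValidationError(
                        f"mixed payloads: fuzzy record at {key} in numeric table"
                    )
                if not math.isfinite(float(payload)):
                    raise ValidationError(f"non-finite value at {key}")
            else:
                if not isinstance(payload, FuzzyRecord):
                    raise ValidationError(
                        f"mixed payloads: numeric value at {key} in fuzzy table"
                    )

    # -- construction -------------------------------------------------

    @classmethod
    def from_numeric(cls, values: Mapping[Key, float]) -> "AssessmentTable":
        return cls(kind="numeric", observations={k: float(v) for k, v in values.items()})

    @classmethod
    def from_fuzzy(cls, records: Mapping[Key, FuzzyRecord]) -> "AssessmentTable":
        return cls(kind="fuzzy", observations=dict(records))

    # -- views ---------------------------------------------------------

    @property
    def unit_ids(self) -> list[str]:
        """Units in first-appearance order."""
        seen: dict[str, None] = {}
        for unit, _ in self.observations:
            seen.setdefault(unit)
        return list(seen)

    def instances_of(self, unit: str) -> list[str]:
        return [i for (u, i) in self.observations if u == unit]

    @property
    def n_instances(self) -> int:
        """All monitored instances, pooled over units."""
        return len(self.observations)

    def instance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for unit, _ in self.observations:
            counts[unit] = counts.get(unit, 0) + 1
        return counts


@dataclass(frozen=True)
class Objective:
    """Demand definition against which observations are judged.

    A *sharp* objective is a finite numeric threshold — a single value
    broadcast to every instance, or a per-(unit, instance) mapping — plus
    a direction. A *fuzzy* objective carries no numbers: failure flags
    and severity ranks live in the table itself.
    """

    kind: str  # "sharp" | "fuzzy"
    threshold: float | Mapping[Key, float] | None = None
    direction: Direction | None = None

    def __post_init__(self) -> None:
        if self.kind == "sharp":
            if self.threshold is None or self.direction is None:
                raise ValidationError("sharp objective requires threshold and direction")
            direction = Direction(self.direction)
            object.__setattr__(self, "direction", direction)
            thresholds = (
                self.threshold.values()
                if isinstance(self.threshold, Mapping)
                else [self.threshold]
            )
            for t in thresholds:
                if not math.isfinite(float(t)):
                    raise ValidationError("sharp threshold must be finite")
                if direction is Direction.MUST_NOT_FALL_SHORT and float(t) <= 0:
                    raise ValidationError(
                        "shortfall threshold must be strictly positive "
                        "(excursions divide by it)"
                    )
        elif self.kind == "fuzzy":
            if self.threshold is not None or self.direction is not None:
                raise ValidationError("fuzzy objective carries no numeric fields")
        else:
            raise ValidationError(f"unknown objective kind: {self.kind!r}")

    def threshold_at(self, key: Key) -> float:
        """Threshold for one (unit, instance); broadcasts a scalar."""
        if self.kind != "sharp":
            raise ValidationError("fuzzy objective has no thresholds")
        if isinstance(self.threshold, Mapping):
            try:
                return float(self.threshold[key])
            except KeyError:
                raise ValidationError(f"no threshold for {key}") from None
        return float(self.threshold)


@dataclass(frozen=True)
class DimensionScores:
    """The three delivery dimensions plus their raw ingredients.

    * ``f1`` (scope): % of units that failed their objective at least once.
    * ``f2`` (frequency): % of all monitored instances that failed.
    * ``nse``: normalized sum of excursions — total excursion over *all*
      monitored instances (embeds frequency).
    * ``moe``: mean excursion over *failing* instances only (pure amplitude).
    * ``f3_nse`` / ``f3_moe``: the two amplitude variants scaled onto
      [0, 100) via x/(x+1).
    """

    f1: float
    f2: float
    nse: float
    moe: float
    f3_nse: float
    f3_moe: float
    n_units: int
    n_failing_units: int
    n_instances: int
    n_failing_instances: int

    def __post_init__(self) -> None:
        if not (0 <= self.f1 <= 100 and 0 <= self.f2 <= 100):
            raise ValidationError("f1 and f2 must lie in [0, 100]")
        if self.nse < 0 or self.moe < 0:
            raise ValidationError("excursion aggregates must be non-negative")
        if self.n_failing_instances == 0 and (self.nse or self.moe):
            raise ValidationError("no failures but non-zero excursion aggregate")


@dataclass(frozen=True)
class ESIReport:
    """Composite scores for every method/evidence-level combination.

    ``method_scores[method][level]`` is a score in [0, 100]; M1 exists
    only at level 3, while M2 and M3 share identical level-1 and level-2
    scores (those levels do not involve amplitude).
    """

    method_scores: Mapping[str, Mapping[int, float]]
    dimensions: DimensionScores
    objective_echo: str
    rounding: int = 1

    def score(self, method: str, level: int = 3) -> float:
        try:
            return self.method_scores[method][level]
        except KeyError:
            raise KeyError(f"no score for method {method!r} at level {level}") from None


def validate_table(
    table: AssessmentTable, objective: Objective
) -> tuple[AssessmentTable, Objective]:
    """Check the table/objective pair and return it unchanged.

    Structural invariants on each side are enforced by the dataclasses;
    this adds the cross-checks: regime agreement and, for a per-instance
    threshold mapping, coverage of every observation. Idempotent.
    """
    expected = "numeric" if objective.kind == "sharp" else "fuzzy"
    if table.kind != expected:
        raise ValidationError(
            f"kind mismatch: {objective.kind} objective with {table.kind} table"
        )
    if objective.kind == "sharp" and isinstance(objective.threshold, Mapping):
        for key in table.observations:
            objective.threshold_at(key)
    return table, objective
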