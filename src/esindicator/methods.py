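"""Combining the delivery dimensions into an Ecosystem Service Indicator.

Three combination methods, each mapping dimension percentages onto a
0 (no delivery) - 100 (full delivery) score:

* **M1** — the CCME Water Quality Index combination,
  ``100 - sqrt((F1^2 + F2^2 + F3^2) / 3)`` with the nse-based F3. Since
  nse already embeds frequency, M1 double-counts F2; it is kept as the
  reference formulation and exists only at full evidence (level 3).
* **M2** — ``100 - sqrt(F1 * F3)`` with the nse-based F3: scope paired
  with an amplitude term that carries frequency inside it, avoiding the
  double count.
* **M3** — ``100 - cbrt(F1 * F2 * F3)`` with the moe-based F3: all three
  dimensions enter once, amplitude taken over failing instances only.

Evidence levels track how much data the assessment had: level 1 uses
scope only (``100 - F1``), level 2 adds frequency (``100 -
sqrt(F1 * F2)``), level 3 adds amplitude. Levels 1-2 are identical for
M2 and M3 and undefined for M1.
"""

from __future__ import annotations

import math

from .core import (
    AssessmentTable,
    DimensionScores,
    ESIReport,
    Objective,
    ValidationError,
    validate_table,
)
from .dimensions import score_dimensions

METHODS = ("M1", "M2", "M3")
LEVELS = (1, 2, 3)


def _check_percent(name: str, x: float) -> float:
    if not (0.0 <= x <= 100.0):
        raise ValidationError(f"{name} out of range [0, 100]: {x!r}")
    return float(x)


def _clamp(score: float) -> float:
    # absorbs float representation error at the extremes
    return min(100.0, max(0.0, score))


def esi_m1(f1: float, f2: float, f3_nse: float) -> float:
    """M1 (CCME-style) combined score at evidence level 3."""
    f1 = _check_percent("f1", f1)
    f2 = _check_percent("f2", f2)
    f3 = _check_percent("f3_nse", f3_nse)
    return _clamp(100.0 - math.sqrt((f1 * f1 + f2 * f2 + f3 * f3) / 3.0))


def esi_m2(f1: float, f2: float, f3_nse: float, level: int = 3) -> float:
    """M2 combined score at the requested evidence level."""
    f1 = _check_percent("f1", f1)
    f2 = _check_percent("f2", f2)
    f3 = _check_percent("f3_nse", f3_nse)
    if level == 1:
        return _clamp(100.0 - f1)
    if level == 2:
        return _clamp(100.0 - math.sqrt(f1 * f2))
    if level == 3:
        return _clamp(100.0 - math.sqrt(f1 * f3))
    raise ValidationError(f"unknown evidence level: {level!r}")


def esi_m3(f1: float, f2: float, f3_moe: float, level: int = 3) -> float:
    """M3 combined score at the requested evidence level."""
    f1 = _check_percent("f1", f1)
    f2 = _check_percent("f2", f2)
    f3 = _check_percent("f3_moe", f3_moe)
    if level == 1:
        return _clamp(100.0 - f1)
    if level == 2:
        return _clamp(100.0 - math.sqrt(f1 * f2))
    if level == 3:
        return _clamp(100.0 - math.cbrt(f1 * f2 * f3))
    raise ValidationError(f"unknown evidence level: {level!r}")


def score_methods(dims: DimensionScores) -> dict[str, dict[int, float]]:
    """All method/level scores computable from a full set of dimensions."""
    return {
        "M1": {3: esi_m1(dims.f1, dims.f2, dims.f3_nse)},
        "M2": {
            1: esi_m2(dims.f1, dims.f2, dims.f3_nse, level=1),
            2: esi_m2(dims.f1, dims.f2, dims.f3_nse, level=2),
            3: esi_m2(dims.f1, dims.f2, dims.f3_nse, level=3),
        },
        "M3": {
            1: esi_m3(dims.f1, dims.f2, dims.f3_moe, level=1),
            2: esi_m3(dims.f1, dims.f2, dims.f3_moe, level=2),
            3: esi_m3(dims.f1, dims.f2, dims.f3_moe, level=3),
        },
    }


def assess(
    table: AssessmentTable,
    objective: Objective,
    *,
    max_level: int = 3,
    rounding: int = 1,
) -> ESIReport:
    """Score a table end to end: classify, dimensions, every method/level.

    ``max_level`` caps the evidence level actually reported, mimicking an
    assessment where frequency or amplitude data were unavailable. M1 is
    reported only when level 3 is reachable. Scores are kept at full
    precision; ``rounding`` is display metadata consumed at serialization.
    """
    validate_table(table, objective)
    if max_level not in LEVELS:
        raise ValidationError(f"evidence level must be 1, 2 or 3, got {max_level!r}")
    dims = score_dimensions(table, objective)
    scores = score_methods(dims)
    if max_level < 3:
        scores.pop("M1")
        for method_levels in scores.values():
            for level in (2, 3):
                if level > max_level:
                    method_levels.pop(level)
    if objective.kind == "sharp":
        echo = f"sharp threshold, direction={objective.direction.value}"  # type: ignore[union-attr]
    else:
        echo = "fuzzy ranks 1-10"
    return ESIReport(
        method_scores=scores,
        dimensions=dims,
        objective_echo=echo,
        rounding=rounding,
    )
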