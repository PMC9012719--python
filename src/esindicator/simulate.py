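"""Monte-Carlo generator of synthetic supply-reliability tables.

The sensitivity study stresses the indicator with tables drawn under two
per-table controls:

* **probability of failure (PoF)** — each instance independently fails
  with this probability (Bernoulli per cell);
* **range of failure (RoF)** — a failing instance's value is drawn
  uniformly on ``(threshold * (1 - RoF/100), threshold)``, so RoF caps
  how far below the threshold supply may drop.

Compliant cells sit exactly at the threshold: reliability cannot exceed
100%, and any at-or-above-threshold value leaves every score unchanged,
so the degenerate choice is also the simplest. Failing values are
rounded to ``value_decimals`` (default 1, as reliability series are
typically reported); rounding can land a failing draw exactly on the
threshold, producing a zero-excursion "failure" that re-classifies as
compliant. Values are floored at ``value_floor`` so the shortfall
excursion (threshold/value - 1) stays finite when RoF approaches 100.

A study draws PoF and RoF per table uniformly on configurable ranges,
scores every table with all methods and levels, and discards
* repeated no-failure tables (the first fully compliant table is kept,
  later ones dropped as duplicates of the same state), and
* tables whose intended failures all rounded onto the threshold
  (zero excursion everywhere — an artifact of value precision).

Randomness comes from one ``numpy`` PCG64 stream, consumed in a fixed
documented order per table: PoF, RoF, then one failure uniform per cell
(unit-major), then one value uniform per cell. Value uniforms are drawn
for every cell, used only where the cell failed, which keeps the stream
layout independent of the failure pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AssessmentTable,
    DimensionScores,
    Direction,
    ESIReport,
    FuzzyRecord,
    Objective,
    ValidationError,
)
from .dimensions import scale_amplitude
from .methods import esi_m1, esi_m2, esi_m3

DISCARD_NONE = "none"
DISCARD_NO_FAILURE_REPEAT = "no_failure_repeat"
DISCARD_ALL_ZERO_EXCURSION = "all_zero_excursion"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the Monte-Carlo sensitivity analysis.

    Defaults mirror the reference scenario: 10,000 tables shaped like a
    17-unit x 12-month supply-reliability dataset judged against a 100%
    reliability threshold (shortfall direction), with PoF and RoF each
    uniform over the full 0-100% range.
    """

    n_tables: int = 10_000
    n_units: int = 17
    n_instances_per_unit: int = 12
    threshold: float = 100.0
    pof_range: tuple[float, float] = (0.0, 100.0)
    rof_range: tuple[float, float] = (0.0, 100.0)
    seed: int = 0
    value_decimals: int = 1
    value_floor: float = 0.1
    discard_all_no_failure: bool = False  # drop even the first all-pass table

    def __post_init__(self) -> None:
        if self.n_tables < 1 or self.n_units < 1 or self.n_instances_per_unit < 1:
            raise ValidationError("table counts and shape must be positive")
        for lo, hi in (self.pof_range, self.rof_range):
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValidationError("pof/rof ranges must be sub-intervals of [0, 100]")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if not (0 < self.value_floor < self.threshold):
            raise ValidationError("value_floor must lie in (0, threshold)")
        if self.value_decimals < 0:
            raise ValidationError("value_decimals must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.n_units * self.n_instances_per_unit

    def objective(self) -> Objective:
        return Objective(
            kind="sharp",
            threshold=self.threshold,
            direction=Direction.MUST_NOT_FALL_SHORT,
        )


@dataclass(frozen=True)
class SimulatedTableResult:
    """Outcome of scoring one generated table."""

    table_index: int
    pof: float
    rof: float
    dimensions: DimensionScores
    scores: ESIReport
    discarded: bool
    discard_reason: str = DISCARD_NONE

    def __post_init__(self) -> None:
        if self.discarded == (self.discard_reason == DISCARD_NONE):
            raise ValidationError("discard flag and reason disagree")


@dataclass(frozen=True)
class StudySummary:
    """Bookkeeping for one study run."""

    n_tables: int
    n_retained: int
    n_discarded_no_failure_repeat: int
    n_discarded_all_zero_excursion: int
    seed: int


@dataclass
class StudyResult:
    config: SimulationConfig
    results: list[SimulatedTableResult] = field(default_factory=list)

    @property
    def retained(self) -> list[SimulatedTableResult]:
        return [r for r in self.results if not r.discarded]

    def summary(self) -> StudySummary:
        reasons = [r.discard_reason for r in self.results]
        return StudySummary(
            n_tables=len(self.results),
            n_retained=len(self.retained),
            n_discarded_no_failure_repeat=reasons.count(DISCARD_NO_FAILURE_REPEAT),
            n_discarded_all_zero_excursion=reasons.count(DISCARD_ALL_ZERO_EXCURSION),
            seed=self.config.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per table, the study's tabular export schema."""
        rows = []
        for r in self.results:
            d = r.dimensions
            rows.append(
                {
                    "table_index": r.table_index,
                    "pof": r.pof,
                    "rof": r.rof,
                    "f1": d.f1,
                    "f2": d.f2,
                    "f3_nse": d.f3_nse,
                    "f3_moe": d.f3_moe,
                    "esi1": r.scores.score("M2", 1),
                    "esi2": r.scores.score("M2", 2),
                    "esi3_m1": r.scores.score("M1", 3),
                    "esi3_m2": r.scores.score("M2", 3),
                    "esi3_m3": r.scores.score("M3", 3),
                    "discarded": r.discarded,
                    "discard_reason": r.discard_reason,
                }
            )
        return pd.DataFrame(rows)


def _draw_cells(
    pof: float, rof: float, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one table's value matrix; returns (values, intended_failure).

    Consumes the stream as documented: n_cells failure uniforms in
    unit-major order, then n_cells value uniforms.
    """
    shape = (config.n_units, config.n_instances_per_unit)
    fail = rng.random(shape) < pof / 100.0
    u = rng.random(shape)
    low = config.threshold * (1.0 - rof / 100.0)
    values = np.round(low + u * (config.threshold - low), config.value_decimals)
    values = np.maximum(values, config.value_floor)
    values = np.where(fail, values, config.threshold)
    return values, fail


def generate_table(
    pof: float,
    rof: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> AssessmentTable:
    """Generate one synthetic reliability table at the given PoF and RoF."""
    if not (0.0 <= pof <= 100.0 and 0.0 <= rof <= 100.0):
        raise ValidationError("pof and rof must lie in [0, 100]")
    values, _ = _draw_cells(pof, rof, config, rng)
    obs = {
        (f"U{u:02d}", f"T{t:02d}"): float(values[u, t])
        for u in range(config.n_units)
        for t in range(config.n_instances_per_unit)
    }
    return AssessmentTable.from_numeric(obs)


def _score_cells(
    values: np.ndarray, config: SimulationConfig
) -> tuple[DimensionScores, dict[str, dict[int, float]]]:
    """Vectorized scoring of one table's value matrix.

    Equivalent to building the :class:`AssessmentTable` and calling
    :func:`esindicator.methods.assess`; the array route keeps a 10,000-table
    study to seconds. The equivalence is exercised in the test suite.
    """
    failing = values < config.threshold
    n_cells = values.size
    n_failing = int(failing.sum())
    n_failing_units = int(failing.any(axis=1).sum())
    f1 = 100.0 * n_failing_units / config.n_units
    f2 = 100.0 * n_failing / n_cells
    if n_failing:
        ex = config.threshold / values[failing] - 1.0
        total = float(ex.sum())
        nse = total / n_cells
        moe = total / n_failing
    else:
        nse = moe = 0.0
    dims = DimensionScores(
        f1=f1,
        f2=f2,
        nse=nse,
        moe=moe,
        f3_nse=scale_amplitude(nse),
        f3_moe=scale_amplitude(moe),
        n_units=config.n_units,
        n_failing_units=n_failing_units,
        n_instances=n_cells,
        n_failing_instances=n_failing,
    )
    scores = {
        "M1": {3: esi_m1(dims.f1, dims.f2, dims.f3_nse)},
        "M2": {
            1: esi_m2(dims.f1, dims.f2, dims.f3_nse, 1),
            2: esi_m2(dims.f1, dims.f2, dims.f3_nse, 2),
            3: esi_m2(dims.f1, dims.f2, dims.f3_nse, 3),
        },
        "M3": {
            1: esi_m3(dims.f1, dims.f2, dims.f3_moe, 1),
            2: esi_m3(dims.f1, dims.f2, dims.f3_moe, 2),
            3: esi_m3(dims.f1, dims.f2, dims.f3_moe, 3),
        },
    }
    return dims, scores


def run_study(config: SimulationConfig) -> StudyResult:
    """Run the full Monte-Carlo study under the given conditions."""
    rng = np.random.default_rng(config.seed)
    pof_lo, pof_hi = config.pof_range
    rof_lo, rof_hi = config.rof_range
    result = StudyResult(config=config)
    seen_no_failure = False
    for idx in range(config.n_tables):
        pof = float(rng.uniform(pof_lo, pof_hi))
        rof = float(rng.uniform(rof_lo, rof_hi))
        values, intended = _draw_cells(pof, rof, config, rng)
        dims, scores = _score_cells(values, config)

        discarded = False
        reason = DISCARD_NONE
        if not intended.any():
            # genuinely failure-free table
            if seen_no_failure or config.discard_all_no_failure:
                discarded, reason = True, DISCARD_NO_FAILURE_REPEAT
            seen_no_failure = True
        elif dims.n_failing_instances == 0:
            # failures were drawn but every value rounded onto the threshold
            discarded, reason = True, DISCARD_ALL_ZERO_EXCURSION

        report = ESIReport(
            method_scores=scores,
            dimensions=dims,
            objective_echo=f"sharp threshold {config.threshold}, direction=must_not_fall_short",
        )
        result.results.append(
            SimulatedTableResult(
                table_index=idx,
                pof=pof,
                rof=rof,
                dimensions=dims,
                scores=report,
                discarded=discarded,
                discard_reason=reason,
            )
        )
    return result


# ---------------------------------------------------------------------------
# Worked example: Dongjiang basin water-supply reliability, 1991 drought year
# ---------------------------------------------------------------------------

_MUNICIPALITIES = ("Heyuan", "Huizhou", "Dongguan", "HongKong", "Shenzhen", "Guangzhou")
_SECTORS = ("R", "I", "A")  # residential, industry, agriculture
_MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
_FAILING_UNITS = (
    "Huizhou-R", "Huizhou-I", "Huizhou-A",
    "Dongguan-R", "Dongguan-I", "Dongguan-A",
    "Guangzhou-R", "Guangzhou-I", "Guangzhou-A",
)
_FAILING_MONTHS = ("Feb", "Mar", "Apr", "May")
# 100 / 25.85 - 1 = 2.8685: nse = 36 * 2.8685 / 204 scales to F3 = 33.6
_FAILING_VALUE = 25.85


def dongjiang_units() -> list[str]:
    """The 17 municipality-sector units (Hong Kong has no agriculture)."""
    return [
        f"{m}-{s}"
        for m in _MUNICIPALITIES
        for s in _SECTORS
        if not (m == "HongKong" and s == "A")
    ]


def dongjiang_fixture() -> tuple[AssessmentTable, Objective]:
    """Reconstructed monthly water-supply reliability for the Dongjiang.

    A synthetic stand-in for the 1991 drought-year reliability table:
    it is built backwards from the published summary of that assessment
    (9 of 17 municipality-sector units failing, 36 of 204 monthly
    instances failing in February-May, amplitude placing the nse-based
    F3 at 33.6) rather than from the hydrological model behind the
    original. Scoring it reproduces the published sharp-threshold scores
    to within rounding.
    """
    obs: dict[tuple[str, str], float] = {}
    for unit in dongjiang_units():
        for month in _MONTHS:
            failing = unit in _FAILING_UNITS and month in _FAILING_MONTHS
            obs[(unit, month)] = _FAILING_VALUE if failing else 100.0
    objective = Objective(
        kind="sharp", threshold=100.0, direction=Direction.MUST_NOT_FALL_SHORT
    )
    return AssessmentTable.from_numeric(obs), objective


def dongjiang_fuzzy_fixture(rank: float) -> tuple[AssessmentTable, Objective]:
    """Fuzzy-threshold variant: every failing instance carries one rank.

    With rank 1 or 10 this reproduces the published fuzzy rows (all
    failures judged minimal, or all judged maximal).
    """
    sharp_table, _ = dongjiang_fixture()
    records = {
        key: (
            FuzzyRecord(failed=True, rank=float(rank))
            if float(value) < 100.0
            else FuzzyRecord(failed=False)
        )
        for key, value in sharp_table.observations.items()
    }
    return AssessmentTable.from_fuzzy(records), Objective(kind="fuzzy")
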