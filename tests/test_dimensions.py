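import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esindicator import (
    AssessmentTable,
    Direction,
    ExcursionSet,
    FuzzyRecord,
    Objective,
    ValidationError,
    classify_failures,
    compute_excursions,
    compute_frequency,
    compute_scope,
    excursion,
    fuzzy_excursion,
    mean_of_excursions,
    normalized_sum_excursions,
    scale_amplitude,
    score_dimensions,
)

SHORT = Direction.MUST_NOT_FALL_SHORT
EXCEED = Direction.MUST_NOT_EXCEED


def sharp(threshold=100.0, direction=SHORT):
    return Objective(kind="sharp", threshold=threshold, direction=direction)


class TestClassification:
    @pytest.mark.parametrize(
        "value,direction,expect_fail",
        [
            (99.9, SHORT, True),
            (100.0, SHORT, False),  # equality complies
            (100.1, SHORT, False),
            (100.0, EXCEED, False),
            (100.1, EXCEED, True),
        ],
    )
    def test_sharp_boundary(self, value, direction, expect_fail):
        table = AssessmentTable.from_numeric({("U", "T"): value})
        flags = classify_failures(table, sharp(direction=direction))
        assert flags[("U", "T")] is expect_fail

    def test_exceedance_objective_soil_erosion(self):
        # erosion of 30 t/ha/yr against a 20 t/ha/yr ceiling fails
        table = AssessmentTable.from_numeric({("basin", "2000"): 30.0})
        obj = sharp(threshold=20.0, direction=EXCEED)
        assert classify_failures(table, obj)[("basin", "2000")]
        assert excursion(30.0, 20.0, EXCEED) == pytest.approx(0.5)

    def test_fuzzy_flags_copied(self):
        table = AssessmentTable.from_fuzzy(
            {("U", "a"): FuzzyRecord(True, 4.0), ("U", "b"): FuzzyRecord(False)}
        )
        flags = classify_failures(table, Objective(kind="fuzzy"))
        assert flags == {("U", "a"): True, ("U", "b"): False}


class TestExcursion:
    @pytest.mark.parametrize(
        "value,threshold,direction,expected",
        [
            (80.0, 100.0, SHORT, 0.25),
            (100.0, 100.0, SHORT, 0.0),
            (30.0, 20.0, EXCEED, 0.5),
            (20.0, 20.0, EXCEED, 0.0),
        ],
    )
    def test_relative_gap(self, value, threshold, direction, expected):
        assert excursion(value, threshold, direction) == pytest.approx(expected)

    def test_nonpositive_value_under_shortfall_points_to_floor_policy(self):
        with pytest.raises(ValidationError, match="value_floor"):
            excursion(0.0, 100.0, SHORT)

    def test_fuzzy_excursion_is_identity_on_ranks(self):
        assert fuzzy_excursion(1) == 1.0
        assert fuzzy_excursion(10) == 10.0
        assert fuzzy_excursion(5.5) == 5.5
        with pytest.raises(ValidationError):
            fuzzy_excursion(10.5)


class TestAggregates:
    def test_nse_and_moe_from_uniform_excursions(self):
        # 36 failing instances of 204, all with unit excursion
        exs = ExcursionSet(
            records=tuple(("U", str(i), 1.0) for i in range(36)), total_instances=204
        )
        assert normalized_sum_excursions(exs) == pytest.approx(36 / 204)
        assert mean_of_excursions(exs) == pytest.approx(1.0)

    def test_zero_failures_conventions(self):
        exs = ExcursionSet(records=(), total_instances=10)
        assert normalized_sum_excursions(exs) == 0.0
        assert mean_of_excursions(exs) == 0.0

    @pytest.mark.parametrize(
        "x,expected", [(0.0, 0.0), (1.0, 50.0), (10.0, 100 * 10 / 11), (0.50601, 33.6)]
    )
    def test_scale_amplitude(self, x, expected):
        assert scale_amplitude(x) == pytest.approx(expected, abs=0.05)

    def test_scale_amplitude_rejects_negative(self):
        with pytest.raises(ValidationError):
            scale_amplitude(-0.1)


# -- brute-force oracle ------------------------------------------------------


def oracle_dimensions(table, objective):
    """Direct per-instance enumeration, independent of the library path."""
    failing = {}
    for key, payload in table.observations.items():
        if objective.kind == "fuzzy":
            failing[key] = payload.failed
        elif objective.direction is SHORT:
            failing[key] = payload < objective.threshold_at(key)
        else:
            failing[key] = payload > objective.threshold_at(key)
    units = {u for (u, _) in table.observations}
    failed_units = {u for (u, _), f in failing.items() if f}
    f1 = 100 * len(failed_units) / len(units)
    f2 = 100 * sum(failing.values()) / len(failing)
    exs = []
    for key, f in failing.items():
        if not f:
            continue
        payload = table.observations[key]
        if objective.kind == "fuzzy":
            exs.append(payload.rank)
        elif objective.direction is SHORT:
            exs.append(objective.threshold_at(key) / payload - 1)
        else:
            exs.append(payload / objective.threshold_at(key) - 1)
    nse = sum(exs) / len(failing)
    moe = sum(exs) / len(exs) if exs else 0.0
    return f1, f2, nse, moe


VALUE_GRID = [25.0, 50.0, 99.9, 100.0, 150.0]
RANK_GRID = [1.0, 5.5, 10.0]


@st.composite
def small_numeric_case(draw):
    n_units = draw(st.integers(1, 3))
    n_inst = draw(st.integers(1, 3))
    obs = {
        (f"U{u}", f"T{t}"): draw(st.sampled_from(VALUE_GRID))
        for u in range(n_units)
        for t in range(n_inst)
    }
    direction = draw(st.sampled_from([SHORT, EXCEED]))
    return AssessmentTable.from_numeric(obs), sharp(100.0, direction)


@st.composite
def small_fuzzy_case(draw):
    n_units = draw(st.integers(1, 3))
    n_inst = draw(st.integers(1, 3))
    obs = {}
    for u in range(n_units):
        for t in range(n_inst):
            failed = draw(st.booleans())
            rank = draw(st.sampled_from(RANK_GRID)) if failed else None
            obs[(f"U{u}", f"T{t}")] = FuzzyRecord(failed=failed, rank=rank)
    return AssessmentTable.from_fuzzy(obs), Objective(kind="fuzzy")


@settings(max_examples=200, derandomize=True)
@given(case=st.one_of(small_numeric_case(), small_fuzzy_case()))
def test_bruteforce_oracle_equivalence_on_small_tables(case):
    """Dimension pipeline matches direct enumeration on tiny tables."""
    table, objective = case
    f1, f2, nse, moe = oracle_dimensions(table, objective)
    dims = score_dimensions(table, objective)
    assert dims.f1 == pytest.approx(f1, abs=1e-12)
    assert dims.f2 == pytest.approx(f2, abs=1e-12)
    assert dims.nse == pytest.approx(nse, abs=1e-12)
    assert dims.moe == pytest.approx(moe, abs=1e-12)
    assert dims.f3_nse == pytest.approx(100 * nse / (nse + 1), abs=1e-9)
    assert dims.f3_moe == pytest.approx(100 * moe / (moe + 1), abs=1e-9)


@settings(max_examples=200, derandomize=True)
@given(case=st.one_of(small_numeric_case(), small_fuzzy_case()))
def test_dimension_invariants(case):
    """Bounds, zero-coupling, and the moe >= nse ordering."""
    table, objective = case
    dims = score_dimensions(table, objective)
    for x in (dims.f1, dims.f2, dims.f3_nse, dims.f3_moe):
        assert 0.0 <= x <= 100.0
    assert dims.nse >= 0 and dims.moe >= 0
    # F1 = 0 <=> F2 = 0 <=> no excursions
    zero = dims.n_failing_instances == 0
    assert (dims.f1 == 0) == zero == (dims.f2 == 0) == (dims.nse == dims.moe == 0)
    assert dims.moe >= dims.nse - 1e-12
    assert dims.f3_moe >= dims.f3_nse - 1e-9
    # equal instance counts per unit by construction: F2 <= F1
    assert dims.f2 <= dims.f1 + 1e-12


def test_scope_and_frequency_limits():
    all_fail = AssessmentTable.from_numeric(
        {(f"U{u}", f"T{t}"): 50.0 for u in range(3) for t in range(4)}
    )
    none_fail = AssessmentTable.from_numeric(
        {(f"U{u}", f"T{t}"): 100.0 for u in range(3) for t in range(4)}
    )
    obj = sharp()
    f_all = classify_failures(all_fail, obj)
    f_none = classify_failures(none_fail, obj)
    assert compute_scope(f_all) == 100.0 and compute_frequency(f_all) == 100.0
    assert compute_scope(f_none) == 0.0 and compute_frequency(f_none) == 0.0


def test_missing_observations_stay_out_of_denominators():
    # unit B monitored only once; the absent months are not failures
    table = AssessmentTable.from_numeric(
        {("A", "T1"): 50.0, ("A", "T2"): 100.0, ("B", "T1"): 100.0}
    )
    dims = score_dimensions(table, sharp())
    assert dims.n_instances == 3
    assert dims.f2 == pytest.approx(100 / 3)
    assert dims.f1 == pytest.approx(50.0)
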