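# Methods

## The indicator model

An assessment partitions a study area into *spatial units* (sub-basins,
monitoring stations, municipality-sector pairs) observed at *instances*
(months, annual maps, a single static layer). Instance labels are
opaque ordered strings: the framework deliberately imposes no calendar
semantics, because real assessments mix monthly series, annual rasters
and static maps, and units may carry unequal instance counts. Missing
observations are simply absent — they never enter a denominator and
never count as failures.

Demand enters as an *objective*. A **sharp** objective is a finite
numeric threshold with a direction; equality complies in both
directions, so a zero-excursion "failure" cannot arise from the
classification itself (such artifacts can still be produced upstream by
value rounding; see the discard rules). A shortfall threshold must be
strictly positive because the excursion divides by it. A **fuzzy**
objective carries no numbers: the data themselves record a failure flag
and, on failure, a severity rank in [1, 10]. Ranks may be fractional —
stakeholder elicitation and multi-criteria scoring routinely average to
non-integers — and the rank is used directly as the excursion, so the
two fixed points are rank 1 → F3(moe) = 50 and rank 10 → F3(moe) = 90.9.

Failure information is condensed along three dimensions — scope F1,
frequency F2, amplitude F3 — and combined by three methods (M1 the
CCME-style root-mean-square; M2 the geometric mean of scope with the
nse-based amplitude; M3 the cube-root product with the moe-based
amplitude) at up to three evidence levels. The pairing of amplitude
variant to method is fixed by construction: nse (which embeds
frequency) feeds M1 and M2, moe (pure amplitude over failing instances)
feeds M3. M1 exists only at full evidence; requesting it at level 1–2
is an error rather than a silent fallback, since its level-1/2 formulas
would be indistinguishable from M2/M3's and the method label would be
misleading.

Numerical conventions:

* `moe` on zero failures is defined as 0 (rather than undefined), so a
  fully compliant table flows to a score of exactly 100 on every
  method/level without branching.
* No rounding occurs inside computations. Display rounding (default 1
  decimal, half away from zero, the convention of published score
  tables) is applied only at report serialization, and reports always
  co-serialize the raw doubles. Consequence for the worked example: the
  level-2 score prints as 69.4 from unrounded inputs, while feeding the
  formula with *rounded* F1/F2 gives 69.5 — score tables assembled by
  hand can differ in the last digit depending on the rounding path, and
  the raw values in the report are authoritative.
* Combined scores are clamped to [0, 100] after floating-point
  combination; the M3 cube root uses `math.cbrt` so the all-100 corner
  maps to exactly 0.

## The worked example

`dongjiang_fixture()` reconstructs a drought-year water-supply
reliability assessment over 17 municipality-sector units × 12 months
(six municipalities × residential/industry/agriculture, one coastal
municipality without agriculture). It is a synthetic stand-in built
backwards from that assessment's published summary — 9 of 17 units
failing, 36 of 204 instances failing in February–May, nse-based F3 at
33.6 — not from the hydrological model behind the original. All failing
cells share the value 25.85 (excursion 100/25.85 − 1 ≈ 2.8685), the
single value for which the summary statistics are reproduced
simultaneously: F1 = 52.9, F2 = 17.6, F3(nse) = 33.6, F3(moe) = 74.2
after display rounding. `dongjiang_fuzzy_fixture(rank)` keeps the
failure pattern and replaces magnitudes with one uniform rank.

## The Monte-Carlo generator

The simulator emulates supply-reliability assessment tables, not the
hydrology that produces them. Each table is governed by two per-table
controls drawn uniformly on (configurable sub-ranges of) 0–100%:

* **probability of failure (PoF)** — each cell independently fails with
  probability PoF/100 (Bernoulli), so E[F2 | PoF] = PoF and, with 12
  instances per unit, E[F1] saturates quickly in PoF;
* **range of failure (RoF)** — a failing cell's value is drawn
  uniformly on `(threshold·(1 − RoF/100), threshold)`, capping how deep
  failures may go.

Defaults define the study conditions: 10,000 tables of 17 units × 12
instances against a sharp shortfall threshold of 100 (percent
reliability), full 0–100% ranges for both controls.

Choices the generator makes where the abstraction is open:

* **Compliant cells sit exactly at the threshold.** Reliability cannot
  exceed 100%, and any at-or-above-threshold law leaves every score
  unchanged, so the degenerate distribution is the simplest faithful
  choice.
* **Uniform failing values.** No particular law is implied by the
  "bounded below the threshold" construction; uniform on the RoF-bounded
  interval is the minimal assumption.
* **Rounding** failing values to `value_decimals = 1` reflects how
  reliability series are reported, and is what makes the all-zero-
  excursion discard class reachable at all: a draw within 0.05 of the
  threshold rounds onto it. With rounding effectively off
  (`value_decimals = 6`) that class has measure zero, which the tests
  assert.
* **`value_floor = 0.1`** keeps the shortfall excursion
  (threshold/value − 1) finite when RoF approaches 100 and a rounded
  draw would otherwise hit 0. It is configurable and echoed in logs.
* **Determinism.** One PCG64 stream seeded once, consumed in a fixed
  documented order per table — PoF, RoF, one failure uniform per cell
  (unit-major), one value uniform per cell (drawn for every cell, used
  only where the cell failed, so the stream layout is independent of
  the failure pattern). Identical seed and config reproduce the study
  bit for bit.

**Discard rules.** A table with no failures at all is retained the
first time (the no-failure state is informative once) and discarded as
a repetition afterwards; `discard_all_no_failure=True` selects the
stricter reading that drops every such table. A table whose Bernoulli
draws produced failures but whose values all rounded onto the threshold
is discarded as an artifact (`all_zero_excursion`). Under the default
conditions discards total roughly 0.5% of tables — the expected number
of fully compliant tables is `n/(204 + 1) ≈ 49` of 10,000 (integrating
`(1 − p)^204` over uniform PoF), plus a handful of zero-excursion
artifacts concentrated at very small RoF.

**Interpretation limits.** Because every instance is i.i.d. Bernoulli
given PoF, the generator has no seasonality, spatial correlation among
units, or autocorrelation in time — features real reliability series
have. Passing tests therefore certify the indicator's algebra and its
sensitivity structure under controlled failure regimes, not its
behavior on serially correlated basin data. The frequency dimension is
unbiased for PoF up to the rounding reclassification (failures that
round onto the threshold become compliant, depressing F2 by ~0.4%
relative when RoF spans the full range); the unbiasedness test pins RoF
at 50 where that effect is negligible.

**Scoring path.** `run_study` scores each table through a vectorized
array routine sharing its generation code with `generate_table`; the
test suite asserts the array route and the object route
(`AssessmentTable` → `assess`) agree to 1e-12 on sampled tables. The
full 10,000-table study runs in about a second, so no scaled-down
variant is needed anywhere.

## Analysis

Summaries run over retained tables only. Correlation and regression
primitives wrap `scipy.stats` (`pearsonr`, `linregress`,
`binned_statistic_2d`); the test suite keeps an independent textbook
two-pass implementation as the oracle against which both are checked to
1e-12. Hexagonal display binning is replaced by rectangular bin grids
exported as tables — binning is a display choice, not a statistic — and
cell counts are asserted to conserve the retained-table total.

Under the default study the expected fingerprints hold: F2 regressed on
PoF gives R² ≈ 0.99; every score is negatively correlated with every
dimension; M1 is scope-dominated (|r| with F1 exceeds |r| with F3)
while M2 is amplitude-dominated; M2 and M3 agree more closely with each
other than either does with M1; and within PoF bands (0–10, 20–30,
40–50%) the level-2 score tracks the full-evidence score better than
the level-1 score does, with both correlations and band mean scores
decreasing as failures become pervasive. In the highest band those
evidence-level correlations are close to zero (scope saturates at 100,
leaving the reduced scores nearly uninformative), so their ordering is
the least stable of these fingerprints from one random run to another.

## Known limitations

* Fuzzy ranks arrive as data; constructing them (stakeholder surveys,
  multi-criteria composites) is out of scope.
* No geospatial semantics: units are labels, not geometries.
* The F2 ≤ F1 guarantee (and hence ESI₁ ≤ ESI₂) holds only under equal
  instance counts per unit; with ragged monitoring a heavily monitored
  failing unit can push F2 above F1.
* Aggregating several services into a basin-level super-index is out of
  scope; the indicator is per service.
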