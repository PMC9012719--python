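"""Summaries of a Monte-Carlo study: percentiles, correlations, grids.

All statistics are computed over *retained* tables only — discarded
tables (no-failure repeats, all-zero-excursion artifacts) carry no
information about indicator behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .simulate import StudyResult

PERCENTILES = (5, 25, 50, 75, 95)
DEFAULT_POF_BANDS = ((0.0, 10.0), (20.0, 30.0), (40.0, 50.0))
SCORE_COLUMNS = (
    "pof", "rof", "f1", "f2", "f3_nse", "f3_moe",
    "esi1", "esi2", "esi3_m1", "esi3_m2", "esi3_m3",
)


def _retained_frame(results: StudyResult | pd.DataFrame) -> pd.DataFrame:
    frame = results.to_frame() if isinstance(results, StudyResult) else results
    if "discarded" in frame.columns:
        frame = frame[~frame["discarded"].astype(bool)]
    if frame.empty:
        raise ValidationError("no retained tables to summarize")
    return frame.reset_index(drop=True)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson_r needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_r undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def ols_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of the ordinary-least-squares line y ~ x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("ols_r2 needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("ols_r2 undefined for constant x")
    if np.ptp(y) == 0:
        return 0.0
    return float(stats.linregress(x, y).rvalue ** 2)


def summarize(results: StudyResult | pd.DataFrame) -> pd.DataFrame:
    """Percentile table (5/25/50/75/95) of metrics, dimensions and scores."""
    frame = _retained_frame(results)
    cols = [c for c in SCORE_COLUMNS if c in frame.columns]
    table = {
        col: {p: float(np.percentile(frame[col], p)) for p in PERCENTILES}
        for col in cols
    }
    out = pd.DataFrame(table).T
    out.index.name = "variable"
    out.columns = [f"p{p}" for p in PERCENTILES]
    return out


def correlation_matrix(results: StudyResult | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among metrics, dimensions and ESI scores."""
    frame = _retained_frame(results)
    cols = [c for c in SCORE_COLUMNS if c in frame.columns]
    return frame[cols].corr(method="pearson")


def subset_correlations(
    results: StudyResult | pd.DataFrame,
    pof_bands: Sequence[tuple[float, float]] = DEFAULT_POF_BANDS,
) -> pd.DataFrame:
    """Evidence-level agreement within probability-of-failure bands.

    For each PoF band and each of the two methods that define all three
    evidence levels (M2 and M3): the band's mean full-evidence score and
    the correlation of the reduced-evidence scores with it. The reduced
    scores (levels 1 and 2) are method-independent, so each method's
    column pair shares the same predictors.
    """
    frame = _retained_frame(results)
    rows = []
    for lo, hi in pof_bands:
        band = frame[(frame["pof"] >= lo) & (frame["pof"] < hi)]
        if len(band) < 3:
            raise ValidationError(f"pof band [{lo}, {hi}) has too few tables")
        for method, col in (("M2", "esi3_m2"), ("M3", "esi3_m3")):
            rows.append(
                {
                    "pof_lo": lo,
                    "pof_hi": hi,
                    "method": method,
                    "n": len(band),
                    "mean_esi3": float(band[col].mean()),
                    "r_esi1_esi3": pearson_r(band["esi1"], band[col]),
                    "r_esi2_esi3": pearson_r(band["esi2"], band[col]),
                }
            )
    return pd.DataFrame(rows)


def binned_grid(
    results: StudyResult | pd.DataFrame,
    value: str = "esi3_m2",
    x: str = "pof",
    y: str = "rof",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean of one score on a rectangular (x, y) bin grid, with counts.

    A tabular stand-in for a hexbin/heatmap display: one row per cell
    with bin edges, the cell count, and the cell mean (NaN where empty).
    Cell counts sum to the number of retained tables when the bin ranges
    span the data.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be at least 2")
    frame = _retained_frame(results)
    mean_stat, x_edges, y_edges, _ = stats.binned_statistic_2d(
        frame[x], frame[y], frame[value], statistic="mean", bins=n_bins
    )
    count_stat, _, _, _ = stats.binned_statistic_2d(
        frame[x], frame[y], frame[value], statistic="count", bins=n_bins
    )
    rows = []
    for i in range(n_bins):
        for j in range(n_bins):
            rows.append(
                {
                    f"{x}_lo": x_edges[i],
                    f"{x}_hi": x_edges[i + 1],
                    f"{y}_lo": y_edges[j],
                    f"{y}_hi": y_edges[j + 1],
                    "count": int(count_stat[i, j]),
                    f"mean_{value}": float(mean_stat[i, j]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StudyAnalysis:
    """Bundled study summaries ready for serialization."""

    percentiles: pd.DataFrame
    r_matrix: pd.DataFrame
    r2_pairs: Mapping[str, float]
    subset_stats: pd.DataFrame
    grids: Mapping[str, pd.DataFrame] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "percentiles": self.percentiles.to_dict(orient="index"),
            "r_matrix": self.r_matrix.round(6).to_dict(orient="index"),
            "r2_pairs": dict(self.r2_pairs),
            "subset_stats": self.subset_stats.to_dict(orient="records"),
        }


DEFAULT_R2_PAIRS = (
    ("pof", "f1"),
    ("pof", "f2"),
    ("pof", "f3_moe"),
    ("rof", "f1"),
    ("rof", "f2"),
    ("rof", "f3_moe"),
)


def analyze_study(
    results: StudyResult | pd.DataFrame,
    r2_pairs: Sequence[tuple[str, str]] = DEFAULT_R2_PAIRS,
    grid_scores: Sequence[str] = ("esi3_m1", "esi3_m2", "esi3_m3"),
    n_bins: int = 10,
) -> StudyAnalysis:
    """Full analysis pass over one study's retained tables."""
    frame = _retained_frame(results)
    return StudyAnalysis(
        percentiles=summarize(frame),
        r_matrix=correlation_matrix(frame),
        r2_pairs={f"{x}~{y}": ols_r2(frame[x], frame[y]) for x, y in r2_pairs},
        subset_stats=subset_correlations(frame),
        grids={s: binned_grid(frame, value=s, n_bins=n_bins) for s in grid_scores},
    )
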