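"""Per-patient score trajectories: robust trends and clinical-grade correlation.

Each patient contributes a time-ordered series of per-visit symmetry
scores. The per-visit aggregate (mean over available expressions by
default) is median-filtered (window 3, only when at least 3 visits
exist), and the trend slope is the Theil-Sen estimator — the median of
all pairwise slopes — classified as improvement (> +0.001),
deterioration (< -0.001) or no significant change otherwise. Scores are
validated against ordinal clinical grades (0 = normal movement to
6 = near-total restriction) via Spearman rank correlation.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError


class TrendLabel(str, enum.Enum):
    IMPROVEMENT = "improvement"
    DETERIORATION = "deterioration"
    NO_SIGNIFICANT_CHANGE = "no_significant_change"


@dataclasses.dataclass
class VisitScores:
    """Scores of one examination: expression index -> symmetry score."""

    date: datetime.date
    scores: dict[int, float]
    grade: int | None = None  # ordinal clinical grade 0-6, when charted

    def __post_init__(self) -> None:
        for idx, s in self.scores.items():
            if not 2 <= idx <= 9:
                raise ValueError(f"expression index {idx} outside 2..9")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} outside [0, 1]")
        if self.grade is not None and not 0 <= int(self.grade) <= 6:
            raise ValueError(f"clinical grade {self.grade} outside 0..6")


@dataclasses.dataclass
class ScoreSeries:
    """Time-ordered per-patient visits."""

    patient_id: str
    entries: list[VisitScores]

    def __post_init__(self) -> None:
        dates = [e.date for e in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("entries must be strictly ordered by date")


@dataclasses.dataclass
class TrendResult:
    slope: float  # score units per examination step (or per day)
    label: TrendLabel
    n_points: int


def aggregate_visit_score(
    scores: dict[int, float] | Sequence[float], method: str = "mean"
) -> float:
    """Collapse one visit's expression scores to a single value.

    method: "mean" (default), "median", or an expression index ("2".."9")
    to track a single expression.
    """
    if isinstance(scores, dict):
        if method.isdigit():
            idx = int(method)
            if idx not in scores:
                raise ValueError(f"expression {idx} missing from visit")
            return float(scores[idx])
        values = np.array(list(scores.values()), dtype=np.float64)
    else:
        values = np.asarray(scores, dtype=np.float64)
    if values.size == 0:
        raise ValueError("no expression scores to aggregate")
    if method == "mean":
        return float(values.mean())
    if method == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregate method {method!r}")


def rolling_median(values: Sequence[float], window: int = 3) -> np.ndarray:
    """Centered rolling median; series shorter than the window pass through.

    End points use shrunken asymmetric windows so the output has the
    same length as the input.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < window:
        return arr.copy()
    return (
        pd.Series(arr)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def theil_sen_slope(t: Sequence[float], y: Sequence[float]) -> float:
    """Median of all pairwise slopes (y_j - y_i) / (t_j - t_i), i < j."""
    t_arr = np.asarray(t, dtype=np.float64)
    y_arr = np.asarray(y, dtype=np.float64)
    if t_arr.size != y_arr.size:
        raise ValueError("t and y must have equal length")
    if np.unique(t_arr).size < 2:
        raise ValueError("need at least 2 points with distinct time values")
    return float(stats.theilslopes(y_arr, t_arr).slope)


def classify_trend(slope: float, threshold: float = 0.001) -> TrendLabel:
    """Strict-threshold trend label; |slope| <= threshold is no change."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if slope > threshold:
        return TrendLabel.IMPROVEMENT
    if slope < -threshold:
        return TrendLabel.DETERIORATION
    return TrendLabel.NO_SIGNIFICANT_CHANGE


def analyze_series(
    series: ScoreSeries,
    aggregate: str = "mean",
    window: int = 3,
    threshold: float = 0.001,
    time_axis: str = "index",
) -> TrendResult:
    """Aggregate, median-filter and classify one patient's trajectory.

    time_axis "index" uses the examination number 0, 1, 2, ... as the
    abscissa (the threshold is per examination step); "days" uses days
    since the first visit.
    """
    if len(series.entries) < 2:
        raise ValueError("trend analysis requires at least 2 visits")
    y = [aggregate_visit_score(e.scores, aggregate) for e in series.entries]
    filtered = rolling_median(y, window)
    if time_axis == "days":
        t0 = series.entries[0].date
        t = [(e.date - t0).days for e in series.entries]
    else:
        t = list(range(len(series.entries)))
    slope = theil_sen_slope(t, filtered)
    return TrendResult(
        slope=slope, label=classify_trend(slope, threshold), n_points=len(y)
    )


def spearman_correlation(
    grades: Sequence[float], scores: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    Returns (r, p); p < 0.05 is conventionally considered significant.
    Raises UndefinedCorrelationError for < 3 pairs or a constant vector.
    """
    g = np.asarray(grades, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    if g.size != s.size:
        raise ValueError("grades and scores must be paired")
    if g.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired observations")
    if np.unique(g).size < 2 or np.unique(s).size < 2:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    res = stats.spearmanr(g, s)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cohort-level I/O
# ---------------------------------------------------------------------------

def read_visits_csv(path: str | Path) -> list[ScoreSeries]:
    """Load the long-format visits table into per-patient series.

    Expected columns: patient_id, date (ISO-8601), expression_index,
    score, and optionally stennert_grade.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    out: list[ScoreSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        entries = []
        for date, visit in grp.groupby("date", sort=True):
            grade = None
            if "stennert_grade" in visit and visit["stennert_grade"].notna().any():
                grade = int(visit["stennert_grade"].dropna().iloc[0])
            entries.append(
                VisitScores(
                    date=date,
                    scores={
                        int(r.expression_index): float(r.score)
                        for r in visit.itertuples()
                    },
                    grade=grade,
                )
            )
        out.append(ScoreSeries(patient_id=str(pid), entries=entries))
    return out


def cohort_summary(
    series_list: list[ScoreSeries],
    aggregate: str = "mean",
    window: int = 3,
    threshold: float = 0.001,
    time_axis: str = "index",
) -> dict:
    """Per-patient trends plus cohort counts and per-expression correlations."""
    trends = {}
    counts = {label.value: 0 for label in TrendLabel}
    for series in series_list:
        if len(series.entries) < 2:
            continue
        tr = analyze_series(series, aggregate, window, threshold, time_axis)
        trends[series.patient_id] = {
            "slope": tr.slope,
            "label": tr.label.value,
            "n_points": tr.n_points,
        }
        counts[tr.label.value] += 1

    correlations: dict[str, dict[str, float]] = {}
    for expr in range(2, 10):
        grades, scores = [], []
        for series in series_list:
            for e in series.entries:
                if e.grade is not None and expr in e.scores:
                    grades.append(e.grade)
                    scores.append(e.scores[expr])
        try:
            r, p = spearman_correlation(grades, scores)
        except UndefinedCorrelationError:
            continue
        correlations[str(expr)] = {"spearman_r": r, "p_value": p, "n": len(grades)}

    return {
        "n_patients_with_trend": len(trends),
        "trend_counts": counts,
        "per_patient_trends": trends,
        "per_expression_correlation": correlations,
    }


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True))
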