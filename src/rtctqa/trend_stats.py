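"""Cohort aggregation and temporal dose/coverage surveillance.

Works on a per-scan table (one row per volumetric scan) joining dose
descriptors, scan-range deltas and QA statuses.  Provides the
minimum-occurrence filter, per-group summary statistics (mean, sample
SD, median, quartiles), date-windowed moving averages with running SD,
and comparison of group medians against configurable reference levels.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MIN_OCCURRENCE",
    "TrendSeries",
    "filter_min_occurrence",
    "group_summary",
    "moving_stats",
    "compare_reference",
]

#: protocols rarer than this across the cohort are excluded from analysis
MIN_OCCURRENCE = 25


@dataclass(frozen=True)
class TrendSeries:
    """A moving average with running SD on the observed-date grid.

    Evaluation dates are the sorted unique scan dates; at each date the
    mean/SD/n are computed over all rows within ``window_days / 2`` days
    on either side.  Edge dates simply use whatever data falls in the
    window (no padding, no window reshaping).
    """

    eval_dates: pd.DatetimeIndex
    mean: np.ndarray
    sd: np.ndarray  # NaN where n < 2
    n: np.ndarray
    window_days: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eval_date": self.eval_dates,
                "mean": self.mean,
                "sd": self.sd,
                "n": self.n,
            }
        )


def filter_min_occurrence(
    table: pd.DataFrame, min_n: int = MIN_OCCURRENCE, by: str = "group"
) -> pd.DataFrame:
    """Drop groups with fewer than ``min_n`` rows (default 25); keep the rest."""
    if table.empty:
        return table.copy()
    counts = table[by].value_counts()
    keep = counts[counts >= min_n].index
    return table[table[by].isin(keep)].copy()


def group_summary(table: pd.DataFrame, metric: str, by: str = "group") -> pd.DataFrame:
    """Per-group mean, sample SD, median, quartiles and count for one metric.

    SD uses the n-1 denominator and is NaN for single-row groups;
    quartiles use linear interpolation.
    """
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}")
    values = table[[by, metric]].dropna(subset=[metric])
    grouped = values.groupby(by)[metric]
    out = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sd": grouped.std(ddof=1),
            "median": grouped.median(),
            "q1": grouped.quantile(0.25),
            "q3": grouped.quantile(0.75),
            "n": grouped.size(),
        }
    )
    out.index.name = by
    return out


def moving_stats(
    table: pd.DataFrame,
    metric: str,
    window_days: float,
    date_column: str = "date",
) -> TrendSeries:
    """Moving mean and running SD over a centred date window.

    At each observed scan date the statistics cover all rows whose date
    lies within ``window_days / 2`` days (inclusive) of it, e.g. a
    12-week window uses all data within +/- 42 days of each date.  The
    running SD is the sample SD of the raw in-window values.
    """
    if not window_days > 0:
        raise ValueError("window_days must be > 0")
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}")
    frame = table[[date_column, metric]].dropna()
    if frame.empty:
        return TrendSeries(
            eval_dates=pd.DatetimeIndex([]),
            mean=np.array([]),
            sd=np.array([]),
            n=np.array([], dtype=int),
            window_days=window_days,
        )
    dates = pd.to_datetime(frame[date_column])
    values = frame[metric].to_numpy(dtype=float)
    eval_dates = pd.DatetimeIndex(sorted(dates.unique()))
    span_days = (eval_dates.max() - eval_dates.min()).days + 1
    # an infinite (or cohort-spanning) window degenerates to the global stats
    effective = min(float(window_days), 2.0 * span_days + 2.0)
    half = pd.Timedelta(days=effective / 2.0)
    means = np.empty(len(eval_dates))
    sds = np.full(len(eval_dates), np.nan)
    ns = np.empty(len(eval_dates), dtype=int)
    date_values = dates.to_numpy()
    for i, d in enumerate(eval_dates):
        in_window = np.abs(date_values - d.to_datetime64()) <= half.to_timedelta64()
        window_values = values[in_window]
        ns[i] = window_values.size
        means[i] = window_values.mean()
        if window_values.size >= 2:
            sds[i] = window_values.std(ddof=1)
    return TrendSeries(
        eval_dates=eval_dates, mean=means, sd=sds, n=ns, window_days=window_days
    )


def compare_reference(
    summary: pd.DataFrame,
    reference_table: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Compare per-group medians against configured reference levels.

    ``reference_table`` maps group -> {level name -> value}, e.g.
    ``{"Brain": {"proposed": 60, "achievable": 45}}``.  Groups absent
    from the table are reported as uncompared.  Returns one row per
    group x level with the median, the level and an ``exceeds`` flag.
    """
    rows = []
    for group, stats in summary.iterrows():
        levels = reference_table.get(group)
        if not levels:
            rows.append(
                {
                    "group": group,
                    "level": None,
                    "reference": np.nan,
                    "median": stats["median"],
                    "exceeds": None,
                    "compared": False,
                }
            )
            continue
        for level_name, level_value in levels.items():
            rows.append(
                {
                    "group": group,
                    "level": level_name,
                    "reference": float(level_value),
                    "median": stats["median"],
                    "exceeds": bool(stats["median"] > level_value),
                    "compared": True,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "level", "reference", "median", "exceeds", "compared"]
    )
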