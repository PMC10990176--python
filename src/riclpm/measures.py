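"""Measurement construction: MET-intensity aggregation and TSK scoring.

Raw inputs are epoch-level accelerometer records (timestamp + MET value,
MET = multiple of resting metabolic rate) and 13-item kinesiophobia
questionnaires (TSK-NL Heart, items scored 1-4, total 13-52).  This module
turns them into the 8 analysis variables: TSK total and total physical
activity minutes/day at weeks 1, 3, 6 and 12 after hospital discharge.

Intensity categories follow the standard MET cut-points: light < 3 MET,
moderate 3-6 MET (closed interval, so the three printed bands partition the
line), heavy > 6 MET.  A configurable sedentary cut (default 1.5 MET)
excludes resting epochs from "light" — without it, sleep would count as
light activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Cutpoints",
    "DailySummary",
    "categorize_epoch",
    "summarize_day",
    "weekly_average",
    "extract_wave_pa",
    "score_tsk",
    "categorize_tsk",
    "WAVE_WEEKS",
    "TSK_BANDS",
]

WAVE_WEEKS = (1, 3, 6, 12)

#: Severity bands on the TSK total, inclusive of both endpoints.
TSK_BANDS = {
    "subclinical": (13, 22),
    "mild": (23, 32),
    "moderate": (33, 42),
    "severe": (43, 52),
}

CATEGORIES = ("sedentary", "light", "moderate", "heavy")


@dataclass(frozen=True)
class Cutpoints:
    """MET cut-points separating intensity categories."""

    sedentary_max: float = 1.5
    light_max: float = 3.0
    moderate_max: float = 6.0

    def __post_init__(self):
        if not (self.sedentary_max < self.light_max < self.moderate_max):
            raise ValueError("cut-points must satisfy sedentary < light < moderate")


@dataclass(frozen=True)
class DailySummary:
    """Minutes of activity on one calendar date, by intensity category."""

    date: object
    minutes_light: float
    minutes_moderate: float
    minutes_heavy: float

    @property
    def minutes_total(self) -> float:
        return self.minutes_light + self.minutes_moderate + self.minutes_heavy


def categorize_epoch(met: float, cuts: Cutpoints = Cutpoints()) -> str:
    """Intensity category of a single epoch."""
    if met < 0:
        raise ValueError(f"MET value must be nonnegative, got {met}")
    if met <= cuts.sedentary_max:
        return "sedentary"
    if met < cuts.light_max:
        return "light"
    if met <= cuts.moderate_max:
        return "moderate"
    return "heavy"


def _categorize_array(met: np.ndarray, cuts: Cutpoints) -> np.ndarray:
    """Vectorized category codes: 0 sedentary, 1 light, 2 moderate, 3 heavy."""
    if (met < 0).any():
        raise ValueError("MET values must be nonnegative")
    codes = np.zeros(len(met), dtype=np.int8)
    codes[met > cuts.sedentary_max] = 1
    codes[met >= cuts.light_max] = 2
    codes[met > cuts.moderate_max] = 3
    return codes


def summarize_day(
    epochs: pd.DataFrame,
    cuts: Cutpoints = Cutpoints(),
    epoch_minutes: float = 1.0,
) -> DailySummary:
    """Minutes per intensity category over one calendar date.

    ``epochs`` needs columns ``timestamp`` and ``met``.  Sedentary epochs
    count toward no activity category and are excluded from the total.
    """
    if len(epochs) == 0:
        return DailySummary(None, 0.0, 0.0, 0.0)
    ts = pd.to_datetime(epochs["timestamp"])
    dates = ts.dt.date.unique()
    if len(dates) > 1:
        raise ValueError(f"epochs span multiple dates: {sorted(map(str, dates))}")
    codes = _categorize_array(epochs["met"].to_numpy(float), cuts)
    counts = np.bincount(codes, minlength=4)
    return DailySummary(
        date=dates[0],
        minutes_light=counts[1] * epoch_minutes,
        minutes_moderate=counts[2] * epoch_minutes,
        minutes_heavy=counts[3] * epoch_minutes,
    )


def summarize_days(
    epochs: pd.DataFrame,
    cuts: Cutpoints = Cutpoints(),
    epoch_minutes: float = 1.0,
) -> pd.DataFrame:
    """Per-date summary table (date, minutes per category, total)."""
    if len(epochs) == 0:
        return pd.DataFrame(
            columns=["date", "minutes_light", "minutes_moderate",
                     "minutes_heavy", "minutes_total"]
        )
    df = epochs.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    df["code"] = _categorize_array(df["met"].to_numpy(float), cuts)
    counts = (
        df.pivot_table(index="date", columns="code", aggfunc="size", fill_value=0)
        .reindex(columns=[1, 2, 3], fill_value=0)
        * epoch_minutes
    )
    counts.columns = ["minutes_light", "minutes_moderate", "minutes_heavy"]
    counts["minutes_total"] = counts.sum(axis=1)
    return counts.reset_index()


def weekly_average(
    days: pd.DataFrame, week: int, discharge_date=None
) -> dict[str, float] | None:
    """Mean minutes/day over the available days of one 7-day window.

    Week ``w`` covers days ``7(w-1)+1 .. 7w`` after discharge; the discharge
    date defaults to the earliest date present.  A week with zero available
    days yields None (missing), never zero.
    """
    if week < 1:
        raise ValueError("week index starts at 1")
    if len(days) == 0:
        return None
    dates = pd.to_datetime(days["date"])
    start = pd.Timestamp(discharge_date) if discharge_date is not None else dates.min()
    offset = (dates - start).dt.days
    in_week = (offset >= 7 * (week - 1)) & (offset < 7 * week)
    sub = days[in_week]
    if len(sub) == 0:
        return None
    return {
        c: float(sub[c].mean())
        for c in ["minutes_light", "minutes_moderate", "minutes_heavy",
                  "minutes_total"]
    }


def extract_wave_pa(
    days: pd.DataFrame,
    wave_weeks: tuple[int, ...] = WAVE_WEEKS,
    discharge_date=None,
) -> pd.DataFrame:
    """Wave-level PA variables: weekly averages at the measurement weeks.

    Returns one row per wave with week index and per-category minutes/day;
    a wave whose week has no available days is missing (NaN).
    """
    rows = []
    for wave, week in enumerate(wave_weeks, start=1):
        avg = weekly_average(days, week, discharge_date)
        rows.append(
            {
                "wave": wave,
                "week": week,
                "pa_light": avg["minutes_light"] if avg else np.nan,
                "pa_moderate": avg["minutes_moderate"] if avg else np.nan,
                "pa_heavy": avg["minutes_heavy"] if avg else np.nan,
                "pa_total": avg["minutes_total"] if avg else np.nan,
            }
        )
    return pd.DataFrame(rows)


def score_tsk(items) -> int:
    """TSK-NL Heart total: sum of the 13 items, each scored 1-4."""
    items = list(items)
    if len(items) != 13:
        raise ValueError(f"expected 13 items, got {len(items)}")
    for i, v in enumerate(items):
        if not float(v).is_integer() or not 1 <= int(v) <= 4:
            raise ValueError(f"item {i} out of range 1..4: {v}")
    return int(sum(int(v) for v in items))


def categorize_tsk(total: float) -> str:
    """Severity band of a TSK total (13-52)."""
    if not 13 <= total <= 52:
        raise ValueError(f"TSK total out of range 13..52: {total}")
    for label, (lo, hi) in TSK_BANDS.items():
        if lo <= total <= hi:
            return label
    raise AssertionError("unreachable: bands partition 13..52")
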