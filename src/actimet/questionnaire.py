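"""Self-reported physical-activity scoring.

Activities arrive as (MET, hours/week) pairs. Total physical activity is
the MET-hours-per-week sum; moderate-to-vigorous physical activity (MVPA)
is the weekly hours over items of >= 3 MET; the WHO 2010 recommendation
flag is >= 2.5 h/wk of MVPA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

MVPA_MET_CUTOFF = 3.0
WHO_MVPA_HOURS_PER_WEEK = 2.5

#: MET intensities for the synthetic questionnaire's activity menu
DEFAULT_MET_VALUES: dict[str, float] = {
    "walking": 3.5,
    "gardening": 4.0,
    "sports": 6.0,
    "housework": 2.5,
}


@dataclass(frozen=True)
class ActivityItem:
    """One reported activity: label, MET intensity, weekly hours."""

    label: str
    met: float
    hours_per_week: float

    def __post_init__(self) -> None:
        if not self.met > 0:
            raise ValueError(f"{self.label}: MET must be positive")
        if self.hours_per_week < 0:
            raise ValueError(f"{self.label}: hours must be nonnegative")


@dataclass(frozen=True)
class QuestionnaireSummary:
    total_met_h_per_week: float
    mvpa_h_per_week: float
    meets_who: bool


def total_met_hours(items: Iterable[ActivityItem]) -> float:
    """Sum of MET x hours/week over all reported activities."""
    return float(sum(item.met * item.hours_per_week for item in items))


def mvpa_hours(items: Iterable[ActivityItem]) -> float:
    """Weekly hours in activities of at least 3 MET (inclusive)."""
    return float(sum(item.hours_per_week for item in items
                     if item.met >= MVPA_MET_CUTOFF))


def meets_who_questionnaire(mvpa_h_per_week: float) -> bool:
    """True iff reported MVPA reaches 2.5 h/wk (inclusive)."""
    if mvpa_h_per_week < 0:
        raise ValueError("MVPA hours must be nonnegative")
    return bool(mvpa_h_per_week >= WHO_MVPA_HOURS_PER_WEEK)


def summarize(items: Iterable[ActivityItem]) -> QuestionnaireSummary:
    items = list(items)
    mvpa = mvpa_hours(items)
    return QuestionnaireSummary(total_met_hours(items), mvpa,
                                meets_who_questionnaire(mvpa))


def score_cohort(df: pd.DataFrame,
                 met_values: Mapping[str, float] = DEFAULT_MET_VALUES) -> pd.DataFrame:
    """Score ``activity_<label>_hours`` columns of a cohort table.

    Adds ``q_total_met_h_wk``, ``q_mvpa_h_wk`` and ``q_meets_who``.
    """
    out = df.copy()
    total = pd.Series(0.0, index=df.index)
    mvpa = pd.Series(0.0, index=df.index)
    found = False
    for label, met in met_values.items():
        col = f"activity_{label}_hours"
        if col not in df.columns:
            continue
        found = True
        hours = df[col].astype(float)
        if (hours < 0).any():
            raise ValueError(f"negative hours in {col}")
        total = total + met * hours
        if met >= MVPA_MET_CUTOFF:
            mvpa = mvpa + hours
    if not found:
        raise ValueError("no activity_<label>_hours columns matched the MET map")
    out["q_total_met_h_wk"] = total
    out["q_mvpa_h_wk"] = mvpa
    out["q_meets_who"] = mvpa >= WHO_MVPA_HOURS_PER_WEEK
    return out
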