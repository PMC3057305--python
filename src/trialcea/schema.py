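"""Column layout of the cohort file shared by all analysis stages.

One row per participant. Waves are the measurement occasions at weeks
0, 5, 8 and 12; costing periods are the 4 weeks before randomization
(``pre``) and the three follow-up intervals weeks 0-5 (``p1``), 5-8
(``p2``) and 8-12 (``p3``). An empty cell denotes a missing value.
"""

from __future__ import annotations

from . import reference

ARMS = reference.ARMS
SERVICES = reference.SERVICES

#: Measurement weeks for CES-D and EQ-5D utility.
WEEKS = (0, 5, 8, 12)

#: Costing periods and their lengths in weeks.
PERIODS = ("pre", "p1", "p2", "p3")
PERIOD_WEEKS = {"pre": 4.0, "p1": 5.0, "p2": 3.0, "p3": 4.0}

#: Follow-up wave index (1..3) -> (outcome week, costing period).
FOLLOWUP_WAVES = {1: (5, "p1"), 2: (8, "p2"), 3: (12, "p3")}

WEEKS_PER_YEAR = 365.25 / 7  # 52.18


def cesd_col(week: int) -> str:
    return f"cesd_w{week}"


def util_col(week: int) -> str:
    return f"util_w{week}"


def use_col(service: str, period: str) -> str:
    return f"use_{service}_{period}"


def med_col(period: str) -> str:
    return f"medmonths_{period}"


def workloss_col(period: str) -> str:
    return f"worklossdays_{period}"


def cutback_col(period: str) -> str:
    return f"cutbackdays_{period}"


def inefficiency_col(period: str) -> str:
    return f"inefficiency_{period}"


def domestic_col(period: str) -> str:
    return f"domestichours_{period}"


def cohort_columns() -> list[str]:
    """Full ordered column list of the cohort CSV."""
    cols = ["id", "arm"]
    cols += [cesd_col(w) for w in WEEKS]
    cols += [util_col(w) for w in WEEKS]
    for period in PERIODS:
        cols += [use_col(s, period) for s in SERVICES]
        cols += [med_col(period), workloss_col(period), cutback_col(period),
                 inefficiency_col(period), domestic_col(period)]
    return cols


#: Admissible ranges for validated cohort fields (inclusive bounds).
RANGES = {
    "cesd": (0.0, 60.0),
    "utility": (-1.0, 1.0),
    "inefficiency": (0.0, 1.0),
}


def column_range(col: str) -> tuple[float, float] | None:
    """Admissible (lo, hi) for a cohort column, or None if only >= 0."""
    if col.startswith("cesd_"):
        return RANGES["cesd"]
    if col.startswith("util_"):
        return RANGES["utility"]
    if col.startswith("inefficiency_"):
        return RANGES["inefficiency"]
    return None
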