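"""Self-reported physical activity: METs totals and the active/less-active
dichotomy.

Total weekly METs are the weighted sum of minutes spent in each activity:
``intensity (METs) x sessions/week x minutes/session`` summed over
activities.  The 450 MET·min/wk threshold corresponds to 150 minutes of
moderate (3.0-MET) or 75 minutes of vigorous (6.0-MET) activity per week.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

MODERATE_ACTIVITY_METS = 3.0
DEFAULT_METS_THRESHOLD = 450.0

#: Fallback intensity table (METs) for common leisure activities, in the
#: spirit of the physical-activity compendium; callers supply their own
#: values when they have them.
DEFAULT_MET_VALUES: dict[str, float] = {
    "walking": 3.5,
    "brisk walking": 4.3,
    "jogging": 7.0,
    "running": 8.0,
    "swimming": 6.0,
    "cycling": 7.5,
    "yoga": 2.5,
    "pilates": 3.0,
    "aerobics": 6.5,
    "weightlifting": 3.0,
    "dancing": 4.5,
    "hiking": 6.0,
    "gardening": 3.8,
}


class ActivityLevel(str, enum.Enum):
    LESS_ACTIVE = "less_active"
    MORE_ACTIVE = "more_active"


@dataclass(frozen=True)
class ActivityRecord:
    """One reported activity: intensity, weekly frequency, session length."""

    activity_name: str
    met_value: float
    sessions_per_week: float
    minutes_per_session: float

    def __post_init__(self):
        for f in ("met_value", "sessions_per_week", "minutes_per_session"):
            v = getattr(self, f)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(
                    f"activity {self.activity_name!r}: {f} must be finite and >= 0, got {v}"
                )


def total_mets(records: Iterable[ActivityRecord]) -> float:
    """Total weekly METs: sum of intensity x sessions x minutes. Empty -> 0."""
    return float(sum(
        r.met_value * r.sessions_per_week * r.minutes_per_session for r in records
    ))


def activity_class(mets: float, threshold: float = DEFAULT_METS_THRESHOLD) -> ActivityLevel:
    """Dichotomize: less_active iff mets < threshold (the boundary itself
    counts as more_active, matching the "METs >=450" subgroup labels)."""
    if not mets >= 0:
        raise ValueError(f"mets must be >= 0, got {mets}")
    return ActivityLevel.LESS_ACTIVE if mets < threshold else ActivityLevel.MORE_ACTIVE


def read_activity_csv(path, met_values: Optional[Mapping[str, float]] = None
                      ) -> dict[str, list[ActivityRecord]]:
    """Read the activity log CSV into per-participant record lists.

    Columns: participant_id, activity_name, met_value (optional if a
    ``met_values`` mapping or the built-in defaults resolve the name),
    sessions_per_week, minutes_per_session.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    lookup = dict(DEFAULT_MET_VALUES)
    if met_values:
        lookup.update({k.lower(): v for k, v in met_values.items()})
    out: dict[str, list[ActivityRecord]] = {}
    for _, row in df.iterrows():
        name = str(row["activity_name"])
        if "met_value" in df.columns and pd.notna(row["met_value"]):
            mv = float(row["met_value"])
        else:
            try:
                mv = lookup[name.lower()]
            except KeyError:
                raise ValueError(f"no MET intensity known for activity {name!r}") from None
        rec = ActivityRecord(name, mv, float(row["sessions_per_week"]),
                             float(row["minutes_per_session"]))
        out.setdefault(str(row["participant_id"]), []).append(rec)
    return out


def read_mets_config(path) -> dict[str, float]:
    """TSV mapping activity_name -> met_value."""
    df = pd.read_csv(path, sep="\t")
    return {str(a).lower(): float(m) for a, m in zip(df["activity_name"], df["met_value"])}
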