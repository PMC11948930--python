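"""Health-care utilization frequency from encounter dates.

Participants are grouped by how often they appear in VHA records over
their own observation period (first to last encounter, truncated at the
cutoff date):

* high-frequency — more than one encounter in every observation year;
* regular — at least one encounter per year on average;
* irregular — fewer than one per year on average but at least one;
* none — no encounters.

Observation years are measured in 365.25-day units, floored at one year
so single-visit participants remain classifiable.  "Every year" is
evaluated over consecutive 365.25-day intervals anchored at the first
encounter; a final partial interval imposes the more-than-one
requirement only when it spans at least half a year.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Optional

import pandas as pd

YEAR_DAYS = 365.25

HIGH = "high-frequency"
REGULAR = "regular"
IRREGULAR = "irregular"
NONE = "none"

CATEGORIES = (HIGH, REGULAR, IRREGULAR, NONE)


@dataclass(frozen=True)
class UtilizationProfile:
    participant_id: str
    first_encounter: Optional[date]
    last_encounter: Optional[date]
    observation_years: float
    total_encounters: int
    encounters_per_year: float
    category: str


def classify_utilization(participant_id: str,
                         encounter_dates: Iterable[date],
                         cutoff: date = date(2020, 9, 18),
                         *, min_years: float = 1.0,
                         partial_interval_min_frac: float = 0.5,
                         ) -> UtilizationProfile:
    """Classify one participant's utilization from their encounter dates.

    Dates after ``cutoff`` are dropped.  High-frequency requires more
    than one encounter in every (requirement-bearing) observation-year
    interval *and* an average above one per year, so degenerate spans
    (e.g. a single visit, whose period is floored to one year) fall back
    to the average-based rule.  Precedence: high > regular > irregular.
    """
    kept = sorted(d for d in encounter_dates if d <= cutoff)
    if not kept:
        return UtilizationProfile(participant_id, None, None, 0.0, 0, 0.0, NONE)
    first, last = kept[0], kept[-1]
    span_days = (last - first).days
    years = max(span_days / YEAR_DAYS, min_years)
    total = len(kept)
    average = total / years

    n_full = int(span_days // YEAR_DAYS)
    remainder = span_days - n_full * YEAR_DAYS
    counts = [0] * (n_full + 1)
    for d in kept:
        idx = min(int((d - first).days // YEAR_DAYS), n_full)
        counts[idx] += 1
    required = counts[:n_full]
    if remainder >= partial_interval_min_frac * YEAR_DAYS:
        required = counts[:n_full + 1]
    every_year = all(c > 1 for c in required)

    if every_year and average > 1:
        category = HIGH
    elif average >= 1:
        category = REGULAR
    else:
        category = IRREGULAR
    return UtilizationProfile(participant_id, first, last, years, total,
                              average, category)


def classify_cohort(encounters: pd.DataFrame,
                    cutoff: date = date(2020, 9, 18),
                    *, source: Optional[str] = "VHA") -> pd.DataFrame:
    """Utilization category per participant from an encounter table.

    By default only VHA-source encounters count (utilization is defined
    on VHA care); pass ``source=None`` to use all rows.  Returns a frame
    (participant_id, category, total_encounters, encounters_per_year).
    """
    df = encounters
    if source is not None:
        df = df[df["source"] == source]
    # distinct dates per participant: several codes on one visit are one encounter
    dates = (pd.DataFrame({
        "participant_id": df["participant_id"],
        "event_date": pd.to_datetime(df["event_date"]).dt.date,
    }).drop_duplicates())
    rows = []
    for pid, grp in dates.groupby("participant_id", sort=True):
        prof = classify_utilization(pid, grp["event_date"], cutoff)
        rows.append((pid, prof.category, prof.total_encounters,
                     prof.encounters_per_year))
    return pd.DataFrame(rows, columns=["participant_id", "category",
                                       "total_encounters",
                                       "encounters_per_year"])
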