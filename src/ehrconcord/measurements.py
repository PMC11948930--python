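"""Height/weight harmonization and Bland-Altman agreement.

Heights are in inches, weights in pounds.  Extreme values (weights
below 80 lb or above 500 lb; heights below 48 in or above 95 in) are
removed before any selection; the bounds themselves are retained.

Height per participant and source is the modal value (ties broken
toward the earliest-dated modal value; all-distinct falls back to the
first recorded).  Weight is the measurement closest in time to the
corresponding survey, within a one-year window on either side by
default.  Differences are always record minus survey, and limits of
agreement are the mean difference plus or minus exactly two sample
standard deviations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

HEIGHT_MIN_IN, HEIGHT_MAX_IN = 48.0, 95.0
WEIGHT_MIN_LB, WEIGHT_MAX_LB = 80.0, 500.0

KIND_HEIGHT = "height"
KIND_WEIGHT = "weight"


def filter_extremes(vitals: pd.DataFrame) -> pd.DataFrame:
    """Drop implausible heights/weights (strict inequalities).

    Expects columns ``kind`` (height|weight) and ``value``; rows of
    other kinds pass through untouched.
    """
    value = vitals["value"].astype(float)
    kind = vitals["kind"]
    bad_height = (kind == KIND_HEIGHT) & ((value < HEIGHT_MIN_IN)
                                          | (value > HEIGHT_MAX_IN))
    bad_weight = (kind == KIND_WEIGHT) & ((value < WEIGHT_MIN_LB)
                                          | (value > WEIGHT_MAX_LB))
    return vitals[~(bad_height | bad_weight)]


def height_in_bounds(value: float) -> bool:
    return HEIGHT_MIN_IN <= value <= HEIGHT_MAX_IN


def weight_in_bounds(value: float) -> bool:
    return WEIGHT_MIN_LB <= value <= WEIGHT_MAX_LB


def select_height(measures: Sequence[Tuple[date, float]]) -> Optional[float]:
    """Representative height for one participant and source.

    Modal value; a frequency tie is broken toward the modal value first
    recorded; if every value is distinct, the first recorded value is
    used; ``None`` when no measurements remain.
    """
    if not measures:
        return None
    counts = Counter(v for _, v in measures)
    first_seen: dict = {}
    for i, (d, v) in enumerate(measures):
        key = (d, i)
        if v not in first_seen or key < first_seen[v]:
            first_seen[v] = key
    best = max(counts.values())
    modal = [v for v, n in counts.items() if n == best]
    return min(modal, key=lambda v: (first_seen[v], v))


def select_weight(measures: Sequence[Tuple[date, float]],
                  survey_date: date,
                  *, window_days: int = 365,
                  two_sided: bool = True,
                  ) -> Optional[float]:
    """Weight recorded closest to the survey date, within the window.

    The window is inclusive and, by default, extends ``window_days`` on
    either side of the survey; the one-sided variant keeps only
    measurements on or before the survey date.  An equidistant
    before/after tie is broken toward the earlier (pre-survey)
    measurement.
    """
    candidates = []
    for d, v in measures:
        delta = (d - survey_date).days
        if two_sided:
            if abs(delta) > window_days:
                continue
        elif not -window_days <= delta <= 0:
            continue
        candidates.append((abs(delta), d, v))
    if not candidates:
        return None
    return min(candidates)[2]


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Mean/spread of paired record-minus-survey differences."""

    n: int
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    proportion_outside: float


def bland_altman(pairs: Sequence[Tuple[float, float]]) -> BlandAltmanSummary:
    """Summarize agreement between paired (record, survey) values.

    Differences are record minus survey; the SD uses the n-1
    denominator; limits are mean plus/minus exactly two SDs; the
    reported proportion counts pairs strictly outside the limits.
    """
    if len(pairs) < 2:
        raise ValueError("at least two pairs are required")
    diffs = np.asarray([record - survey for record, survey in pairs], float)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lower, upper = mean - 2 * sd, mean + 2 * sd
    outside = float(np.mean((diffs < lower) | (diffs > upper)))
    return BlandAltmanSummary(len(pairs), mean, sd, lower, upper, outside)


def bland_altman_plot(pairs: Sequence[Tuple[float, float]], path,
                      title: Optional[str] = None,
                      unit: str = "") -> BlandAltmanSummary:
    """Scatter of pair means against differences with the mean line and
    two-SD limits; written to ``path``.  Returns the summary."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = bland_altman(pairs)
    arr = np.asarray(pairs, float)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=6, alpha=0.4, edgecolors="none")
    ax.axhline(0, color="0.6", lw=0.8)
    ax.axhline(summary.mean_difference, color="C0", label="mean difference")
    for lim in (summary.lower_limit, summary.upper_limit):
        ax.axhline(lim, color="C3", ls="--", lw=1, label="mean ± 2 SD")
    ax.set_xlabel(f"mean of record and survey {unit}".strip())
    ax.set_ylabel(f"record − survey {unit}".strip())
    if title:
        ax.set_title(title)
    handles, labels = ax.get_legend_handles_labels()
    seen: dict = {}
    for h, l in zip(handles, labels):
        seen.setdefault(l, h)
    ax.legend(seen.values(), seen.keys(), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return summary
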