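"""Survey-based case classification with carry-forward.

A participant is a survey case for a condition once they answer "yes"
to the doctor-told-you item at any wave; the diagnosis date is the
survey date of first self-report, and later "no" answers do not revoke
the classification.  A participant who never answers "yes" but answers
"no" at some wave is a negative; one with missing responses at every
available wave is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agreement import MISSING, NEGATIVE, POSITIVE

YES = "yes"
NO = "no"


def normalize_answer(answer) -> Optional[str]:
    """Map survey item codings (1/0/blank, yes/no, bool) to yes/no/None."""
    if answer is None:
        return None
    if isinstance(answer, float) and math.isnan(answer):
        return None
    if answer in (YES, 1, 1.0, True, "1"):
        return YES
    if answer in (NO, 0, 0.0, False, "0"):
        return NO
    if answer in ("", MISSING):
        return None
    raise ValueError(f"unrecognized survey answer {answer!r}")


@dataclass(frozen=True)
class SurveyWaveResponse:
    """One participant-wave of survey answers."""

    participant_id: str
    wave: int
    survey_date: date
    condition_answers: dict = field(default_factory=dict)
    phq_items: Tuple = (None,) * 5
    cigarettes_100: Optional[str] = None
    height_in: Optional[float] = None
    weight_lb: Optional[float] = None


def classify_survey_case(
        wave_answers: Sequence[Tuple[date, Optional[str]]],
) -> Tuple[str, Optional[date]]:
    """Classify one participant-condition from answers ordered by wave.

    Returns ``(status, diagnosis_date)`` where the diagnosis date is the
    survey date at first self-report (``None`` unless positive).
    """
    if not wave_answers:
        raise ValueError("at least one survey wave is required")
    first_yes: Optional[date] = None
    any_no = False
    for survey_date, answer in wave_answers:
        a = normalize_answer(answer)
        if a == YES and first_yes is None:
            first_yes = survey_date
        elif a == NO:
            any_no = True
    if first_yes is not None:
        return POSITIVE, first_yes
    if any_no:
        return NEGATIVE, None
    return MISSING, None


def status_as_of(wave_answers: Sequence[Tuple[date, Optional[str]]],
                 wave_index: int) -> str:
    """Carried-forward status using only waves up to ``wave_index``.

    Monotone: once positive, positive at every later index.
    """
    if not 0 <= wave_index < len(wave_answers):
        raise ValueError(f"wave index {wave_index} out of range")
    return classify_survey_case(wave_answers[:wave_index + 1])[0]


@dataclass
class SurveyClassification:
    """Cohort-scale classification: per-condition status frames plus the
    last completed survey date per participant."""

    conditions: dict            # condition -> DataFrame(status, first_yes_date)
    last_survey_date: pd.Series

    def status(self, condition: str) -> pd.Series:
        return self.conditions[condition]["status"]

    def first_yes_date(self, condition: str) -> pd.Series:
        return self.conditions[condition]["first_yes_date"]


def classify_survey_cohort(survey: pd.DataFrame,
                           conditions: Sequence[str],
                           participants: Optional[Sequence[str]] = None,
                           ) -> SurveyClassification:
    """Vectorized carry-forward classification of a survey table.

    ``survey`` has one row per completed participant-wave with columns
    ``participant_id, wave, survey_date`` and one ``cond_<name>`` column
    per condition coded 1/0/blank.  Roster members absent from the table
    (no completed wave) are missing for every condition.
    """
    if survey.empty and participants is None:
        raise ValueError("empty survey table and no roster supplied")
    sdate = pd.to_datetime(survey["survey_date"])
    pid = survey["participant_id"]
    roster = pd.Index(participants) if participants is not None \
        else pd.Index(pid.unique())
    last = sdate.groupby(pid.to_numpy()).max().reindex(roster)

    frames = {}
    for cond in conditions:
        col = survey[f"cond_{cond}"]
        first_yes = sdate.where(col == 1).groupby(pid.to_numpy()).min() \
            .reindex(roster)
        answered = col.notna().groupby(pid.to_numpy()).any() \
            .reindex(roster, fill_value=False)
        status = np.where(first_yes.notna(), POSITIVE,
                          np.where(answered, NEGATIVE, MISSING))
        frames[cond] = pd.DataFrame(
            {"status": status, "first_yes_date": first_yes}, index=roster)
    return SurveyClassification(frames, last)
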