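"""Smoking and alcohol-use harmonization between survey and record.

Survey side: problem drinking is endorsement of at least one of five
PHQ risky-drinking items; ever-smoking is an affirmative answer to the
lifetime-100-cigarettes item at any wave (carry-forward).  Record side:
alcohol misuse is an AUDIT-C score of 3+ for women or 4+ for men, from
the assessment closest in time *prior to* the survey (same-day
duplicates resolved to the highest score); smoking status comes from
the assessment closest to the survey date on either side.

Flags are "yes"/"no"/"missing" and are never imputed.
"""

from __future__ import annotations

from datetime import date
from typing import Optional, Sequence, Tuple

from .agreement import MISSING
from .survey import NO, YES, normalize_answer

AUDITC_MIN, AUDITC_MAX = 0, 12
AUDITC_CUTOFF_FEMALE = 3
AUDITC_CUTOFF_MALE = 4

EVER_SMOKER_STATUSES = frozenset({"current", "former"})

KIND_AUDITC = "audit_c"
KIND_SMOKING = "smoking"


def phq_problem_drinking(items: Sequence) -> str:
    """Flag from the five PHQ drinking items.

    "yes" when at least one item is endorsed; "no" when all five are
    denied; "missing" when nothing is endorsed but an item is missing
    (a denial cannot be established).
    """
    if len(items) != 5:
        raise ValueError(f"expected 5 PHQ items, got {len(items)}")
    norm = [normalize_answer(i) for i in items]
    if YES in norm:
        return YES
    if all(a == NO for a in norm):
        return NO
    return MISSING


def _normalize_sex(sex: str) -> str:
    s = str(sex).strip().upper()[:1]
    if s not in ("F", "M"):
        raise ValueError(f"unrecognized sex {sex!r}")
    return s


def auditc_misuse(score: int, sex: str) -> str:
    """Alcohol misuse at AUDIT-C >= 3 (women) or >= 4 (men)."""
    if not AUDITC_MIN <= score <= AUDITC_MAX or int(score) != score:
        raise ValueError(f"AUDIT-C score must be an integer in [0, 12], got {score!r}")
    cutoff = AUDITC_CUTOFF_FEMALE if _normalize_sex(sex) == "F" \
        else AUDITC_CUTOFF_MALE
    return YES if score >= cutoff else NO


def select_auditc(assessments: Sequence[Tuple[date, int]],
                  survey_date: date) -> Optional[int]:
    """AUDIT-C score closest in time strictly prior to the survey.

    Among assessments before the survey date, the latest date wins;
    same-day duplicates resolve to the highest score; ``None`` when no
    prior assessment exists.
    """
    prior = [(d, s) for d, s in assessments if d < survey_date]
    if not prior:
        return None
    latest = max(d for d, _ in prior)
    return max(s for d, s in prior if d == latest)


def survey_ever_smoker(wave_answers: Sequence) -> str:
    """Lifetime-100-cigarettes flag across waves, with carry-forward."""
    if not wave_answers:
        raise ValueError("at least one survey wave is required")
    norm = [normalize_answer(a) for a in wave_answers]
    if YES in norm:
        return YES
    if NO in norm:
        return NO
    return MISSING


def select_ehr_smoking(assessments: Sequence[Tuple[date, str]],
                       survey_date: date) -> Optional[str]:
    """Smoking status recorded closest to the survey date (two-sided).

    An equidistant tie resolves to the earlier record; ``None`` when no
    assessment exists.
    """
    if not assessments:
        return None
    return min(assessments,
               key=lambda t: (abs((t[0] - survey_date).days), t[0]))[1]


def smoking_status_is_ever(status: str) -> str:
    """Map a recorded smoking status to an ever-smoker flag."""
    return YES if str(status).strip().lower() in EVER_SMOKER_STATUSES else NO
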