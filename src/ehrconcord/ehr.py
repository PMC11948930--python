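"""Rule-based case ascertainment from coded medical encounters.

A participant's record-based case status for a condition is decided by
matching ICD-9/ICD-10/CPT codes (any diagnostic position) against a
condition code set inside a fixed observation window, under one of two
criteria:

* sensitive — one qualifying code on any inpatient or outpatient record;
* specific — one inpatient code, or outpatient codes on at least two
  distinct encounter dates (the "rule of two"; single-visit
  double-coding does not qualify).

The diagnosis date is the earliest qualifying encounter or admission
date.  Temporally restricted analyses keep only codes strictly before a
per-participant reference date and drop personal-history codes, which
carry no date of diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .agreement import MISSING, NEGATIVE, POSITIVE

VHA = "VHA"
MDR = "MDR"
INPATIENT = "inpatient"
OUTPATIENT = "outpatient"
SENSITIVE = "sensitive"
SPECIFIC = "specific"
SCOPE_VHA = "vha"
SCOPE_VHA_MDR = "vha-mdr"

CODE_SYSTEMS = ("ICD9", "ICD10", "CPT")


def normalize_code(raw: str) -> str:
    """Canonical code form: upper-cased, whitespace and decimal point removed.

    Idempotent; raises ``ValueError`` on empty input.
    """
    if raw is None:
        raise ValueError("code must be a non-empty string")
    s = "".join(str(raw).split()).upper().replace(".", "")
    if not s:
        raise ValueError("code must be a non-empty string")
    return s


@dataclass(frozen=True)
class ObservationWindow:
    """Code-eligibility period: fiscal-year 1999 start through 2020-09-18."""

    start: date = date(1999, 10, 1)
    end: date = date(2020, 9, 18)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


@dataclass(frozen=True)
class CodedDiagnosis:
    """One code on an encounter, with its diagnostic position."""

    code: str
    system: str = "ICD10"
    position: int = 1
    personal_history: bool = False

    def __post_init__(self) -> None:
        if not str(self.code).strip():
            raise ValueError("code must be non-empty")
        if self.position < 1:
            raise ValueError("diagnostic position must be >= 1")


@dataclass(frozen=True)
class EncounterRecord:
    """One coded encounter.  ``event_date`` is the admission date for
    inpatient stays and the encounter date otherwise.  Purchased-care
    encounters are ingested with ``source=VHA``."""

    participant_id: str
    source: str
    setting: str
    event_date: date
    codes: Tuple[CodedDiagnosis, ...] = ()

    def __post_init__(self) -> None:
        if self.source not in (VHA, MDR):
            raise ValueError(f"unknown source {self.source!r}")
        if self.setting not in (INPATIENT, OUTPATIENT):
            raise ValueError(f"unknown setting {self.setting!r}")


@dataclass(frozen=True)
class ConditionCodeSet:
    """Code patterns defining one condition.

    Entries are (code system, pattern) pairs; patterns are normalized at
    construction.  ``prefix`` matching (the default) lets truncated
    parent codes in published lists match their children; ``exact``
    requires full equality of normalized codes.
    """

    condition: str
    entries: Tuple[Tuple[str, str], ...]
    match_mode: str = "prefix"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("code set needs at least one entry")
        if self.match_mode not in ("prefix", "exact"):
            raise ValueError(f"unknown match mode {self.match_mode!r}")
        norm = tuple((system, normalize_code(pattern))
                     for system, pattern in self.entries)
        object.__setattr__(self, "entries", norm)

    def matches(self, system: str, normalized: str) -> bool:
        for sys_, pat in self.entries:
            if sys_ != system:
                continue
            if self.match_mode == "exact":
                if normalized == pat:
                    return True
            elif normalized.startswith(pat):
                return True
        return False


@dataclass(frozen=True)
class CaseStatus:
    """Per participant-condition-source verdict."""

    participant_id: str
    condition: str
    status: str
    diagnosis_date: Optional[date] = None
    criterion: Optional[str] = None
    scope: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in (POSITIVE, NEGATIVE, MISSING):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == POSITIVE and self.diagnosis_date is None:
            raise ValueError("positive status requires a diagnosis date")
        if self.status != POSITIVE and self.diagnosis_date is not None:
            raise ValueError("non-positive status must not carry a diagnosis date")


def match_condition(record: EncounterRecord,
                    codeset: ConditionCodeSet) -> list[CodedDiagnosis]:
    """Codes on the record (any position) matching the condition's code set."""
    return [cd for cd in record.codes
            if codeset.matches(cd.system, normalize_code(cd.code))]


def _qualifying_events(records: Sequence[EncounterRecord],
                       codeset: ConditionCodeSet,
                       window: ObservationWindow,
                       reference_date: Optional[date],
                       exclude_personal_history: bool) -> list[Tuple[date, str]]:
    events = []
    for rec in records:
        if not window.contains(rec.event_date):
            continue
        if reference_date is not None and not rec.event_date < reference_date:
            continue
        matched = match_condition(rec, codeset)
        if exclude_personal_history:
            matched = [cd for cd in matched if not cd.personal_history]
        if matched:
            events.append((rec.event_date, rec.setting))
    return events


def ascertain_sensitive(participant_id: str,
                        records: Sequence[EncounterRecord],
                        codeset: ConditionCodeSet,
                        window: ObservationWindow = ObservationWindow(),
                        *, reference_date: Optional[date] = None,
                        exclude_personal_history: bool = False) -> CaseStatus:
    """Positive on one in-window matching code; date = earliest match."""
    events = _qualifying_events(records, codeset, window,
                                reference_date, exclude_personal_history)
    if events:
        return CaseStatus(participant_id, codeset.condition, POSITIVE,
                          min(d for d, _ in events), criterion=SENSITIVE)
    return CaseStatus(participant_id, codeset.condition, NEGATIVE,
                      criterion=SENSITIVE)


def ascertain_specific(participant_id: str,
                       records: Sequence[EncounterRecord],
                       codeset: ConditionCodeSet,
                       window: ObservationWindow = ObservationWindow(),
                       *, reference_date: Optional[date] = None,
                       exclude_personal_history: bool = False,
                       distinct_outpatient_dates: bool = True) -> CaseStatus:
    """Positive on one inpatient match or two qualifying outpatient matches.

    With ``distinct_outpatient_dates`` (default) the two outpatient
    codes must fall on different encounter dates.  The diagnosis date is
    the earliest qualifying match: the admission date, or the first of
    the outpatient dates.
    """
    events = _qualifying_events(records, codeset, window,
                                reference_date, exclude_personal_history)
    inpatient_dates = [d for d, s in events if s == INPATIENT]
    outpatient_dates = [d for d, s in events if s == OUTPATIENT]
    qualifying: list[date] = list(inpatient_dates)
    n_out = (len(set(outpatient_dates)) if distinct_outpatient_dates
             else len(outpatient_dates))
    if n_out >= 2:
        qualifying.extend(outpatient_dates)
    if qualifying:
        return CaseStatus(participant_id, codeset.condition, POSITIVE,
                          min(qualifying), criterion=SPECIFIC)
    return CaseStatus(participant_id, codeset.condition, NEGATIVE,
                      criterion=SPECIFIC)


def restrict_prior(participant_id: str,
                   records: Sequence[EncounterRecord],
                   codeset: ConditionCodeSet,
                   window: ObservationWindow,
                   reference_date: date,
                   *, criterion: str = SENSITIVE,
                   distinct_outpatient_dates: bool = True) -> CaseStatus:
    """Ascertain using only codes strictly before ``reference_date``.

    Personal-history codes are excluded because they lack a date of
    diagnosis.  A code dated on the reference date itself does not count
    (it cannot be shown to precede the self-report).
    """
    if reference_date is None:
        raise ValueError("temporal restriction requires a reference date")
    if criterion == SENSITIVE:
        return ascertain_sensitive(participant_id, records, codeset, window,
                                   reference_date=reference_date,
                                   exclude_personal_history=True)
    if criterion == SPECIFIC:
        return ascertain_specific(participant_id, records, codeset, window,
                                  reference_date=reference_date,
                                  exclude_personal_history=True,
                                  distinct_outpatient_dates=distinct_outpatient_dates)
    raise ValueError(f"unknown criterion {criterion!r}")


def merge_sources(first: CaseStatus, second: CaseStatus) -> CaseStatus:
    """Combine verdicts from two record sources (e.g. VHA and MDR).

    Positive if either is positive, with the earliest available
    diagnosis date; negative only if both are negative; missing
    propagates only if both are missing.
    """
    for attr in ("participant_id", "condition", "criterion"):
        if getattr(first, attr) != getattr(second, attr):
            raise ValueError(f"cannot merge case statuses with different {attr}")
    dates = [cs.diagnosis_date for cs in (first, second)
             if cs.diagnosis_date is not None]
    if dates:
        return CaseStatus(first.participant_id, first.condition, POSITIVE,
                          min(dates), criterion=first.criterion,
                          scope=SCOPE_VHA_MDR)
    status = MISSING if (first.status == MISSING and second.status == MISSING) \
        else NEGATIVE
    return CaseStatus(first.participant_id, first.condition, status,
                      criterion=first.criterion, scope=SCOPE_VHA_MDR)


# ---------------------------------------------------------------------------
# Cohort-scale (vectorized) ascertainment


def _match_mask(encounters: pd.DataFrame, codeset: ConditionCodeSet,
                excluded: Optional[set] = None) -> np.ndarray:
    """Boolean row mask of encounters matching the code set.

    Matching is evaluated once per distinct (system, code) pair, then
    broadcast through a categorical encoding, so cost scales with the
    number of distinct codes rather than the number of rows.
    """
    key = (encounters["code_system"].astype(str) + "\x1f"
           + encounters["code"].astype(str)).astype("category")
    matched_levels = []
    for level_idx, level in enumerate(key.cat.categories):
        system, code = level.split("\x1f", 1)
        norm = normalize_code(code)
        if excluded and norm in excluded:
            continue
        if codeset.matches(system, norm):
            matched_levels.append(level_idx)
    return np.isin(key.cat.codes.to_numpy(), matched_levels)


def ascertain_cohort(encounters: pd.DataFrame,
                     codesets: Iterable[ConditionCodeSet],
                     *,
                     window: ObservationWindow = ObservationWindow(),
                     criterion: str = SENSITIVE,
                     scope: str = SCOPE_VHA_MDR,
                     participants: Optional[Sequence[str]] = None,
                     reference_dates: Optional[Mapping[str, pd.Series]] = None,
                     distinct_outpatient_dates: bool = True,
                     code_exclusions: Optional[Mapping[str, Sequence[str]]] = None,
                     ) -> pd.DataFrame:
    """Vectorized case ascertainment for a whole encounter table.

    Parameters
    ----------
    encounters
        One row per code with columns ``participant_id, source, setting,
        event_date, code, code_system, position, personal_history``.
    codesets
        One :class:`ConditionCodeSet` per condition.
    participants
        Roster of ids to classify; defaults to the ids present in the
        encounter table.  Roster members with no qualifying codes are
        negative (absence of evidence is a negative in the record).
    reference_dates
        Optional per-condition mapping of participant id to reference
        date; when given, only codes strictly before the reference date
        count, personal-history codes are dropped, and roster members
        without a reference date are reported missing (excluded from the
        restricted comparison).

    Returns a long frame (participant_id, condition, status,
    diagnosis_date) consistent with the per-participant operations.
    """
    if criterion not in (SENSITIVE, SPECIFIC):
        raise ValueError(f"unknown criterion {criterion!r}")
    if scope not in (SCOPE_VHA, SCOPE_VHA_MDR):
        raise ValueError(f"unknown scope {scope!r}")

    df = encounters
    if scope == SCOPE_VHA:
        df = df[df["source"] == VHA]
    event = pd.to_datetime(df["event_date"])
    in_window = ((event >= pd.Timestamp(window.start))
                 & (event <= pd.Timestamp(window.end))).to_numpy()
    pid = df["participant_id"]
    if participants is None:
        roster = pd.Index(encounters["participant_id"].unique())
    else:
        roster = pd.Index(participants)

    frames = []
    for codeset in codesets:
        excluded = None
        if code_exclusions and codeset.condition in code_exclusions:
            excluded = {normalize_code(c)
                        for c in code_exclusions[codeset.condition]}
        mask = _match_mask(df, codeset, excluded) & in_window
        refs = None
        if reference_dates is not None:
            refs = reference_dates.get(codeset.condition) \
                if hasattr(reference_dates, "get") else reference_dates
            if refs is None:
                raise ValueError(f"no reference dates for {codeset.condition!r}")
            mask = mask & (df["personal_history"].to_numpy() == 0)
            ref_per_row = pid.map(refs)
            mask = mask & (event < pd.to_datetime(ref_per_row)).to_numpy()

        sub = pd.DataFrame({"pid": pid.to_numpy()[mask],
                            "event": event.to_numpy()[mask],
                            "setting": df["setting"].to_numpy()[mask]})
        if criterion == SENSITIVE:
            pos_dates = sub.groupby("pid")["event"].min()
        else:
            inp = sub[sub["setting"] == INPATIENT].groupby("pid")["event"].min()
            out = sub[sub["setting"] == OUTPATIENT].groupby("pid")["event"]
            n_events = out.nunique() if distinct_outpatient_dates else out.size()
            out_min = out.min()[n_events >= 2]
            pos_dates = pd.concat([inp, out_min]).groupby(level=0).min()

        pos_dates = pos_dates[pos_dates.index.isin(roster)]
        status = pd.Series(NEGATIVE, index=roster, dtype=object)
        diag = pd.Series(pd.NaT, index=roster, dtype="datetime64[ns]")
        status.loc[pos_dates.index] = POSITIVE
        diag.loc[pos_dates.index] = pos_dates
        if refs is not None:
            has_ref = roster.isin(pd.Series(refs).dropna().index)
            status.loc[~has_ref] = MISSING
            diag.loc[~has_ref] = pd.NaT
        frames.append(pd.DataFrame({
            "participant_id": roster,
            "condition": codeset.condition,
            "status": status.to_numpy(),
            "diagnosis_date": diag.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
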