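"""Record-based case ascertainment: matching, criteria, temporality, merging."""

import string
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ehrconcord.agreement import MISSING, NEGATIVE, POSITIVE
from ehrconcord.ehr import (SENSITIVE, SPECIFIC, CaseStatus, ConditionCodeSet,
                            ObservationWindow, ascertain_cohort,
                            ascertain_sensitive, ascertain_specific,
                            match_condition, merge_sources, normalize_code,
                            restrict_prior)

from conftest import make_record


class TestNormalizeCode:
    @pytest.mark.parametrize("raw, expected", [
        ("250.00", "25000"), ("f32.9", "F329"), (" I10 ", "I10"),
        ("v 70.0", "V700"),
    ])
    def test_canonical_form(self, raw, expected):
        assert normalize_code(raw) == expected

    @given(st.text(alphabet=string.ascii_letters + string.digits + ". ",
                   min_size=1).filter(lambda s: s.strip().replace(".", "")))
    def test_idempotent(self, raw):
        once = normalize_code(raw)
        assert normalize_code(once) == once

    @pytest.mark.parametrize("bad", ["", "   ", None])
    def test_empty_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_code(bad)


class TestMatching:
    def test_any_diagnostic_position_matches(self, hypertension_codeset):
        rec = make_record(codes=("E11", "J45", "I10"))  # I10 in position 3
        matched = match_condition(rec, hypertension_codeset)
        assert [m.code for m in matched] == ["I10"]

    def test_unrelated_codes_do_not_match(self, hypertension_codeset):
        assert match_condition(make_record(codes=("E11", "J45")),
                               hypertension_codeset) == []

    def test_prefix_vs_exact_mode(self):
        rec = make_record(codes=("I10.9",))
        prefix = ConditionCodeSet("htn", (("ICD10", "I10"),), "prefix")
        exact = ConditionCodeSet("htn", (("ICD10", "I10"),), "exact")
        assert match_condition(rec, prefix)
        assert not match_condition(rec, exact)

    def test_system_must_agree(self):
        codeset = ConditionCodeSet("htn", (("ICD9", "401"),), "prefix")
        assert not match_condition(make_record(codes=("401",)), codeset)


class TestSensitiveCriterion:
    def test_single_outpatient_code_is_positive(self, hypertension_codeset):
        rec = make_record(setting="outpatient", when=date(2005, 3, 2))
        cs = ascertain_sensitive("P1", [rec], hypertension_codeset)
        assert cs.status == POSITIVE
        assert cs.diagnosis_date == date(2005, 3, 2)

    def test_code_outside_window_is_negative(self, hypertension_codeset):
        rec = make_record(when=date(2021, 1, 1))   # after window end
        assert ascertain_sensitive("P1", [rec],
                                   hypertension_codeset).status == NEGATIVE

    def test_diagnosis_date_is_earliest_match(self, hypertension_codeset):
        recs = [make_record(when=date(2010, 5, 1)),
                make_record(when=date(2003, 2, 1)),
                make_record(when=date(2015, 8, 1))]
        for ordering in (recs, recs[::-1]):
            cs = ascertain_sensitive("P1", ordering, hypertension_codeset)
            assert cs.diagnosis_date == date(2003, 2, 1)


class TestSpecificCriterion:
    def test_single_outpatient_code_is_negative(self, hypertension_codeset):
        """The worked example: one outpatient code flags a case under
        sensitive criteria but not under specific criteria."""
        rec = make_record(setting="outpatient")
        assert ascertain_sensitive("P1", [rec],
                                   hypertension_codeset).status == POSITIVE
        assert ascertain_specific("P1", [rec],
                                  hypertension_codeset).status == NEGATIVE

    def test_single_inpatient_code_is_positive(self, hypertension_codeset):
        rec = make_record(setting="inpatient", when=date(2007, 1, 5))
        cs = ascertain_specific("P1", [rec], hypertension_codeset)
        assert cs.status == POSITIVE
        assert cs.diagnosis_date == date(2007, 1, 5)

    def test_two_outpatient_dates_rule(self, hypertension_codeset):
        same_day = [make_record(when=date(2010, 1, 1)),
                    make_record(when=date(2010, 1, 1))]
        distinct = [make_record(when=date(2010, 1, 1)),
                    make_record(when=date(2010, 1, 2))]
        assert ascertain_specific("P1", same_day,
                                  hypertension_codeset).status == NEGATIVE
        cs = ascertain_specific("P1", distinct, hypertension_codeset)
        assert cs.status == POSITIVE
        assert cs.diagnosis_date == date(2010, 1, 1)   # first of the two
        # the distinct-date requirement is configurable
        cs = ascertain_specific("P1", same_day, hypertension_codeset,
                                distinct_outpatient_dates=False)
        assert cs.status == POSITIVE


class TestTemporalRestriction:
    def test_same_day_code_does_not_count(self, hypertension_codeset, window):
        rec = make_record(when=date(2010, 6, 1))
        cs = restrict_prior("P1", [rec], hypertension_codeset, window,
                            reference_date=date(2010, 6, 1))
        assert cs.status == NEGATIVE
        cs = restrict_prior("P1", [rec], hypertension_codeset, window,
                            reference_date=date(2010, 6, 2))
        assert cs.status == POSITIVE

    def test_personal_history_code_excluded(self, hypertension_codeset, window):
        rec = make_record(when=date(2005, 1, 1), personal_history=True)
        cs = restrict_prior("P1", [rec], hypertension_codeset, window,
                            reference_date=date(2010, 1, 1))
        assert cs.status == NEGATIVE
        # but the same code counts in the unrestricted analysis
        assert ascertain_sensitive("P1", [rec],
                                   hypertension_codeset).status == POSITIVE

    def test_late_reference_equals_unrestricted_minus_history(
            self, hypertension_codeset, window):
        recs = [make_record(when=date(2003, 1, 1)),
                make_record(when=date(2012, 7, 1)),
                make_record(when=date(2018, 1, 1), personal_history=True)]
        restricted = restrict_prior("P1", recs, hypertension_codeset, window,
                                    reference_date=date(2020, 12, 31))
        unrestricted = ascertain_sensitive("P1", recs, hypertension_codeset,
                                           window,
                                           exclude_personal_history=True)
        assert restricted.status == unrestricted.status
        assert restricted.diagnosis_date == unrestricted.diagnosis_date

    def test_missing_reference_rejected(self, hypertension_codeset, window):
        with pytest.raises(ValueError):
            restrict_prior("P1", [], hypertension_codeset, window,
                           reference_date=None)


class TestMergeSources:
    def test_earliest_date_wins_both_orderings(self):
        vha = CaseStatus("P1", "htn", POSITIVE, date(2005, 1, 1),
                         criterion=SENSITIVE)
        mdr = CaseStatus("P1", "htn", POSITIVE, date(2003, 6, 1),
                         criterion=SENSITIVE)
        for pair in ((vha, mdr), (mdr, vha)):
            merged = merge_sources(*pair)
            assert merged.status == POSITIVE
            assert merged.diagnosis_date == date(2003, 6, 1)

    def test_either_positive_suffices(self):
        pos = CaseStatus("P1", "htn", POSITIVE, date(2005, 1, 1),
                         criterion=SENSITIVE)
        neg = CaseStatus("P1", "htn", NEGATIVE, criterion=SENSITIVE)
        merged = merge_sources(pos, neg)
        assert merged.status == POSITIVE
        assert merged.diagnosis_date == date(2005, 1, 1)

    def test_both_negative_and_mismatch_error(self):
        neg = CaseStatus("P1", "htn", NEGATIVE, criterion=SENSITIVE)
        assert merge_sources(neg, neg).status == NEGATIVE
        other = CaseStatus("P1", "asthma", NEGATIVE, criterion=SENSITIVE)
        with pytest.raises(ValueError):
            merge_sources(neg, other)


# ---------------------------------------------------------------------------
# Randomized cross-checks against an exhaustive brute-force evaluator


def _brute_force(records, codeset, window, criterion, reference_date=None,
                 exclude_ph=False):
    """Independent loop-based evaluator of both criteria."""
    events = []
    for rec in records:
        if not window.start <= rec.event_date <= window.end:
            continue
        if reference_date is not None and rec.event_date >= reference_date:
            continue
        hit = False
        for cd in rec.codes:
            if exclude_ph and cd.personal_history:
                continue
            norm = normalize_code(cd.code)
            for system, pattern in codeset.entries:
                if system != cd.system:
                    continue
                if codeset.match_mode == "exact" and norm == pattern:
                    hit = True
                if codeset.match_mode == "prefix" and norm.startswith(pattern):
                    hit = True
        if hit:
            events.append(rec)
    if criterion == SENSITIVE:
        dates = [r.event_date for r in events]
    else:
        dates = [r.event_date for r in events if r.setting == "inpatient"]
        out_dates = [r.event_date for r in events if r.setting == "outpatient"]
        if len(set(out_dates)) >= 2:
            dates += out_dates
    if dates:
        return POSITIVE, min(dates)
    return NEGATIVE, None


def _random_records(rng, n_max=20):
    n = rng.integers(0, n_max + 1)
    recs = []
    for _ in range(n):
        when = date(1997, 1, 1) + timedelta(days=int(rng.integers(0, 9000)))
        codes = tuple(str(rng.choice(["I10", "I109", "E11", "J45", "Z000"]))
                      for _ in range(rng.integers(1, 4)))
        recs.append(make_record(
            source=str(rng.choice(["VHA", "MDR"])),
            setting=str(rng.choice(["inpatient", "outpatient"])),
            when=when, codes=codes,
            personal_history=bool(rng.random() < 0.15)))
    return recs


@pytest.mark.parametrize("criterion", [SENSITIVE, SPECIFIC])
def test_criteria_agree_with_brute_force(criterion, hypertension_codeset,
                                         window):
    rng = np.random.default_rng(20259)
    fn = ascertain_sensitive if criterion == SENSITIVE else ascertain_specific
    for _ in range(200):
        recs = _random_records(rng)
        expected = _brute_force(recs, hypertension_codeset, window, criterion)
        got = fn("P1", recs, hypertension_codeset, window)
        assert (got.status, got.diagnosis_date) == expected


def test_restricted_criteria_agree_with_brute_force(hypertension_codeset,
                                                    window):
    rng = np.random.default_rng(404)
    for _ in range(200):
        recs = _random_records(rng)
        ref = date(1999, 1, 1) + timedelta(days=int(rng.integers(0, 9000)))
        for criterion in (SENSITIVE, SPECIFIC):
            expected = _brute_force(recs, hypertension_codeset, window,
                                    criterion, reference_date=ref,
                                    exclude_ph=True)
            got = restrict_prior("P1", recs, hypertension_codeset, window,
                                 ref, criterion=criterion)
            assert (got.status, got.diagnosis_date) == expected


def test_specific_implies_sensitive(hypertension_codeset, window):
    rng = np.random.default_rng(11)
    for _ in range(200):
        recs = _random_records(rng)
        spec = ascertain_specific("P1", recs, hypertension_codeset, window)
        sens = ascertain_sensitive("P1", recs, hypertension_codeset, window)
        if spec.status == POSITIVE:
            assert sens.status == POSITIVE
            assert sens.diagnosis_date <= spec.diagnosis_date


def test_shrinking_window_never_creates_positives(hypertension_codeset):
    rng = np.random.default_rng(77)
    wide = ObservationWindow(date(1999, 10, 1), date(2020, 9, 18))
    narrow = ObservationWindow(date(2005, 1, 1), date(2015, 1, 1))
    for _ in range(100):
        recs = _random_records(rng)
        for fn in (ascertain_sensitive, ascertain_specific):
            if fn("P1", recs, hypertension_codeset, narrow).status == POSITIVE:
                assert fn("P1", recs, hypertension_codeset,
                          wide).status == POSITIVE


# ---------------------------------------------------------------------------
# Vectorized cohort path vs the per-participant operations


def _records_to_frame(records_by_pid):
    rows = []
    for pid, recs in records_by_pid.items():
        for rec in recs:
            for cd in rec.codes:
                rows.append({"participant_id": pid, "source": rec.source,
                             "setting": rec.setting,
                             "event_date": rec.event_date, "code": cd.code,
                             "code_system": cd.system,
                             "position": cd.position,
                             "personal_history": int(cd.personal_history)})
    return pd.DataFrame(rows)


@pytest.mark.parametrize("criterion", [SENSITIVE, SPECIFIC])
@pytest.mark.parametrize("scope", ["vha", "vha-mdr"])
def test_cohort_ascertainment_matches_scalar(criterion, scope,
                                             hypertension_codeset, window):
    rng = np.random.default_rng(9001)
    cohort = {f"P{i}": _random_records(rng, n_max=10) for i in range(40)}
    frame = _records_to_frame(cohort)
    result = ascertain_cohort(frame, [hypertension_codeset], window=window,
                              criterion=criterion, scope=scope,
                              participants=list(cohort))
    fn = ascertain_sensitive if criterion == SENSITIVE else ascertain_specific
    for _, row in result.iterrows():
        recs = cohort[row["participant_id"]]
        if scope == "vha":
            recs = [r for r in recs if r.source == "VHA"]
        expected = fn(row["participant_id"], recs, hypertension_codeset, window)
        assert row["status"] == expected.status
        got_date = None if pd.isna(row["diagnosis_date"]) \
            else row["diagnosis_date"].date()
        assert got_date == expected.diagnosis_date


def test_cohort_restricted_matches_scalar(hypertension_codeset, window):
    rng = np.random.default_rng(31337)
    cohort = {f"P{i}": _random_records(rng, n_max=10) for i in range(40)}
    refs = {pid: date(2000, 1, 1) + timedelta(days=int(rng.integers(0, 7000)))
            for pid in list(cohort)[:30]}    # last 10 lack a reference date
    frame = _records_to_frame(cohort)
    ref_series = pd.Series({p: pd.Timestamp(d) for p, d in refs.items()})
    result = ascertain_cohort(frame, [hypertension_codeset], window=window,
                              criterion=SENSITIVE, scope="vha-mdr",
                              participants=list(cohort),
                              reference_dates={"hypertension": ref_series})
    for _, row in result.iterrows():
        pid = row["participant_id"]
        if pid not in refs:
            assert row["status"] == MISSING
            continue
        expected = restrict_prior(pid, cohort[pid], hypertension_codeset,
                                  window, refs[pid])
        assert row["status"] == expected.status
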