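"""End-to-end concordance runs: ascertain, compare, stratify, report.

A run classifies every participant-condition twice — from the survey
with carry-forward, and from coded encounters under the configured
criterion / temporality / source scope — then crosses the two verdicts
into 2x2 tables and agreement statistics.  Health-behavior flags and
height/weight Bland-Altman summaries are produced alongside, with an
optional stratification by health-care utilization frequency.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import behaviors as bh
from . import measurements as ms
from .agreement import (MISSING, NEGATIVE, POSITIVE, AgreementResult,
                        InconsistentTableError, reconstructed_statistics,
                        round_half_up)
from .ehr import (SCOPE_VHA, SCOPE_VHA_MDR, SENSITIVE, SPECIFIC,
                  ObservationWindow, ascertain_cohort)
from .survey import classify_survey_cohort
from .synthetic import SimulationConfig, SyntheticCohort, generate_cohort
from .utilization import classify_cohort as classify_utilization_cohort
from . import io as eio

TEMPORAL_ANY = "any"
TEMPORAL_PRIOR = "prior"

_FLAG_TO_STATUS = {bh.YES: POSITIVE, bh.NO: NEGATIVE, MISSING: MISSING}


@dataclass
class RunConfig:
    """Analysis configuration for one concordance run."""

    criterion: str = SENSITIVE
    temporality: str = TEMPORAL_ANY
    scope: str = SCOPE_VHA
    stratify_utilization: bool = False
    distinct_outpatient_dates: bool = True
    code_exclusions: dict = field(default_factory=dict)
    weight_window_days: int = 365
    weight_window_two_sided: bool = True
    negatives_reference: str = "last-survey"   # or "exclude"
    window: ObservationWindow = field(default_factory=ObservationWindow)

    def validate(self) -> None:
        if self.criterion not in (SENSITIVE, SPECIFIC):
            raise ValueError(f"criterion: unknown value {self.criterion!r}")
        if self.temporality not in (TEMPORAL_ANY, TEMPORAL_PRIOR):
            raise ValueError(f"temporality: unknown value {self.temporality!r}")
        if self.scope not in (SCOPE_VHA, SCOPE_VHA_MDR):
            raise ValueError(f"scope: unknown value {self.scope!r}")
        if self.negatives_reference not in ("last-survey", "exclude"):
            raise ValueError(
                f"negatives_reference: unknown value {self.negatives_reference!r}")
        if self.weight_window_days < 0:
            raise ValueError("weight_window_days: must be >= 0")


@dataclass
class CohortData:
    """The five input tables plus the condition code sets."""

    participants: pd.DataFrame
    encounters: pd.DataFrame
    survey: pd.DataFrame
    vitals: pd.DataFrame
    behaviors: pd.DataFrame
    codesets: list
    source_digests: dict = field(default_factory=dict)

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort) -> "CohortData":
        return cls(cohort.participants, cohort.encounters, cohort.survey,
                   cohort.vitals, cohort.behaviors, cohort.codesets())

    @classmethod
    def from_dir(cls, directory) -> "CohortData":
        directory = Path(directory)
        paths = {name: directory / f"{name}.csv"
                 for name in ("participants", "encounters", "survey",
                              "vitals", "behaviors", "codesets")}
        digests = {name: hashlib.sha256(p.read_bytes()).hexdigest()
                   for name, p in paths.items()}
        return cls(eio.read_participants(paths["participants"]),
                   eio.read_encounters(paths["encounters"]),
                   eio.read_survey(paths["survey"]),
                   eio.read_vitals(paths["vitals"]),
                   eio.read_behaviors(paths["behaviors"]),
                   eio.read_codesets(paths["codesets"]),
                   source_digests=digests)


@dataclass
class ConcordanceReport:
    """Everything one run produces."""

    conditions: pd.DataFrame
    behaviors: pd.DataFrame
    height: Optional[ms.BlandAltmanSummary]
    weight_by_year: dict
    strata: Optional[pd.DataFrame]
    manifest: dict


def reference_date_for(status: str, first_yes_date: Optional[date],
                       last_survey_date: Optional[date],
                       negatives_reference: str = "last-survey",
                       ) -> Optional[date]:
    """Reference date anchoring the prior-to-self-report restriction.

    Survey positives use the first-yes survey date; negatives use their
    last completed survey date so both groups face a comparable
    look-back (configurable to exclusion); survey-missing participants
    have no reference date and drop out of the restricted comparison.
    """
    if status == POSITIVE:
        return first_yes_date
    if status == NEGATIVE and negatives_reference == "last-survey":
        return last_survey_date
    return None


def _agreement_row(survey_status: pd.Series, ehr_status: pd.Series,
                   condition: str, **extra) -> dict:
    ok = (survey_status != MISSING) & (ehr_status != MISSING)
    s = survey_status[ok] == POSITIVE
    e = ehr_status[ok] == POSITIVE
    a = int((s & e).sum())
    b = int((s & ~e).sum())
    c = int((~s & e).sum())
    d = int((~s & ~e).sum())
    row = {"condition": condition, "n": a + b + c + d,
           "n_excluded_missing": int((~ok).sum()),
           "survey_n": a + b, "ehr_n": a + c}
    if a + b + c + d > 0:
        res = AgreementResult.from_cells(a, b, c, d, condition=condition)
        row.update({"survey_prevalence": res.survey_prevalence,
                    "ehr_prevalence": res.ehr_prevalence,
                    "positive_agreement": res.positive_agreement,
                    "negative_agreement": res.negative_agreement,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "youden_j": res.youden_j})
    else:
        row.update(dict.fromkeys(
            ["survey_prevalence", "ehr_prevalence", "positive_agreement",
             "negative_agreement", "sensitivity", "specificity", "youden_j"],
            np.nan))
    row.update(extra)
    return row


def _behavior_flags(data: CohortData, roster: pd.Index,
                    last_survey: pd.Series) -> pd.DataFrame:
    """Per-participant survey and record flags for smoking and drinking."""
    survey = data.survey
    pid = survey["participant_id"]

    # survey ever-smoker: carry-forward of the 100-cigarette item
    cig = survey["cigs_100"]
    any_yes = (cig == 1).groupby(pid.to_numpy()).any().reindex(roster,
                                                               fill_value=False)
    any_no = (cig == 0).groupby(pid.to_numpy()).any().reindex(roster,
                                                              fill_value=False)
    survey_smoker = np.where(any_yes, bh.YES, np.where(any_no, bh.NO, MISSING))

    # survey problem drinking: any-wave endorsement of >=1 of 5 PHQ items
    phq = survey[[f"phq_{i}" for i in range(1, 6)]]
    wave_yes = (phq == 1).any(axis=1)
    wave_no = (phq == 0).all(axis=1)
    p_yes = wave_yes.groupby(pid.to_numpy()).any().reindex(roster,
                                                           fill_value=False)
    p_no = wave_no.groupby(pid.to_numpy()).any().reindex(roster,
                                                         fill_value=False)
    survey_drink = np.where(p_yes, bh.YES, np.where(p_no, bh.NO, MISSING))

    anchor = last_survey  # record assessments are matched to the last survey

    beh = data.behaviors.copy()
    beh["date"] = pd.to_datetime(beh["date"])
    beh["anchor"] = pd.to_datetime(beh["participant_id"].map(anchor))

    # AUDIT-C: latest assessment strictly before the anchor, highest score
    audit = beh[(beh["kind"] == bh.KIND_AUDITC)
                & (beh["date"] < beh["anchor"])].copy()
    audit["score"] = audit["value"].astype(float).astype(int)
    audit = audit.sort_values(["participant_id", "date", "score"])
    chosen = audit.groupby("participant_id").tail(1).set_index("participant_id")
    sex = data.participants.set_index("participant_id")["sex"].reindex(roster)
    ehr_drink = pd.Series(MISSING, index=roster, dtype=object)
    have = chosen.index.intersection(roster)
    cutoff = np.where(sex.loc[have].astype(str).str.upper().str[:1] == "F",
                      bh.AUDITC_CUTOFF_FEMALE, bh.AUDITC_CUTOFF_MALE)
    ehr_drink.loc[have] = np.where(
        chosen.loc[have, "score"].to_numpy() >= cutoff, bh.YES, bh.NO)

    # smoking status closest to the anchor on either side; ties earlier
    smoke = beh[(beh["kind"] == bh.KIND_SMOKING) & beh["anchor"].notna()].copy()
    smoke["absdelta"] = (smoke["date"] - smoke["anchor"]).abs()
    smoke = smoke.sort_values(["participant_id", "absdelta", "date"])
    nearest = smoke.groupby("participant_id").head(1).set_index("participant_id")
    ehr_smoker = pd.Series(MISSING, index=roster, dtype=object)
    have = nearest.index.intersection(roster)
    ever = nearest.loc[have, "value"].astype(str).str.strip().str.lower() \
        .isin(bh.EVER_SMOKER_STATUSES)
    ehr_smoker.loc[have] = np.where(ever, bh.YES, bh.NO)

    return pd.DataFrame({
        "survey_ever_smoker": survey_smoker,
        "ehr_ever_smoker": ehr_smoker.to_numpy(),
        "survey_problem_drinking": survey_drink,
        "ehr_alcohol_misuse": ehr_drink.to_numpy(),
    }, index=roster)


def _modal_value(df: pd.DataFrame) -> pd.Series:
    """Per-participant modal value of (participant_id, date, value) rows;
    frequency ties break toward the earliest-dated value."""
    if df.empty:
        return pd.Series(dtype=float)
    grp = df.groupby(["participant_id", "value"])
    stats = grp.agg(count=("value", "size"), first_date=("date", "min"))
    stats = stats.reset_index().sort_values(
        ["participant_id", "count", "first_date", "value"],
        ascending=[True, False, True, True])
    best = stats.groupby("participant_id").head(1)
    return best.set_index("participant_id")["value"]


def _height_pairs(data: CohortData) -> list:
    survey = data.survey
    sh = pd.DataFrame({"participant_id": survey["participant_id"],
                       "date": pd.to_datetime(survey["survey_date"]),
                       "value": survey["height_in"]}).dropna(subset=["value"])
    sh = sh[(sh["value"] >= ms.HEIGHT_MIN_IN) & (sh["value"] <= ms.HEIGHT_MAX_IN)]
    vit = ms.filter_extremes(data.vitals)
    eh = vit[vit["kind"] == ms.KIND_HEIGHT][["participant_id", "date", "value"]]
    survey_mode = _modal_value(sh)
    record_mode = _modal_value(eh)
    both = pd.concat([record_mode.rename("record"),
                      survey_mode.rename("survey")], axis=1).dropna()
    return list(zip(both["record"], both["survey"]))


def _weight_pairs_by_year(data: CohortData, window_days: int,
                          two_sided: bool) -> dict:
    survey = data.survey
    sw = pd.DataFrame({"participant_id": survey["participant_id"],
                       "survey_date": pd.to_datetime(survey["survey_date"]),
                       "wave": survey["wave"],
                       "survey_weight": survey["weight_lb"]}) \
        .dropna(subset=["survey_weight"])
    sw = sw[(sw["survey_weight"] >= ms.WEIGHT_MIN_LB)
            & (sw["survey_weight"] <= ms.WEIGHT_MAX_LB)]
    vit = ms.filter_extremes(data.vitals)
    ew = vit[vit["kind"] == ms.KIND_WEIGHT][["participant_id", "date", "value"]]
    ew = ew.assign(date=pd.to_datetime(ew["date"]))
    merged = sw.merge(ew, on="participant_id", how="inner")
    delta = (merged["date"] - merged["survey_date"]).dt.days
    if two_sided:
        merged = merged[delta.abs() <= window_days]
    else:
        merged = merged[(delta <= 0) & (delta >= -window_days)]
    if merged.empty:
        return {}
    merged["absdelta"] = (merged["date"] - merged["survey_date"]).abs()
    merged = merged.sort_values(["participant_id", "wave", "absdelta", "date"])
    closest = merged.groupby(["participant_id", "wave"]).head(1)
    out = {}
    for year, grp in closest.groupby(closest["survey_date"].dt.year):
        if len(grp) >= 2:
            out[int(year)] = list(zip(grp["value"], grp["survey_weight"]))
    return out


def run_concordance(data: CohortData,
                    config: RunConfig = RunConfig()) -> ConcordanceReport:
    """Run the full survey-vs-record concordance analysis on one cohort."""
    config.validate()
    roster = pd.Index(data.participants["participant_id"])
    conditions = [cs.condition for cs in data.codesets]

    classification = classify_survey_cohort(data.survey, conditions,
                                            participants=roster)
    reference_dates = None
    if config.temporality == TEMPORAL_PRIOR:
        reference_dates = {}
        for cond in conditions:
            frame = classification.conditions[cond]
            refs = frame["first_yes_date"].copy()
            if config.negatives_reference == "last-survey":
                neg = frame["status"] == NEGATIVE
                refs[neg] = classification.last_survey_date[neg]
            reference_dates[cond] = refs.dropna()

    ehr_status = ascertain_cohort(
        data.encounters, data.codesets, window=config.window,
        criterion=config.criterion, scope=config.scope,
        participants=roster, reference_dates=reference_dates,
        distinct_outpatient_dates=config.distinct_outpatient_dates,
        code_exclusions=config.code_exclusions or None)

    common = {"criterion": config.criterion, "temporality": config.temporality,
              "scope": config.scope}
    rows = []
    ehr_by_cond = {}
    for cond, grp in ehr_status.groupby("condition", sort=False):
        ehr_by_cond[cond] = grp.set_index("participant_id")["status"] \
            .reindex(roster)
    for cond in conditions:
        rows.append(_agreement_row(classification.status(cond),
                                   ehr_by_cond[cond], cond, **common))
    condition_report = pd.DataFrame(rows)

    # health behaviors
    flags = _behavior_flags(data, roster, classification.last_survey_date)
    beh_rows = []
    for measure, (scol, ecol) in {
            "ever_smoker": ("survey_ever_smoker", "ehr_ever_smoker"),
            "problem_drinking": ("survey_problem_drinking",
                                 "ehr_alcohol_misuse")}.items():
        beh_rows.append(_agreement_row(
            flags[scol].map(_FLAG_TO_STATUS),
            flags[ecol].map(_FLAG_TO_STATUS), measure, **common))
    behavior_report = pd.DataFrame(beh_rows)

    # body measurements
    height_pairs = _height_pairs(data)
    height_summary = ms.bland_altman(height_pairs) \
        if len(height_pairs) >= 2 else None
    weight_by_year = {year: ms.bland_altman(pairs) for year, pairs
                      in _weight_pairs_by_year(
                          data, config.weight_window_days,
                          config.weight_window_two_sided).items()}

    # utilization strata
    strata = None
    if config.stratify_utilization:
        util = classify_utilization_cohort(data.encounters,
                                           cutoff=config.window.end) \
            .set_index("participant_id")["category"].reindex(roster,
                                                             fill_value="none")
        strata_rows = []
        for cond in conditions:
            for cat in sorted(util.unique()):
                members = util.index[util == cat]
                strata_rows.append(_agreement_row(
                    classification.status(cond).loc[members],
                    ehr_by_cond[cond].loc[members], cond,
                    utilization=cat, **common))
        strata = pd.DataFrame(strata_rows)

    n_pairs = int(condition_report["n"].sum())
    n_excluded = int(condition_report["n_excluded_missing"].sum())
    manifest = {
        "config": {**asdict(config),
                   "window": {"start": config.window.start.isoformat(),
                              "end": config.window.end.isoformat()}},
        "n_participants": int(len(roster)),
        "n_encounter_rows": int(len(data.encounters)),
        "n_survey_rows": int(len(data.survey)),
        "conditions": conditions,
        "pairs_retained": n_pairs,
        "pairs_excluded_missing": n_excluded,
        "pairs_total": n_pairs + n_excluded,
        "input_digests": data.source_digests,
    }
    return ConcordanceReport(condition_report, behavior_report,
                             height_summary, weight_by_year, strata, manifest)


def _format_row(row: pd.Series) -> str:
    def pct(x):
        return f"{100 * x:5.1f}%" if pd.notna(x) else "   -  "

    def num(x):
        return f"{x:5.2f}" if pd.notna(x) else "  -  "

    return (f"{row['condition']:<24} {row['survey_n']:>8} ({pct(row['survey_prevalence'])})"
            f" {row['ehr_n']:>8} ({pct(row['ehr_prevalence'])})"
            f"  PA {pct(row['positive_agreement'])}  NA {pct(row['negative_agreement'])}"
            f"  J {num(row['youden_j'])}")


def render_report(report: ConcordanceReport) -> str:
    """Aligned human-readable rendering of the condition table."""
    lines = [f"{'condition':<24} {'survey n (%)':>17} {'record n (%)':>17}"
             f"  {'PA':>9}  {'NA':>9}  {'J':>7}"]
    for _, row in report.conditions.iterrows():
        lines.append(_format_row(row))
    for _, row in report.behaviors.iterrows():
        lines.append(_format_row(row))
    return "\n".join(lines)


def write_report(report: ConcordanceReport, outdir) -> dict:
    """Write the report bundle (delimited tables + manifest) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    report.conditions.to_csv(outdir / "conditions.csv", index=False)
    paths["conditions"] = outdir / "conditions.csv"
    report.behaviors.to_csv(outdir / "behaviors.csv", index=False)
    paths["behaviors"] = outdir / "behaviors.csv"
    ba_rows = []
    if report.height is not None:
        ba_rows.append({"measure": "height_in", "year": "",
                        **asdict(report.height)})
    for year, summary in sorted(report.weight_by_year.items()):
        ba_rows.append({"measure": "weight_lb", "year": year,
                        **asdict(summary)})
    pd.DataFrame(ba_rows).to_csv(outdir / "bland_altman.csv", index=False)
    paths["bland_altman"] = outdir / "bland_altman.csv"
    if report.strata is not None:
        report.strata.to_csv(outdir / "strata.csv", index=False)
        paths["strata"] = outdir / "strata.csv"
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(report.manifest, fh, indent=2, default=str)
    paths["manifest"] = outdir / "manifest.json"
    (outdir / "report.txt").write_text(render_report(report) + "\n",
                                       encoding="utf-8")
    paths["report"] = outdir / "report.txt"
    return paths


def validate_printed_table(table: pd.DataFrame, *, pa_decimals: int = 1,
                           na_decimals: int = 1,
                           j_decimals: int = 2) -> pd.DataFrame:
    """Check printed table rows for internal consistency.

    Each row must provide ``condition, n_total, n_survey, n_ehr,
    positive_agreement`` (percent at printed precision) and the printed
    ``negative_agreement`` (percent) and ``youden_j``.  The cells are
    reconstructed from N, the margins, and PA; a row is flagged when no
    consistent integer dual-positive count reproduces the printed NA
    and J at printed precision.
    """
    required = ["condition", "n_total", "n_survey", "n_ehr",
                "positive_agreement", "negative_agreement", "youden_j"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"printed table lacks columns {missing}")
    out = []
    for _, row in table.iterrows():
        entry = {"condition": row["condition"], "ok": False,
                 "n_candidates": 0, "reconstructed_na": None,
                 "reconstructed_j": None, "note": ""}
        try:
            recon = reconstructed_statistics(
                int(row["n_total"]), int(row["n_survey"]), int(row["n_ehr"]),
                float(row["positive_agreement"]), pa_decimals=pa_decimals,
                na_decimals=na_decimals, j_decimals=j_decimals)
        except InconsistentTableError as exc:
            entry["note"] = str(exc)
            out.append(entry)
            continue
        entry["n_candidates"] = len(recon["tables"])
        entry["reconstructed_na"] = recon["na_percent"]
        entry["reconstructed_j"] = recon["j"]
        na_ok = round_half_up(float(row["negative_agreement"]),
                              na_decimals) in recon["na_percent"]
        j_ok = round_half_up(float(row["youden_j"]),
                             j_decimals) in recon["j"]
        entry["ok"] = bool(na_ok and j_ok)
        if not entry["ok"]:
            entry["note"] = ("printed NA/J not reproducible from margins "
                             "and printed PA")
        out.append(entry)
    return pd.DataFrame(out)
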