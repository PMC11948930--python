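"""Synthetic linked survey+EHR cohorts with known latent truth.

Every participant carries a latent true status per condition.  Two
imperfect observation channels look at that truth:

* the survey channel self-reports the condition with the configured
  survey sensitivity/specificity;
* the record channel produces qualifying diagnosis codes with the
  configured coding sensitivity/specificity.

The two channels are conditionally independent given the true status
(a shared-error knob induces positive dependence when set above zero),
so the expected 2x2 cell probabilities — and hence positive/negative
agreement and Youden's J — have a closed form, implemented in
:func:`expected_agreement`.  That closed form is the ground-truth
oracle for the whole downstream pipeline.

The channel outcome is drawn once per participant-condition; wave
answers are then materialized consistently with it (a channel-positive
participant first reports at a uniformly chosen completed wave and at
every completed wave thereafter).  Missingness therefore arises from
wave nonresponse, which is independent of the true status, and the
closed form remains exact among classified pairs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from datetime import date
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .agreement import AgreementResult
from .ehr import (INPATIENT, MDR, OUTPATIENT, VHA, ConditionCodeSet,
                  ObservationWindow)


@dataclass(frozen=True)
class ConditionSpec:
    """Generative parameters for one condition.

    ``prevalence`` is the latent true prevalence; the four operating
    characteristics are the per-channel probabilities of a positive
    observation given the true status; ``mean_coded_encounters`` is the
    mean number of coded encounters among record-channel-positive true
    cases (at least one is always drawn).
    """

    name: str
    prevalence: float
    survey_sensitivity: float
    survey_specificity: float
    ehr_sensitivity: float
    ehr_specificity: float
    mean_coded_encounters: float = 2.0
    code: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            object.__setattr__(self, "code", "X" + self.name[:3].upper())


#: Default panel of conditions spanning the prevalence/agreement range a
#: large veteran cohort exhibits: a common chronic condition coded often,
#: a symptom-defined condition reported more than coded, a moderately
#: rare condition, a very rare one, and a mental-health condition coded
#: more often than reported.
DEFAULT_CONDITIONS: Tuple[ConditionSpec, ...] = (
    ConditionSpec("hypertension", 0.25, 0.70, 0.95, 0.75, 0.97, 3.0, "I10"),
    ConditionSpec("migraine", 0.20, 0.65, 0.92, 0.60, 0.97, 2.0, "G43"),
    ConditionSpec("asthma", 0.09, 0.60, 0.97, 0.55, 0.99, 2.0, "J45"),
    ConditionSpec("multiple_sclerosis", 0.008, 0.50, 0.999, 0.50, 0.999, 2.0, "G35"),
    ConditionSpec("depression", 0.35, 0.60, 0.90, 0.75, 0.90, 4.0, "F32"),
)

DEFAULT_WAVE_DATES: Tuple[date, ...] = (
    date(2001, 7, 1), date(2004, 7, 1), date(2007, 7, 1),
    date(2011, 7, 1), date(2014, 7, 1),
)

_PROB_FIELDS = ("wave_response_prob", "item_missing_prob", "inpatient_fraction",
                "vha_fraction", "personal_history_fraction", "shared_error",
                "female_fraction", "problem_drinking_prevalence",
                "smoking_prevalence")


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults emulate a five-wave,
    two-decade linked cohort of regular health-system users."""

    n_participants: int = 1000
    conditions: Tuple[ConditionSpec, ...] = DEFAULT_CONDITIONS
    wave_dates: Tuple[date, ...] = DEFAULT_WAVE_DATES
    wave_response_prob: float = 0.7
    item_missing_prob: float = 0.0
    window: ObservationWindow = field(default_factory=ObservationWindow)
    encounter_rate: float = 1.0          # background encounters per person-year
    inpatient_fraction: float = 0.10
    vha_fraction: float = 0.85           # remainder lands in MDR
    personal_history_fraction: float = 0.0
    shared_error: float = 0.0            # channel-correlation knob
    female_fraction: float = 0.30
    height_mean_male_in: float = 69.5
    height_mean_female_in: float = 64.5
    height_sd_in: float = 2.8
    weight_mean_male_lb: float = 190.0
    weight_mean_female_lb: float = 155.0
    weight_sd_lb: float = 30.0
    height_report_bias_in: float = 0.5   # self-report minus truth
    height_report_sd_in: float = 0.8
    weight_report_bias_lb: float = -6.0
    weight_report_sd_lb: float = 8.0
    problem_drinking_prevalence: float = 0.30
    smoking_prevalence: float = 0.50
    seed: int = 0

    @property
    def n_waves(self) -> int:
        return len(self.wave_dates)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants: must be >= 1")
        if not self.conditions:
            raise ValueError("conditions: at least one condition is required")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: probability must be in [0, 1], got {v}")
        for spec in self.conditions:
            for attr in ("prevalence", "survey_sensitivity", "survey_specificity",
                         "ehr_sensitivity", "ehr_specificity"):
                v = getattr(spec, attr)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"conditions[{spec.name}].{attr}: must be in [0, 1], got {v}")
            if spec.mean_coded_encounters < 0:
                raise ValueError(
                    f"conditions[{spec.name}].mean_coded_encounters: must be >= 0")
        if any(b >= a for a, b in zip(self.wave_dates[1:], self.wave_dates)):
            raise ValueError("wave_dates: must be strictly increasing")
        if self.encounter_rate < 0:
            raise ValueError("encounter_rate: must be >= 0")
        if self.window.start >= self.window.end:
            raise ValueError("window: start must precede end")

    def condition(self, name: str) -> ConditionSpec:
        for spec in self.conditions:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown condition {name!r}")


@dataclass
class SyntheticCohort:
    """Generated tables plus the parameters that produced them."""

    participants: pd.DataFrame
    encounters: pd.DataFrame
    survey: pd.DataFrame
    vitals: pd.DataFrame
    behaviors: pd.DataFrame
    config: SimulationConfig

    def codesets(self) -> list[ConditionCodeSet]:
        return [ConditionCodeSet(s.name, (("ICD10", s.code),), "prefix")
                for s in self.config.conditions]

    @property
    def condition_names(self) -> list[str]:
        return [s.name for s in self.config.conditions]


def _uniform_dates(rng: np.random.Generator, n: int,
                   window: ObservationWindow) -> np.ndarray:
    span = (window.end - window.start).days
    offsets = rng.integers(0, span + 1, n)
    return (np.datetime64(window.start, "D")
            + offsets.astype("timedelta64[D]")).astype("datetime64[ns]")


def _channel_flags(rng: np.random.Generator, truth: np.ndarray,
                   spec: ConditionSpec, shared_error: float
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Draw the two channel outcomes, optionally sharing a uniform."""
    n = truth.size
    u_shared = rng.random(n)
    share = rng.random(n) < shared_error
    u1 = np.where(share, u_shared, rng.random(n))
    u2 = np.where(share, u_shared, rng.random(n))
    p_survey = np.where(truth, spec.survey_sensitivity, 1 - spec.survey_specificity)
    p_ehr = np.where(truth, spec.ehr_sensitivity, 1 - spec.ehr_specificity)
    return u1 < p_survey, u2 < p_ehr


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Deterministically generate a linked cohort from the configuration.

    Each output table draws from its own pseudo-random stream spawned
    from the master seed, so regenerating with an extra table leaves
    the others byte-identical.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rng_people, rng_chan, rng_enc, rng_survey, rng_vitals, rng_behav = \
        (np.random.default_rng(s) for s in seeds)

    n = config.n_participants
    window = config.window
    years = (window.end - window.start).days / 365.25
    pids = np.array([f"P{i:06d}" for i in range(n)])

    # ----- participants: latent truth -------------------------------------
    female = rng_people.random(n) < config.female_fraction
    sex = np.where(female, "F", "M")
    true_height = np.where(
        female,
        rng_people.normal(config.height_mean_female_in, config.height_sd_in, n),
        rng_people.normal(config.height_mean_male_in, config.height_sd_in, n))
    true_weight = np.where(
        female,
        rng_people.normal(config.weight_mean_female_lb, config.weight_sd_lb, n),
        rng_people.normal(config.weight_mean_male_lb, config.weight_sd_lb, n))
    true_weight = np.clip(true_weight, 90.0, 450.0)
    true_height = np.clip(true_height, 50.0, 90.0)
    truth = {s.name: rng_people.random(n) < s.prevalence
             for s in config.conditions}
    true_misuse = rng_people.random(n) < config.problem_drinking_prevalence
    true_smoker = rng_people.random(n) < config.smoking_prevalence

    participants = pd.DataFrame({"participant_id": pids, "sex": sex,
                                 "true_height_in": true_height,
                                 "true_weight_lb": true_weight,
                                 "true_problem_drinking": true_misuse.astype(int),
                                 "true_ever_smoker": true_smoker.astype(int)})
    for name, t in truth.items():
        participants[f"true_{name}"] = t.astype(int)

    # ----- observation channels -------------------------------------------
    survey_flag = {}
    ehr_flag = {}
    for spec in config.conditions:
        s_flag, e_flag = _channel_flags(rng_chan, truth[spec.name], spec,
                                        config.shared_error)
        survey_flag[spec.name] = s_flag
        ehr_flag[spec.name] = e_flag

    # ----- encounters ------------------------------------------------------
    parts = []

    def _encounter_block(rng, pid_idx, code, personal_history):
        m = pid_idx.size
        return pd.DataFrame({
            "participant_id": pids[pid_idx],
            "source": np.where(rng.random(m) < config.vha_fraction, VHA, MDR),
            "setting": np.where(rng.random(m) < config.inpatient_fraction,
                                INPATIENT, OUTPATIENT),
            "event_date": _uniform_dates(rng, m, window),
            "code": code,
            "code_system": "ICD10",
            "position": rng.integers(1, 4, m),
            "personal_history": personal_history,
        })

    bg_counts = rng_enc.poisson(config.encounter_rate * years, n)
    bg_idx = np.repeat(np.arange(n), bg_counts)
    parts.append(_encounter_block(rng_enc, bg_idx, "Z000",
                                  np.zeros(bg_idx.size, int)))

    for spec in config.conditions:
        flag = ehr_flag[spec.name]
        tp = flag & truth[spec.name]
        fp = flag & ~truth[spec.name]
        k = np.zeros(n, int)
        k[tp] = 1 + rng_enc.poisson(max(spec.mean_coded_encounters - 1, 0.0),
                                    tp.sum())
        k[fp] = 1                       # a stray miscoded visit
        idx = np.repeat(np.arange(n), k)
        ph = (rng_enc.random(idx.size)
              < config.personal_history_fraction).astype(int)
        parts.append(_encounter_block(rng_enc, idx, spec.code, ph))

    encounters = pd.concat(parts, ignore_index=True)

    # ----- survey -----------------------------------------------------------
    n_waves = config.n_waves
    responded = rng_survey.random((n, n_waves)) < config.wave_response_prob
    n_resp = responded.sum(axis=1)
    cum = responded.cumsum(axis=1)
    row_pid, row_wave = np.nonzero(responded)
    m = row_pid.size
    wave_dates64 = np.array([np.datetime64(d, "D") for d in config.wave_dates],
                            dtype="datetime64[D]").astype("datetime64[ns]")
    survey = pd.DataFrame({"participant_id": pids[row_pid],
                           "wave": row_wave,
                           "survey_date": wave_dates64[row_wave]})

    wave_grid = np.arange(n_waves)
    for spec in config.conditions:
        flag = survey_flag[spec.name]
        # uniformly chosen first-report wave among each participant's
        # completed waves (only meaningful where flag & n_resp > 0)
        j = np.minimum((rng_survey.random(n) * np.maximum(n_resp, 1)).astype(int),
                       np.maximum(n_resp - 1, 0))
        first_yes_wave = np.argmax((cum == (j + 1)[:, None]) & responded, axis=1)
        yes_matrix = flag[:, None] & (wave_grid[None, :] >= first_yes_wave[:, None])
        answers = yes_matrix[row_pid, row_wave].astype(float)
        if config.item_missing_prob > 0:
            answers[rng_survey.random(m) < config.item_missing_prob] = np.nan
        survey[f"cond_{spec.name}"] = answers

    # PHQ drinking items: an endorsing participant marks one item
    endorse = np.where(true_misuse, 0.80, 0.15) > rng_survey.random(n)
    which_item = rng_survey.integers(0, 5, n)
    for item in range(5):
        survey[f"phq_{item + 1}"] = (endorse[row_pid]
                                     & (which_item[row_pid] == item)).astype(float)
    reports_smoker = rng_survey.random(n) < np.where(true_smoker, 0.95, 0.05)
    survey["cigs_100"] = reports_smoker[row_pid].astype(float)
    survey["height_in"] = np.round(
        true_height[row_pid] + config.height_report_bias_in
        + rng_survey.normal(0, config.height_report_sd_in, m))
    survey["weight_lb"] = np.round(
        true_weight[row_pid] + config.weight_report_bias_lb
        + rng_survey.normal(0, config.weight_report_sd_lb, m), 1)

    # ----- vitals -----------------------------------------------------------
    kh = 1 + rng_vitals.poisson(1.0, n)
    h_idx = np.repeat(np.arange(n), kh)
    heights = pd.DataFrame({
        "participant_id": pids[h_idx],
        "date": _uniform_dates(rng_vitals, h_idx.size, window),
        "kind": "height",
        "value": np.round(true_height[h_idx]
                          + rng_vitals.normal(0, 0.4, h_idx.size)),
    })
    kw = rng_vitals.poisson(3.0, n)
    w_idx = np.repeat(np.arange(n), kw)
    weights = pd.DataFrame({
        "participant_id": pids[w_idx],
        "date": _uniform_dates(rng_vitals, w_idx.size, window),
        "kind": "weight",
        "value": np.round(true_weight[w_idx]
                          + rng_vitals.normal(0, 5.0, w_idx.size), 1),
    })
    vitals = pd.concat([heights, weights], ignore_index=True)

    # ----- behaviors (health-factors analogue) ------------------------------
    ka = rng_behav.poisson(2.0, n)
    a_idx = np.repeat(np.arange(n), ka)
    raw = np.where(true_misuse[a_idx],
                   rng_behav.normal(5.5, 2.0, a_idx.size),
                   rng_behav.normal(1.2, 1.2, a_idx.size))
    scores = np.clip(np.round(raw), 0, 12).astype(int)
    audit = pd.DataFrame({"participant_id": pids[a_idx],
                          "date": _uniform_dates(rng_behav, a_idx.size, window),
                          "kind": "audit_c",
                          "value": scores.astype(str)})
    ks = rng_behav.poisson(2.0, n)
    s_idx = np.repeat(np.arange(n), ks)
    u = rng_behav.random(s_idx.size)
    smoker_rows = true_smoker[s_idx]
    status = np.where(smoker_rows,
                      np.where(u < 0.60, "current",
                               np.where(u < 0.95, "former", "never")),
                      np.where(u < 0.90, "never",
                               np.where(u < 0.98, "former", "current")))
    smoking = pd.DataFrame({"participant_id": pids[s_idx],
                            "date": _uniform_dates(rng_behav, s_idx.size, window),
                            "kind": "smoking",
                            "value": status})
    behaviors = pd.concat([audit, smoking], ignore_index=True)

    return SyntheticCohort(participants, encounters, survey, vitals,
                           behaviors, config)


# ---------------------------------------------------------------------------
# Closed-form oracle


def expected_cells(spec: ConditionSpec, shared_error: float = 0.0
                   ) -> Tuple[float, float, float, float]:
    """Expected 2x2 cell probabilities (a, b, c, d) for one condition.

    Under conditional independence given true status (shared_error=0):
    P(both+) = p*s1*s2 + (1-p)*(1-c1)*(1-c2) and so on, where p is the
    true prevalence, s1/c1 the survey sensitivity/specificity and s2/c2
    the record-channel ones.  A positive shared-error probability mixes
    in the comonotone coupling of the two channels.
    """
    p = spec.prevalence
    s1, s2 = spec.survey_sensitivity, spec.ehr_sensitivity
    c1, c2 = spec.survey_specificity, spec.ehr_specificity
    rho = shared_error
    both_pos_true = rho * min(s1, s2) + (1 - rho) * s1 * s2
    both_pos_false = (rho * min(1 - c1, 1 - c2)
                      + (1 - rho) * (1 - c1) * (1 - c2))
    a = p * both_pos_true + (1 - p) * both_pos_false
    b = p * (s1 - both_pos_true) + (1 - p) * ((1 - c1) - both_pos_false)
    c = p * (s2 - both_pos_true) + (1 - p) * ((1 - c2) - both_pos_false)
    d = 1.0 - a - b - c
    return a, b, c, d


def expected_agreement(config: SimulationConfig,
                       condition: str) -> AgreementResult:
    """Exact expected agreement statistics for one configured condition.

    This is what the pipeline estimates converge to (sensitive
    criterion, any-time temporality, combined source scope) as the
    cohort grows.
    """
    spec = config.condition(condition)
    a, b, c, d = expected_cells(spec, config.shared_error)
    return AgreementResult.from_cells(a, b, c, d, condition=condition)


# ---------------------------------------------------------------------------
# Serialization


def config_to_dict(config: SimulationConfig) -> dict:
    def convert(v):
        if isinstance(v, date):
            return v.isoformat()
        if isinstance(v, tuple):
            return [convert(x) for x in v]
        if isinstance(v, ObservationWindow):
            return {"start": v.start.isoformat(), "end": v.end.isoformat()}
        if isinstance(v, ConditionSpec):
            return asdict(v)
        return v
    return {f.name: convert(getattr(config, f.name))
            for f in fields(SimulationConfig)}


def config_from_dict(data: dict) -> SimulationConfig:
    kwargs = dict(data)
    if "conditions" in kwargs:
        kwargs["conditions"] = tuple(
            s if isinstance(s, ConditionSpec) else ConditionSpec(**s)
            for s in kwargs["conditions"])
    if "wave_dates" in kwargs:
        kwargs["wave_dates"] = tuple(
            d if isinstance(d, date) else date.fromisoformat(d)
            for d in kwargs["wave_dates"])
    if "window" in kwargs and not isinstance(kwargs["window"], ObservationWindow):
        w = kwargs["window"]
        kwargs["window"] = ObservationWindow(date.fromisoformat(w["start"]),
                                             date.fromisoformat(w["end"]))
    return SimulationConfig(**kwargs)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the five tables, the code sets, and the config to a directory.

    Delimited UTF-8 text with a header row and ISO-8601 dates, matching
    the reader schemas in :mod:`ehrconcord.io`.  Returns the paths.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, df, date_cols):
        df = df.copy()
        for col in date_cols:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path

    _write("participants", cohort.participants, [])
    _write("encounters", cohort.encounters, ["event_date"])
    _write("survey", cohort.survey, ["survey_date"])
    _write("vitals", cohort.vitals, ["date"])
    _write("behaviors", cohort.behaviors, ["date"])

    codesets = pd.DataFrame(
        [(cs.condition, system, pattern, cs.match_mode)
         for cs in cohort.codesets()
         for system, pattern in cs.entries],
        columns=["condition_id", "code_system", "code", "match_mode"])
    codesets.to_csv(outdir / "codesets.csv", index=False)
    paths["codesets"] = outdir / "codesets.csv"

    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cohort.config), fh, sort_keys=False)
    paths["config"] = outdir / "config.yaml"
    return paths
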