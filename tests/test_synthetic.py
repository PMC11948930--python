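"""Synthetic cohort generator and its closed-form agreement oracle."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from ehrconcord.pipeline import CohortData, RunConfig, run_concordance
from ehrconcord.synthetic import (ConditionSpec, SimulationConfig,
                                  config_from_dict, config_to_dict,
                                  expected_agreement, expected_cells,
                                  generate_cohort)


def _one_condition_config(**kwargs):
    spec = ConditionSpec("target", kwargs.pop("prevalence", 0.2),
                         kwargs.pop("survey_sensitivity", 0.8),
                         kwargs.pop("survey_specificity", 1.0),
                         kwargs.pop("ehr_sensitivity", 0.6),
                         kwargs.pop("ehr_specificity", 1.0),
                         kwargs.pop("mean_coded_encounters", 2.0))
    return SimulationConfig(conditions=(spec,), **kwargs)


class TestDeterminism:
    def test_same_seed_reproduces_every_table(self):
        config = SimulationConfig(n_participants=250, seed=42)
        first = generate_cohort(config)
        second = generate_cohort(SimulationConfig(n_participants=250, seed=42))
        for name in ("participants", "encounters", "survey", "vitals",
                     "behaviors"):
            assert_frame_equal(getattr(first, name), getattr(second, name))

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(n_participants=250, seed=1))
        b = generate_cohort(SimulationConfig(n_participants=250, seed=2))
        assert not a.encounters.equals(b.encounters)


class TestValidation:
    @pytest.mark.parametrize("bad, message", [
        ({"n_participants": 0}, "n_participants"),
        ({"wave_response_prob": 1.5}, "wave_response_prob"),
        ({"encounter_rate": -1.0}, "encounter_rate"),
    ])
    def test_invalid_field_named_in_error(self, bad, message):
        config = SimulationConfig(**bad)
        with pytest.raises(ValueError, match=message):
            config.validate()

    def test_invalid_condition_probability_named(self):
        spec = ConditionSpec("x", 1.2, 0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError, match=r"conditions\[x\].prevalence"):
            SimulationConfig(conditions=(spec,)).validate()

    def test_nonincreasing_wave_dates_rejected(self):
        import datetime
        config = SimulationConfig(wave_dates=(datetime.date(2004, 1, 1),
                                              datetime.date(2001, 1, 1)))
        with pytest.raises(ValueError, match="wave_dates"):
            config.validate()


class TestExpectedAgreement:
    def test_perfect_channels(self):
        config = _one_condition_config(prevalence=0.5, survey_sensitivity=1.0,
                                       survey_specificity=1.0,
                                       ehr_sensitivity=1.0,
                                       ehr_specificity=1.0)
        res = expected_agreement(config, "target")
        assert res.positive_agreement == pytest.approx(1.0)
        assert res.negative_agreement == pytest.approx(1.0)
        assert res.youden_j == pytest.approx(1.0)

    def test_uninformative_survey_has_zero_j(self):
        # yes-probability identical for true cases and non-cases
        config = _one_condition_config(survey_sensitivity=0.3,
                                       survey_specificity=0.7,
                                       ehr_sensitivity=0.8,
                                       ehr_specificity=0.95)
        assert expected_agreement(config, "target").youden_j == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_positive_agreement(self):
        # p=0.2, s1=0.8, s2=0.6, perfect specificities:
        # a=0.096, PA = 0.192/0.280
        config = _one_condition_config()
        res = expected_agreement(config, "target")
        assert res.positive_agreement == pytest.approx(0.192 / 0.280, abs=1e-12)

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError):
            expected_agreement(_one_condition_config(), "nope")

    def test_cells_sum_to_one(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p, s1, c1, s2, c2 = rng.random(5)
            spec = ConditionSpec("x", p, s1, c1, s2, c2)
            rho = float(rng.random())
            assert sum(expected_cells(spec, rho)) == pytest.approx(1, abs=1e-12)
            assert all(v >= -1e-12 for v in expected_cells(spec, rho))

    def test_j_monotone_in_coding_sensitivity(self):
        previous = -1.0
        for ehr_sens in np.linspace(0.05, 1.0, 20):
            config = _one_condition_config(survey_specificity=0.95,
                                           ehr_sensitivity=float(ehr_sens),
                                           ehr_specificity=0.97)
            j = expected_agreement(config, "target").youden_j
            assert j >= previous - 1e-12
            previous = j


class TestGeneratedStructure:
    def test_tables_reference_known_participants(self, small_cohort):
        ids = set(small_cohort.participants["participant_id"])
        for table in (small_cohort.encounters, small_cohort.survey,
                      small_cohort.vitals, small_cohort.behaviors):
            assert set(table["participant_id"]) <= ids

    def test_encounters_inside_window(self, small_cohort):
        window = small_cohort.config.window
        dates = pd.to_datetime(small_cohort.encounters["event_date"])
        assert (dates >= pd.Timestamp(window.start)).all()
        assert (dates <= pd.Timestamp(window.end)).all()

    def test_survey_dates_follow_wave_calendar(self, small_cohort):
        wave_dates = {pd.Timestamp(d)
                      for d in small_cohort.config.wave_dates}
        assert set(small_cohort.survey["survey_date"].unique()) <= wave_dates

    def test_roundtrip_config_serialization(self, small_cohort):
        config = small_cohort.config
        restored = config_from_dict(config_to_dict(config))
        assert restored == config


def test_dual_positive_rate_matches_closed_form():
    """Empirical dual-positive proportion vs p*s1*s2 on a large cohort.

    With perfect specificities the expected dual-positive probability is
    prevalence x survey sensitivity x coding sensitivity = 0.096; the
    pipeline estimate must fall within three Monte-Carlo standard errors.
    """
    config = _one_condition_config(n_participants=200_000, seed=91,
                                   encounter_rate=0.2)
    cohort = generate_cohort(config)
    report = run_concordance(CohortData.from_cohort(cohort),
                             RunConfig(scope="vha-mdr"))
    row = report.conditions.iloc[0]
    expected = 0.2 * 0.8 * 0.6
    # a/n recovered from PA = 2a/(2a+b+c) and the two prevalences
    observed = row["positive_agreement"] \
        * (row["survey_prevalence"] + row["ehr_prevalence"]) / 2
    se = math.sqrt(expected * (1 - expected) / row["n"])
    assert abs(observed - expected) <= 3 * se
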