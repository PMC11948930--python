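from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from ehrconcord.ehr import (CodedDiagnosis, EncounterRecord, ObservationWindow,
                            ConditionCodeSet)
from ehrconcord.synthetic import SimulationConfig, generate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_record(pid="P1", source="VHA", setting="outpatient",
                when=date(2010, 6, 1), codes=("I10",), system="ICD10",
                personal_history=False):
    """Terse encounter factory for the ascertainment tests."""
    coded = tuple(CodedDiagnosis(c, system, i + 1, personal_history)
                  for i, c in enumerate(codes))
    return EncounterRecord(pid, source, setting, when, coded)


@pytest.fixture(scope="session")
def hypertension_codeset():
    return ConditionCodeSet("hypertension", (("ICD10", "I10"),), "prefix")


@pytest.fixture(scope="session")
def window():
    return ObservationWindow()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant default-parameter cohort shared across tests."""
    config = SimulationConfig(n_participants=400, seed=7)
    return generate_cohort(config)
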