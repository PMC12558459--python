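import pytest

from keeneye import (
    PatientProfile,
    generate_main_schedule,
    score_session,
    simulate_cohort,
    simulate_session,
    study_cohort_spec,
)


@pytest.fixture(scope="session")
def main_schedule():
    return generate_main_schedule(seed=7)


@pytest.fixture(scope="session")
def perfect_session(main_schedule):
    """A session with every circle detected and every digit correct."""
    return simulate_session(PatientProfile(), main_schedule, seed=0)


@pytest.fixture(scope="session")
def study_cohort():
    """Calibrated 38 neglect-like / 64 control-like cohort, fixed seed."""
    return simulate_cohort(study_cohort_spec(38, 64, seed=20240501))


@pytest.fixture(scope="session")
def study_cohort_sheets(study_cohort):
    sheets = [score_session(record) for record, _ in study_cohort]
    labels = [label for _, label in study_cohort]
    return sheets, labels
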