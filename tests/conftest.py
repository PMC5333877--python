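import pytest

from agestage import Cohort, IndividualRecord, StageScheme, simulate_cohort, study_spec


@pytest.fixture
def toy_scheme():
    return StageScheme(stages=("egg", "L1", "L2", "pupa", "adult"))


@pytest.fixture
def study_cohort():
    """A simulated 150-egg cohort in the study's 27 °C configuration."""
    return simulate_cohort(study_spec(27, n0=150, seed=42))


def make_record(
    scheme,
    identifier="x",
    sex="undetermined",
    durations=None,
    death_stage="egg",
    days_in_death_stage=1,
    fecundity=None,
    treatment="t",
):
    return IndividualRecord(
        identifier=identifier,
        treatment=treatment,
        sex=sex,
        stage_durations=dict(durations or {}),
        death_stage=death_stage,
        days_in_death_stage=days_in_death_stage,
        fecundity_by_age=dict(fecundity or {}),
    )


@pytest.fixture
def tiny_cohort(toy_scheme):
    """Four handmade individuals: one fecund female, one male, two deaths."""
    recs = [
        make_record(
            toy_scheme, "f1", sex="female",
            durations={"egg": 2, "L1": 1, "L2": 2, "pupa": 3},
            death_stage="adult", days_in_death_stage=5,
            fecundity={9: 4, 10: 6, 12: 2},
        ),
        make_record(
            toy_scheme, "m1", sex="male",
            durations={"egg": 2, "L1": 2, "L2": 2, "pupa": 2},
            death_stage="adult", days_in_death_stage=7,
        ),
        make_record(toy_scheme, "d1", death_stage="egg", days_in_death_stage=1),
        make_record(
            toy_scheme, "d2", durations={"egg": 2, "L1": 1},
            death_stage="L2", days_in_death_stage=2,
        ),
    ]
    return Cohort(treatment="t", records=recs, scheme=toy_scheme)
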