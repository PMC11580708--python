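import pytest

from copd_indices import CohortConfig, PatientRecord, Sex, generate_cohort


def make_record(**overrides) -> PatientRecord:
    """A valid typical record (elderly male smoker, moderate obstruction),
    with keyword overrides."""
    fields = dict(
        patient_id="P001",
        age=73,
        sex=Sex.MALE,
        bmi=27.0,
        fev1_pct=46.0,
        fev1_fvc_ratio=55.0,
        mmrc=2,
        severe_exacerbations_prior_year=1,
        pack_years=59.0,
        hemoglobin=14.5,
        dead_1y=False,
        dead_3y=False,
    )
    fields.update(overrides)
    return PatientRecord(**fields)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort (n=141, fixed seed)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def record_factory():
    return make_record
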