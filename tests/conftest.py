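import pytest

from mtbench.cohort_model import PatientRecord


BASELINE = dict(
    age=40,
    sex="female",
    mechanism="blunt",
    primary_admission=True,
    survived_to_icu=True,
    heart_rate_er=80.0,
    sbp_er=130.0,
    hemoglobin_er=13.0,
    base_excess_er=0.0,
    lactate_er=1.0,
    inr_er=1.0,
    quick_er=100.0,
    gcs=15,
    fast_positive=False,
    ct_free_fluid=False,
    pelvis_ais=0,
    femur_ais=0,
    prbc_units_er_to_icu=0,
    hemostatic_agents=False,
    iss=9,
)


def make_record(patient_id="P0", **overrides):
    """A complete, eligible record that scores 0 on every score; override
    fields to build fixtures."""
    values = dict(BASELINE)
    values.update(overrides)
    return PatientRecord(patient_id=patient_id, **values)


@pytest.fixture
def record_factory():
    return make_record
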