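import dataclasses

import pytest

from eposgait import PatientRecord, generate_cohort, preset


def make_record(**overrides) -> PatientRecord:
    """A valid baseline patient; override any field."""
    base = dict(
        patient_id="p1",
        age=70,
        sex="female",
        affected_side="left",
        stroke_type="ischemic",
        nihss_total=9,
        nihss_loc=0,
        nihss_hemianopia=1,
        tct_s_v1=25,
        tct_s_v2=25,
        mi_le_v1=33,
        mi_le_v2=50,
        fac_baseline=1,
        fac_90=5,
        died_before_90=False,
        visit1_day=1,
        visit2_day=8,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def cohort1_records():
    """One deterministic draw of the cohort-1 emulation."""
    return generate_cohort(dataclasses.replace(preset("cohort1"), seed=11)).records


@pytest.fixture(scope="session")
def cohort2_records():
    """One deterministic draw of the cohort-2 emulation."""
    return generate_cohort(dataclasses.replace(preset("cohort2"), seed=11)).records
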