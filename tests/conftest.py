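import datetime as dt
import logging

import pytest

from ahpdc.model import DiagnosisClaim, PatientRecord, Prescription, StudyConfig
from ahpdc.ontology import default_ontology

logging.getLogger("ahpdc").setLevel(logging.ERROR)
logging.getLogger("ahpdc.adherence").setLevel(logging.ERROR)

INDEX = dt.date(2014, 6, 1)


@pytest.fixture(scope="session")
def ontology():
    return default_ontology()


@pytest.fixture()
def config():
    return StudyConfig()


def rx(code="AML5", day=0, days_supplied=30, pills=1.0, setting="outpatient",
       pid="P1", index=INDEX):
    """Prescription at an integer day offset from the test index date."""
    return Prescription(
        patient_id=pid,
        product_code=code,
        date=index + dt.timedelta(days=day),
        days_supplied=days_supplied,
        pills_per_day=pills,
        setting=setting,
    )


def dx(code="I10", day=0, setting="outpatient", pid="P1", index=INDEX):
    return DiagnosisClaim(
        patient_id=pid, code=code, date=index + dt.timedelta(days=day), setting=setting
    )


def patient(pid="P1", birth="1950-01", sex="male", diagnoses=(), prescriptions=()):
    return PatientRecord(
        patient_id=pid,
        sex=sex,
        birth_year_month=birth,
        diagnoses=list(diagnoses),
        prescriptions=list(prescriptions),
    )
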