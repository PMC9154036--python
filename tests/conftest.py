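from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import settings

from pharmacheck.ehr_model import (
    Analyte,
    CANONICAL_UNITS,
    EhrStore,
    LabResultDocument,
    PatientRecord,
    PrescriptionDocument,
    PrescriptionStatus,
    ProblemNote,
    Route,
    Sex,
)
from pharmacheck.rule_engine import build_default_rulebook

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

AS_OF = datetime(2020, 3, 16, 8, 0)


@pytest.fixture(scope="session")
def rulebook():
    return build_default_rulebook()


@pytest.fixture()
def as_of():
    return AS_OF


class StoreBuilder:
    """Terse one-patient (or few-patient) store construction for rule tests."""

    def __init__(self, as_of: datetime = AS_OF):
        self.store = EhrStore()
        self.as_of = as_of
        self._seq = 0

    def patient(self, pid="P1", sex=Sex.male, age=80, weight=50.0, height=None):
        self.store.add_patient(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                age=age,
                weight_measured_kg=weight,
                height_cm=height,
                admitted_at=self.as_of - timedelta(days=5),
            )
        )
        return self

    def rx(self, atc, label, pid="P1", status=PrescriptionStatus.CHECKED,
           route=Route.oral, is_prn=False, rate=None, conc=None,
           start_days_ago=3.0, end_days_ago=None):
        self._seq += 1
        self.store.add_prescription(
            PrescriptionDocument(
                prescription_id=f"RX{self._seq}",
                patient_id=pid,
                atc_code=atc,
                drug_label=label,
                status=status,
                route=route,
                is_prn=is_prn,
                rate_mmol_per_h=rate,
                concentration_mmol_per_ml=conc,
                start_at=self.as_of - timedelta(days=start_days_ago),
                end_at=None if end_days_ago is None
                else self.as_of - timedelta(days=end_days_ago),
            )
        )
        return self

    def lab(self, analyte, value, pid="P1", days_ago=1.0):
        analyte = Analyte(analyte)
        self.store.add_lab(
            LabResultDocument(
                patient_id=pid,
                analyte=analyte,
                value=value,
                unit=CANONICAL_UNITS[analyte],
                published_at=self.as_of - timedelta(days=days_ago),
            )
        )
        return self

    def note(self, text, pid="P1", days_ago=4.0):
        self.store.add_note(
            ProblemNote(
                patient_id=pid,
                text=text,
                written_at=self.as_of - timedelta(days=days_ago),
            )
        )
        return self


@pytest.fixture()
def builder():
    return StoreBuilder()
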