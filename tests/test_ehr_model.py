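from datetime import datetime, timedelta

import pytest
from pydantic import ValidationError

from pharmacheck.ehr_model import (
    Analyte,
    LabResultDocument,
    PatientRecord,
    PrescriptionDocument,
    StoreError,
    active_prescriptions,
    last_two_values,
    load_store,
    recent_labs,
    write_store,
)
from pharmacheck.synthetic_ehr import GeneratorConfig, generate_cohort

from conftest import AS_OF, StoreBuilder


class TestDocumentValidation:
    def test_atc_grammar_accepts_all_truncation_levels(self):
        for code in ("B", "B01", "B01A", "B01AF", "B01AF02"):
            rx = PrescriptionDocument(
                prescription_id="r", patient_id="p", atc_code=code,
                drug_label="x", start_at=AS_OF,
            )
            assert rx.atc_code == code

    @pytest.mark.parametrize("code", ["9XYZ", "b01af02", "B1", "B01AF025", "B01-A"])
    def test_atc_grammar_rejects_malformed_codes(self, code):
        with pytest.raises(ValidationError):
            PrescriptionDocument(
                prescription_id="r", patient_id="p", atc_code=code,
                drug_label="x", start_at=AS_OF,
            )

    def test_patient_invariants(self):
        with pytest.raises(ValidationError):
            PatientRecord(patient_id="p", sex="male", age=150, admitted_at=AS_OF)
        with pytest.raises(ValidationError):
            PatientRecord(
                patient_id="p", sex="male", age=70, weight_measured_kg=-1,
                admitted_at=AS_OF,
            )
        with pytest.raises(ValidationError):
            PatientRecord(
                patient_id="p", sex="male", age=70,
                admitted_at=AS_OF, discharged_at=AS_OF - timedelta(days=1),
            )

    def test_creatinine_mgdl_normalised_to_umol_l(self):
        lab = LabResultDocument(
            patient_id="p", analyte="creatinine", value=1.0, unit="mg/dL",
            published_at=AS_OF,
        )
        assert lab.unit == "umol/L"
        assert lab.value == pytest.approx(88.4)

    def test_non_canonical_unit_rejected(self):
        with pytest.raises(ValidationError):
            LabResultDocument(
                patient_id="p", analyte="potassium", value=4.0, unit="mEq/dL",
                published_at=AS_OF,
            )

    def test_timestamps_truncated_to_minute(self):
        p = PatientRecord(
            patient_id="p", sex="male", age=70,
            admitted_at=datetime(2020, 3, 1, 10, 30, 45, 123),
        )
        assert p.admitted_at == datetime(2020, 3, 1, 10, 30)


class TestActivePrescriptions:
    def test_checked_open_order_included_draft_excluded(self, builder, as_of):
        builder.patient().rx("B01AF02", "apixaban")
        builder.rx("C01AA05", "digoxin", status="DRAFT")
        active = active_prescriptions(builder.store, "P1", as_of)
        assert [rx.atc_code for rx in active] == ["B01AF02"]

    def test_half_open_interval_boundaries(self, as_of):
        # start_at == as_of -> included; end_at == as_of -> excluded
        b = StoreBuilder().patient()
        b.rx("B01AF02", "apixaban", start_days_ago=0.0)
        b.rx("C01AA05", "digoxin", start_days_ago=5.0, end_days_ago=0.0)
        active = active_prescriptions(b.store, "P1", as_of)
        assert [rx.atc_code for rx in active] == ["B01AF02"]

    def test_unknown_patient_yields_empty_not_error(self, builder, as_of):
        builder.patient()
        assert active_prescriptions(builder.store, "nobody", as_of) == []

    def test_stable_ordering_by_start_then_id(self, builder, as_of):
        builder.patient()
        builder.rx("C10AA05", "atorvastatin", start_days_ago=1.0)
        builder.rx("A02BC02", "pantoprazole", start_days_ago=2.0)
        active = active_prescriptions(builder.store, "P1", as_of)
        assert [rx.atc_code for rx in active] == ["A02BC02", "C10AA05"]


class TestRecentLabs:
    def test_strict_window_lower_bound(self, builder, as_of):
        builder.patient()
        builder.lab("creatinine", 90.0, days_ago=29.0)
        builder.lab("creatinine", 95.0, days_ago=30.0)  # exactly 30 d: excluded
        rows = recent_labs(builder.store, "P1", Analyte.creatinine, 30, as_of)
        assert [lab.value for lab in rows] == [90.0]

    def test_sorted_most_recent_first(self, builder, as_of):
        builder.patient()
        builder.lab("creatinine", 80.0, days_ago=10.0)
        builder.lab("creatinine", 120.0, days_ago=1.0)
        rows = recent_labs(builder.store, "P1", "creatinine", 30, as_of)
        assert [lab.value for lab in rows] == [120.0, 80.0]

    def test_unknown_analyte_raises(self, builder, as_of):
        builder.patient()
        with pytest.raises(ValueError):
            recent_labs(builder.store, "P1", "troponin", 30, as_of)

    def test_last_two_values_drops_oldest(self, builder, as_of):
        builder.patient()
        builder.lab("egfr_ckdepi", 44.0, days_ago=3.0)
        builder.lab("egfr_ckdepi", 50.0, days_ago=2.0)
        builder.lab("egfr_ckdepi", 57.0, days_ago=1.0)
        prev, latest = last_two_values(builder.store, "P1", "egfr_ckdepi", as_of)
        assert (prev.value, latest.value) == (50.0, 57.0)

    def test_last_two_values_single_measurement(self, builder, as_of):
        builder.patient()
        builder.lab("egfr_ckdepi", 50.0, days_ago=1.0)
        prev, latest = last_two_values(builder.store, "P1", "egfr_ckdepi", as_of)
        assert prev is None and latest.value == 50.0


class TestOnDiskRoundTrip:
    def test_round_trip_is_lossless_and_deterministic(self, tmp_path):
        store, _ = generate_cohort(GeneratorConfig(n_patients=25, seed=3))
        d1, d2, d3 = tmp_path / "a", tmp_path / "b", tmp_path / "c"
        write_store(store, d1)
        reloaded = load_store(d1)
        write_store(reloaded, d2)
        for name in ("patients", "prescriptions", "labs", "notes", "administrations"):
            assert (d1 / f"{name}.jsonl").read_bytes() == (d2 / f"{name}.jsonl").read_bytes()
        # same seed -> byte-identical store
        store2, _ = generate_cohort(GeneratorConfig(n_patients=25, seed=3))
        write_store(store2, d3)
        for name in ("patients", "prescriptions", "labs", "notes", "administrations"):
            assert (d1 / f"{name}.jsonl").read_bytes() == (d3 / f"{name}.jsonl").read_bytes()

    def test_counts_preserved(self, tmp_path):
        b = StoreBuilder().patient("P1").patient("P2")
        b.rx("B01AF02", "apixaban", pid="P1")
        b.rx("C01AA05", "digoxin", pid="P2")
        b.rx("A10BA02", "metformin", pid="P2")
        write_store(b.store, tmp_path / "s")
        loaded = load_store(tmp_path / "s")
        assert len(loaded.patients) == 2
        assert len(loaded.prescriptions) == 3

    def test_malformed_line_names_collection_and_line(self, tmp_path):
        b = StoreBuilder().patient("P1")
        write_store(b.store, tmp_path / "s")
        f = tmp_path / "s" / "prescriptions.jsonl"
        f.write_text(f.read_text() + '{"atc_code": "9XYZ"}\n')
        with pytest.raises(StoreError, match=r"prescriptions.*line 2|line 2.*prescriptions"):
            load_store(tmp_path / "s")

    def test_missing_collection_file_is_fatal(self, tmp_path):
        b = StoreBuilder().patient("P1")
        write_store(b.store, tmp_path / "s")
        (tmp_path / "s" / "labs.jsonl").unlink()
        with pytest.raises(StoreError, match="missing"):
            load_store(tmp_path / "s")

    def test_orphan_document_rejected(self, tmp_path):
        b = StoreBuilder().patient("P1")
        write_store(b.store, tmp_path / "s")
        f = tmp_path / "s" / "labs.jsonl"
        f.write_text(
            f.read_text()
            + '{"patient_id": "GHOST", "analyte": "potassium", "value": 4.0, '
            '"unit": "mmol/L", "published_at": "2020-03-15T08:00"}\n'
        )
        with pytest.raises(StoreError, match="GHOST"):
            load_store(tmp_path / "s")
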