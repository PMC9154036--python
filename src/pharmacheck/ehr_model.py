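"""Document model for the inpatient EHR snapshot and its staged query primitives.

The screening engine never talks to a live hospital database: it reads a
point-in-time snapshot organised as five document collections (patients,
prescriptions, labs, notes, administration events), mirroring a
document-store data warehouse.  Rules are evaluated against three staged
query primitives — active-prescription filtering, time-windowed lab lookup,
and last-two-value projection — whose time semantics are deliberately
uniform: prescription activity is the half-open interval
``[start_at, end_at)`` and lab recency is the half-open window
``(as_of - window, as_of]``.
"""

from __future__ import annotations

import json
import re
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, ValidationError, field_validator, model_validator

SCHEMA_VERSION = 1

#: WHO ATC code truncated at any hierarchy level (1, 3, 4, 5 or 7 characters).
ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

#: Default lab recency window applied by lab-triggered rules (days).
DEFAULT_LAB_WINDOW_DAYS = 30.0


class Sex(str, Enum):
    male = "male"
    female = "female"


class PrescriptionStatus(str, Enum):
    CHECKED = "CHECKED"  # signed and active; the only status rules act on
    DRAFT = "DRAFT"
    STOPPED = "STOPPED"


class Route(str, Enum):
    oral = "oral"
    iv_intermittent = "iv_intermittent"
    iv_continuous = "iv_continuous"
    sc = "sc"
    other = "other"


class Analyte(str, Enum):
    creatinine = "creatinine"
    egfr_ckdepi = "egfr_ckdepi"
    potassium = "potassium"
    lactate = "lactate"
    platelets = "platelets"
    inr = "inr"
    glucose = "glucose"
    digoxin_level = "digoxin_level"
    vancomycin_level = "vancomycin_level"
    gentamicin_level = "gentamicin_level"
    tobramycin_level = "tobramycin_level"
    amikacin_level = "amikacin_level"


#: Canonical unit per analyte; lab documents are normalised to these.
CANONICAL_UNITS: dict[Analyte, str] = {
    Analyte.creatinine: "umol/L",
    Analyte.egfr_ckdepi: "mL/min/1.73m2",
    Analyte.potassium: "mmol/L",
    Analyte.lactate: "mmol/L",
    Analyte.platelets: "G/L",
    Analyte.inr: "ratio",
    Analyte.glucose: "mmol/L",
    Analyte.digoxin_level: "nmol/L",
    Analyte.vancomycin_level: "mg/L",
    Analyte.gentamicin_level: "mg/L",
    Analyte.tobramycin_level: "mg/L",
    Analyte.amikacin_level: "mg/L",
}

_CREATININE_MGDL_TO_UMOLL = 88.4


def _naive_minute(v: datetime) -> datetime:
    if v.tzinfo is not None:
        raise ValueError("timestamps must be timezone-naive")
    return v.replace(second=0, microsecond=0)


class PatientRecord(BaseModel):
    patient_id: str
    sex: Sex
    age: int
    height_cm: Optional[float] = None
    weight_measured_kg: Optional[float] = None
    ward_id: str = "W0"
    admitted_at: datetime
    discharged_at: Optional[datetime] = None

    _ts = field_validator("admitted_at", "discharged_at")(
        lambda v: None if v is None else _naive_minute(v)
    )

    @field_validator("age")
    @classmethod
    def _age_range(cls, v: int) -> int:
        if not (0 <= v <= 130):
            raise ValueError("age must be in [0, 130]")
        return v

    @field_validator("height_cm", "weight_measured_kg")
    @classmethod
    def _positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("height/weight must be strictly positive")
        return v

    @model_validator(mode="after")
    def _stay_interval(self) -> "PatientRecord":
        if self.discharged_at is not None and self.admitted_at > self.discharged_at:
            raise ValueError("admitted_at must be <= discharged_at")
        return self


class PrescriptionDocument(BaseModel):
    prescription_id: str
    patient_id: str
    atc_code: str
    drug_label: str
    status: PrescriptionStatus = PrescriptionStatus.CHECKED
    route: Route = Route.oral
    is_prn: bool = False
    dose_value: Optional[float] = None
    dose_unit: Optional[str] = None
    rate_mmol_per_h: Optional[float] = None
    concentration_mmol_per_ml: Optional[float] = None
    start_at: datetime
    end_at: Optional[datetime] = None
    free_text_comment: Optional[str] = None

    _ts = field_validator("start_at", "end_at")(
        lambda v: None if v is None else _naive_minute(v)
    )

    @field_validator("atc_code")
    @classmethod
    def _atc_grammar(cls, v: str) -> str:
        if not ATC_RE.match(v):
            raise ValueError(f"invalid ATC code {v!r}")
        return v

    @model_validator(mode="after")
    def _order_interval(self) -> "PrescriptionDocument":
        if self.end_at is not None and self.start_at > self.end_at:
            raise ValueError("start_at must be <= end_at")
        if self.route not in (Route.iv_intermittent, Route.iv_continuous):
            if self.rate_mmol_per_h is not None or self.concentration_mmol_per_ml is not None:
                raise ValueError("rate/concentration only meaningful for iv routes")
        return self


class LabResultDocument(BaseModel):
    patient_id: str
    analyte: Analyte
    value: float
    unit: str
    published_at: datetime

    _ts = field_validator("published_at")(_naive_minute)

    @model_validator(mode="after")
    def _canonical_unit(self) -> "LabResultDocument":
        canonical = CANONICAL_UNITS[self.analyte]
        if self.unit != canonical:
            if self.analyte is Analyte.creatinine and self.unit == "mg/dL":
                object.__setattr__(self, "value", self.value * _CREATININE_MGDL_TO_UMOLL)
                object.__setattr__(self, "unit", canonical)
            else:
                raise ValueError(
                    f"unit {self.unit!r} not canonical for {self.analyte.value} "
                    f"(expected {canonical!r})"
                )
        if self.value < 0:
            raise ValueError("lab value must be >= 0")
        return self


class NoteKind(str, Enum):
    admission_note = "admission_note"


class ProblemNote(BaseModel):
    patient_id: str
    note_kind: NoteKind = NoteKind.admission_note
    text: str = ""
    written_at: datetime

    _ts = field_validator("written_at")(_naive_minute)


class AdministrationEvent(BaseModel):
    patient_id: str
    atc_code: str
    scheduled_at: datetime
    given: bool = False

    _ts = field_validator("scheduled_at")(_naive_minute)

    @field_validator("atc_code")
    @classmethod
    def _atc_grammar(cls, v: str) -> str:
        if not ATC_RE.match(v):
            raise ValueError(f"invalid ATC code {v!r}")
        return v


class StoreError(Exception):
    """Raised for malformed or inconsistent on-disk stores."""


class EhrStore:
    """In-memory EHR snapshot: five append-only collections indexed by patient.

    Child documents must reference an existing patient; insertion order is
    preserved (it is the tie-break for simultaneous lab values).
    """

    def __init__(self) -> None:
        self.patients: dict[str, PatientRecord] = {}
        self.prescriptions: list[PrescriptionDocument] = []
        self.labs: list[LabResultDocument] = []
        self.notes: list[ProblemNote] = []
        self.administrations: list[AdministrationEvent] = []
        self._rx_by_patient: dict[str, list[PrescriptionDocument]] = {}
        self._labs_by_patient: dict[str, list[LabResultDocument]] = {}
        self._notes_by_patient: dict[str, list[ProblemNote]] = {}
        self._admin_by_patient: dict[str, list[AdministrationEvent]] = {}

    # -- construction -----------------------------------------------------

    def add_patient(self, patient: PatientRecord) -> None:
        if patient.patient_id in self.patients:
            raise StoreError(f"duplicate patient_id {patient.patient_id!r}")
        self.patients[patient.patient_id] = patient
        self._rx_by_patient[patient.patient_id] = []
        self._labs_by_patient[patient.patient_id] = []
        self._notes_by_patient[patient.patient_id] = []
        self._admin_by_patient[patient.patient_id] = []

    def _require_patient(self, patient_id: str) -> None:
        if patient_id not in self.patients:
            raise StoreError(f"document references unknown patient {patient_id!r}")

    def add_prescription(self, rx: PrescriptionDocument) -> None:
        self._require_patient(rx.patient_id)
        self.prescriptions.append(rx)
        self._rx_by_patient[rx.patient_id].append(rx)

    def add_lab(self, lab: LabResultDocument) -> None:
        self._require_patient(lab.patient_id)
        self.labs.append(lab)
        self._labs_by_patient[lab.patient_id].append(lab)

    def add_note(self, note: ProblemNote) -> None:
        self._require_patient(note.patient_id)
        self.notes.append(note)
        self._notes_by_patient[note.patient_id].append(note)

    def add_administration(self, event: AdministrationEvent) -> None:
        self._require_patient(event.patient_id)
        self.administrations.append(event)
        self._admin_by_patient[event.patient_id].append(event)

    # -- per-patient access ------------------------------------------------

    def prescriptions_for(self, patient_id: str) -> list[PrescriptionDocument]:
        return self._rx_by_patient.get(patient_id, [])

    def labs_for(self, patient_id: str) -> list[LabResultDocument]:
        return self._labs_by_patient.get(patient_id, [])

    def notes_for(self, patient_id: str) -> list[ProblemNote]:
        return self._notes_by_patient.get(patient_id, [])

    def administrations_for(self, patient_id: str) -> list[AdministrationEvent]:
        return self._admin_by_patient.get(patient_id, [])

    def patient_ids(self) -> list[str]:
        return sorted(self.patients)


# -- staged query primitives ------------------------------------------------


def active_prescriptions(
    store: EhrStore, patient_id: str, as_of: datetime
) -> list[PrescriptionDocument]:
    """Signed (CHECKED) prescriptions active at ``as_of``.

    Activity is the half-open interval ``start_at <= as_of < end_at`` (an
    absent ``end_at`` is an open order).  Unknown patients yield an empty
    list — screening an empty bed is not an error.
    """
    rows = [
        rx
        for rx in store.prescriptions_for(patient_id)
        if rx.status is PrescriptionStatus.CHECKED
        and rx.start_at <= as_of
        and (rx.end_at is None or as_of < rx.end_at)
    ]
    rows.sort(key=lambda rx: (rx.start_at, rx.prescription_id))
    return rows


def recent_labs(
    store: EhrStore,
    patient_id: str,
    analyte: Analyte | str,
    window_days: float,
    as_of: datetime,
) -> list[LabResultDocument]:
    """Lab results published within the last ``window_days`` (strict lower
    bound), most recent first; ties keep document insertion order."""
    analyte = Analyte(analyte)
    if window_days <= 0:
        raise ValueError("window_days must be > 0")
    lo = as_of - timedelta(days=window_days)
    rows = [
        (i, lab)
        for i, lab in enumerate(store.labs_for(patient_id))
        if lab.analyte is analyte and lo < lab.published_at <= as_of
    ]
    # most recent first; equal timestamps keep insertion order
    rows.sort(key=lambda pair: (-pair[1].published_at.timestamp(), pair[0]))
    return [lab for _, lab in rows]


def last_two_values(
    store: EhrStore,
    patient_id: str,
    analyte: Analyte | str,
    as_of: datetime,
    window_days: float = DEFAULT_LAB_WINDOW_DAYS,
) -> tuple[Optional[LabResultDocument], Optional[LabResultDocument]]:
    """The ``(previous, latest)`` pair of in-window results; either may be None."""
    rows = recent_labs(store, patient_id, analyte, window_days, as_of)
    latest = rows[0] if rows else None
    previous = rows[1] if len(rows) > 1 else None
    return previous, latest


# -- on-disk format ----------------------------------------------------------

_COLLECTIONS: dict[str, type[BaseModel]] = {
    "patients": PatientRecord,
    "prescriptions": PrescriptionDocument,
    "labs": LabResultDocument,
    "notes": ProblemNote,
    "administrations": AdministrationEvent,
}


def _dump_doc(doc: BaseModel) -> str:
    return json.dumps(doc.model_dump(mode="json", exclude_none=True), sort_keys=True)


def write_store(store: EhrStore, path: str | Path) -> None:
    """Write one UTF-8 line-delimited file per collection with a header line."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    collections: dict[str, Iterable[BaseModel]] = {
        "patients": [store.patients[pid] for pid in sorted(store.patients)],
        "prescriptions": store.prescriptions,
        "labs": store.labs,
        "notes": store.notes,
        "administrations": store.administrations,
    }
    for name, docs in collections.items():
        header = json.dumps(
            {"format": "pharmacheck-ehr", "schema_version": SCHEMA_VERSION, "collection": name},
            sort_keys=True,
        )
        lines = [header] + [_dump_doc(doc) for doc in docs]
        (path / f"{name}.jsonl").write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_store(path: str | Path) -> EhrStore:
    """Load and validate a store directory; fails loudly on malformed input."""
    path = Path(path)
    parsed: dict[str, list[BaseModel]] = {}
    for name, model in _COLLECTIONS.items():
        file = path / f"{name}.jsonl"
        if not file.exists():
            raise StoreError(f"missing collection file {file}")
        lines = file.read_text(encoding="utf-8").splitlines()
        if not lines:
            raise StoreError(f"{file}: empty file (header line required)")
        try:
            header = json.loads(lines[0])
        except json.JSONDecodeError as exc:
            raise StoreError(f"{file}: line 1: malformed header: {exc}") from exc
        if header.get("collection") != name or header.get("schema_version") != SCHEMA_VERSION:
            raise StoreError(f"{file}: line 1: unexpected header {header!r}")
        docs: list[BaseModel] = []
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            try:
                docs.append(model.model_validate(json.loads(line)))
            except (json.JSONDecodeError, ValidationError) as exc:
                raise StoreError(f"{file}: line {lineno} ({name}): {exc}") from exc
        parsed[name] = docs

    store = EhrStore()
    for patient in parsed["patients"]:
        store.add_patient(patient)  # type: ignore[arg-type]
    for rx in parsed["prescriptions"]:
        store.add_prescription(rx)  # type: ignore[arg-type]
    for lab in parsed["labs"]:
        store.add_lab(lab)  # type: ignore[arg-type]
    for note in parsed["notes"]:
        store.add_note(note)  # type: ignore[arg-type]
    for event in parsed["administrations"]:
        store.add_administration(event)  # type: ignore[arg-type]
    return store
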