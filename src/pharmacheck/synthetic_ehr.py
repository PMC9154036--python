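"""Seeded synthetic inpatient EHR cohorts with known ground truth.

The generator emulates an adult internal-medicine census: ages with median
74 (IQR 61–82), about 13 drug orders per patient, length of stay around
10.5 days, French admission notes, and lab time series.  Into this
background it injects, per rule, patients who satisfy the exact trigger and
*near-miss* controls that violate exactly one trigger condition minimally
(ClCG 31 instead of ≤ 30, platelets 51 G/L, a methotrexate gap of 8 days,
...).  Background prescriptions are drawn from a curated ATC list disjoint
from every rule drug set, so controls cannot alert by accident.

The module also builds the published-performance ledger fixture: a synthetic
alert/intervention ledger whose per-rule counts equal the study's reported
distribution (447 alerts over 132 screening days, 90 interventions, 63
accepted changes, 383 alerting patients of 5,466 screened).
"""

from __future__ import annotations

from datetime import date, datetime, timedelta
from typing import Callable, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .alert_manager import AlertLedger, Channel, Outcome
from .ehr_model import (
    AdministrationEvent,
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
from .evaluation import ScreeningCensus
from .rule_engine import AlertCandidate, RuleBook, build_default_rulebook

DEFAULT_AS_OF = datetime(2020, 3, 16, 8, 0)

# Piecewise-linear quantile anchors emulating the study cohort's medians/IQRs.
_AGE_ANCHORS = ((0.0, 18), (0.25, 61), (0.5, 74), (0.75, 82), (1.0, 97))
_NDRUGS_ANCHORS = ((0.0, 1), (0.25, 10), (0.5, 13), (0.75, 17), (1.0, 40))
_LOS_ANCHORS = ((0.0, 0.5), (0.25, 4.0), (0.5, 10.5), (0.75, 13.5), (1.0, 84.0))

#: Background (never-triggering) formulary: ATC codes disjoint from every
#: rule drug set, labels absent from every substance list.
_BACKGROUND_DRUGS = [
    ("A02BC01", "omeprazole"),
    ("A02BC02", "pantoprazole"),
    ("A06AB06", "senna"),
    ("A06AD11", "lactulose"),
    ("A07EC02", "mesalazine"),
    ("A11CC05", "colecalciferol"),
    ("A11DA01", "thiamine"),
    ("A12AA04", "calcium carbonate"),
    ("B01AC06", "aspirin"),
    ("B03AA07", "ferrous sulfate"),
    ("B03BB01", "folic acid"),
    ("B03XA01", "erythropoietin"),
    ("C01DA14", "isosorbide mononitrate"),
    ("C03CA01", "furosemide"),
    ("C03CA04", "torasemide"),
    ("C03DA01", "spironolactone"),
    ("C07AB07", "bisoprolol"),
    ("C07AG02", "carvedilol"),
    ("C08CA01", "amlodipine"),
    ("C09AA02", "enalapril"),
    ("C09AA05", "ramipril"),
    ("C09CA01", "losartan"),
    ("C10AA01", "simvastatin"),
    ("C10AA05", "atorvastatin"),
    ("H02AB06", "prednisolone"),
    ("H02AB07", "prednisone"),
    ("H03AA01", "levothyroxine"),
    ("J01FA09", "clarithromycin"),
    ("M04AA01", "allopurinol"),
    ("M05BA04", "alendronate"),
    ("N02BE01", "paracetamol"),
    ("N05BA06", "lorazepam"),
    ("N05CF02", "zolpidem"),
    ("R03AC02", "salbutamol"),
    ("R03BB01", "ipratropium"),
    ("R03BB04", "tiotropium"),
    ("R05CB01", "acetylcysteine"),
]

_CLEAN_NOTES = [
    "Patient admis pour pneumonie communautaire.",
    "Hospitalisation pour décompensation de BPCO.",
    "Chute mécanique à domicile, sans gravité.",
    "Bilan d'asthénie et perte pondérale.",
    "Admission pour pyélonéphrite aiguë.",
]


class GroundTruthEntry(BaseModel):
    rule_id: str
    expected_alert: bool
    near_miss: bool


class GroundTruth(BaseModel):
    entries: dict[str, list[GroundTruthEntry]] = Field(default_factory=dict)

    def add(self, patient_id: str, rule_id: str, expected: bool, near_miss: bool) -> None:
        self.entries.setdefault(patient_id, []).append(
            GroundTruthEntry(rule_id=rule_id, expected_alert=expected, near_miss=near_miss)
        )

    def expected_alerts(self) -> set[tuple[str, str]]:
        return {
            (pid, e.rule_id)
            for pid, rows in self.entries.items()
            for e in rows
            if e.expected_alert
        }


class GeneratorConfig(BaseModel):
    n_patients: int = 60
    injections: Optional[dict[str, int]] = None  # rule_id -> count; default 1 each
    near_miss_fraction: float = 0.25
    seed: int = 0
    as_of: datetime = DEFAULT_AS_OF

    @model_validator(mode="after")
    def _bounds(self) -> "GeneratorConfig":
        if not (0.0 <= self.near_miss_fraction <= 1.0):
            raise ValueError("near_miss_fraction must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        return self


def _quantile_sample(rng: np.random.Generator, anchors) -> float:
    qs = [q for q, _ in anchors]
    vals = [v for _, v in anchors]
    return float(np.interp(rng.uniform(), qs, vals))


class _Builder:
    """Mutable construction state shared by the per-rule injectors."""

    def __init__(self, rng: np.random.Generator, as_of: datetime) -> None:
        self.store = EhrStore()
        self.rng = rng
        self.as_of = as_of
        self._rx_seq = 0
        self._pat_seq = 0

    def new_patient(
        self,
        *,
        sex: Optional[Sex] = None,
        age: Optional[int] = None,
        weight: Optional[float] = None,
        height: Optional[float] = None,
        note_text: Optional[str] = None,
    ) -> PatientRecord:
        self._pat_seq += 1
        rng = self.rng
        if sex is None:
            sex = Sex.male if rng.uniform() < 0.5 else Sex.female
        if age is None:
            age = int(round(_quantile_sample(rng, _AGE_ANCHORS)))
        los_so_far = _quantile_sample(rng, _LOS_ANCHORS) * rng.uniform(0.2, 1.0)
        admitted = self.as_of - timedelta(days=los_so_far)
        patient = PatientRecord(
            patient_id=f"P{self._pat_seq:04d}",
            sex=sex,
            age=age,
            height_cm=height,
            weight_measured_kg=weight,
            ward_id=f"W{int(rng.integers(1, 5))}",
            admitted_at=admitted,
        )
        self.store.add_patient(patient)
        text = note_text if note_text is not None else _CLEAN_NOTES[
            int(self.rng.integers(len(_CLEAN_NOTES)))
        ]
        self.store.add_note(
            ProblemNote(
                patient_id=patient.patient_id,
                text=text,
                written_at=admitted + timedelta(hours=1),
            )
        )
        return patient

    def rx(
        self,
        patient: PatientRecord,
        atc: str,
        label: str,
        *,
        route: Route = Route.oral,
        status: PrescriptionStatus = PrescriptionStatus.CHECKED,
        is_prn: bool = False,
        rate: Optional[float] = None,
        conc: Optional[float] = None,
        start_days_ago: float = 3.0,
    ) -> PrescriptionDocument:
        self._rx_seq += 1
        doc = PrescriptionDocument(
            prescription_id=f"RX{self._rx_seq:05d}",
            patient_id=patient.patient_id,
            atc_code=atc,
            drug_label=label,
            status=status,
            route=route,
            is_prn=is_prn,
            rate_mmol_per_h=rate,
            concentration_mmol_per_ml=conc,
            start_at=self.as_of - timedelta(days=start_days_ago),
        )
        self.store.add_prescription(doc)
        return doc

    def lab(
        self, patient: PatientRecord, analyte: Analyte, value: float, days_ago: float
    ) -> None:
        self.store.add_lab(
            LabResultDocument(
                patient_id=patient.patient_id,
                analyte=analyte,
                value=value,
                unit=CANONICAL_UNITS[analyte],
                published_at=self.as_of - timedelta(days=days_ago),
            )
        )

    def admin_event(self, patient: PatientRecord, atc: str, days_from_now: float) -> None:
        self.store.add_administration(
            AdministrationEvent(
                patient_id=patient.patient_id,
                atc_code=atc,
                scheduled_at=self.as_of + timedelta(days=days_from_now),
            )
        )

    def background(self, patient: PatientRecord) -> None:
        """Non-triggering drug burden and normal-range labs."""
        rng = self.rng
        n_drugs = int(round(_quantile_sample(rng, _NDRUGS_ANCHORS)))
        n_drugs = min(n_drugs, len(_BACKGROUND_DRUGS))
        picks = rng.choice(len(_BACKGROUND_DRUGS), size=n_drugs, replace=False)
        for idx in picks:
            atc, label = _BACKGROUND_DRUGS[int(idx)]
            status = (
                PrescriptionStatus.DRAFT
                if rng.uniform() < 0.05
                else PrescriptionStatus.CHECKED
            )
            self.rx(
                patient, atc, label,
                status=status,
                start_days_ago=float(rng.uniform(0.5, 10.0)),
            )
        # normal-range labs published well before any injected excursion
        for analyte, lo, hi in (
            (Analyte.potassium, 3.8, 5.2),
            (Analyte.glucose, 5.0, 9.0),
            (Analyte.platelets, 160.0, 380.0),
        ):
            if rng.uniform() < 0.8:
                self.lab(
                    patient, analyte,
                    float(np.round(rng.uniform(lo, hi), 2)),
                    days_ago=float(rng.uniform(5.0, 25.0)),
                )


# -- per-rule injectors ------------------------------------------------------
# Each injector builds one patient satisfying the exact trigger (near=False)
# or violating exactly one condition minimally (near=True).

_RENAL_PATIENT = dict(sex=Sex.male, age=80, weight=50.0, height=None)
# ClCG = (140-80) * 50 * 1.23 / creatinine = 3690 / creatinine


def _inject_renal(b: _Builder, near: bool, atc: str, label: str, *,
                  crea: float, crea_near: float) -> PatientRecord:
    p = b.new_patient(**_RENAL_PATIENT)
    b.rx(p, atc, label)
    b.lab(p, Analyte.creatinine, 90.0, days_ago=6.0)  # earlier baseline (context)
    b.lab(p, Analyte.creatinine, crea_near if near else crea, days_ago=1.0)
    b.lab(p, Analyte.egfr_ckdepi, 50.0, days_ago=2.0)
    b.lab(p, Analyte.egfr_ckdepi, 57.0, days_ago=1.0)  # +14% progression context
    return p


def _lab_injector(atc: str, label: str, analyte: Analyte, value: float,
                  value_near: float, **rx_kw) -> Callable:
    def inject(b: _Builder, near: bool) -> PatientRecord:
        p = b.new_patient()
        b.rx(p, atc, label, **rx_kw)
        b.lab(p, analyte, value_near if near else value, days_ago=1.0)
        return p
    return inject


def _problem_injector(atc: str, label: str, note: str) -> Callable:
    def inject(b: _Builder, near: bool) -> PatientRecord:
        p = b.new_patient(note_text=None if near else note)
        b.rx(p, atc, label)
        return p
    return inject


def _inject_anticoag_dup(b: _Builder, near: bool) -> PatientRecord:
    p = b.new_patient()
    if near:  # VKA + LMWH: the explicitly excluded combination
        b.rx(p, "B01AA07", "acenocoumarol")
        b.rx(p, "B01AB05", "enoxaparin", route=Route.sc)
    else:
        b.rx(p, "B01AF02", "apixaban")
        b.rx(p, "B01AF01", "rivaroxaban")
    return p


def _inject_serotonergic(b: _Builder, near: bool) -> PatientRecord:
    p = b.new_patient()
    b.rx(p, "N06AB06", "sertraline")
    if not near:
        b.rx(p, "N02AX02", "tramadol")
    return p


def _inject_mtx(b: _Builder, near: bool) -> PatientRecord:
    p = b.new_patient()
    gap_first, gap_second = (-4.0, 4.0) if near else (-3.0, 2.0)  # 8 vs 5 day gap
    b.admin_event(p, "L04AX03", gap_first)
    b.admin_event(p, "L04AX03", gap_second)
    return p


def _inject_kcl_rate(b: _Builder, near: bool) -> PatientRecord:
    p = b.new_patient()
    b.rx(p, "B05XA01", "potassium chloride", route=Route.iv_continuous,
         rate=10.0 if near else 12.0)
    return p


def _inject_kcl_conc(b: _Builder, near: bool) -> PatientRecord:
    p = b.new_patient()
    b.rx(p, "B05XA01", "potassium chloride", route=Route.iv_intermittent,
         conc=0.08 if near else 0.12)
    return p


_INJECTORS: dict[str, Callable[[_Builder, bool], PatientRecord]] = {
    "doac_renal_failure": lambda b, near: _inject_renal(
        b, near, "B01AF02", "apixaban", crea=150.0, crea_near=119.0),
    "colchicine_renal_failure": lambda b, near: _inject_renal(
        b, near, "M04AC01", "colchicine", crea=150.0, crea_near=119.0),
    "morphine_renal_failure": lambda b, near: _inject_renal(
        b, near, "N02AA01", "morphine", crea=280.0, crea_near=230.0),
    "metformin_renal_failure": lambda b, near: _inject_renal(
        b, near, "A10BA02", "metformin", crea=150.0, crea_near=119.0),
    "vka_supratherapeutic_inr": _lab_injector(
        "B01AA03", "warfarin", Analyte.inr, 4.5, 3.9),
    "vancomycin_supratherapeutic_level": _lab_injector(
        "J01XA01", "vancomycin", Analyte.vancomycin_level, 30.0, 24.0,
        route=Route.iv_intermittent),
    "digoxin_supratherapeutic_level": _lab_injector(
        "C01AA05", "digoxin", Analyte.digoxin_level, 3.5, 2.9),
    "aminoglycoside_supratherapeutic_level": _lab_injector(
        "J01GB03", "gentamicin", Analyte.gentamicin_level, 1.5, 0.9,
        route=Route.iv_intermittent),
    "glucose_lowering_hypoglycemia": _lab_injector(
        "A10AB05", "insulin aspart", Analyte.glucose, 3.2, 4.1, route=Route.sc),
    "heparin_thrombopenia": _lab_injector(
        "B01AB05", "enoxaparin", Analyte.platelets, 35.0, 51.0, route=Route.sc),
    "digoxin_dyskalemia": _lab_injector(
        "C01AA05", "digoxin", Analyte.potassium, 5.8, 5.4),
    "metformin_hyperlactatemia": _lab_injector(
        "A10BA02", "metformin", Analyte.lactate, 6.0, 4.9),
    "anticholinergic_comorbidity": _problem_injector(
        "N05AA07", "thioridazine", "Antécédents: démence avancée, vit en EMS."),
    "seizure_threshold_epilepsy": _problem_injector(
        "J01XD01", "metronidazole", "Connu pour épilepsie traitée depuis 2010."),
    "nsaid_comorbidity": _problem_injector(
        "M01AE01", "ibuprofen", "Insuffisance cardiaque chronique stade III."),
    "anticoagulant_duplication": _inject_anticoag_dup,
    "serotonergic_duplication": _inject_serotonergic,
    "mtx_dose_interval": _inject_mtx,
    "kcl_infusion_rate": _inject_kcl_rate,
    "kcl_concentration": _inject_kcl_conc,
}

ALL_RULE_IDS = list(_INJECTORS)


def generate_cohort(config: GeneratorConfig) -> tuple[EhrStore, GroundTruth]:
    """Build a seeded cohort with injected risk situations and controls.

    Every injected patient satisfies exactly one rule's trigger; near-miss
    controls sit just outside one threshold; remaining patients are clean
    background.  Deterministic for a given config (same seed twice yields
    byte-identical stores on disk).
    """
    injections = dict.fromkeys(ALL_RULE_IDS, 1) if config.injections is None \
        else dict(config.injections)
    unknown = set(injections) - set(_INJECTORS)
    if unknown:
        raise ValueError(f"unknown rule ids in injections: {sorted(unknown)}")
    n_injected = sum(injections.values())
    if n_injected > config.n_patients:
        raise ValueError(
            f"cannot inject {n_injected} situations into {config.n_patients} patients"
        )

    roles: list[tuple[str, Optional[str]]] = []
    for rule_id, count in injections.items():
        roles += [("inject", rule_id)] * count
    n_rest = config.n_patients - n_injected
    n_near = int(round(config.near_miss_fraction * n_rest))
    for i in range(n_near):
        roles.append(("near_miss", ALL_RULE_IDS[i % len(ALL_RULE_IDS)]))
    roles += [("clean", None)] * (n_rest - n_near)

    rng = np.random.default_rng(config.seed)
    rng.shuffle(roles)  # mixes roles across patient ids, still seed-deterministic

    builder = _Builder(rng, config.as_of)
    truth = GroundTruth()
    for role, rule_id in roles:
        if role == "clean":
            patient = builder.new_patient()
            builder.background(patient)
        else:
            near = role == "near_miss"
            patient = _INJECTORS[rule_id](builder, near)
            builder.background(patient)
            truth.add(patient.patient_id, rule_id, expected=not near, near_miss=near)
    return builder.store, truth


# -- published-performance ledger fixture ------------------------------------

#: Per-rule (alerts, interventions, accepted changes) from the study period.
TABLE3_COUNTS: dict[str, tuple[int, int, int]] = {
    "doac_renal_failure": (64, 25, 16),
    "colchicine_renal_failure": (21, 6, 4),
    "morphine_renal_failure": (16, 1, 1),
    "metformin_renal_failure": (20, 9, 8),
    "vka_supratherapeutic_inr": (36, 7, 2),
    "vancomycin_supratherapeutic_level": (4, 3, 1),
    "digoxin_supratherapeutic_level": (1, 1, 1),
    "aminoglycoside_supratherapeutic_level": (1, 0, 0),
    "glucose_lowering_hypoglycemia": (30, 0, 0),
    "heparin_thrombopenia": (30, 4, 2),
    "digoxin_dyskalemia": (15, 7, 6),
    "metformin_hyperlactatemia": (4, 2, 2),
    "anticholinergic_comorbidity": (66, 1, 1),
    "seizure_threshold_epilepsy": (51, 1, 0),
    "nsaid_comorbidity": (10, 2, 2),
    "anticoagulant_duplication": (38, 20, 17),
    "serotonergic_duplication": (33, 0, 0),
    "mtx_dose_interval": (5, 0, 0),
    "kcl_infusion_rate": (2, 1, 0),
    "kcl_concentration": (0, 0, 0),
}

_REP_ATC = {
    "doac_renal_failure": ("B01AF02",),
    "colchicine_renal_failure": ("M04AC01",),
    "morphine_renal_failure": ("N02AA01",),
    "metformin_renal_failure": ("A10BA02",),
    "vka_supratherapeutic_inr": ("B01AA03",),
    "vancomycin_supratherapeutic_level": ("J01XA01",),
    "digoxin_supratherapeutic_level": ("C01AA05",),
    "aminoglycoside_supratherapeutic_level": ("J01GB03",),
    "glucose_lowering_hypoglycemia": ("A10AB05",),
    "heparin_thrombopenia": ("B01AB05",),
    "digoxin_dyskalemia": ("C01AA05",),
    "metformin_hyperlactatemia": ("A10BA02",),
    "anticholinergic_comorbidity": ("N05AA07",),
    "seizure_threshold_epilepsy": ("J01XD01",),
    "nsaid_comorbidity": ("M01AE01",),
    "anticoagulant_duplication": ("B01AF01", "B01AF02"),
    "serotonergic_duplication": ("N02AX02", "N06AB06"),
    "mtx_dose_interval": ("L04AX03",),
    "kcl_infusion_rate": ("B05XA01",),
    "kcl_concentration": ("B05XA01",),
}

N_SCREENING_DAYS = 132
N_PATIENTS_SCREENED = 5466
N_ALERTING_PATIENTS = 383
_CENSUS_START = date(2020, 2, 3)


def table3_census() -> ScreeningCensus:
    days = [_CENSUS_START + timedelta(days=i) for i in range(N_SCREENING_DAYS)]
    return ScreeningCensus(days=days, n_patients_screened=N_PATIENTS_SCREENED)


def make_table3_ledger(rulebook: Optional[RuleBook] = None) -> AlertLedger:
    """Synthetic ledger reproducing the published per-rule alert,
    intervention and acceptance counts over 132 screening days.

    Alerts are spread round-robin over the screening calendar and over a
    pool of 383 distinct patients (so 64 patients alert twice, under
    different rules), then folded through the normal reconcile /
    intervention / outcome pathway.
    """
    rulebook = rulebook or build_default_rulebook()
    flat: list[tuple[str, int]] = []  # (rule_id, per-rule alert index)
    for rule in rulebook.rules:
        n_alerts, _, _ = TABLE3_COUNTS[rule.rule_id]
        flat += [(rule.rule_id, j) for j in range(n_alerts)]

    by_day: dict[int, list[tuple[str, int]]] = {d: [] for d in range(N_SCREENING_DAYS)}
    patient_of: dict[tuple[str, int], str] = {}
    for i, item in enumerate(flat):
        by_day[i % N_SCREENING_DAYS].append(item)
        patient_of[item] = f"T{(i % N_ALERTING_PATIENTS) + 1:04d}"

    ledger = AlertLedger()
    for d in range(N_SCREENING_DAYS):
        run_at = datetime.combine(_CENSUS_START + timedelta(days=d), datetime.min.time()) \
            + timedelta(hours=10)
        candidates = [
            AlertCandidate(
                rule_id=rule_id,
                patient_id=patient_of[(rule_id, j)],
                as_of=run_at,
                trigger_atcs=_REP_ATC[rule_id],
                snapshot={"synthetic": True},
            )
            for rule_id, j in by_day[d]
        ]
        new_alerts, _ = ledger.reconcile(candidates, run_at)
        for alert, (rule_id, j) in zip(new_alerts, by_day[d]):
            _, n_int, n_acc = TABLE3_COUNTS[rule_id]
            if j < n_int:
                ledger.record_intervention(
                    alert.alert_id, True, run_at + timedelta(hours=2),
                    channel=Channel.phone,
                )
                outcome = Outcome.accepted if j < n_acc else Outcome.declined_benefit_risk
                ledger.record_outcome(
                    alert.alert_id, outcome, run_at + timedelta(hours=8)
                )
    return ledger
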