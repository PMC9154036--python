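"""Declarative clinical rules and their evaluation against an EHR snapshot.

Twenty rules screen for high-risk medication situations across four risk
categories: prescriptions with an abnormal laboratory value (including a
renal-failure sub-category triggered on computed Cockcroft–Gault clearance),
contraindicated-in-context prescriptions matched against French free-text
problem entries, therapeutic duplications, and inadequate administration
modes (methotrexate scheduling, IV potassium chloride rate/concentration).

Each rule is a declarative :class:`ClinicalRule` holding one of four trigger
variants; :func:`evaluate_rule` turns a rule plus a store into
:class:`AlertCandidate` objects carrying the evidence snapshot and the
decision-support context values.

Comparator inclusivity follows the printed thresholds exactly: ``<=``/``>=``
are inclusive, ``>`` is strict, and "dyskalemia" is the inclusive
outside-range test K <= 3.5 or K >= 5.5 mmol/L.
"""

from __future__ import annotations

import logging
from datetime import datetime
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Annotated, Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from ._textnorm import fold
from .clinical_calculators import assess_renal
from .ehr_model import (
    Analyte,
    AdministrationEvent,
    DEFAULT_LAB_WINDOW_DAYS,
    EhrStore,
    NoteKind,
    PrescriptionDocument,
    ProblemNote,
    Route,
    active_prescriptions,
    recent_labs,
)

log = logging.getLogger(__name__)


class RiskCategory(str, Enum):
    abnormal_lab = "abnormal_lab"
    contraindicated_in_context = "contraindicated_in_context"
    drug_drug_interaction = "drug_drug_interaction"
    inadequate_administration = "inadequate_administration"


class RiskSubcategory(str, Enum):
    renal_failure = "renal_failure"
    supratherapeutic_level = "supratherapeutic_level"
    abnormal_lab_value = "abnormal_lab_value"
    none = "none"


class Comparator(str, Enum):
    le = "le"  # inclusive <=
    ge = "ge"  # inclusive >=
    lt = "lt"  # strict <
    gt = "gt"  # strict >
    outside_range = "outside_range"  # value <= low OR value >= high (inclusive)


class DrugSet(BaseModel):
    """A drug list given as ATC prefixes (class matches) and/or normalized
    substance names (label matches, case- and diacritic-insensitive)."""

    atc_prefixes: list[str] = Field(default_factory=list)
    substances: list[str] = Field(default_factory=list)

    def matches(self, rx: PrescriptionDocument) -> bool:
        if any(rx.atc_code.startswith(p) for p in self.atc_prefixes):
            return True
        label = fold(rx.drug_label)
        return any(label == fold(s) for s in self.substances)

    def is_empty(self) -> bool:
        return not self.atc_prefixes and not self.substances


def match_drug_set(
    prescriptions: list[PrescriptionDocument], drug_set: DrugSet
) -> list[PrescriptionDocument]:
    """Prescriptions whose ATC code starts with a listed prefix or whose
    folded label equals a listed substance."""
    return [rx for rx in prescriptions if drug_set.matches(rx)]


class LabPredicate(BaseModel):
    analyte: Analyte
    comparator: Comparator
    threshold: Optional[float] = None
    low: Optional[float] = None  # outside_range only
    high: Optional[float] = None
    unit: str = ""

    @model_validator(mode="after")
    def _thresholds(self) -> "LabPredicate":
        if self.comparator is Comparator.outside_range:
            if self.low is None or self.high is None or self.low <= 0 or self.high <= 0:
                raise ValueError("outside_range requires positive low and high")
        elif self.threshold is None or self.threshold <= 0:
            raise ValueError("comparator requires a positive threshold")
        return self

    def test(self, value: float) -> bool:
        if self.comparator is Comparator.le:
            return value <= self.threshold
        if self.comparator is Comparator.ge:
            return value >= self.threshold
        if self.comparator is Comparator.lt:
            return value < self.threshold
        if self.comparator is Comparator.gt:
            return value > self.threshold
        return value <= self.low or value >= self.high


class RenalMode(str, Enum):
    none = "none"
    clcg_selected_weight = "clcg_selected_weight"


class LabBranch(BaseModel):
    """One (drug set, lab predicate) pair; rules with several monitored drugs
    (the aminoglycosides) carry one branch per drug/analyte."""

    drug_set: DrugSet
    predicate: LabPredicate


class DrugLabTrigger(BaseModel):
    kind: Literal["drug_lab"] = "drug_lab"
    branches: list[LabBranch]
    renal_mode: RenalMode = RenalMode.none
    exclude_prn: bool = False
    window_days: float = DEFAULT_LAB_WINDOW_DAYS


class DrugProblemTrigger(BaseModel):
    kind: Literal["drug_problem"] = "drug_problem"
    drug_set: DrugSet
    keywords: list[str]
    note_kind: NoteKind = NoteKind.admission_note

    @model_validator(mode="after")
    def _nonempty(self) -> "DrugProblemTrigger":
        if not self.keywords:
            raise ValueError("keyword set must be non-empty")
        return self


class DrugComboTrigger(BaseModel):
    kind: Literal["drug_combo"] = "drug_combo"
    class_sets: dict[str, DrugSet]
    excluded_pairs: list[tuple[str, str]] = Field(default_factory=list)
    min_distinct: int = 2

    @model_validator(mode="after")
    def _min(self) -> "DrugComboTrigger":
        if self.min_distinct < 2:
            raise ValueError("min_distinct must be >= 2")
        return self


class AdminMode(str, Enum):
    rate_threshold = "rate_threshold"
    concentration_thresholds = "concentration_thresholds"
    dose_interval = "dose_interval"


class AdminModeTrigger(BaseModel):
    kind: Literal["admin_mode"] = "admin_mode"
    drug_set: DrugSet
    mode: AdminMode
    rate_limit_mmol_per_h: Optional[float] = None  # strict >
    conc_limit_intermittent_mmol_per_ml: Optional[float] = None  # strict >
    conc_limit_continuous_mmol_per_ml: Optional[float] = None  # strict >
    max_gap_days: Optional[float] = None  # inclusive <=


TriggerSpec = Annotated[
    Union[DrugLabTrigger, DrugProblemTrigger, DrugComboTrigger, AdminModeTrigger],
    Field(discriminator="kind"),
]


class ClinicalRule(BaseModel):
    rule_id: str
    name: str
    risk_category: RiskCategory
    risk_subcategory: RiskSubcategory = RiskSubcategory.none
    trigger: TriggerSpec
    context_spec: list[str] = Field(default_factory=list)
    enabled: bool = True

    @model_validator(mode="after")
    def _subcategory_scope(self) -> "ClinicalRule":
        if (
            self.risk_subcategory is not RiskSubcategory.none
            and self.risk_category is not RiskCategory.abnormal_lab
        ):
            raise ValueError("named sub-categories only exist under abnormal_lab")
        return self


class RuleBook(BaseModel):
    version: str = "1"
    rules: list[ClinicalRule]
    #: user-fillable list of strong P-gp/CYP3A4 inducers/inhibitors shown as
    #: context with the renal DOAC/colchicine rules (empty by default).
    pgp_cyp3a4_modulators: DrugSet = Field(default_factory=DrugSet)

    @model_validator(mode="after")
    def _unique_ids(self) -> "RuleBook":
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ValueError("rule_id values must be unique")
        return self

    def rule(self, rule_id: str) -> ClinicalRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleBook":
        return cls.model_validate(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


class AlertCandidate(BaseModel):
    rule_id: str
    patient_id: str
    as_of: datetime
    trigger_atcs: tuple[str, ...]  # sorted trigger-drug ATC set (dedup identity)
    snapshot: dict = Field(default_factory=dict)
    context: dict = Field(default_factory=dict)


# -- elementary trigger evaluators ------------------------------------------


def eval_problem_keywords(
    notes: list[ProblemNote], keywords: list[str]
) -> Optional[dict]:
    """First matching (keyword, note) pair under folded substring search.

    No negation detection: "pas d'épilepsie" still matches "épilepsie" —
    a documented limitation of free-text problem screening.
    """
    for note in notes:
        folded_text = fold(note.text)
        for kw in keywords:
            offset = folded_text.find(fold(kw))
            if offset >= 0:
                return {
                    "keyword": kw,
                    "offset": offset,
                    "written_at": note.written_at.isoformat(timespec="minutes"),
                    "excerpt": note.text[max(0, offset - 20) : offset + len(kw) + 20],
                }
    return None


def eval_combo(
    prescriptions: list[PrescriptionDocument],
    class_sets: dict[str, DrugSet],
    excluded_pairs: list[tuple[str, str]],
    min_distinct: int = 2,
) -> list[tuple[PrescriptionDocument, PrescriptionDocument]]:
    """Offending unordered pairs of concurrently active prescriptions.

    A prescription belongs to the first class set that matches it; pairs
    whose (class, class) combination is excluded (e.g. VKA with LMWH/UFH)
    do not fire, and pairs of the same substance (same ATC code) are
    treated as refills, not duplication.
    """
    excluded = {frozenset(p) for p in excluded_pairs}
    classified: list[tuple[str, PrescriptionDocument]] = []
    for rx in prescriptions:
        for cls_name, ds in class_sets.items():
            if ds.matches(rx):
                classified.append((cls_name, rx))
                break
    if len(classified) < min_distinct:
        return []
    offending = []
    for (c1, rx1), (c2, rx2) in combinations(classified, 2):
        if rx1.atc_code == rx2.atc_code:
            continue
        if frozenset((c1, c2)) in excluded:
            continue
        offending.append((rx1, rx2))
    return offending


def eval_mtx_interval(
    admin_events: list[AdministrationEvent], max_gap_days: float = 7.0
) -> list[tuple[AdministrationEvent, AdministrationEvent]]:
    """Pairs of scheduled doses separated by 0 < gap <= max_gap_days (inclusive)."""
    events = sorted(admin_events, key=lambda e: e.scheduled_at)
    pairs = []
    for e1, e2 in combinations(events, 2):
        gap_days = (e2.scheduled_at - e1.scheduled_at).total_seconds() / 86400.0
        if 0 < gap_days <= max_gap_days:
            pairs.append((e1, e2))
    return pairs


def eval_kcl(
    rx: PrescriptionDocument,
    rate_limit: Optional[float] = None,
    conc_limit_intermittent: Optional[float] = None,
    conc_limit_continuous: Optional[float] = None,
) -> Optional[dict]:
    """Rate/concentration violation descriptor for one IV KCl order, or None.

    All limits are strict ``>``; non-IV routes abstain.
    """
    if rx.route not in (Route.iv_intermittent, Route.iv_continuous):
        return None
    if rate_limit is not None and rx.rate_mmol_per_h is not None:
        if rx.rate_mmol_per_h > rate_limit:
            return {
                "violation": "rate",
                "value": rx.rate_mmol_per_h,
                "limit": rate_limit,
                "unit": "mmol/h",
            }
    if rx.concentration_mmol_per_ml is not None:
        limit = (
            conc_limit_intermittent
            if rx.route is Route.iv_intermittent
            else conc_limit_continuous
        )
        if limit is not None and rx.concentration_mmol_per_ml > limit:
            return {
                "violation": "concentration",
                "value": rx.concentration_mmol_per_ml,
                "limit": limit,
                "unit": "mmol/mL",
                "route": rx.route.value,
            }
    return None


# -- rule evaluation ---------------------------------------------------------


def _rx_brief(rx: PrescriptionDocument) -> dict:
    return {
        "prescription_id": rx.prescription_id,
        "atc_code": rx.atc_code,
        "drug_label": rx.drug_label,
        "route": rx.route.value,
        "start_at": rx.start_at.isoformat(timespec="minutes"),
    }


def _lab_brief(lab) -> dict:
    return {
        "analyte": lab.analyte.value,
        "value": lab.value,
        "unit": lab.unit,
        "published_at": lab.published_at.isoformat(timespec="minutes"),
    }


def _candidate(
    rule: ClinicalRule,
    patient_id: str,
    as_of: datetime,
    atcs: set[str],
    snapshot: dict,
    context: dict,
) -> AlertCandidate:
    return AlertCandidate(
        rule_id=rule.rule_id,
        patient_id=patient_id,
        as_of=as_of,
        trigger_atcs=tuple(sorted(atcs)),
        snapshot=snapshot,
        context=context,
    )


def _eval_drug_lab(
    rule: ClinicalRule,
    trig: DrugLabTrigger,
    store: EhrStore,
    patient_id: str,
    as_of: datetime,
    modulators: Optional[DrugSet],
) -> Optional[AlertCandidate]:
    rx_active = active_prescriptions(store, patient_id, as_of)
    matched_rx: list[PrescriptionDocument] = []
    evidence: list[dict] = []
    context: dict = {}
    for branch in trig.branches:
        matched = match_drug_set(rx_active, branch.drug_set)
        if trig.exclude_prn:
            matched = [rx for rx in matched if not rx.is_prn]
        if not matched:
            continue
        if trig.renal_mode is RenalMode.clcg_selected_weight:
            patient = store.patients[patient_id]
            assessment = assess_renal(patient, store, as_of, trig.window_days)
            if assessment is None:
                log.debug(
                    "rule %s abstains for %s: renal assessment unavailable",
                    rule.rule_id,
                    patient_id,
                )
                continue
            if branch.predicate.test(assessment.clcg_ml_min):
                matched_rx.extend(matched)
                evidence.append(
                    {
                        "trigger_quantity": "clcg_selected_weight",
                        "clcg_ml_min": assessment.clcg_ml_min,
                        "creatinine_umol_l": assessment.creatinine_umol_l,
                        "published_at": assessment.creatinine_published_at.isoformat(
                            timespec="minutes"
                        ),
                    }
                )
                context.update(
                    {
                        "weight_measured_kg": assessment.weight_measured_kg,
                        "weight_ideal_kg": assessment.weight_ideal_kg,
                        "weight_selected_kg": assessment.weight_selected_kg,
                        "egfr_ckdepi": assessment.egfr_ml_min_173,
                        "delta_egfr_pct": assessment.delta_egfr_pct,
                        "previous_creatinine_umol_l": assessment.previous_creatinine_umol_l,
                    }
                )
                if modulators is not None and not modulators.is_empty():
                    context["pgp_cyp3a4_modulators"] = [
                        _rx_brief(rx) for rx in match_drug_set(rx_active, modulators)
                    ]
        else:
            labs = recent_labs(
                store, patient_id, branch.predicate.analyte, trig.window_days, as_of
            )
            if not labs:
                continue  # no in-window value: abstain, never alert-on-missing
            latest = labs[0]
            if branch.predicate.test(latest.value):
                matched_rx.extend(matched)
                evidence.append(_lab_brief(latest))
                context.setdefault("previous_values", {})[
                    branch.predicate.analyte.value
                ] = [_lab_brief(lab) for lab in labs[1:]]
    if not evidence:
        return None
    return _candidate(
        rule,
        patient_id,
        as_of,
        {rx.atc_code for rx in matched_rx},
        {"prescriptions": [_rx_brief(rx) for rx in matched_rx], "evidence": evidence},
        context,
    )


def _eval_drug_problem(
    rule: ClinicalRule,
    trig: DrugProblemTrigger,
    store: EhrStore,
    patient_id: str,
    as_of: datetime,
) -> Optional[AlertCandidate]:
    rx_active = active_prescriptions(store, patient_id, as_of)
    matched = match_drug_set(rx_active, trig.drug_set)
    if not matched:
        return None
    notes = [
        n
        for n in store.notes_for(patient_id)
        if n.note_kind is trig.note_kind and n.written_at <= as_of
    ]
    hit = eval_problem_keywords(notes, trig.keywords)
    if hit is None:
        return None
    return _candidate(
        rule,
        patient_id,
        as_of,
        {rx.atc_code for rx in matched},
        {"prescriptions": [_rx_brief(rx) for rx in matched], "problem": hit},
        {"note_excerpt": hit["excerpt"]},
    )


def _eval_drug_combo(
    rule: ClinicalRule,
    trig: DrugComboTrigger,
    store: EhrStore,
    patient_id: str,
    as_of: datetime,
) -> Optional[AlertCandidate]:
    rx_active = active_prescriptions(store, patient_id, as_of)
    pairs = eval_combo(rx_active, trig.class_sets, trig.excluded_pairs, trig.min_distinct)
    if not pairs:
        return None
    atcs = {rx.atc_code for pair in pairs for rx in pair}
    return _candidate(
        rule,
        patient_id,
        as_of,
        atcs,
        {
            "pairs": [
                {"a": _rx_brief(rx1), "b": _rx_brief(rx2)} for rx1, rx2 in pairs
            ]
        },
        {"n_pairs": len(pairs)},
    )


def _eval_admin_mode(
    rule: ClinicalRule,
    trig: AdminModeTrigger,
    store: EhrStore,
    patient_id: str,
    as_of: datetime,
) -> Optional[AlertCandidate]:
    if trig.mode is AdminMode.dose_interval:
        events = [
            e
            for e in store.administrations_for(patient_id)
            if any(e.atc_code.startswith(p) for p in trig.drug_set.atc_prefixes)
        ]
        pairs = eval_mtx_interval(events, trig.max_gap_days or 7.0)
        if not pairs:
            return None
        return _candidate(
            rule,
            patient_id,
            as_of,
            {e.atc_code for pair in pairs for e in pair},
            {
                "dose_pairs": [
                    {
                        "first": e1.scheduled_at.isoformat(timespec="minutes"),
                        "second": e2.scheduled_at.isoformat(timespec="minutes"),
                    }
                    for e1, e2 in pairs
                ]
            },
            {"max_gap_days": trig.max_gap_days},
        )

    rx_active = active_prescriptions(store, patient_id, as_of)
    matched = match_drug_set(rx_active, trig.drug_set)
    violations = []
    offending = []
    for rx in matched:
        if trig.mode is AdminMode.rate_threshold:
            v = eval_kcl(rx, rate_limit=trig.rate_limit_mmol_per_h)
            v = v if v is not None and v["violation"] == "rate" else None
        else:
            v = eval_kcl(
                rx,
                conc_limit_intermittent=trig.conc_limit_intermittent_mmol_per_ml,
                conc_limit_continuous=trig.conc_limit_continuous_mmol_per_ml,
            )
            v = v if v is not None and v["violation"] == "concentration" else None
        if v is not None:
            violations.append(v)
            offending.append(rx)
    if not violations:
        return None
    return _candidate(
        rule,
        patient_id,
        as_of,
        {rx.atc_code for rx in offending},
        {
            "prescriptions": [_rx_brief(rx) for rx in offending],
            "violations": violations,
        },
        {},
    )


def evaluate_rule(
    rule: ClinicalRule,
    store: EhrStore,
    as_of: datetime,
    modulators: Optional[DrugSet] = None,
) -> list[AlertCandidate]:
    """All candidates for one rule: at most one per patient, ordered by
    patient_id. Disabled rules yield nothing."""
    if not rule.enabled:
        return []
    out: list[AlertCandidate] = []
    for patient_id in store.patient_ids():
        trig = rule.trigger
        if isinstance(trig, DrugLabTrigger):
            cand = _eval_drug_lab(rule, trig, store, patient_id, as_of, modulators)
        elif isinstance(trig, DrugProblemTrigger):
            cand = _eval_drug_problem(rule, trig, store, patient_id, as_of)
        elif isinstance(trig, DrugComboTrigger):
            cand = _eval_drug_combo(rule, trig, store, patient_id, as_of)
        else:
            cand = _eval_admin_mode(rule, trig, store, patient_id, as_of)
        if cand is not None:
            out.append(cand)
    return out


def evaluate_all(
    rulebook: RuleBook, store: EhrStore, as_of: datetime
) -> list[AlertCandidate]:
    """Union of evaluate_rule over enabled rules, sorted by (patient, rule)."""
    out: list[AlertCandidate] = []
    for rule in rulebook.rules:
        out.extend(evaluate_rule(rule, store, as_of, rulebook.pgp_cyp3a4_modulators))
    out.sort(key=lambda c: (c.patient_id, c.rule_id))
    return out


# -- the default twenty-rule book -------------------------------------------

# Long drug lists for the three context rules and the serotonergic
# duplication rule. Class entries are encoded as ATC prefixes; substances as
# normalized labels. These ship as editable configuration once exported to
# YAML.

_ANTICHOLINERGIC = DrugSet(
    atc_prefixes=[
        "R06AA",  # aminoalkyl ethers
        "R06AB",  # substituted alkylamines
        "R06AC",  # substituted ethylene diamines
        "R06AD",  # phenothiazine derivatives
        "N04A",   # anticholinergic antiparkinson agents
        "A03",    # drugs for functional GI disorders / synthetic anticholinergics
        "G04BD",  # drugs for urinary frequency and incontinence
        "N06AA",  # non-selective monoamine reuptake inhibitors
    ],
    substances=[
        "acepromazine", "antazoline", "azatadine", "bamipine", "buclizine",
        "carbamazepine", "chlorcyclizine", "chlorpromazine", "cinnarizine",
        "clozapine", "cyamemazine", "cyclizine", "cyproheptadine", "deptropine",
        "dimetindene", "disopyramide", "fluphenazine", "hydroxyzine",
        "hyoscyamine", "levomepromazine", "loxapine", "mebhydrolin", "meclozine",
        "nefopam", "oxatomide", "oxcarbazepine", "paroxetine", "pethidine",
        "phenindamine", "pimethixene", "pimozide", "piritramide", "pizotifen",
        "propantheline", "pyrrobutamine", "quetiapine", "scopolamine",
        "thenalidine", "thioridazine", "thiothixene", "tizanidine",
    ],
)

_SEIZURE_THRESHOLD = DrugSet(
    atc_prefixes=[
        "N04A",   # anticholinergic agents
        "R06A",   # antihistamines for systemic use
        "J01C",   # beta-lactams, penicillins
        "J01D",   # other beta-lactam antibacterials
        "L04AD",  # calcineurin inhibitors
        "G04BD",  # drugs for urinary frequency and incontinence
        "A02BA",  # H2-receptor antagonists
        "M03B",   # centrally acting muscle relaxants
        "N06AA",  # non-selective monoamine reuptake inhibitors
        "N05AA",  # phenothiazines with aliphatic side-chain
        "N05AB",  # phenothiazines with piperazine structure
        "J01M",   # quinolone antibacterials
        "N06AB",  # selective serotonin reuptake inhibitors
    ],
    substances=[
        "azithromycin", "bupropion", "busulfan", "carmustine", "chlorambucil",
        "chlorpromazine", "clonidine", "clozapine", "cyamemazine",
        "disopyramide", "domperidone", "enflurane", "ephedrine", "flumazenil",
        "foscarnet", "ganciclovir", "haloperidol", "hydroxyzine", "ketamine",
        "ketoconazole", "levomepromazine", "lidocaine", "lithium", "loxapine",
        "mefloquine", "methotrexate", "methylphenidate", "metronidazole",
        "midecamycin", "nefopam", "oxetorone", "oxybutynin", "pentazocine",
        "pethidine", "phenylpropanolamine", "pimozide", "piritramide",
        "pizotifen", "propantheline", "pyrimethamine", "scopolamine",
        "terbutaline", "theophylline", "tramadol", "vincristine",
    ],
)

_SEROTONERGIC = DrugSet(
    substances=[
        "amitriptyline", "bromocriptine", "bupropion", "buspirone",
        "cabergoline", "carbamazepine", "citalopram", "clomipramine",
        "clozapine", "dextromethorphan", "dihydroergotamine", "dosulepin",
        "doxepin", "eletriptan", "ergotamine", "escitalopram", "fentanyl",
        "fluoxetine", "fluvoxamine", "haloperidol", "imipramine", "isoniazid",
        "lamotrigine", "linezolid", "lithium", "maprotiline", "methadone",
        "metoclopramide", "mianserin", "mirtazapine", "moclobemide",
        "naratriptan", "nortriptyline", "olanzapine", "ondansetron",
        "oxycodone", "paroxetine", "pergolide", "pethidine", "quetiapine",
        "risperidone", "rizatriptan", "selegiline", "sertraline", "sibutramine",
        "sumatriptan", "tramadol", "trazodone", "trimipramine", "valproate",
        "venlafaxine", "zolmitriptan",
    ],
)

_VKA = DrugSet(
    atc_prefixes=["B01AA"],
    substances=["acenocoumarol", "fluindione", "warfarin", "phenprocoumon"],
)
_DOAC_RENAL = DrugSet(
    atc_prefixes=["B01AF01", "B01AF02", "B01AF03", "B01AE07"],
    substances=["apixaban", "dabigatran", "edoxaban", "rivaroxaban"],
)
# Edoxaban is listed with the renal rule but not with the duplication rule.
_DOAC_DUPLICATION = DrugSet(
    atc_prefixes=["B01AF01", "B01AF02", "B01AE07"],
    substances=["apixaban", "dabigatran", "rivaroxaban"],
)
_LMWH = DrugSet(
    atc_prefixes=["B01AB04", "B01AB05", "B01AB06", "B01AB10"],
    substances=["enoxaparin", "dalteparin", "nadroparin", "tinzaparin"],
)
_UFH = DrugSet(atc_prefixes=["B01AB01"], substances=["heparin"])
_HEPARINS = DrugSet(atc_prefixes=["B01AB"], substances=["enoxaparin", "dalteparin",
                                                        "nadroparin", "tinzaparin",
                                                        "heparin"])
_KCL = DrugSet(atc_prefixes=["B05XA01", "A12BA01"], substances=["potassium chloride"])
_MTX = DrugSet(atc_prefixes=["L01BA01", "L04AX03"], substances=["methotrexate"])


def _renal_rule(
    rule_id: str, name: str, drug_set: DrugSet, clcg_threshold: float,
    context: list[str],
) -> ClinicalRule:
    return ClinicalRule(
        rule_id=rule_id,
        name=name,
        risk_category=RiskCategory.abnormal_lab,
        risk_subcategory=RiskSubcategory.renal_failure,
        trigger=DrugLabTrigger(
            branches=[
                LabBranch(
                    drug_set=drug_set,
                    predicate=LabPredicate(
                        analyte=Analyte.creatinine,  # raw input; trigger is computed ClCG
                        comparator=Comparator.le,
                        threshold=clcg_threshold,
                        unit="mL/min",
                    ),
                )
            ],
            renal_mode=RenalMode.clcg_selected_weight,
        ),
        context_spec=context,
    )


def _level_rule(
    rule_id: str, name: str, branches: list[tuple[DrugSet, Analyte, float]],
) -> ClinicalRule:
    return ClinicalRule(
        rule_id=rule_id,
        name=name,
        risk_category=RiskCategory.abnormal_lab,
        risk_subcategory=RiskSubcategory.supratherapeutic_level,
        trigger=DrugLabTrigger(
            branches=[
                LabBranch(
                    drug_set=ds,
                    predicate=LabPredicate(
                        analyte=analyte, comparator=Comparator.ge, threshold=thr,
                    ),
                )
                for ds, analyte, thr in branches
            ]
        ),
        context_spec=["previous_levels"],
    )


def build_default_rulebook() -> RuleBook:
    """The default book of twenty enabled clinical rules."""
    renal_context = ["previous_creatinine", "clcg", "delta_egfr"]
    rules: list[ClinicalRule] = [
        _renal_rule(
            "doac_renal_failure",
            "DOAC in acute renal failure (ClCG <= 30 mL/min)",
            _DOAC_RENAL, 30.0,
            renal_context + ["pgp_cyp3a4_modulators"],
        ),
        _renal_rule(
            "colchicine_renal_failure",
            "Colchicine in acute renal failure (ClCG <= 30 mL/min)",
            DrugSet(atc_prefixes=["M04AC01"], substances=["colchicine"]), 30.0,
            renal_context + ["pgp_cyp3a4_modulators"],
        ),
        _renal_rule(
            "morphine_renal_failure",
            "Morphine in acute renal failure (ClCG <= 15 mL/min)",
            DrugSet(atc_prefixes=["N02AA01"], substances=["morphine"]), 15.0,
            renal_context,
        ),
        _renal_rule(
            "metformin_renal_failure",
            "Metformin in acute renal failure (ClCG <= 30 mL/min)",
            DrugSet(atc_prefixes=["A10BA02"], substances=["metformin"]), 30.0,
            renal_context,
        ),
        _level_rule(
            "vka_supratherapeutic_inr",
            "VKA with supra-therapeutic INR (>= 4)",
            [(_VKA, Analyte.inr, 4.0)],
        ),
        _level_rule(
            "vancomycin_supratherapeutic_level",
            "Vancomycin level >= 25 mg/L",
            [(DrugSet(atc_prefixes=["J01XA01"], substances=["vancomycin"]),
              Analyte.vancomycin_level, 25.0)],
        ),
        _level_rule(
            "digoxin_supratherapeutic_level",
            "Digoxin level >= 3 nmol/L",
            [(DrugSet(atc_prefixes=["C01AA05"], substances=["digoxin"]),
              Analyte.digoxin_level, 3.0)],
        ),
        _level_rule(
            "aminoglycoside_supratherapeutic_level",
            "Aminoglycoside trough above limit (gentamicin/tobramycin >= 1, amikacin >= 5 mg/L)",
            [
                (DrugSet(atc_prefixes=["J01GB03"], substances=["gentamicin"]),
                 Analyte.gentamicin_level, 1.0),
                (DrugSet(atc_prefixes=["J01GB01"], substances=["tobramycin"]),
                 Analyte.tobramycin_level, 1.0),
                (DrugSet(atc_prefixes=["J01GB06"], substances=["amikacin"]),
                 Analyte.amikacin_level, 5.0),
            ],
        ),
        ClinicalRule(
            rule_id="glucose_lowering_hypoglycemia",
            name="Blood-glucose-lowering drug with hypoglycemia (<= 4 mmol/L)",
            risk_category=RiskCategory.abnormal_lab,
            risk_subcategory=RiskSubcategory.abnormal_lab_value,
            trigger=DrugLabTrigger(
                branches=[
                    LabBranch(
                        drug_set=DrugSet(atc_prefixes=["A10A", "A10B"]),
                        predicate=LabPredicate(
                            analyte=Analyte.glucose,
                            comparator=Comparator.le,
                            threshold=4.0,
                            unit="mmol/L",
                        ),
                    )
                ],
                exclude_prn=True,
            ),
            context_spec=["previous_glucose"],
        ),
        ClinicalRule(
            rule_id="heparin_thrombopenia",
            name="Heparin (LMWH/UFH) with thrombopenia (platelets <= 50 G/L)",
            risk_category=RiskCategory.abnormal_lab,
            risk_subcategory=RiskSubcategory.abnormal_lab_value,
            trigger=DrugLabTrigger(
                branches=[
                    LabBranch(
                        drug_set=_HEPARINS,
                        predicate=LabPredicate(
                            analyte=Analyte.platelets,
                            comparator=Comparator.le,
                            threshold=50.0,
                            unit="G/L",
                        ),
                    )
                ]
            ),
            context_spec=["previous_platelets", "previous_heparin_prescriptions"],
        ),
        ClinicalRule(
            rule_id="digoxin_dyskalemia",
            name="Digoxin with dyskalemia (K <= 3.5 or >= 5.5 mmol/L)",
            risk_category=RiskCategory.abnormal_lab,
            risk_subcategory=RiskSubcategory.abnormal_lab_value,
            trigger=DrugLabTrigger(
                branches=[
                    LabBranch(
                        drug_set=DrugSet(atc_prefixes=["C01AA05"], substances=["digoxin"]),
                        predicate=LabPredicate(
                            analyte=Analyte.potassium,
                            comparator=Comparator.outside_range,
                            low=3.5,
                            high=5.5,
                            unit="mmol/L",
                        ),
                    )
                ]
            ),
            context_spec=["previous_potassium", "previous_digoxin_prescriptions"],
        ),
        ClinicalRule(
            rule_id="metformin_hyperlactatemia",
            name="Metformin with hyperlactatemia (lactate >= 5.0 mmol/L)",
            risk_category=RiskCategory.abnormal_lab,
            risk_subcategory=RiskSubcategory.abnormal_lab_value,
            trigger=DrugLabTrigger(
                branches=[
                    LabBranch(
                        drug_set=DrugSet(atc_prefixes=["A10BA02"], substances=["metformin"]),
                        predicate=LabPredicate(
                            analyte=Analyte.lactate,
                            comparator=Comparator.ge,
                            threshold=5.0,
                            unit="mmol/L",
                        ),
                    )
                ]
            ),
            context_spec=["previous_lactate"],
        ),
        ClinicalRule(
            rule_id="anticholinergic_comorbidity",
            name="Anticholinergic drug with at-risk comorbidity in admission note",
            risk_category=RiskCategory.contraindicated_in_context,
            trigger=DrugProblemTrigger(
                drug_set=_ANTICHOLINERGIC,
                keywords=[
                    "démence", "état confusionnel", "confusion", "globe urinaire",
                    "prostatisme", "rétention urinaire", "glaucome",
                    "trouble de la conduction",
                ],
            ),
            context_spec=["medication_history"],
        ),
        ClinicalRule(
            rule_id="seizure_threshold_epilepsy",
            name="Seizure-threshold-lowering drug with epilepsy history",
            risk_category=RiskCategory.contraindicated_in_context,
            trigger=DrugProblemTrigger(
                drug_set=_SEIZURE_THRESHOLD,
                keywords=["épilepsie", "épileptique", "convulsion"],
            ),
            context_spec=["medication_history"],
        ),
        ClinicalRule(
            rule_id="nsaid_comorbidity",
            name="NSAID/metamizole with at-risk comorbidity in admission note",
            risk_category=RiskCategory.contraindicated_in_context,
            trigger=DrugProblemTrigger(
                drug_set=DrugSet(
                    atc_prefixes=["M01A", "N02BB02", "N02BB52", "N02BB72"],
                    substances=["metamizole"],
                ),
                keywords=[
                    "insuffisance rénale chronique", "insuffisance cardiaque",
                    "infarctus du myocarde", "ulcère gastrique",
                    "ulcère duodénal", "ulcère gastroduodénal",
                    "ulcère gastro-duodénal",
                ],
            ),
            context_spec=["medication_history"],
        ),
        ClinicalRule(
            rule_id="anticoagulant_duplication",
            name="Co-prescription of 2 anticoagulants (VKA with LMWH/UFH excluded)",
            risk_category=RiskCategory.drug_drug_interaction,
            trigger=DrugComboTrigger(
                class_sets={
                    "VKA": _VKA,
                    "DOAC": _DOAC_DUPLICATION,
                    "LMWH": _LMWH,
                    "UFH": _UFH,
                },
                excluded_pairs=[("VKA", "LMWH"), ("VKA", "UFH")],
            ),
            context_spec=["medication_history"],
        ),
        ClinicalRule(
            rule_id="serotonergic_duplication",
            name="Co-prescription of 2 serotonergic drugs",
            risk_category=RiskCategory.drug_drug_interaction,
            trigger=DrugComboTrigger(class_sets={"serotonergic": _SEROTONERGIC}),
            context_spec=["medication_history"],
        ),
        ClinicalRule(
            rule_id="mtx_dose_interval",
            name="Two methotrexate doses scheduled <= 7 days apart",
            risk_category=RiskCategory.inadequate_administration,
            trigger=AdminModeTrigger(
                drug_set=_MTX, mode=AdminMode.dose_interval, max_gap_days=7.0,
            ),
        ),
        ClinicalRule(
            rule_id="kcl_infusion_rate",
            name="IV potassium chloride flow rate > 10 mmol/h",
            risk_category=RiskCategory.inadequate_administration,
            trigger=AdminModeTrigger(
                drug_set=_KCL, mode=AdminMode.rate_threshold,
                rate_limit_mmol_per_h=10.0,
            ),
        ),
        ClinicalRule(
            rule_id="kcl_concentration",
            name="IV potassium chloride concentration above route limit",
            risk_category=RiskCategory.inadequate_administration,
            trigger=AdminModeTrigger(
                drug_set=_KCL, mode=AdminMode.concentration_thresholds,
                conc_limit_intermittent_mmol_per_ml=0.08,
                conc_limit_continuous_mmol_per_ml=1.00,
            ),
        ),
    ]
    return RuleBook(version="1", rules=rules)
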