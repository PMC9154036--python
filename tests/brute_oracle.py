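"""Brute-force cross-product re-evaluation of every rule, independent of the
staged query primitives.

This oracle reads only the declarative fields of each rule and the raw
document lists of the store, re-deriving activity windows, latest-lab
selection, weight selection and the Cockcroft-Gault arithmetic with its own
inline code.  It returns the set of (patient_id, rule_id) pairs that should
alert; the test asserts equality with the engine's staged evaluation.
"""

from __future__ import annotations

import unicodedata
from datetime import timedelta
from itertools import combinations

from pharmacheck.ehr_model import PrescriptionStatus, Route
from pharmacheck.rule_engine import (
    AdminMode,
    AdminModeTrigger,
    Comparator,
    DrugComboTrigger,
    DrugLabTrigger,
    DrugProblemTrigger,
    RenalMode,
)


def _fold(text):
    d = unicodedata.normalize("NFKD", text.casefold())
    return "".join(c for c in d if not unicodedata.combining(c))


def _matches(rx, drug_set):
    for prefix in drug_set.atc_prefixes:
        if rx.atc_code.startswith(prefix):
            return True
    return _fold(rx.drug_label) in {_fold(s) for s in drug_set.substances}


def _active(store, pid, as_of):
    return [
        rx for rx in store.prescriptions
        if rx.patient_id == pid
        and rx.status == PrescriptionStatus.CHECKED
        and rx.start_at <= as_of
        and (rx.end_at is None or as_of < rx.end_at)
    ]


def _latest_lab(store, pid, analyte, as_of, window_days):
    lo = as_of - timedelta(days=window_days)
    best = None
    best_idx = -1
    for idx, lab in enumerate(store.labs):
        if lab.patient_id != pid or lab.analyte != analyte:
            continue
        if not (lo < lab.published_at <= as_of):
            continue
        if (
            best is None
            or lab.published_at > best.published_at
            or (lab.published_at == best.published_at and idx < best_idx)
        ):
            best, best_idx = lab, idx
    return best


def _predicate_holds(pred, value):
    if pred.comparator == Comparator.le:
        return value <= pred.threshold
    if pred.comparator == Comparator.ge:
        return value >= pred.threshold
    if pred.comparator == Comparator.lt:
        return value < pred.threshold
    if pred.comparator == Comparator.gt:
        return value > pred.threshold
    return value <= pred.low or value >= pred.high


def _clcg(store, patient, as_of, window_days):
    """Inline Cockcroft-Gault on min(measured, Devine ideal) weight."""
    if patient.age < 18:
        return None
    crea = _latest_lab(store, patient.patient_id, "creatinine", as_of, window_days)
    if crea is None or crea.value <= 0:
        return None
    ibw = None
    if patient.height_cm is not None:
        base = 50.0 if patient.sex == "male" else 45.5
        ibw = max(base + 0.9 * (patient.height_cm - 152.0), 0.0)
    weights = [w for w in (patient.weight_measured_kg, ibw) if w is not None]
    if not weights:
        return None
    k = 1.23 if patient.sex == "male" else 1.04
    return max((140.0 - patient.age) * min(weights) * k / crea.value, 0.0)


def _fires_drug_lab(trig, store, patient, as_of):
    rx_active = _active(store, patient.patient_id, as_of)
    for branch in trig.branches:
        matched = [rx for rx in rx_active if _matches(rx, branch.drug_set)]
        if trig.exclude_prn:
            matched = [rx for rx in matched if not rx.is_prn]
        if not matched:
            continue
        if trig.renal_mode == RenalMode.clcg_selected_weight:
            clcg = _clcg(store, patient, as_of, trig.window_days)
            if clcg is not None and _predicate_holds(branch.predicate, clcg):
                return True
        else:
            lab = _latest_lab(
                store, patient.patient_id, branch.predicate.analyte,
                as_of, trig.window_days,
            )
            if lab is not None and _predicate_holds(branch.predicate, lab.value):
                return True
    return False


def _fires_drug_problem(trig, store, patient, as_of):
    rx_active = _active(store, patient.patient_id, as_of)
    if not any(_matches(rx, trig.drug_set) for rx in rx_active):
        return False
    for note in store.notes:
        if note.patient_id != patient.patient_id or note.written_at > as_of:
            continue
        if note.note_kind != trig.note_kind:
            continue
        text = _fold(note.text)
        if any(_fold(kw) in text for kw in trig.keywords):
            return True
    return False


def _fires_drug_combo(trig, store, patient, as_of):
    rx_active = _active(store, patient.patient_id, as_of)
    classified = []
    for rx in rx_active:
        for cls_name, ds in trig.class_sets.items():
            if _matches(rx, ds):
                classified.append((cls_name, rx))
                break
    excluded = {frozenset(p) for p in trig.excluded_pairs}
    if len(classified) < trig.min_distinct:
        return False
    for (c1, r1), (c2, r2) in combinations(classified, 2):
        if r1.atc_code == r2.atc_code:
            continue
        if frozenset((c1, c2)) in excluded:
            continue
        return True
    return False


def _fires_admin_mode(trig, store, patient, as_of):
    if trig.mode == AdminMode.dose_interval:
        events = [
            e for e in store.administrations
            if e.patient_id == patient.patient_id
            and any(e.atc_code.startswith(p) for p in trig.drug_set.atc_prefixes)
        ]
        for e1, e2 in combinations(events, 2):
            gap = abs((e2.scheduled_at - e1.scheduled_at).total_seconds()) / 86400.0
            if 0 < gap <= (trig.max_gap_days or 7.0):
                return True
        return False
    for rx in _active(store, patient.patient_id, as_of):
        if not _matches(rx, trig.drug_set):
            continue
        if rx.route not in (Route.iv_intermittent, Route.iv_continuous):
            continue
        if trig.mode == AdminMode.rate_threshold:
            if rx.rate_mmol_per_h is not None and \
                    rx.rate_mmol_per_h > trig.rate_limit_mmol_per_h:
                return True
        else:
            limit = (
                trig.conc_limit_intermittent_mmol_per_ml
                if rx.route == Route.iv_intermittent
                else trig.conc_limit_continuous_mmol_per_ml
            )
            if rx.concentration_mmol_per_ml is not None and limit is not None \
                    and rx.concentration_mmol_per_ml > limit:
                return True
    return False


def brute_alert_set(rulebook, store, as_of):
    """All (patient_id, rule_id) pairs firing, by exhaustive nested scan."""
    out = set()
    for rule in rulebook.rules:
        if not rule.enabled:
            continue
        trig = rule.trigger
        for patient in store.patients.values():
            if isinstance(trig, DrugLabTrigger):
                fires = _fires_drug_lab(trig, store, patient, as_of)
            elif isinstance(trig, DrugProblemTrigger):
                fires = _fires_drug_problem(trig, store, patient, as_of)
            elif isinstance(trig, DrugComboTrigger):
                fires = _fires_drug_combo(trig, store, patient, as_of)
            elif isinstance(trig, AdminModeTrigger):
                fires = _fires_admin_mode(trig, store, patient, as_of)
            else:  # pragma: no cover
                raise TypeError(type(trig))
            if fires:
                out.add((patient.patient_id, rule.rule_id))
    return out
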