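from datetime import datetime, timedelta

import pytest

from pharmacheck.ehr_model import Route, Sex
from pharmacheck.rule_engine import (
    AdministrationEvent,
    DrugComboTrigger,
    DrugLabTrigger,
    DrugProblemTrigger,
    DrugSet,
    RiskCategory,
    RiskSubcategory,
    build_default_rulebook,
    eval_combo,
    eval_kcl,
    eval_mtx_interval,
    eval_problem_keywords,
    evaluate_all,
    evaluate_rule,
    match_drug_set,
)

from conftest import AS_OF, StoreBuilder


def fires(rulebook, rule_id, builder):
    rule = rulebook.rule(rule_id)
    return len(evaluate_rule(rule, builder.store, builder.as_of)) == 1


class TestDefaultRulebook:
    def test_twenty_rules_with_expected_category_split(self, rulebook):
        assert len(rulebook.rules) == 20
        by_cat = {}
        for r in rulebook.rules:
            by_cat.setdefault(r.risk_category, []).append(r)
        assert len(by_cat[RiskCategory.abnormal_lab]) == 12
        assert len(by_cat[RiskCategory.contraindicated_in_context]) == 3
        assert len(by_cat[RiskCategory.drug_drug_interaction]) == 2
        assert len(by_cat[RiskCategory.inadequate_administration]) == 3
        subs = [r.risk_subcategory for r in by_cat[RiskCategory.abnormal_lab]]
        assert subs.count(RiskSubcategory.renal_failure) == 4
        assert subs.count(RiskSubcategory.supratherapeutic_level) == 4
        assert subs.count(RiskSubcategory.abnormal_lab_value) == 4

    def test_doac_rule_covers_apixaban_atc(self, rulebook):
        ds = rulebook.rule("doac_renal_failure").trigger.branches[0].drug_set
        assert "B01AF02" in ds.atc_prefixes
        assert "apixaban" in ds.substances

    def test_duplication_rule_excludes_vka_heparin_pairs(self, rulebook):
        trig = rulebook.rule("anticoagulant_duplication").trigger
        excluded = {frozenset(p) for p in trig.excluded_pairs}
        assert frozenset(("VKA", "LMWH")) in excluded
        assert frozenset(("VKA", "UFH")) in excluded
        # edoxaban is in the renal DOAC set but not the duplication set
        assert "edoxaban" not in trig.class_sets["DOAC"].substances

    def test_yaml_round_trip_preserves_semantics(self, rulebook, tmp_path):
        path = tmp_path / "rules.yaml"
        rulebook.to_yaml(path)
        reloaded = type(rulebook).from_yaml(path)
        assert reloaded.model_dump() == rulebook.model_dump()


class TestMatchDrugSet:
    def test_atc_prefix_class_match(self, builder):
        builder.patient().rx("M01AB05", "diclofenac")
        active = builder.store.prescriptions
        assert match_drug_set(active, DrugSet(atc_prefixes=["M01A"])) == active

    def test_label_match_is_case_and_diacritic_insensitive(self, builder):
        builder.patient().rx("A10BA02", "Metformine".replace("e", "é", 1))
        ds = DrugSet(substances=["métformine"])
        assert len(match_drug_set(builder.store.prescriptions, ds)) == 1

    def test_no_match_on_unlisted_drug(self, builder):
        builder.patient().rx("N02BE01", "paracetamol")
        assert match_drug_set(builder.store.prescriptions, DrugSet(atc_prefixes=["M01A"])) == []


class TestProblemKeywords:
    def test_accented_and_uppercase_notes_match(self, builder):
        builder.patient().note("Connu pour ÉPILEPSIE ancienne.")
        hit = eval_problem_keywords(builder.store.notes, ["épilepsie"])
        assert hit is not None and hit["keyword"] == "épilepsie"

    def test_empty_note_no_match(self, builder):
        builder.patient().note("")
        assert eval_problem_keywords(builder.store.notes, ["épilepsie"]) is None

    def test_no_negation_detection(self, builder):
        # documented limitation: negated mentions still match
        builder.patient().note("pas d'épilepsie connue")
        assert eval_problem_keywords(builder.store.notes, ["épilepsie"]) is not None


class TestCombos:
    def test_two_doacs_offend(self, builder, rulebook):
        builder.patient().rx("B01AF02", "apixaban").rx("B01AF01", "rivaroxaban")
        assert fires(rulebook, "anticoagulant_duplication", builder)

    def test_vka_plus_lmwh_excluded(self, builder, rulebook):
        builder.patient().rx("B01AA07", "acenocoumarol").rx("B01AB05", "enoxaparin",
                                                            route=Route.sc)
        assert not fires(rulebook, "anticoagulant_duplication", builder)

    def test_vka_plus_doac_offends(self, builder, rulebook):
        builder.patient().rx("B01AA03", "warfarin").rx("B01AF02", "apixaban")
        assert fires(rulebook, "anticoagulant_duplication", builder)

    def test_single_serotonergic_below_min(self, builder, rulebook):
        builder.patient().rx("N06AB06", "sertraline")
        assert not fires(rulebook, "serotonergic_duplication", builder)

    def test_same_substance_twice_is_not_duplication(self):
        b = StoreBuilder().patient()
        b.rx("B01AF02", "apixaban").rx("B01AF02", "apixaban")
        trig_sets = {"DOAC": DrugSet(atc_prefixes=["B01AF02"])}
        assert eval_combo(b.store.prescriptions, trig_sets, [], 2) == []


class TestMtxInterval:
    def _events(self, *day_offsets):
        return [
            AdministrationEvent(
                patient_id="P1", atc_code="L04AX03",
                scheduled_at=AS_OF + timedelta(days=d),
            )
            for d in day_offsets
        ]

    def test_seven_day_gap_inclusive(self):
        assert len(eval_mtx_interval(self._events(0, 7))) == 1

    def test_eight_day_gap_not_offending(self):
        assert eval_mtx_interval(self._events(0, 8)) == []

    def test_single_dose_no_pair(self):
        assert eval_mtx_interval(self._events(0)) == []


class TestKcl:
    def _kcl(self, route, rate=None, conc=None):
        b = StoreBuilder().patient()
        b.rx("B05XA01", "potassium chloride", route=route, rate=rate, conc=conc)
        return b.store.prescriptions[0]

    def test_rate_limit_is_strict(self):
        assert eval_kcl(self._kcl(Route.iv_continuous, rate=10.0), rate_limit=10.0) is None
        v = eval_kcl(self._kcl(Route.iv_continuous, rate=10.1), rate_limit=10.0)
        assert v["violation"] == "rate"

    def test_intermittent_concentration_limit(self):
        v = eval_kcl(self._kcl(Route.iv_intermittent, conc=0.09),
                     conc_limit_intermittent=0.08, conc_limit_continuous=1.0)
        assert v["violation"] == "concentration"
        assert eval_kcl(self._kcl(Route.iv_intermittent, conc=0.08),
                        conc_limit_intermittent=0.08, conc_limit_continuous=1.0) is None

    def test_oral_route_abstains(self):
        assert eval_kcl(self._kcl(Route.oral), rate_limit=10.0) is None


class TestRenalRuleEvaluation:
    def _renal_builder(self, crea, drug=("B01AF02", "apixaban")):
        # age 90, weight 50, male -> ClCG = 3075 / creatinine exactly
        b = StoreBuilder().patient(age=90, weight=50.0, sex=Sex.male)
        b.rx(*drug)
        b.lab("creatinine", crea)
        return b

    def test_trigger_uses_clcg_not_stored_egfr(self, rulebook):
        # stored eGFR is high but ClCG is 24.6: the rule must still fire
        b = self._renal_builder(125.0)
        b.lab("egfr_ckdepi", 85.0)
        assert fires(rulebook, "doac_renal_failure", b)

    def test_inclusive_threshold_at_exactly_30(self, rulebook):
        assert fires(rulebook, "doac_renal_failure", self._renal_builder(102.5))  # 30.0
        assert not fires(rulebook, "doac_renal_failure", self._renal_builder(102.0))  # 30.15

    def test_missing_weight_abstains(self, rulebook):
        b = StoreBuilder().patient(age=90, weight=None, height=None)
        b.rx("B01AF02", "apixaban")
        b.lab("creatinine", 300.0)
        assert not fires(rulebook, "doac_renal_failure", b)

    def test_missing_creatinine_abstains(self, rulebook):
        b = StoreBuilder().patient(age=90, weight=50.0)
        b.rx("B01AF02", "apixaban")
        assert not fires(rulebook, "doac_renal_failure", b)

    def test_ideal_weight_selected_when_lower(self, rulebook):
        # obese patient: measured 120 kg, height 162 cm -> IBW 59 kg selected
        # ClCG = (140-90)*59*1.23/121 = 29.99 -> fires only via IBW
        b = StoreBuilder().patient(age=90, weight=120.0, height=162.0, sex=Sex.male)
        b.rx("B01AF02", "apixaban")
        b.lab("creatinine", 121.0)
        cands = evaluate_rule(rulebook.rule("doac_renal_failure"), b.store, b.as_of)
        assert len(cands) == 1
        assert cands[0].context["weight_selected_kg"] == pytest.approx(59.0)

    def test_candidate_context_carries_renal_values(self, rulebook):
        b = self._renal_builder(125.0)
        b.lab("egfr_ckdepi", 50.0, days_ago=2.0)
        b.lab("egfr_ckdepi", 57.0, days_ago=1.0)
        cand = evaluate_rule(rulebook.rule("doac_renal_failure"), b.store, b.as_of)[0]
        assert cand.context["delta_egfr_pct"] == pytest.approx(14.0)
        assert cand.snapshot["evidence"][0]["clcg_ml_min"] == pytest.approx(3075 / 125.0)


class TestLabRuleBoundaries:
    """Comparator inclusivity at threshold for every lab-triggered rule."""

    @pytest.mark.parametrize(
        "rule_id,drug,analyte,at_threshold,outside",
        [
            ("vka_supratherapeutic_inr", ("B01AA03", "warfarin"), "inr", 4.0, 3.99),
            ("vancomycin_supratherapeutic_level", ("J01XA01", "vancomycin"),
             "vancomycin_level", 25.0, 24.9),
            ("digoxin_supratherapeutic_level", ("C01AA05", "digoxin"),
             "digoxin_level", 3.0, 2.99),
            ("aminoglycoside_supratherapeutic_level", ("J01GB03", "gentamicin"),
             "gentamicin_level", 1.0, 0.99),
            ("aminoglycoside_supratherapeutic_level", ("J01GB01", "tobramycin"),
             "tobramycin_level", 1.0, 0.99),
            ("aminoglycoside_supratherapeutic_level", ("J01GB06", "amikacin"),
             "amikacin_level", 5.0, 4.99),
            ("glucose_lowering_hypoglycemia", ("A10AB05", "insulin aspart"),
             "glucose", 4.0, 4.01),
            ("heparin_thrombopenia", ("B01AB05", "enoxaparin"), "platelets", 50.0, 50.5),
            ("digoxin_dyskalemia", ("C01AA05", "digoxin"), "potassium", 3.5, 3.6),
            ("digoxin_dyskalemia", ("C01AA05", "digoxin"), "potassium", 5.5, 5.4),
            ("metformin_hyperlactatemia", ("A10BA02", "metformin"), "lactate", 5.0, 4.9),
        ],
    )
    def test_threshold_inclusive_and_epsilon_outside(
        self, rulebook, rule_id, drug, analyte, at_threshold, outside
    ):
        hit = StoreBuilder().patient().rx(*drug)
        hit.lab(analyte, at_threshold)
        assert fires(rulebook, rule_id, hit)
        miss = StoreBuilder().patient().rx(*drug)
        miss.lab(analyte, outside)
        assert not fires(rulebook, rule_id, miss)

    def test_prn_glucose_lowering_excluded(self, rulebook):
        b = StoreBuilder().patient()
        b.rx("A10AB05", "insulin aspart", is_prn=True)
        b.lab("glucose", 3.0)
        assert not fires(rulebook, "glucose_lowering_hypoglycemia", b)

    def test_trigger_uses_latest_value_only(self, rulebook):
        # older supra-therapeutic INR followed by a normal one: no alert
        b = StoreBuilder().patient().rx("B01AA03", "warfarin")
        b.lab("inr", 5.0, days_ago=3.0)
        b.lab("inr", 2.5, days_ago=1.0)
        assert not fires(rulebook, "vka_supratherapeutic_inr", b)

    def test_lab_outside_30_day_window_ignored(self, rulebook):
        b = StoreBuilder().patient().rx("B01AA03", "warfarin")
        b.lab("inr", 6.0, days_ago=31.0)
        assert not fires(rulebook, "vka_supratherapeutic_inr", b)


class TestEvaluateAll:
    def test_empty_store_yields_nothing(self, rulebook, builder):
        assert evaluate_all(rulebook, builder.store, builder.as_of) == []

    def test_disabled_rule_yields_nothing(self, rulebook, builder):
        builder.patient().rx("B01AA03", "warfarin").lab("inr", 5.0)
        rule = rulebook.rule("vka_supratherapeutic_inr").model_copy(
            update={"enabled": False}
        )
        assert evaluate_rule(rule, builder.store, builder.as_of) == []

    def test_idempotent_and_ordered(self, rulebook):
        b = StoreBuilder().patient("P2").patient("P1")
        for pid in ("P1", "P2"):
            b.rx("B01AA03", "warfarin", pid=pid)
            b.lab("inr", 5.0, pid=pid)
        first = evaluate_all(rulebook, b.store, b.as_of)
        second = evaluate_all(rulebook, b.store, b.as_of)
        assert first == second
        assert [c.patient_id for c in first] == ["P1", "P2"]
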