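"""Alert deduplication and intervention tracking across screening runs.

Screening runs twice a day; a situation that persists must be counted once.
When the pharmacist intervenes and the prescriber changes the order within
24 h, the outcome counts as accepted.
"""

from datetime import timedelta

from pharmacheck import AlertLedger, Outcome, build_default_rulebook, evaluate_all, GeneratorConfig, generate_cohort
from pharmacheck.synthetic_ehr import DEFAULT_AS_OF

store, _ = generate_cohort(GeneratorConfig(n_patients=40, seed=7))
rulebook = build_default_rulebook()
ledger = AlertLedger()

morning = DEFAULT_AS_OF
afternoon = DEFAULT_AS_OF + timedelta(hours=6)

new1, _ = ledger.reconcile(evaluate_all(rulebook, store, morning), morning)
new2, refreshed = ledger.reconcile(evaluate_all(rulebook, store, afternoon), afternoon)
print(f"morning run   : {len(new1)} new alerts")
print(f"afternoon run : {len(new2)} new alerts, {len(refreshed)} refreshed (counted once)")

alert = new1[0]
ledger.record_intervention(alert.alert_id, True, morning + timedelta(hours=2),
                           channel="phone", suggestion="reduce dose / switch drug")
ledger.record_outcome(alert.alert_id, Outcome.accepted, morning + timedelta(hours=8))
record = ledger.interventions[alert.alert_id]
print(f"alert {alert.alert_id} ({alert.rule_id}): outcome = {record.outcome.value}")

replayed = AlertLedger.replay(ledger.events)
print(f"ledger replay reproduces state : {len(replayed.alerts) == len(ledger.alerts)}")
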