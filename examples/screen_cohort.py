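"""Generate a synthetic ward and screen it with all twenty rules.

The cohort has one injected high-risk situation per rule plus near-miss
and clean controls; screening must find exactly the injected situations
(sensitivity 1.0, no false positives against the known ground truth).
"""

from pharmacheck import GeneratorConfig, build_default_rulebook, evaluate_all, generate_cohort
from pharmacheck.synthetic_ehr import DEFAULT_AS_OF

store, truth = generate_cohort(GeneratorConfig(n_patients=40, seed=7))
rulebook = build_default_rulebook()
candidates = evaluate_all(rulebook, store, DEFAULT_AS_OF)

print(f"patients screened : {len(store.patients)}")
print(f"alert candidates  : {len(candidates)}")
for cand in candidates[:5]:
    print(f"  {cand.patient_id}  {cand.rule_id}  drugs={'/'.join(cand.trigger_atcs)}")
print("  ...")

expected = truth.expected_alerts()
found = {(c.patient_id, c.rule_id) for c in candidates}
print(f"injected situations recovered : {len(found & expected)}/{len(expected)}")
print(f"false positives               : {len(found - expected)}")
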