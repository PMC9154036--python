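"""PPV rollup over the published-distribution ledger fixture.

Builds the synthetic ledger whose per-rule counts match the study period
(447 alerts, 90 interventions, 63 accepted changes over 132 days) and
prints the three PPVs at every scope, plus throughput statistics.
"""

from pharmacheck import build_default_rulebook, build_report, make_table3_ledger, table3_census, throughput
from pharmacheck.evaluation import format_report_text, report_row

rulebook = build_default_rulebook()
ledger = make_table3_ledger(rulebook)
rows = build_report(ledger, rulebook)

total = report_row(rows, "total", "total")
print(f"alerts={total.n_alerts}  interventions={total.n_interventions}  "
      f"accepted={total.n_accepted}")
print(f"intervention PPV        : {total.intervention_ppv}%")
print(f"clinical PPV (with)     : {total.clinical_ppv_with}%")
print(f"clinical PPV (without)  : {total.clinical_ppv_without}%")

stats = throughput(ledger, table3_census())
print(f"mean new alerts/day     : {stats.mean_new_alerts_per_day}")
print(f"patients alerting       : {stats.n_alerting_patients} "
      f"({stats.pct_patients_alerting}% of {stats.n_patients_screened})")
print()
print(format_report_text([r for r in rows if r.scope in ("category", "total")]))
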