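# pharmacheck

Rule-based screening of electronic-health-record snapshots for high-risk
medication situations, built for clinical pharmacists rather than
prescribers. The package implements a twenty-rule screening engine over a
document-store EHR model, deduplicates alerts across repeated screening
runs, tracks pharmacist interventions and prescriber outcomes, and computes
the positive-predictive-value metrics used to evaluate such a system.

## The problem

Hospital CDSS alerts shown to physicians at order entry suffer from alert
fatigue: override rates of 60–90 % are typical. An alternative model routes
alerts to clinical pharmacists, who filter out futile alerts and telephone
the prescriber only for the relevant ones. Evaluating that model needs
three quantities, per rule and overall:

```
intervention PPV          = n interventions         / n alerts
clinical PPV (with)       = n accepted changes      / n interventions
clinical PPV (without)    = n accepted changes      / n alerts
```

where an intervention is *accepted* only if it changed patient management
within 24 h. Pre-rounding, the three satisfy
`intervention_PPV × clinical_PPV_with / 100 = clinical_PPV_without`.

## What is inside

- **`ehr_model`** — pydantic document types (patients, prescriptions with
  WHO ATC codes, timestamped lab results, French free-text admission notes,
  nursing administration events), a line-delimited on-disk store format,
  and the staged query primitives rules run on: CHECKED-status activity over
  the half-open interval `[start_at, end_at)`, lab recency over the
  half-open window `(as_of − 30 d, as_of]`, last-two-value projection.
- **`clinical_calculators`** — Cockcroft–Gault clearance in SI form
  `ClCG = (140 − age) · weight · k / Scr[µmol/L]` (k = 1.23 male / 1.04
  female) on the *dosing weight* `min(measured, Devine ideal)`; CKD-EPI 2009
  eGFR (race-free); delta-eGFR percent progression; unit harmonisation.
- **`rule_engine`** — twenty declarative clinical rules in four risk
  categories (abnormal lab value — including four renal-failure rules
  triggered on computed ClCG, four supra-therapeutic drug levels and four
  abnormal-lab rules; contraindicated in context via diacritic-folded
  French keyword search; two therapeutic-duplication rules; three
  inadequate-administration rules for methotrexate scheduling and IV
  potassium chloride rate/concentration). Thresholds keep their printed
  inclusivity: `≤ / ≥` inclusive, `>` strict.
- **`alert_manager`** — dedup by `(patient, rule, trigger-drug ATC set)`
  across runs, alert lifecycle (new → under review → handled/resolved),
  append-only replayable ledger, intervention/outcome records with the 24 h
  acceptance window.
- **`evaluation`** — the three PPVs with half-up 0.1 % rounding and NA for
  zero denominators, the per-rule/sub-category/category rollup report, and
  daily throughput statistics.
- **`synthetic_ehr`** — a seeded cohort generator (ages median 74,
  IQR 61–82; ~13 drugs per patient; French notes) that injects per-rule
  trigger situations and near-miss controls sitting just outside one
  threshold, with machine-readable ground truth; plus a ledger fixture
  reproducing the published alert/intervention distribution.

## Worked example

```bash
python examples/screen_cohort.py
```

```
patients screened : 40
alert candidates  : 20
  P0001  vka_supratherapeutic_inr  drugs=B01AA03
  P0002  doac_renal_failure  drugs=B01AF02
  ...
injected situations recovered : 20/20
false positives               : 0
```

Forty synthetic inpatients contain exactly one injected situation per rule;
screening recovers all twenty and nothing else (the near-miss controls,
e.g. ClCG 31 mL/min or platelets 51 G/L, stay silent). The other examples
show the renal work-up (`renal_function.py` — a 92 kg patient whose ideal
body weight of 66.2 kg pulls the ClCG down to 28.7 mL/min and fires the
DOAC rule), alert deduplication across two runs of the same day
(`alert_lifecycle.py` — 20 new alerts in the morning, 0 new / 20 refreshed
in the afternoon), and the full PPV rollup (`performance_report.py` — 447
alerts, 90 interventions, 63 accepted: intervention PPV 20.1 %, clinical
PPV with pharmacist 70.0 %, without 14.1 %).

A thin CLI wraps the same library calls:

```bash
pharmacheck simulate --n 40 --seed 7 --out store/
pharmacheck screen --store store/ --ledger ledger.jsonl --as-of 2020-03-16T08:00
pharmacheck track intervene --ledger ledger.jsonl --alert-id A000001 --at 2020-03-16T10:00
pharmacheck track outcome --ledger ledger.jsonl --alert-id A000001 --outcome accepted --at 2020-03-16T15:00
pharmacheck report --ledger ledger.jsonl
```

## Limitations

Free-text problem matching is a plain diacritic-folded substring search
with no negation detection; the synthetic cohort emulates trigger
conditions, not realistic pharmacology. See `docs/methods.md` for the full
account of the model, parameters and design choices.
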