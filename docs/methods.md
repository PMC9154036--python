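# Methods

## Screening model

The engine is a rules-based system over a point-in-time EHR snapshot
organised as five document collections (patients, prescriptions, labs,
notes, administration events), mirroring a document-store warehouse queried
by staged aggregation: filter prescriptions, look up recent labs for the
matched patients, project the alert table. Evaluation is *modus ponens*
over declarative IF–THEN rules: each rule is data (drug sets, lab
predicate, keywords, administration limits), and the evaluator is generic
per trigger family. The test suite exploits this by re-deriving every
rule's firing set with an independent brute-force cross-product scan and
asserting equality on randomized cohorts.

### Time semantics

All timestamps are timezone-naive ISO-8601 at minute resolution (the
models truncate finer precision so disk round-trips are lossless).
Prescription activity is the half-open interval `start_at ≤ t < end_at`
with CHECKED (signed, active) the only status that can trigger; DRAFT and
STOPPED orders are invisible to rules. Lab recency is the half-open window
`as_of − w < published_at ≤ as_of` with a default `w` of 30 days for every
lab-triggered rule (per-rule override available in the rule config). A
result published exactly `w` days ago is out of window; a prescription
ending exactly at the screening instant is inactive. Stopped-then-restarted
orders are distinct documents and form distinct alerts.

### Drug matching

Rule drug sets hold WHO ATC prefixes (a class entry such as `M01A` matches
`M01AB05`) and/or normalized substance names compared case- and
diacritic-insensitively against prescription labels. The long
anticholinergic / seizure-threshold / serotonergic lists ship as editable
data in the rulebook (exportable to YAML); class phrases in those lists are
encoded as the corresponding ATC prefixes (e.g. aminoalkyl-ether
antihistamines → `R06AA`, drugs for urinary frequency and incontinence →
`G04BD`). The P-gp/CYP3A4 inducer/inhibitor context list is intentionally
empty and user-fillable.

### Renal triggers

The four renal rules (DOAC, colchicine, metformin at ClCG ≤ 30 mL/min;
morphine at ≤ 15 mL/min) trigger on the Cockcroft–Gault clearance computed
at screening time, never on the stored eGFR. The weight entering the
formula is the *dosing weight*: the lower of measured weight and Devine
ideal body weight (50 kg male / 45.5 kg female + 0.9 kg per cm above
152 cm, floored at 0; configurable). Cockcroft–Gault is evaluated once in
SI units, `(140 − age) · weight · k / Scr[µmol/L]` with k = 1.23 / 1.04 —
algebraically identical to the mg/dL "/72" form but avoiding a double unit
conversion. CKD-EPI 2009 (two-arm spline, sex-specific κ and α, 0.993^age,
1.018 female factor, no race coefficient) and the signed percent change
between the last two eGFR values are computed as decision context.

Missing data makes renal rules *abstain*: no in-window creatinine, no
usable weight, or age < 18 (adult internal-medicine scope) skips the
patient rather than alerting on missing information. The same
abstain-not-alert policy applies to every lab rule with no in-window
result. Only the latest in-window value can trigger; older values are
context.

### Combination and administration rules

Therapeutic-duplication rules pair concurrently active prescriptions from
named class sets. The anticoagulant rule excludes the deliberate
(VKA, LMWH) and (VKA, UFH) bridging combinations; edoxaban belongs to the
renal DOAC set but not to the duplication set (fidelity to the source rule
table over symmetry). Two orders of the same substance (identical ATC
code) are treated as a refill, not duplication — a design choice; the
duplication risk the rule encodes is two *different* anticoagulants or
serotonergics. Methotrexate scheduling alerts on any pair of nursing-
scheduled doses with a gap in `(0, 7]` days (inclusive). IV potassium
chloride limits are strict: rate > 10 mmol/h; concentration > 0.08 mmol/mL
(intermittent) or > 1.00 mmol/mL (continuous). An alternative
catheter-based concentration variant (40/80 mmol/L by peripheral/central
line) exists in the literature of such rules; the route-based thresholds
are the shipped default and the variant is left to user configuration.

### Keyword search

Problem rules match French keywords in admission notes by diacritic-folded
substring search. There is deliberately **no negation detection** —
"pas d'épilepsie" matches "épilepsie" — reproducing the low specificity of
free-text problem screening; the keyword lists are editable config
(translations of the English comorbidity terms, e.g. démence, rétention
urinaire, insuffisance cardiaque).

## Alert lifecycle

An alert's identity is `(patient, rule, sorted trigger-drug ATC set)`.
Re-screening an unchanged situation refreshes `last_seen_at` and never
creates a second alert (dedup monotonicity); a new offending drug enlarges
the ATC set and therefore re-alerts. When a key stops firing the alert
resolves; a later recurrence is a fresh alert. Resolution-on-clear is a
design choice: the source workflow only states that repeated alerts are
counted once, not when an alert ends.

Interventions record whether the pharmacist contacted the prescriber
(phone or ward round) or ruled the alert futile. An outcome of `accepted`
recorded more than 24 h after the intervention is stored as
`accepted_late` and excluded from acceptance counts — the 24 h window is
measured from the intervention, the 24–72 h chart re-check being an
observation schedule, not the window. Declined outcomes use a fixed
three-reason taxonomy (benefit–risk judged positive, unknown, patient
discharged). The ledger is an append-only event log; state is a pure fold
over events, and replay determinism is tested.

## Evaluation

Report counts derive solely from the ledger: alerts count once regardless
of refreshes; `n_interventions` counts records with `intervened=True`;
`n_accepted` counts `accepted` outcomes only. Percentages are rounded
half-up to 0.1 at display; zero denominators render NA rather than 0 %.
Rollups (rule → sub-category → category → total) are sums of the same
counters, so conservation is exact by construction and asserted in tests.
Throughput reports the mean/SD of new alerts per screening-calendar day
and the share of screened patients with ≥ 1 alert.

## Synthetic cohorts

The generator's defaults emulate the study conditions rather than being
free dials: ages sampled through a piecewise-linear quantile curve anchored
at (min 18, Q1 61, median 74, Q3 82, max 97); drugs per patient anchored at
(1, 10, 13, 17, 40) from a curated 37-item background formulary whose ATC
codes and labels are disjoint from every rule drug set, so background
patients cannot alert; length of stay anchored at (0.5, 4, 10.5, 13.5, 84)
days with patients sampled mid-stay. Default cohort size is 60 patients
with one injection per rule; screening time is fixed at 2020-03-16 08:00.

Injected patients satisfy exactly one rule's trigger (e.g. the renal
template is an 80-year-old 50 kg man whose creatinine of 150 µmol/L gives
ClCG 24.6 mL/min); near-miss controls violate exactly one condition
minimally (ClCG ≈ 31, INR 3.9, platelets 51 G/L, potassium 5.4, an 8-day
methotrexate gap, a KCl rate of exactly 10.0 mmol/h, the excluded VKA+LMWH
pair, a seizure drug without the épilepsie note). Trigger labs are always
published within the last two days so they dominate the earlier
normal-range background series. Everything is driven by one
`numpy.random.default_rng(seed)`; identical seeds yield byte-identical
on-disk stores.

What the generator does **not** emulate: dose–response, pharmacokinetics,
correlated comorbidity structure, free-text variety beyond a few note
templates, or clerical noise. Passing tests therefore demonstrate the
engine's logical correctness at and around every threshold, not its yield
on real hospital data.

The published-distribution ledger fixture (`make_table3_ledger`) encodes
the reported per-rule alert/intervention/acceptance counts (447/90/63 in
total), spreads alerts round-robin over the 132-day screening calendar and
over 383 distinct patients (64 of whom alert twice under different rules),
and folds them through the normal reconcile/intervene/outcome pathway.
The reported clinical PPV with pharmacist is computed as 63/90 = 70.0 %;
the report never substitutes externally printed values for computed ones.

## Numerical choices and problem sizes

Boundary tests use creatinine values chosen so the ClCG quotient is exactly
representable in binary floating point (e.g. 3075/102.5 = 30.0), making
inclusive-threshold assertions exact rather than tolerance-based.
Rounding uses decimal half-up, matching the display convention of such
reports. Property suites run 50 seeded cohorts of 40 patients (one
injection per rule plus ~25 % near-miss controls) for oracle equivalence
and ground-truth recovery; the acceptance script uses 10 cohorts of 40
patients. These sizes give every rule path multiple randomized exercises
while keeping the whole suite under half a minute.

## Known limitations

- Keyword matching has no negation or section awareness.
- Prescription activity for drug-level rules is assessed at screening time
  only, not at the lab's publication time; a drug stopped between sampling
  and screening does not alert.
- The inducer/inhibitor context list ships empty.
- No severity grading, pediatric equations, dialysis adjustment, or
  external interaction knowledge base.
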