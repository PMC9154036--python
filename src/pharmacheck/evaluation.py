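"""Screening-performance metrics: the three PPVs and the rollup report.

Three positive predictive values characterise the alert stream::

    intervention PPV        = interventions / alerts
    clinical PPV (with)     = accepted changes / interventions
    clinical PPV (without)  = accepted changes / alerts

The "with pharmacist" PPV measures acceptance after a pharmacist has
filtered futile alerts; the "without" value is the hypothetical acceptance
rate had every alert gone straight to prescribers.  Pre-rounding, the three
satisfy ``intervention_ppv × clinical_ppv_with / 100 = clinical_ppv_without``.

Percentages are rounded half-up to 0.1; a zero denominator renders as NA
(None), never 0%.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .alert_manager import AlertLedger, Outcome
from .rule_engine import RiskCategory, RiskSubcategory, RuleBook


def round_half_up(value: float, decimals: int = 1) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _ppv(numerator: int, denominator: int) -> Optional[float]:
    if numerator > denominator:
        raise ValueError("PPV numerator cannot exceed its denominator")
    if numerator < 0:
        raise ValueError("counts must be non-negative")
    if denominator == 0:
        return None  # rendered as NA
    return round_half_up(100.0 * numerator / denominator)


def intervention_ppv(n_interventions: int, n_alerts: int) -> Optional[float]:
    """Percent of fired alerts that led to a pharmacist intervention."""
    return _ppv(n_interventions, n_alerts)


def clinical_ppv_with(n_accepted: int, n_interventions: int) -> Optional[float]:
    """Percent of interventions accepted by the prescriber within 24 h."""
    return _ppv(n_accepted, n_interventions)


def clinical_ppv_without(n_accepted: int, n_alerts: int) -> Optional[float]:
    """Hypothetical acceptance percent had alerts gone straight to physicians."""
    return _ppv(n_accepted, n_alerts)


class PerformanceRow(BaseModel):
    scope: str  # rule | subcategory | category | total
    scope_id: str
    n_alerts: int
    n_interventions: int
    n_accepted: int
    intervention_ppv: Optional[float] = None
    clinical_ppv_with: Optional[float] = None
    clinical_ppv_without: Optional[float] = None

    @classmethod
    def from_counts(
        cls, scope: str, scope_id: str, alerts: int, interventions: int, accepted: int
    ) -> "PerformanceRow":
        if not (accepted <= interventions <= alerts):
            raise ValueError(
                f"{scope_id}: counts must satisfy accepted <= interventions <= alerts"
            )
        return cls(
            scope=scope,
            scope_id=scope_id,
            n_alerts=alerts,
            n_interventions=interventions,
            n_accepted=accepted,
            intervention_ppv=intervention_ppv(interventions, alerts),
            clinical_ppv_with=clinical_ppv_with(accepted, interventions),
            clinical_ppv_without=clinical_ppv_without(accepted, alerts),
        )


def build_report(ledger: AlertLedger, rulebook: RuleBook) -> list[PerformanceRow]:
    """Per-rule, per-sub-category, per-category and total performance rows.

    Counts are derived solely from the ledger: every alert counts once
    (deduplicated), an intervention is a record with ``intervened=True``,
    and only ``accepted`` outcomes (within the 24 h window) count as
    prescription changes.
    """
    known = {r.rule_id for r in rulebook.rules}
    counts: dict[str, list[int]] = {r.rule_id: [0, 0, 0] for r in rulebook.rules}
    for alert in ledger.alerts.values():
        if alert.rule_id not in known:
            raise ValueError(f"ledger alert {alert.alert_id} has orphan rule {alert.rule_id!r}")
        counts[alert.rule_id][0] += 1
        record = ledger.interventions.get(alert.alert_id)
        if record is not None and record.intervened:
            counts[alert.rule_id][1] += 1
            if record.outcome is Outcome.accepted:
                counts[alert.rule_id][2] += 1

    rows: list[PerformanceRow] = []
    cat_totals: dict[RiskCategory, list[int]] = {c: [0, 0, 0] for c in RiskCategory}
    sub_totals: dict[RiskSubcategory, list[int]] = {
        s: [0, 0, 0] for s in RiskSubcategory if s is not RiskSubcategory.none
    }
    total = [0, 0, 0]
    for rule in rulebook.rules:
        a, i, acc = counts[rule.rule_id]
        rows.append(PerformanceRow.from_counts("rule", rule.rule_id, a, i, acc))
        for bucket in (cat_totals[rule.risk_category], total):
            bucket[0] += a
            bucket[1] += i
            bucket[2] += acc
        if rule.risk_subcategory is not RiskSubcategory.none:
            sub = sub_totals[rule.risk_subcategory]
            sub[0] += a
            sub[1] += i
            sub[2] += acc
    for sub, (a, i, acc) in sub_totals.items():
        rows.append(PerformanceRow.from_counts("subcategory", sub.value, a, i, acc))
    for cat, (a, i, acc) in cat_totals.items():
        rows.append(PerformanceRow.from_counts("category", cat.value, a, i, acc))
    rows.append(PerformanceRow.from_counts("total", "total", *total))
    return rows


def report_row(rows: list[PerformanceRow], scope: str, scope_id: str) -> PerformanceRow:
    for row in rows:
        if row.scope == scope and row.scope_id == scope_id:
            return row
    raise KeyError((scope, scope_id))


def report_to_frame(rows: list[PerformanceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.model_dump() for r in rows])


def write_report_csv(rows: list[PerformanceRow], path) -> None:
    report_to_frame(rows).to_csv(path, index=False, na_rep="NA")


def format_report_text(rows: list[PerformanceRow]) -> str:
    """Aligned text table with NA for undefined percentages."""
    frame = report_to_frame(rows)
    for col in ("intervention_ppv", "clinical_ppv_with", "clinical_ppv_without"):
        frame[col] = frame[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.1f}%")
    return frame.to_string(index=False)


class ScreeningCensus(BaseModel):
    """The screening calendar and how many patients were covered."""

    days: list[date]
    n_patients_screened: int = Field(ge=0)


@dataclass
class ThroughputStats:
    n_days_screened: int
    n_patients_screened: int
    n_alerting_patients: int
    mean_new_alerts_per_day: float
    sd_new_alerts_per_day: Optional[float]
    pct_patients_alerting: float


def throughput(ledger: AlertLedger, census: ScreeningCensus) -> ThroughputStats:
    """Daily new-alert statistics and the share of screened patients alerting."""
    if not census.days:
        raise ValueError("census must cover at least one screening day")
    day_counts = {d: 0 for d in census.days}
    alerting_patients = set()
    for alert in ledger.alerts.values():
        alerting_patients.add(alert.patient_id)
        day = alert.first_fired_at.date()
        if day in day_counts:
            day_counts[day] += 1
    counts = np.array(list(day_counts.values()), dtype=float)
    mean = round_half_up(float(counts.mean()))
    sd = round_half_up(float(counts.std(ddof=1))) if len(counts) > 1 else None
    if census.n_patients_screened:
        pct = round_half_up(100.0 * len(alerting_patients) / census.n_patients_screened)
    else:
        pct = 0.0
    return ThroughputStats(
        n_days_screened=len(census.days),
        n_patients_screened=census.n_patients_screened,
        n_alerting_patients=len(alerting_patients),
        mean_new_alerts_per_day=mean,
        sd_new_alerts_per_day=sd,
        pct_patients_alerting=pct,
    )
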