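"""Alert lifecycle: deduplication across repeated screening runs, pharmacist
intervention tracking, and prescriber-outcome recording.

Screening runs twice per working day, so the same risk situation is seen
many times; an alert is identified by its dedup key
``(patient, rule, sorted trigger-drug ATC set)`` and a repeat firing only
refreshes ``last_seen_at``.  A *new* offending drug for the same rule forms
a new key and re-alerts.  When a key stops firing (lab back in range, order
stopped) the alert resolves; if the situation later recurs a fresh alert is
created.

An intervention is *accepted* only when the prescriber changed management
within 24 h; later changes are recorded as ``accepted_late`` and excluded
from acceptance counts.  The ledger is an append-only event log whose state
is a pure fold over its entries.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, Field

from .rule_engine import AlertCandidate

ACCEPTANCE_WINDOW_H = 24.0

DedupKey = tuple[str, str, tuple[str, ...]]


class AlertStatus(str, Enum):
    new = "new"
    under_review = "under_review"
    handled = "handled"  # assessed as futile, no intervention sent
    resolved = "resolved"


class Channel(str, Enum):
    phone = "phone"
    ward_round = "ward_round"


class Outcome(str, Enum):
    accepted = "accepted"
    accepted_late = "accepted_late"  # change after the 24 h window; not counted
    declined_benefit_risk = "declined_benefit_risk"
    declined_unknown = "declined_unknown"
    declined_discharged = "declined_discharged"
    pending = "pending"


class Alert(BaseModel):
    alert_id: str
    patient_id: str
    rule_id: str
    trigger_atcs: tuple[str, ...]
    first_fired_at: datetime
    last_seen_at: datetime
    status: AlertStatus = AlertStatus.new
    snapshot: dict = Field(default_factory=dict)
    context: dict = Field(default_factory=dict)

    @property
    def dedup_key(self) -> DedupKey:
        return (self.patient_id, self.rule_id, self.trigger_atcs)


class InterventionRecord(BaseModel):
    alert_id: str
    intervened: bool
    intervened_at: datetime
    channel: Optional[Channel] = None
    suggestion: str = ""
    outcome: Outcome = Outcome.pending
    outcome_at: Optional[datetime] = None


class LedgerError(Exception):
    pass


class AlertLedger:
    """Append-only alert/intervention event log with replayable state."""

    def __init__(self) -> None:
        self.alerts: dict[str, Alert] = {}
        self.interventions: dict[str, InterventionRecord] = {}
        self.events: list[dict] = []
        self._seq = 0

    # -- state helpers ----------------------------------------------------

    def _active_by_key(self) -> dict[DedupKey, Alert]:
        return {
            a.dedup_key: a
            for a in self.alerts.values()
            if a.status is not AlertStatus.resolved
        }

    def alert(self, alert_id: str) -> Alert:
        try:
            return self.alerts[alert_id]
        except KeyError:
            raise LedgerError(f"unknown alert {alert_id!r}") from None

    # -- screening reconciliation ----------------------------------------

    def reconcile(
        self, candidates: Iterable[AlertCandidate], run_at: datetime
    ) -> tuple[list[Alert], list[Alert]]:
        """Fold one screening run into the ledger.

        Returns ``(new_alerts, refreshed_alerts)``.  A candidate matching a
        non-resolved alert's dedup key refreshes it; otherwise a new alert
        is created.  Non-resolved alerts whose key stopped firing resolve.
        """
        candidates = list(candidates)
        active = self._active_by_key()
        new_alerts: list[Alert] = []
        refreshed: list[Alert] = []
        seen_keys: set[DedupKey] = set()
        for cand in candidates:
            key: DedupKey = (cand.patient_id, cand.rule_id, tuple(cand.trigger_atcs))
            seen_keys.add(key)
            if key in active:
                alert = active[key]
                alert.last_seen_at = run_at
                refreshed.append(alert)
                self._append(
                    {"event": "refresh", "alert_id": alert.alert_id,
                     "at": run_at.isoformat(timespec="minutes")}
                )
            else:
                self._seq += 1
                alert = Alert(
                    alert_id=f"A{self._seq:06d}",
                    patient_id=cand.patient_id,
                    rule_id=cand.rule_id,
                    trigger_atcs=tuple(cand.trigger_atcs),
                    first_fired_at=run_at,
                    last_seen_at=run_at,
                    snapshot=cand.snapshot,
                    context=cand.context,
                )
                self.alerts[alert.alert_id] = alert
                active[key] = alert
                new_alerts.append(alert)
                self._append({"event": "new_alert", "alert": alert.model_dump(mode="json")})
        for key, alert in active.items():
            if key not in seen_keys:
                alert.status = AlertStatus.resolved
                self._append(
                    {"event": "resolve", "alert_id": alert.alert_id,
                     "at": run_at.isoformat(timespec="minutes")}
                )
        self._append(
            {"event": "run", "at": run_at.isoformat(timespec="minutes"),
             "n_candidates": len(candidates), "n_new": len(new_alerts)}
        )
        return new_alerts, refreshed

    # -- intervention tracking --------------------------------------------

    def record_intervention(
        self,
        alert_id: str,
        intervened: bool,
        at: datetime,
        channel: Optional[Channel] = None,
        suggestion: str = "",
    ) -> None:
        alert = self.alert(alert_id)
        if alert.status is AlertStatus.resolved:
            raise LedgerError(f"alert {alert_id!r} already resolved")
        if alert_id in self.interventions:
            raise LedgerError(f"alert {alert_id!r} already assessed")
        record = InterventionRecord(
            alert_id=alert_id,
            intervened=intervened,
            intervened_at=at,
            channel=Channel(channel) if channel else None,
            suggestion=suggestion,
        )
        self.interventions[alert_id] = record
        alert.status = AlertStatus.under_review if intervened else AlertStatus.handled
        self._append({"event": "intervention", "record": record.model_dump(mode="json")})

    def record_outcome(self, alert_id: str, outcome: Outcome | str, at: datetime) -> None:
        outcome = Outcome(outcome)
        record = self.interventions.get(alert_id)
        if record is None or not record.intervened:
            raise LedgerError(f"no pending intervention for alert {alert_id!r}")
        if record.outcome is not Outcome.pending:
            raise LedgerError(f"outcome already recorded for alert {alert_id!r}")
        if outcome is Outcome.pending:
            raise LedgerError("cannot record a pending outcome")
        if (
            outcome is Outcome.accepted
            and at - record.intervened_at > timedelta(hours=ACCEPTANCE_WINDOW_H)
        ):
            outcome = Outcome.accepted_late
        record.outcome = outcome
        record.outcome_at = at
        self.alert(alert_id).status = AlertStatus.handled
        self._append(
            {"event": "outcome", "alert_id": alert_id, "outcome": outcome.value,
             "at": at.isoformat(timespec="minutes")}
        )

    # -- event log ---------------------------------------------------------

    def _append(self, event: dict) -> None:
        self.events.append(event)

    def save(self, path: str | Path) -> None:
        lines = [json.dumps({"format": "pharmacheck-ledger", "schema_version": 1})]
        lines += [json.dumps(e, sort_keys=True) for e in self.events]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "AlertLedger":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or json.loads(lines[0]).get("format") != "pharmacheck-ledger":
            raise LedgerError(f"{path}: not a ledger file")
        return cls.replay(json.loads(line) for line in lines[1:] if line.strip())

    @classmethod
    def replay(cls, events: Iterable[dict]) -> "AlertLedger":
        """Rebuild state as a pure fold over the event sequence."""
        ledger = cls()
        for event in events:
            kind = event["event"]
            if kind == "new_alert":
                alert = Alert.model_validate(event["alert"])
                ledger.alerts[alert.alert_id] = alert
                ledger._seq = max(ledger._seq, int(alert.alert_id[1:]))
            elif kind == "refresh":
                ledger.alert(event["alert_id"]).last_seen_at = datetime.fromisoformat(
                    event["at"]
                )
            elif kind == "resolve":
                ledger.alert(event["alert_id"]).status = AlertStatus.resolved
            elif kind == "intervention":
                record = InterventionRecord.model_validate(event["record"])
                ledger.interventions[record.alert_id] = record
                if record.outcome is Outcome.pending and record.intervened:
                    ledger.alert(record.alert_id).status = AlertStatus.under_review
                else:
                    ledger.alert(record.alert_id).status = AlertStatus.handled
            elif kind == "outcome":
                record = ledger.interventions[event["alert_id"]]
                record.outcome = Outcome(event["outcome"])
                record.outcome_at = datetime.fromisoformat(event["at"])
                ledger.alert(event["alert_id"]).status = AlertStatus.handled
            elif kind == "run":
                pass
            else:
                raise LedgerError(f"unknown event kind {kind!r}")
            ledger.events.append(event)
        return ledger

    # -- export ------------------------------------------------------------

    def to_tracking_csv(self, path: str | Path) -> None:
        """Flat CSV tracking table shared with the pharmacy team."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["alert_id", "rule_id", "patient_id", "first_fired_at",
                 "intervened", "outcome", "outcome_at"]
            )
            for alert_id in sorted(self.alerts):
                alert = self.alerts[alert_id]
                record = self.interventions.get(alert_id)
                writer.writerow(
                    [
                        alert.alert_id,
                        alert.rule_id,
                        alert.patient_id,
                        alert.first_fired_at.isoformat(timespec="minutes"),
                        "" if record is None else record.intervened,
                        "" if record is None else record.outcome.value,
                        ""
                        if record is None or record.outcome_at is None
                        else record.outcome_at.isoformat(timespec="minutes"),
                    ]
                )
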