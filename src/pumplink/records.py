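"""Domain records for the medication-use event streams.

The pipeline reconciles three sources for continuous intravenous
infusions:

* medication orders and their dated dose/rate changes (the *prescribed*
  side),
* medication administration records (MARs) documented by clinicians in
  the EHR, and
* smart pump records (SPRs) logged by the infusion pumps themselves.

All doses/rates for a given medication are assumed to be expressed in a
single consistent unit (e.g. mcg/kg/min for vasopressors), so no unit
conversion layer exists.  Timestamps are timezone-naive datetimes at
one-minute resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterator, Optional

#: Pump states emitted by the infusion pumps.  Only ``started`` and
#: ``restarted`` events represent initiation of drug delivery and enter
#: the discrepancy analysis.
SPR_STATES = ("started", "restarted", "stopped", "completed", "paused", "canceled", "delayed")

#: States that mark the initiation (or re-initiation) of delivery.
STARTED_STATES = frozenset({"started", "restarted"})

#: Order-event kinds.  ``audit`` events act as event-block boundaries
#: when present; ``communication`` events carry no numeric value and
#: count only as linkage activity.
ORDER_EVENT_KINDS = ("initiation", "modification", "audit", "communication")


@dataclass(frozen=True)
class MedicationOrder:
    """A prescription for a continuous infusion."""

    order_id: str
    patient_id: str
    medication: str
    start: datetime
    dose: float
    unit: str = "mcg/kg/min"

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError(f"order {self.order_id}: dose must be > 0, got {self.dose}")


@dataclass(frozen=True)
class OrderEvent:
    """A dated change on an order: initiation, dose modification, audit,
    or a free-text communication (no numeric value)."""

    order_id: str
    timestamp: datetime
    kind: str
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ORDER_EVENT_KINDS:
            raise ValueError(f"unknown order-event kind {self.kind!r}")
        if self.kind == "communication" and self.value is not None:
            raise ValueError("communication events carry no numeric value")
        if self.kind in ("initiation", "modification") and self.value is None:
            raise ValueError(f"{self.kind} events require a numeric value")

    @property
    def is_boundary(self) -> bool:
        """True for events that delimit event blocks (initiations,
        modifications and audits; not communications)."""
        return self.kind in ("initiation", "modification", "audit")

    @property
    def has_value(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class MAREntry:
    """A clinician-documented administration in the EHR."""

    mar_id: str
    patient_id: str
    medication: str
    timestamp: datetime
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"MAR {self.mar_id}: dose must be >= 0")


@dataclass(frozen=True)
class SPREntry:
    """A pump-logged event.

    ``patient_id_raw`` is whatever string the bedside staff typed into
    the pump; it may be invalid.  ``medication`` is empty when the pump
    was programmed as a *basic* infusion without selecting a drug-library
    profile.
    """

    spr_id: str
    patient_id_raw: str
    medication: str  # "" when missing (basic infusion)
    timestamp: datetime
    state: str
    value: float

    def __post_init__(self) -> None:
        if self.state not in SPR_STATES:
            raise ValueError(f"SPR {self.spr_id}: unknown pump state {self.state!r}")


# sort rank for simultaneous records: an order event placed at the same
# minute as an administration legitimizes it, so it must sort first.
_TYPE_RANK = {OrderEvent: 0, MAREntry: 1, SPREntry: 2}


def record_sort_key(record) -> tuple:
    rank = _TYPE_RANK[type(record)]
    rid = getattr(record, "order_id", None) or getattr(record, "mar_id", None) or record.spr_id
    return (record.timestamp, rank, rid)


@dataclass
class Timeline:
    """The chronologically merged per-patient-per-medication sequence.

    ``links`` maps each linked SPR id to the order id the alignment step
    attached it to; SPRs that could not be linked within the time window
    are kept in ``unlinked_sprs`` and excluded from discrepancy rates.
    """

    patient_id: str
    medication: str
    orders: list[MedicationOrder] = field(default_factory=list)
    events: list[OrderEvent] = field(default_factory=list)
    mars: list[MAREntry] = field(default_factory=list)
    sprs: list[SPREntry] = field(default_factory=list)
    links: dict[str, str] = field(default_factory=dict)
    unlinked_sprs: list[SPREntry] = field(default_factory=list)

    def merged(self) -> Iterator:
        """All records in chronological order; ties break order event <
        MAR < SPR, then by record id for determinism."""
        yield from sorted([*self.events, *self.mars, *self.sprs], key=record_sort_key)

    def value_events(self) -> list[OrderEvent]:
        """Order events carrying a numeric dose/rate, chronologically."""
        return sorted(
            (e for e in self.events if e.has_value), key=lambda e: (e.timestamp, e.order_id)
        )

    def boundary_events(self) -> list[OrderEvent]:
        """Block-delimiting order events, chronologically."""
        return sorted(
            (e for e in self.events if e.is_boundary), key=lambda e: (e.timestamp, e.order_id)
        )
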