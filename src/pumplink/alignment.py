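"""Chronological alignment of EHR and pump streams.

Without a closed-loop pump integration there is no key joining a pump
record to the order it administered.  The linkage here reproduces the
post-hoc approach: group every record by (patient, medication), then
attach each started/restarted SPR to the *closest* order, where
closeness is the smallest absolute gap between the SPR timestamp and
any activity on the order (its placement, modifications, audits,
communications, or MAR documentation), subject to a 24-hour window.
SPRs with no order activity inside the window stay unlinked and are
excluded from discrepancy rates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Iterable, Optional, Sequence

from .records import (
    MAREntry,
    MedicationOrder,
    OrderEvent,
    SPREntry,
    STARTED_STATES,
    Timeline,
)

#: Default linkage window, hours.
LINKAGE_WINDOW_HOURS = 24.0


def filter_started(sprs: Iterable[SPREntry]) -> list[SPREntry]:
    """Keep only pump records marking the start or restart of delivery —
    the moments at which an erroneous infusion could be intercepted.
    Input order is preserved."""
    return [s for s in sprs if s.state in STARTED_STATES]


@dataclass
class RecordGroup:
    """All records sharing one (patient, medication) key."""

    patient_id: str
    medication: str
    orders: list[MedicationOrder] = field(default_factory=list)
    events: list[OrderEvent] = field(default_factory=list)
    mars: list[MAREntry] = field(default_factory=list)
    sprs: list[SPREntry] = field(default_factory=list)

    @property
    def has_orders(self) -> bool:
        return bool(self.orders)


def group_records(
    orders: Sequence[MedicationOrder],
    events: Sequence[OrderEvent],
    mars: Sequence[MAREntry],
    sprs: Sequence[SPREntry],
) -> list[RecordGroup]:
    """Partition all records by (patient_id, medication).

    SPRs are expected to be validity-screened already (their raw ID
    string is taken as the patient ID).  A group without orders still
    carries its SPRs; they are unlinkable by construction.
    """
    groups: dict[tuple[str, str], RecordGroup] = {}

    def get(key: tuple[str, str]) -> RecordGroup:
        if key not in groups:
            groups[key] = RecordGroup(patient_id=key[0], medication=key[1])
        return groups[key]

    order_key = {}
    for o in orders:
        key = (o.patient_id, o.medication)
        order_key[o.order_id] = key
        get(key).orders.append(o)
    for e in events:
        if e.order_id not in order_key:
            raise ValueError(f"order event references unknown order {e.order_id!r}")
        get(order_key[e.order_id]).events.append(e)
    for m in mars:
        get((m.patient_id, m.medication)).mars.append(m)
    for s in sprs:
        get((s.patient_id_raw, s.medication)).sprs.append(s)
    return [groups[k] for k in sorted(groups)]


def _assign_mars_to_orders(group: RecordGroup) -> dict[str, list[MAREntry]]:
    """Attribute each MAR to the order most recently initiated at or
    before it (the first order if the MAR precedes all initiations)."""
    assigned: dict[str, list[MAREntry]] = {o.order_id: [] for o in group.orders}
    if not group.orders:
        return assigned
    ordered = sorted(group.orders, key=lambda o: (o.start, o.order_id))
    for mar in group.mars:
        active = ordered[0]
        for o in ordered:
            if o.start <= mar.timestamp:
                active = o
            else:
                break
        assigned[active.order_id].append(mar)
    return assigned


def align_spr_to_order(
    spr: SPREntry,
    group_orders: Sequence[tuple[MedicationOrder, Sequence[OrderEvent], Sequence[MAREntry]]],
    window_hours: float = LINKAGE_WINDOW_HOURS,
    symmetric: bool = True,
) -> Optional[str]:
    """Link one started/restarted SPR to its most plausible order.

    Candidates are orders with at least one activity (any order event or
    MAR) within ``window_hours`` of the SPR timestamp; among candidates
    the order with the smallest absolute gap wins.  Ties break by
    earlier order initiation, then by order id.  ``symmetric=False``
    restricts activity to look-back only (at or before the SPR).
    Returns None when no order qualifies.
    """
    window = timedelta(hours=window_hours)
    best: Optional[tuple[timedelta, object, str]] = None
    for order, events, mars in group_orders:
        times = [e.timestamp for e in events] + [m.timestamp for m in mars]
        if not symmetric:
            times = [t for t in times if t <= spr.timestamp]
        if not times:
            continue
        gap = min(abs(t - spr.timestamp) for t in times)
        if gap > window:
            continue
        key = (gap, order.start, order.order_id)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def build_timeline(
    group: RecordGroup,
    links: dict[str, Optional[str]],
) -> Timeline:
    """Assemble the merged chronological timeline for one group.

    ``links`` maps every started/restarted SPR id in the group to an
    order id or None.  Linked SPRs join the merged sequence; unlinked
    ones are retained separately.  Ties at equal timestamps keep order
    events before administrations so a simultaneous modification
    legitimizes the administration.
    """
    linked, unlinked = [], []
    for spr in group.sprs:
        target = links.get(spr.spr_id)
        (linked if target is not None else unlinked).append(spr)
    return Timeline(
        patient_id=group.patient_id,
        medication=group.medication,
        orders=sorted(group.orders, key=lambda o: (o.start, o.order_id)),
        events=sorted(group.events, key=lambda e: (e.timestamp, e.order_id)),
        mars=sorted(group.mars, key=lambda m: (m.timestamp, m.mar_id)),
        sprs=sorted(linked, key=lambda s: (s.timestamp, s.spr_id)),
        links={k: v for k, v in links.items() if v is not None},
        unlinked_sprs=sorted(unlinked, key=lambda s: (s.timestamp, s.spr_id)),
    )


def align_group(
    group: RecordGroup,
    window_hours: float = LINKAGE_WINDOW_HOURS,
    symmetric: bool = True,
) -> Timeline:
    """Filter, link, and merge one (patient, medication) group."""
    started = filter_started(group.sprs)
    mars_by_order = _assign_mars_to_orders(group)
    events_by_order: dict[str, list[OrderEvent]] = {o.order_id: [] for o in group.orders}
    for e in group.events:
        events_by_order[e.order_id].append(e)
    triples = [
        (o, events_by_order[o.order_id], mars_by_order[o.order_id]) for o in group.orders
    ]
    links = {
        s.spr_id: align_spr_to_order(s, triples, window_hours, symmetric) for s in started
    }
    pruned = RecordGroup(
        patient_id=group.patient_id,
        medication=group.medication,
        orders=group.orders,
        events=group.events,
        mars=group.mars,
        sprs=started,
    )
    return build_timeline(pruned, links)


def align_all(
    groups: Iterable[RecordGroup],
    window_hours: float = LINKAGE_WINDOW_HOURS,
    symmetric: bool = True,
) -> list[Timeline]:
    return [align_group(g, window_hours, symmetric) for g in groups]
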