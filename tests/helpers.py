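"""Shared builders for hand-crafted timelines used across the suite."""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import Sequence

from pumplink import MAREntry, MedicationOrder, OrderEvent, SPREntry, Timeline

T0 = datetime(2014, 3, 1, 9, 0)


def ts(minutes: float) -> datetime:
    """Minutes after the fixture epoch (2014-03-01 09:00)."""
    return T0 + timedelta(minutes=minutes)


def make_timeline(
    events: Sequence[tuple[float, float]],
    mars: Sequence[tuple[float, float]] = (),
    sprs: Sequence[tuple[float, float]] = (),
    patient: str = "1000001",
    medication: str = "epinephrine",
    order_id: str = "O00000",
) -> Timeline:
    """Single-order timeline: ``events`` are (minutes, dose) with the
    first treated as the initiation; MARs/SPRs are (minutes, dose)."""
    ev = [
        OrderEvent(order_id, ts(m), "initiation" if i == 0 else "modification", v)
        for i, (m, v) in enumerate(events)
    ]
    order = MedicationOrder(order_id, patient, medication, ev[0].timestamp, ev[0].value)
    mar_entries = [
        MAREntry(f"M{i:04d}", patient, medication, ts(m), v) for i, (m, v) in enumerate(mars)
    ]
    spr_entries = [
        SPREntry(f"S{i:04d}", patient, medication, ts(m), "restarted" if i else "started", v)
        for i, (m, v) in enumerate(sprs)
    ]
    return Timeline(
        patient_id=patient,
        medication=medication,
        orders=[order],
        events=ev,
        mars=mar_entries,
        sprs=spr_entries,
        links={s.spr_id: order_id for s in spr_entries},
    )
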