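"""CSV / JSONL persistence for the event streams and results.

All tables are plain CSV with ISO-8601 minute-resolution timestamps;
the ground-truth ledger and aligned timelines are JSON lines.  Column
schemas:

* ``orders.csv``: order_id, patient_id, medication, start, dose, unit
* ``order_events.csv``: order_id, timestamp, kind, value (empty for
  free-text communications)
* ``mar.csv``: mar_id, patient_id, medication, timestamp, value
* ``spr.csv``: spr_id, patient_id_raw, medication, timestamp, state, value
* ``registry.csv``: kind (valid|expired|encounter|name), value,
  mapped_to (merge target for expired IDs)
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .records import MAREntry, MedicationOrder, OrderEvent, SPREntry, Timeline
from .screen import PatientRegistry
from .synthetic import GroundTruthLedger, LedgerEntry, SyntheticCohort

TIME_FORMAT = "%Y-%m-%d %H:%M"


def _fmt(t: datetime) -> str:
    return t.strftime(TIME_FORMAT)


def _parse(s: str) -> datetime:
    return datetime.strptime(s, TIME_FORMAT)


# ---------------------------------------------------------------- writers

def orders_to_frame(orders: Sequence[MedicationOrder]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "order_id": o.order_id,
                "patient_id": o.patient_id,
                "medication": o.medication,
                "start": _fmt(o.start),
                "dose": o.dose,
                "unit": o.unit,
            }
            for o in orders
        ],
        columns=["order_id", "patient_id", "medication", "start", "dose", "unit"],
    )


def events_to_frame(events: Sequence[OrderEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "order_id": e.order_id,
                "timestamp": _fmt(e.timestamp),
                "kind": e.kind,
                "value": e.value if e.value is not None else "",
            }
            for e in events
        ],
        columns=["order_id", "timestamp", "kind", "value"],
    )


def mars_to_frame(mars: Sequence[MAREntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mar_id": m.mar_id,
                "patient_id": m.patient_id,
                "medication": m.medication,
                "timestamp": _fmt(m.timestamp),
                "value": m.value,
            }
            for m in mars
        ],
        columns=["mar_id", "patient_id", "medication", "timestamp", "value"],
    )


def sprs_to_frame(sprs: Sequence[SPREntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spr_id": s.spr_id,
                "patient_id_raw": s.patient_id_raw,
                "medication": s.medication,
                "timestamp": _fmt(s.timestamp),
                "state": s.state,
                "value": s.value,
            }
            for s in sprs
        ],
        columns=["spr_id", "patient_id_raw", "medication", "timestamp", "state", "value"],
    )


def registry_to_frame(registry: PatientRegistry) -> pd.DataFrame:
    rows = [{"kind": "valid", "value": v, "mapped_to": ""} for v in sorted(registry.valid_ids)]
    rows += [
        {"kind": "expired", "value": k, "mapped_to": v}
        for k, v in sorted(registry.expired_ids.items())
    ]
    rows += [
        {"kind": "encounter", "value": v, "mapped_to": ""}
        for v in sorted(registry.encounter_ids)
    ]
    rows += [{"kind": "name", "value": v, "mapped_to": ""} for v in sorted(registry.patient_names)]
    return pd.DataFrame(rows, columns=["kind", "value", "mapped_to"])


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write the four streams, the registry and the ledger under
    ``out_dir`` (orders.csv, order_events.csv, mar.csv, spr.csv,
    registry.csv, ledger.jsonl)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    orders_to_frame(cohort.orders).to_csv(out / "orders.csv", index=False)
    events_to_frame(cohort.order_events).to_csv(out / "order_events.csv", index=False)
    mars_to_frame(cohort.mars).to_csv(out / "mar.csv", index=False)
    sprs_to_frame(cohort.sprs).to_csv(out / "spr.csv", index=False)
    registry_to_frame(cohort.registry).to_csv(out / "registry.csv", index=False)
    (out / "ledger.jsonl").write_text(
        cohort.ledger.to_jsonl() + ("\n" if len(cohort.ledger) else "")
    )


# ---------------------------------------------------------------- readers

def _read(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, **kw)
    except Exception as exc:  # pragma: no cover - message plumbing
        raise ValueError(f"cannot parse {path}: {exc}") from exc


def read_orders(path: str | Path) -> list[MedicationOrder]:
    df = _read(path)
    return [
        MedicationOrder(r.order_id, r.patient_id, r.medication, _parse(r.start),
                        float(r.dose), r.unit)
        for r in df.itertuples()
    ]


def read_order_events(path: str | Path) -> list[OrderEvent]:
    df = _read(path)
    return [
        OrderEvent(r.order_id, _parse(r.timestamp), r.kind,
                   float(r.value) if r.value != "" else None)
        for r in df.itertuples()
    ]


def read_mars(path: str | Path) -> list[MAREntry]:
    df = _read(path)
    return [
        MAREntry(r.mar_id, r.patient_id, r.medication, _parse(r.timestamp), float(r.value))
        for r in df.itertuples()
    ]


def read_sprs(path: str | Path) -> list[SPREntry]:
    df = _read(path)
    return [
        SPREntry(r.spr_id, r.patient_id_raw, r.medication, _parse(r.timestamp),
                 r.state, float(r.value))
        for r in df.itertuples()
    ]


def read_registry(path: str | Path) -> PatientRegistry:
    df = _read(path)
    valid, expired, encounters, names = set(), {}, set(), set()
    for r in df.itertuples():
        if r.kind == "valid":
            valid.add(r.value)
        elif r.kind == "expired":
            expired[r.value] = r.mapped_to
        elif r.kind == "encounter":
            encounters.add(r.value)
        elif r.kind == "name":
            names.add(r.value)
        else:
            raise ValueError(f"unknown registry row kind {r.kind!r}")
    return PatientRegistry(
        valid_ids=frozenset(valid),
        expired_ids=expired,
        encounter_ids=frozenset(encounters),
        patient_names=frozenset(names),
    )


def read_ledger(path: str | Path) -> GroundTruthLedger:
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        entries.append(LedgerEntry(**d))
    return GroundTruthLedger(entries)


# ------------------------------------------------------------- timelines

def timeline_to_dict(tl: Timeline) -> dict:
    return {
        "patient_id": tl.patient_id,
        "medication": tl.medication,
        "orders": [
            [o.order_id, o.patient_id, o.medication, _fmt(o.start), o.dose, o.unit]
            for o in tl.orders
        ],
        "events": [
            [e.order_id, _fmt(e.timestamp), e.kind, e.value] for e in tl.events
        ],
        "mars": [
            [m.mar_id, m.patient_id, m.medication, _fmt(m.timestamp), m.value]
            for m in tl.mars
        ],
        "sprs": [
            [s.spr_id, s.patient_id_raw, s.medication, _fmt(s.timestamp), s.state, s.value]
            for s in tl.sprs
        ],
        "links": tl.links,
        "unlinked_sprs": [
            [s.spr_id, s.patient_id_raw, s.medication, _fmt(s.timestamp), s.state, s.value]
            for s in tl.unlinked_sprs
        ],
    }


def timeline_from_dict(d: dict) -> Timeline:
    return Timeline(
        patient_id=d["patient_id"],
        medication=d["medication"],
        orders=[
            MedicationOrder(a, b, c, _parse(t), v, u) for a, b, c, t, v, u in d["orders"]
        ],
        events=[OrderEvent(a, _parse(t), k, v) for a, t, k, v in d["events"]],
        mars=[MAREntry(a, b, c, _parse(t), v) for a, b, c, t, v in d["mars"]],
        sprs=[SPREntry(a, b, c, _parse(t), st, v) for a, b, c, t, st, v in d["sprs"]],
        links=dict(d["links"]),
        unlinked_sprs=[
            SPREntry(a, b, c, _parse(t), st, v) for a, b, c, t, st, v in d["unlinked_sprs"]
        ],
    )


def write_timelines(timelines: Sequence[Timeline], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tl in timelines:
            fh.write(json.dumps(timeline_to_dict(tl)) + "\n")


def read_timelines(path: str | Path) -> list[Timeline]:
    return [
        timeline_from_dict(json.loads(line))
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
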