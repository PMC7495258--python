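"""Synthetic paired EHR/pump event streams with a ground-truth ledger.

Institutional EHR and pump-vendor extracts cannot be shared, so every
downstream stage is exercised on generated cohorts that emulate the
study conditions: per-patient sequences of continuous-infusion orders
with dose titrations, clinician MAR documentation on a regular cadence,
pump start/restart events between order changes, and injected
corruption — invalid patient IDs across nine observed failure modes,
missing medication names (basic infusions), dose misprogramming in one
or both sources, and orders placed late relative to their
administrations.

Every injected error is recorded in a ledger carrying the record id,
the true prescribed value, the corrupted value and the true magnitude
of discrepancy, so detection sensitivity, precision and magnitude
recovery can be scored exactly.  Generation is fully deterministic
given (config, error mixture, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterator, Optional, Sequence

import numpy as np

from .records import MAREntry, MedicationOrder, OrderEvent, SPREntry, STARTED_STATES
from .screen import INVALID_ID_CATEGORIES, PatientRegistry, classify_invalid_id

#: The nine studied continuous-infusion medications.
DEFAULT_MEDICATIONS = (
    "dopamine",
    "dobutamine",
    "epinephrine",
    "milrinone",
    "vasopressin",
    "fentanyl",
    "morphine",
    "TPN",
    "lipid",
)

#: Typical starting doses/rates, one consistent unit per medication.
BASE_DOSES = {
    "dopamine": 5.0,
    "dobutamine": 5.0,
    "epinephrine": 0.05,
    "milrinone": 0.5,
    "vasopressin": 0.0005,
    "fentanyl": 1.0,
    "morphine": 0.02,
    "TPN": 10.0,
    "lipid": 1.0,
}

_FIRST_NAMES = (
    "OLIVIA", "LIAM", "EMMA", "NOAH", "AVA", "ELIJAH", "SOPHIA", "LUCAS",
    "ISABELLA", "MASON", "MIA", "ETHAN", "AMELIA", "LOGAN", "HARPER", "JAMES",
)
_LAST_NAMES = (
    "SMITH", "JOHNSON", "WILLIAMS", "BROWN", "JONES", "GARCIA", "MILLER",
    "DAVIS", "RODRIGUEZ", "MARTINEZ", "WILSON", "ANDERSON", "TAYLOR", "THOMAS",
)

#: Default mixture weights over the nine invalid-ID failure modes
#: (shaped like the observed 2014 category tallies).
DEFAULT_ID_CATEGORY_WEIGHTS = {
    "dob_out_of_range": 42,
    "patient_name": 33,
    "missing_digits": 30,
    "random_number": 23,
    "encounter_id": 20,
    "invalid_letters": 13,
    "expired_id": 4,
    "extra_digits": 4,
    "typographical": 4,
}

# injected-MoD mixture: (low, high, weight) per report bin, weights
# shaped like the observed pooled MAR+SPR bin tallies (0% bin excluded —
# zero-magnitude discrepancies arise only from late orders).
_MOD_BIN_MIX = (
    (-90.0, -50.0, 62),
    (-50.0, -20.0, 165),
    (-20.0, -10.0, 104),
    (-10.0, -0.5, 24),
    (0.5, 10.0, 35),
    (10.0, 20.0, 124),
    (20.0, 50.0, 142),
    (50.0, 100.0, 175),
    (100.0, 300.0, 167),
)


@dataclass(frozen=True)
class ModDistribution:
    """Distribution of injected signed relative dose errors (percent).

    ``binned`` draws a report bin by weight then a uniform value within
    it; ``degenerate`` always returns ``value``.
    """

    kind: str = "binned"
    value: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("binned", "degenerate"):
            raise ValueError(f"unknown MoD distribution kind {self.kind!r}")
        if self.kind == "degenerate" and (self.value <= -100 or self.value == 0):
            raise ValueError("degenerate MoD must be > -100% and nonzero")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "degenerate":
            return self.value
        weights = np.array([w for _, _, w in _MOD_BIN_MIX], dtype=float)
        weights /= weights.sum()
        while True:
            lo, hi, _ = _MOD_BIN_MIX[rng.choice(len(_MOD_BIN_MIX), p=weights)]
            mod = float(rng.uniform(lo, hi))
            if abs(mod) >= 0.01:  # keep injections distinguishable from 0%
                return mod


@dataclass(frozen=True)
class DelayDistribution:
    """Late-order delays, minutes; support strictly beyond the 30-min
    grace window so every late order is a genuine documentation miss."""

    low: float = 45.0
    high: float = 180.0

    def __post_init__(self) -> None:
        if not (30.0 < self.low <= self.high):
            raise ValueError("late-order delays must satisfy 30 < low <= high")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class CohortConfig:
    """Shape of the generated cohort.

    Count distributions are dicts like ``{"kind": "poisson", "lam": 3.0,
    "min": 1}`` (kinds: poisson, fixed, uniform_int).  Administration
    cadences are in minutes; event-block durations are drawn uniformly
    from ``block_hours``.
    """

    n_patients: int = 50
    medications: tuple[str, ...] = DEFAULT_MEDICATIONS
    orders_per_patient: dict = field(
        default_factory=lambda: {"kind": "poisson", "lam": 3.0, "min": 1}
    )
    modifications_per_order: dict = field(
        default_factory=lambda: {"kind": "poisson", "lam": 1.0}
    )
    mar_interval_minutes: float = 240.0
    spr_interval_minutes: float = 120.0
    block_hours: tuple[float, float] = (6.0, 10.0)
    study_window: tuple[datetime, datetime] = (
        datetime(2014, 1, 1),
        datetime(2014, 12, 31),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.medications:
            raise ValueError("medication list must be nonempty")
        if self.mar_interval_minutes <= 0 or self.spr_interval_minutes <= 0:
            raise ValueError("administration intervals must be positive")
        if self.study_window[0] >= self.study_window[1]:
            raise ValueError("study window start must precede its end")
        if not (0 < self.block_hours[0] <= self.block_hours[1]):
            raise ValueError("block_hours must satisfy 0 < min <= max")


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ErrorMixture:
    """Corruption channels and their per-record / per-block rates.

    Defaults emulate the observed study conditions: ~22% of pump
    records with an invalid patient ID, ~10% with a missing medication
    name, and block-level dose-discrepancy rates shaped so MAR-flagged
    blocks (~4%), SPR-flagged blocks (~10%) and jointly-flagged blocks
    (~2.5%) match the concordance-table marginals.
    """

    p_invalid_id: float = 0.22
    invalid_id_category_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_ID_CATEGORY_WEIGHTS)
    )
    p_missing_med_name: float = 0.10
    p_mar_discrepancy: float = 0.017
    p_spr_discrepancy: float = 0.075
    p_joint_discrepancy: float = 0.025
    mod_distribution: ModDistribution = field(default_factory=ModDistribution)
    p_late_order: float = 0.005
    late_order_delay_minutes: DelayDistribution = field(default_factory=DelayDistribution)

    def __post_init__(self) -> None:
        for name in (
            "p_invalid_id",
            "p_missing_med_name",
            "p_mar_discrepancy",
            "p_spr_discrepancy",
            "p_joint_discrepancy",
            "p_late_order",
        ):
            _check_prob(getattr(self, name), name)
        unknown = set(self.invalid_id_category_weights) - set(INVALID_ID_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown invalid-ID categories: {sorted(unknown)}")
        weights = [self.invalid_id_category_weights.get(c, 0.0) for c in INVALID_ID_CATEGORIES]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("category weights must be nonnegative with positive sum")

    @classmethod
    def none(cls) -> "ErrorMixture":
        """All corruption channels off (noiseless cohort)."""
        return cls(
            p_invalid_id=0.0,
            p_missing_med_name=0.0,
            p_mar_discrepancy=0.0,
            p_spr_discrepancy=0.0,
            p_joint_discrepancy=0.0,
            p_late_order=0.0,
        )


@dataclass(frozen=True)
class LedgerEntry:
    """One injected error.  ``source`` is MAR/SPR for dose corruption,
    ID/NAME for identifier corruption, LATE_ORDER for a zero-magnitude
    documentation discrepancy created by delaying an order event."""

    record_id: str
    source: str  # MAR | SPR | ID | NAME | LATE_ORDER
    patient_id: str
    medication: str
    order_id: Optional[str]
    block_index: Optional[int]
    true_value: object
    corrupted_value: object
    mod_percent: Optional[float]
    category: Optional[str] = None  # invalid-ID failure mode (source=ID)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruthLedger:
    entries: list[LedgerEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LedgerEntry]:
        return iter(self.entries)

    def dose_entries(self) -> list[LedgerEntry]:
        """Entries the discrepancy detector is expected to recover."""
        return [e for e in self.entries if e.source in ("MAR", "SPR", "LATE_ORDER")]

    def by_source(self, source: str) -> list[LedgerEntry]:
        return [e for e in self.entries if e.source == source]

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps({**e.to_dict(), "true_value": _jsonable(e.true_value),
                        "corrupted_value": _jsonable(e.corrupted_value)})
            for e in self.entries
        )


def _jsonable(v):
    return float(v) if isinstance(v, (int, float, np.floating)) else v


@dataclass
class SyntheticCohort:
    """Generated streams plus the registry and ground truth.  Iterating
    yields (orders, order_events, mars, sprs, ledger)."""

    orders: list[MedicationOrder]
    order_events: list[OrderEvent]
    mars: list[MAREntry]
    sprs: list[SPREntry]
    ledger: GroundTruthLedger
    registry: PatientRegistry
    drug_library: tuple[str, ...]

    def __iter__(self):
        return iter((self.orders, self.order_events, self.mars, self.sprs, self.ledger))


# --------------------------------------------------------------------------
# patient-ID corruption

def corrupt_patient_id(
    valid_id: str,
    category: str,
    registry: PatientRegistry,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> str:
    """Produce an invalid ID string of the requested failure mode.

    The result is guaranteed (by rejection sampling against
    :func:`classify_invalid_id`) to be absent from the registry's valid
    set and to classify back to ``category`` under the screening
    precedence chain.
    """
    if category not in INVALID_ID_CATEGORIES:
        raise ValueError(f"unknown invalid-ID category {category!r}")
    digits = "0123456789"
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

    def build() -> str:
        if category == "patient_name":
            names = sorted(registry.patient_names)
            return names[int(rng.integers(len(names)))]
        if category == "encounter_id":
            enc = sorted(registry.encounter_ids)
            return enc[int(rng.integers(len(enc)))]
        if category == "expired_id":
            exp = sorted(registry.expired_ids)
            return exp[int(rng.integers(len(exp)))]
        if category == "dob_out_of_range":
            year = int(rng.choice(np.r_[1940:1965, 2015:2031]))
            month = int(rng.integers(1, 13))
            day = int(rng.integers(1, 29))
            return f"{year:04d}{month:02d}{day:02d}"
        if category == "invalid_letters":
            chars = list(valid_id)
            for pos in rng.choice(len(chars), size=int(rng.integers(1, 3)), replace=False):
                chars[pos] = letters[int(rng.integers(26))]
            return "".join(chars)
        if category == "missing_digits":
            n_drop = int(rng.integers(1, min(3, len(valid_id) - 1) + 1))
            keep = sorted(
                rng.choice(len(valid_id), size=len(valid_id) - n_drop, replace=False)
            )
            return "".join(valid_id[i] for i in keep)
        if category == "extra_digits":
            chars = list(valid_id)
            for _ in range(int(rng.integers(1, 3))):
                pos = int(rng.integers(len(chars) + 1))
                chars.insert(pos, digits[int(rng.integers(10))])
            return "".join(chars)
        if category == "typographical":
            chars = list(valid_id)
            pos = int(rng.integers(len(chars)))
            new = digits[int(rng.integers(10))]
            while new == chars[pos]:
                new = digits[int(rng.integers(10))]
            chars[pos] = new
            return "".join(chars)
        # random_number
        return "".join(digits[int(rng.integers(10))] for _ in range(len(valid_id)))

    for _ in range(max_tries):
        candidate = build()
        if candidate in registry.valid_ids:
            continue
        if classify_invalid_id(candidate, registry) == category:
            return candidate
    raise RuntimeError(f"could not construct a {category!r} corruption of {valid_id!r}")


# --------------------------------------------------------------------------
# registry construction

def _build_registry(config: CohortConfig) -> PatientRegistry:
    n = config.n_patients
    valid = frozenset(f"{1000000 + i}" for i in range(n))
    n_expired = max(2, n // 10)
    valid_sorted = sorted(valid)
    expired = {
        f"{2000000 + i}": valid_sorted[i % n] for i in range(n_expired)
    }
    encounters = frozenset(f"{900000000 + 13 * i}" for i in range(max(4, n)))
    names = frozenset(
        f"{_LAST_NAMES[i % len(_LAST_NAMES)]}, {_FIRST_NAMES[(3 * i) % len(_FIRST_NAMES)]}"
        for i in range(max(4, n))
    )
    return PatientRegistry(
        valid_ids=valid, expired_ids=expired, encounter_ids=encounters, patient_names=names
    )


# --------------------------------------------------------------------------
# generation

def _sample_count(rng: np.random.Generator, params: dict) -> int:
    kind = params.get("kind", "poisson")
    if kind == "poisson":
        v = int(rng.poisson(params["lam"]))
    elif kind == "fixed":
        v = int(params["value"])
    elif kind == "uniform_int":
        v = int(rng.integers(params["low"], params["high"] + 1))
    else:
        raise ValueError(f"unknown count distribution kind {kind!r}")
    return max(int(params.get("min", 0)), v)


def _floor_minute(t: datetime) -> datetime:
    return t.replace(second=0, microsecond=0)


@dataclass
class _Interval:
    """One generation-time event block of an order."""

    index: int
    start: datetime
    end: datetime
    value: float
    mar_ix: list[int] = field(default_factory=list)
    spr_ix: list[int] = field(default_factory=list)  # started/restarted only


@dataclass
class _OrderPlan:
    order: MedicationOrder
    events: list[OrderEvent]
    intervals: list[_Interval]


def _titrate(rng: np.random.Generator, dose: float) -> float:
    if rng.random() < 0.5:
        return dose * float(rng.uniform(1.15, 1.6))
    return dose * float(rng.uniform(0.6, 0.85))


def generate_cohort(
    config: CohortConfig, errors: Optional[ErrorMixture] = None
) -> SyntheticCohort:
    """Generate the four event streams plus registry and ledger.

    Phase 1 lays down perfectly consistent streams (every MAR/SPR
    between consecutive order events carries the active prescribed
    value); phase 2 injects the configured corruption and records every
    injection in the ledger.  Identical (config, errors) give
    byte-identical output.
    """
    errors = errors if errors is not None else ErrorMixture()
    rng = np.random.default_rng(config.seed)
    registry = _build_registry(config)
    patients = sorted(registry.valid_ids)
    window_start, window_end = config.study_window

    plans: list[_OrderPlan] = []
    mars: list[MAREntry] = []
    sprs: list[SPREntry] = []
    cursors: dict[tuple[str, str], datetime] = {}
    n_order = n_mar = n_spr = 0

    for pid in patients:
        for _ in range(_sample_count(rng, config.orders_per_patient)):
            med = config.medications[int(rng.integers(len(config.medications)))]
            key = (pid, med)
            if key not in cursors:
                cursors[key] = window_start + timedelta(hours=float(rng.uniform(0, 96)))
            start = _floor_minute(cursors[key])
            k = _sample_count(rng, config.modifications_per_order)
            durations = [
                timedelta(hours=float(rng.uniform(*config.block_hours))) for _ in range(k + 1)
            ]
            total = sum(durations, timedelta())
            if start + total >= window_end:
                continue  # order would overrun the study window
            order_id = f"O{n_order:05d}"
            n_order += 1
            dose = BASE_DOSES.get(med, 1.0) * float(rng.uniform(0.5, 1.5))

            events = [OrderEvent(order_id, start, "initiation", dose)]
            intervals: list[_Interval] = []
            t = start
            value = dose
            for i in range(k + 1):
                end = _floor_minute(t + durations[i])
                intervals.append(_Interval(index=i, start=t, end=end, value=value))
                if i < k:
                    value = _titrate(rng, value)
                    events.append(OrderEvent(order_id, end, "modification", value))
                t = end

            order = MedicationOrder(order_id, pid, med, start, dose)
            # administrations: one shortly after each order event, then on
            # the configured cadence until the next event
            first_of_order = True
            for iv in intervals:
                for offset_min, step_min, which in (
                    (5, config.mar_interval_minutes, "mar"),
                    (2, config.spr_interval_minutes, "spr"),
                ):
                    tt = iv.start + timedelta(minutes=offset_min)
                    while tt < iv.end - timedelta(minutes=1):
                        jitter = timedelta(minutes=int(rng.integers(0, 4)))
                        stamp = _floor_minute(min(tt + jitter, iv.end - timedelta(minutes=1)))
                        if which == "mar":
                            mars.append(
                                MAREntry(f"M{n_mar:06d}", pid, med, stamp, iv.value)
                            )
                            iv.mar_ix.append(len(mars) - 1)
                            n_mar += 1
                        else:
                            state = "started" if first_of_order else "restarted"
                            first_of_order = False
                            sprs.append(
                                SPREntry(f"S{n_spr:06d}", pid, med, stamp, state, iv.value)
                            )
                            iv.spr_ix.append(len(sprs) - 1)
                            n_spr += 1
                        tt += timedelta(minutes=step_min)
                # occasional non-delivery pump event mid-block
                if rng.random() < 0.25:
                    mid = _floor_minute(iv.start + (iv.end - iv.start) / 2)
                    state = str(rng.choice(["paused", "stopped", "delayed"]))
                    sprs.append(SPREntry(f"S{n_spr:06d}", pid, med, mid, state, iv.value))
                    n_spr += 1
            # completion event at order end
            sprs.append(
                SPREntry(f"S{n_spr:06d}", pid, med, intervals[-1].end, "completed",
                         intervals[-1].value)
            )
            n_spr += 1

            plans.append(_OrderPlan(order, events, intervals))
            cursors[key] = intervals[-1].end + timedelta(
                hours=49.0 + float(rng.uniform(0, 48))
            )

    ledger = GroundTruthLedger()
    _inject_identifier_errors(rng, errors, registry, sprs, plans, ledger)
    _inject_dose_errors(rng, errors, plans, mars, sprs, ledger)

    orders = [p.order for p in plans]
    order_events = [e for p in plans for e in p.events]
    return SyntheticCohort(
        orders=orders,
        order_events=order_events,
        mars=mars,
        sprs=sprs,
        ledger=ledger,
        registry=registry,
        drug_library=tuple(config.medications),
    )


def _inject_identifier_errors(
    rng: np.random.Generator,
    errors: ErrorMixture,
    registry: PatientRegistry,
    sprs: list[SPREntry],
    plans: list[_OrderPlan],
    ledger: GroundTruthLedger,
) -> None:
    """Invalid patient IDs and missing medication names on SPRs."""
    if errors.p_invalid_id == 0 and errors.p_missing_med_name == 0:
        return
    block_of: dict[str, tuple[str, int]] = {}
    for p in plans:
        for iv in p.intervals:
            for ix in iv.spr_ix:
                block_of[sprs[ix].spr_id] = (p.order.order_id, iv.index)
    cats = list(INVALID_ID_CATEGORIES)
    weights = np.array(
        [errors.invalid_id_category_weights.get(c, 0.0) for c in cats], dtype=float
    )
    weights /= weights.sum()
    for i, spr in enumerate(sprs):
        oid, bix = block_of.get(spr.spr_id, (None, None))
        if errors.p_invalid_id and rng.random() < errors.p_invalid_id:
            category = cats[int(rng.choice(len(cats), p=weights))]
            bad = corrupt_patient_id(spr.patient_id_raw, category, registry, rng)
            ledger.entries.append(
                LedgerEntry(spr.spr_id, "ID", spr.patient_id_raw, spr.medication,
                            oid, bix, spr.patient_id_raw, bad, None, category)
            )
            spr = dataclasses.replace(spr, patient_id_raw=bad)
            sprs[i] = spr
        if errors.p_missing_med_name and rng.random() < errors.p_missing_med_name:
            ledger.entries.append(
                LedgerEntry(spr.spr_id, "NAME", spr.patient_id_raw, spr.medication,
                            oid, bix, spr.medication, "", None)
            )
            sprs[i] = dataclasses.replace(spr, medication="")


def _sample_mod(
    rng: np.random.Generator,
    dist: ModDistribution,
    prescribed: float,
    avoid: Sequence[float],
) -> tuple[float, float]:
    """Draw an injected MoD whose corrupted value collides with no order
    value of the group (so detection cannot be masked by coincidence)."""
    for _ in range(20):
        mod = dist.sample(rng)
        corrupted = prescribed * (1.0 + mod / 100.0)
        if corrupted > 0 and all(abs(corrupted - v) > 1e-5 * abs(v) for v in avoid):
            return mod, corrupted
        if dist.kind == "degenerate":
            break  # resampling cannot change a degenerate draw
    return mod, corrupted


def _inject_dose_errors(
    rng: np.random.Generator,
    errors: ErrorMixture,
    plans: list[_OrderPlan],
    mars: list[MAREntry],
    sprs: list[SPREntry],
    ledger: GroundTruthLedger,
) -> None:
    """Per-block dose corruption and late-order documentation errors."""
    if (
        errors.p_mar_discrepancy == 0
        and errors.p_spr_discrepancy == 0
        and errors.p_joint_discrepancy == 0
        and errors.p_late_order == 0
    ):
        return
    # order-event values per (patient, medication): collision guard
    group_values: dict[tuple[str, str], list[float]] = {}
    for p in plans:
        key = (p.order.patient_id, p.order.medication)
        group_values.setdefault(key, []).extend(e.value for e in p.events if e.has_value)

    id_name_corrupted = {e.record_id for e in ledger.entries if e.source in ("ID", "NAME")}

    for plan in plans:
        key = (plan.order.patient_id, plan.order.medication)
        avoid = group_values[key]
        for iv in plan.intervals:
            # screened-out SPRs can never be detected downstream; keep
            # dose/late injection on detectable records only
            clean_spr_ix = [
                ix for ix in iv.spr_ix if sprs[ix].spr_id not in id_name_corrupted
            ]
            admin_times = [mars[ix].timestamp for ix in iv.mar_ix] + [
                sprs[ix].timestamp for ix in clean_spr_ix
            ]
            if iv.index >= 1 and errors.p_late_order and rng.random() < errors.p_late_order:
                if _inject_late_order(rng, errors, plan, iv, mars, sprs,
                                      clean_spr_ix, ledger):
                    continue  # at most one injection type per block
            taken_mar: set[int] = set()
            taken_spr: set[int] = set()

            def corrupt_mar(mod: Optional[float] = None) -> Optional[float]:
                free = [ix for ix in iv.mar_ix if ix not in taken_mar]
                if not free:
                    return None
                ix = free[int(rng.integers(len(free)))]
                taken_mar.add(ix)
                rec = mars[ix]
                if mod is None:
                    mod, bad = _sample_mod(rng, errors.mod_distribution, iv.value, avoid)
                else:
                    bad = iv.value * (1.0 + mod / 100.0)
                mars[ix] = dataclasses.replace(rec, value=bad)
                ledger.entries.append(
                    LedgerEntry(rec.mar_id, "MAR", plan.order.patient_id,
                                plan.order.medication, plan.order.order_id, iv.index,
                                iv.value, bad, (bad - iv.value) / iv.value * 100.0)
                )
                return mod

            def corrupt_spr(mod: Optional[float] = None) -> Optional[float]:
                free = [ix for ix in clean_spr_ix if ix not in taken_spr]
                if not free:
                    return None
                ix = free[int(rng.integers(len(free)))]
                taken_spr.add(ix)
                rec = sprs[ix]
                if mod is None:
                    mod, bad = _sample_mod(rng, errors.mod_distribution, iv.value, avoid)
                else:
                    bad = iv.value * (1.0 + mod / 100.0)
                sprs[ix] = dataclasses.replace(rec, value=bad)
                ledger.entries.append(
                    LedgerEntry(rec.spr_id, "SPR", plan.order.patient_id,
                                plan.order.medication, plan.order.order_id, iv.index,
                                iv.value, bad, (bad - iv.value) / iv.value * 100.0)
                )
                return mod

            if errors.p_joint_discrepancy and rng.random() < errors.p_joint_discrepancy:
                if iv.mar_ix and clean_spr_ix:
                    mod, _ = _sample_mod(rng, errors.mod_distribution, iv.value, avoid)
                    corrupt_mar(mod)
                    corrupt_spr(mod)
            if errors.p_mar_discrepancy and rng.random() < errors.p_mar_discrepancy:
                corrupt_mar()
            if errors.p_spr_discrepancy and rng.random() < errors.p_spr_discrepancy:
                corrupt_spr()


def _inject_late_order(
    rng: np.random.Generator,
    errors: ErrorMixture,
    plan: _OrderPlan,
    iv: _Interval,
    mars: list[MAREntry],
    sprs: list[SPREntry],
    clean_spr_ix: list[int],
    ledger: GroundTruthLedger,
) -> bool:
    """Delay the modification that opens block ``iv`` until after its
    first administrations, leaving the administered values equal to the
    (now late) order value.  Creates pure documentation discrepancies
    with 0% magnitude.  Returns False when infeasible."""
    admins = [("MAR", ix, mars[ix].timestamp) for ix in iv.mar_ix] + [
        ("SPR", ix, sprs[ix].timestamp) for ix in clean_spr_ix
    ]
    if not admins:
        return False
    first_t = min(t for _, _, t in admins)
    delay = errors.late_order_delay_minutes.sample(rng)
    new_t = _floor_minute(first_t + timedelta(minutes=delay))
    if new_t >= iv.end - timedelta(minutes=1):
        return False
    # administrations more than the grace window ahead of the late order
    affected = [
        (src, ix, t) for src, ix, t in admins if new_t - t > timedelta(minutes=30)
    ]
    if not affected:
        return False
    # move the boundary modification (the event at the block start)
    moved = False
    for j, ev in enumerate(plan.events):
        if ev.is_boundary and ev.timestamp == iv.start and ev.kind == "modification":
            plan.events[j] = dataclasses.replace(ev, timestamp=new_t)
            moved = True
            break
    if not moved:
        return False
    for src, ix, t in sorted(affected, key=lambda a: (a[2], a[0], a[1])):
        rid = mars[ix].mar_id if src == "MAR" else sprs[ix].spr_id
        ledger.entries.append(
            LedgerEntry(rid, "LATE_ORDER", plan.order.patient_id, plan.order.medication,
                        plan.order.order_id, iv.index, iv.value, iv.value, 0.0)
        )
    return True
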