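"""Rule-based detection of medication administration discrepancies.

A discrepancy is a mismatch between the prescribed dose/rate and its
documented administration, in either the clinician-entered MAR or the
pump-logged SPR.  Two rules shape the detection:

* **Grace window.**  Verbal orders take time to transcribe, so an
  administration that anticipates an order modification arriving within
  30 minutes is legitimate.
* **Late documentation.**  If the only order matching the administered
  value arrives *more* than 30 minutes later, the administration is
  still counted as a discrepancy — but with a 0% magnitude, marking a
  documentation problem rather than a dosing one.

The magnitude of discrepancy (MoD) is the signed relative difference,
``(administered - prescribed) / prescribed x 100``; overdoses are
positive.  MoD values are summarized in ten report bins from ``<-50%``
to ``>100%``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Optional, Sequence

from .records import MAREntry, SPREntry, Timeline
from .utils import round_half_up

#: Default transcription grace window, minutes.
GRACE_MINUTES = 30.0

#: Relative tolerance for dose equality (values are machine-entered,
#: not measured; widen for data with rounding dialects).
DOSE_RTOL = 1e-6

#: The ten MoD report bins, in ascending order.
MOD_BIN_LABELS = (
    "<-50%",
    "[-50%,-20%)",
    "[-20%,-10%)",
    "[-10%,0%)",
    "0%",
    "(0%,10%]",
    "(10%,20%]",
    "(20%,50%]",
    "(50%,100%]",
    ">100%",
)

#: Bins counting as overdoses (administered above prescribed).
OVERDOSE_BINS = ("(0%,10%]", "(10%,20%]", "(20%,50%]", "(50%,100%]", ">100%")

#: A substantial overdose exceeds double the prescribed dose.
SUBSTANTIAL_OVERDOSE_BIN = ">100%"


@dataclass(frozen=True)
class Discrepancy:
    """One detected mismatch between prescription and administration."""

    record_id: str
    source: str  # "MAR" | "SPR"
    timestamp: datetime
    administered: float
    reference: float
    mod_percent: float
    mod_bin: str
    documentation_only: bool = False
    pre_order: bool = False  # administration preceded every order event

    def __post_init__(self) -> None:
        if self.source not in ("MAR", "SPR"):
            raise ValueError(f"unknown discrepancy source {self.source!r}")
        if self.documentation_only and self.mod_percent != 0:
            raise ValueError("documentation-only discrepancies have 0% magnitude")


def magnitude_of_discrepancy(administered: float, prescribed: float) -> float:
    """Signed percentage of the dose error over the correct dose."""
    if prescribed <= 0:
        raise ValueError(f"prescribed dose must be > 0, got {prescribed}")
    return (administered - prescribed) / prescribed * 100.0


def bin_mod(mod: float) -> str:
    """Assign a MoD to its report bin (a partition of the real line)."""
    if not math.isfinite(mod):
        raise ValueError(f"MoD must be finite, got {mod}")
    if mod < -50:
        return "<-50%"
    if mod < -20:
        return "[-50%,-20%)"
    if mod < -10:
        return "[-20%,-10%)"
    if mod < 0:
        return "[-10%,0%)"
    if mod == 0:
        return "0%"
    if mod <= 10:
        return "(0%,10%]"
    if mod <= 20:
        return "(10%,20%]"
    if mod <= 50:
        return "(20%,50%]"
    if mod <= 100:
        return "(50%,100%]"
    return ">100%"


def _matches(administered: float, prescribed: float, rtol: float) -> bool:
    return abs(administered - prescribed) <= rtol * abs(prescribed)


def prescribed_value_at(
    timeline: Timeline,
    t: datetime,
    grace_minutes: float = GRACE_MINUTES,
    admin_value: Optional[float] = None,
    rtol: float = DOSE_RTOL,
) -> Optional[tuple[float, bool]]:
    """The dose/rate prescribed at time ``t``, as ``(value, via_grace)``.

    Normally the value of the latest order event at or before ``t``.
    When ``admin_value`` is given and disagrees with that value but
    matches an order event arriving within the grace window after
    ``t``, the grace value is returned with ``via_grace=True``.
    Returns None when no order event exists at/before ``t`` nor within
    the grace window.
    """
    events = timeline.value_events()
    prior = [e for e in events if e.timestamp <= t]
    active = prior[-1].value if prior else None
    if admin_value is not None and (active is None or not _matches(admin_value, active, rtol)):
        horizon = t + timedelta(minutes=grace_minutes)
        for e in events:
            if t < e.timestamp <= horizon and _matches(admin_value, e.value, rtol):
                return e.value, True
    if active is None:
        return None
    return active, False


def _evaluate(
    record_id: str,
    source: str,
    t: datetime,
    value: float,
    events: Sequence,
    grace: timedelta,
    rtol: float,
) -> Optional[Discrepancy]:
    """Apply the discrepancy rule to one administration record."""
    prior = [e for e in events if e.timestamp <= t]
    active = prior[-1].value if prior else None

    if active is not None and _matches(value, active, rtol):
        return None
    # anticipated order arriving within the grace window: legitimate
    for e in events:
        if t < e.timestamp <= t + grace and _matches(value, e.value, rtol):
            return None
    # matching order placed too late: documentation discrepancy, MoD 0
    for e in events:
        if e.timestamp > t + grace and _matches(value, e.value, rtol):
            return Discrepancy(
                record_id, source, t, value, e.value, 0.0, "0%",
                documentation_only=True, pre_order=active is None,
            )
    reference = active if active is not None else events[0].value
    mod = magnitude_of_discrepancy(value, reference)
    return Discrepancy(
        record_id, source, t, value, reference, mod, bin_mod(mod),
        pre_order=active is None,
    )


def detect_discrepancies(
    timeline: Timeline,
    grace_minutes: float = GRACE_MINUTES,
    rtol: float = DOSE_RTOL,
) -> list[Discrepancy]:
    """Evaluate every MAR and every linked started/restarted SPR of a
    timeline against the prescription stream.

    Unlinked SPRs never reach this point (they sit in
    ``timeline.unlinked_sprs``) and are excluded from counts and rates.
    Administrations that precede every order event are compared against
    the first order value and flagged ``pre_order``.
    """
    events = timeline.value_events()
    if not events:
        return []
    grace = timedelta(minutes=grace_minutes)
    found: list[Discrepancy] = []
    for mar in timeline.mars:
        d = _evaluate(mar.mar_id, "MAR", mar.timestamp, mar.value, events, grace, rtol)
        if d:
            found.append(d)
    for spr in timeline.sprs:
        d = _evaluate(spr.spr_id, "SPR", spr.timestamp, spr.value, events, grace, rtol)
        if d:
            found.append(d)
    return found


def discrepancy_rate(n_discrepant: int, n_records: int, ndigits: int = 1) -> float:
    """Percentage of administration records found discrepant, rounded
    half-up to report precision."""
    if n_records <= 0:
        raise ValueError("discrepancy rate needs a positive record count")
    return round_half_up(100.0 * n_discrepant / n_records, ndigits)


def mod_bin_counts(discrepancies: Iterable[Discrepancy]) -> dict[str, int]:
    """Tally of discrepancies per MoD bin, all ten bins present."""
    counts = Counter(d.mod_bin for d in discrepancies)
    return {label: counts.get(label, 0) for label in MOD_BIN_LABELS}


@dataclass(frozen=True)
class OverdoseSummary:
    """Overdose share of discrepancies and substantial-overdose share
    of overdoses.  Shares are None (undefined) on zero denominators."""

    n_total: int
    n_overdose: int
    n_substantial: int

    @property
    def overdose_pct(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return 100.0 * self.n_overdose / self.n_total

    @property
    def substantial_pct(self) -> Optional[float]:
        if self.n_overdose == 0:
            return None
        return 100.0 * self.n_substantial / self.n_overdose


def overdose_summary(binned: Mapping[str, int]) -> OverdoseSummary:
    """Summarize a MoD bin tally: what share of discrepancies were
    overdoses, and what share of those exceeded +100%."""
    unknown = set(binned) - set(MOD_BIN_LABELS)
    if unknown:
        raise ValueError(f"unknown MoD bins: {sorted(unknown)}")
    total = sum(binned.values())
    overdose = sum(binned.get(b, 0) for b in OVERDOSE_BINS)
    substantial = binned.get(SUBSTANTIAL_OVERDOSE_BIN, 0)
    return OverdoseSummary(total, overdose, substantial)
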