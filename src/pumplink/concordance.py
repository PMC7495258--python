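"""Block-level concordance between MAR and SPR discrepancies.

MAR discrepancies often reflect documentation slips while pump records
sit closest to the patient, so comparing *where* the two sources flag
problems separates documentation issues from likely true administration
errors.  Each order's timeline is segmented into event blocks delimited
by order initiations, modifications and audits; a block is categorized
by which sources show discrepancies among its member administrations
(none / MAR-only / SPR-only / both), and Cohen's kappa over the
resulting 2x2 table quantifies the agreement between the two sources.

Only orders carrying both MAR and SPR data enter the assessment, and
only intervals that actually contain administrations become blocks — an
empty interval has no members to categorize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

from .discrepancy import Discrepancy
from .records import MAREntry, SPREntry, Timeline
from .utils import round_half_up

#: Block categories, in 2x2 order (MAR axis, SPR axis).
CATEGORIES = ("none", "MAR_only", "SPR_only", "both")


@dataclass
class EventBlock:
    """One inter-order-event interval with its member administrations.

    ``start`` is None for administrations preceding every order event;
    ``end`` is None for the tail interval after the last event.
    """

    order_id: str
    index: int
    start: Optional[datetime]
    end: Optional[datetime]
    mars: list[MAREntry] = field(default_factory=list)
    sprs: list[SPREntry] = field(default_factory=list)
    category: Optional[str] = None
    n_mar_discrepant: int = 0
    n_spr_discrepant: int = 0

    @property
    def n_members(self) -> int:
        return len(self.mars) + len(self.sprs)


def segment_event_blocks(timeline: Timeline) -> list[EventBlock]:
    """Cut a timeline into event blocks at every boundary order event.

    Every administration lands in exactly one interval ``[b_i,
    b_{i+1})`` (administrations at precisely a boundary minute open the
    new block, consistent with the order-event-first tie rule); a
    leading interval collects administrations preceding the first
    event and belongs to the first order.  Intervals without any
    administration emit no block.
    """
    boundaries = timeline.boundary_events()
    if not boundaries:
        return []
    edges: list[tuple[Optional[datetime], Optional[datetime], str]] = []
    first_order = boundaries[0].order_id
    edges.append((None, boundaries[0].timestamp, first_order))
    for i, b in enumerate(boundaries):
        end = boundaries[i + 1].timestamp if i + 1 < len(boundaries) else None
        edges.append((b.timestamp, end, b.order_id))

    blocks = [
        EventBlock(order_id=oid, index=i, start=s, end=e)
        for i, (s, e, oid) in enumerate(edges)
    ]

    def locate(t: datetime) -> EventBlock:
        for blk in blocks:
            if (blk.start is None or blk.start <= t) and (blk.end is None or t < blk.end):
                return blk
        return blocks[-1]

    for mar in timeline.mars:
        locate(mar.timestamp).mars.append(mar)
    for spr in timeline.sprs:
        locate(spr.timestamp).sprs.append(spr)

    occupied = [b for b in blocks if b.n_members > 0]
    # re-index contiguously per order
    counters: dict[str, int] = {}
    for b in occupied:
        b.index = counters.get(b.order_id, 0)
        counters[b.order_id] = b.index + 1
    return occupied


def classify_block(block: EventBlock, discrepancies: Iterable[Discrepancy]) -> str:
    """Assign a block its concordance category from the discrepancy
    status of its member records; also records the member discrepancy
    counts on the block."""
    flagged = {(d.source, d.record_id) for d in discrepancies}
    n_mar = sum(1 for m in block.mars if ("MAR", m.mar_id) in flagged)
    n_spr = sum(1 for s in block.sprs if ("SPR", s.spr_id) in flagged)
    if n_mar and n_spr:
        category = "both"
    elif n_mar:
        category = "MAR_only"
    elif n_spr:
        category = "SPR_only"
    else:
        category = "none"
    block.category = category
    block.n_mar_discrepant = n_mar
    block.n_spr_discrepant = n_spr
    return category


def include_order(order_blocks: Sequence[EventBlock]) -> bool:
    """An order enters the concordance analysis only when it carries
    both MAR and SPR data."""
    return any(b.mars for b in order_blocks) and any(b.sprs for b in order_blocks)


def cohen_kappa(counts: tuple[int, int, int, int]) -> Optional[float]:
    """Cohen's kappa for the block-level 2x2 agreement table.

    ``counts`` is ``(both, MAR_only, SPR_only, none)``.  With observed
    agreement po = (both + none)/N and chance agreement pe from the
    marginal products, kappa = (po - pe) / (1 - pe).  Returns None when
    the marginals are degenerate (pe = 1), where kappa is undefined.
    """
    both, mar_only, spr_only, none = counts
    n = both + mar_only + spr_only + none
    if n <= 0:
        raise ValueError("kappa needs at least one block")
    po = (both + none) / n
    mar_yes, mar_no = both + mar_only, spr_only + none
    spr_yes, spr_no = both + spr_only, mar_only + none
    pe = (mar_yes * spr_yes + mar_no * spr_no) / (n * n)
    if pe == 1.0:
        return None
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class ConcordanceResult:
    """One concordance-table row (a medication, or the overall sums)."""

    medication: str
    n_orders_all: int
    n_orders_included: int
    n_blocks: int
    n_mar_discrepancies: int
    n_spr_discrepancies: int
    counts: Mapping[str, int]  # keys = CATEGORIES

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_blocks:
            raise ValueError("category counts must sum to the block count")

    @property
    def kappa(self) -> Optional[float]:
        return cohen_kappa(
            (
                self.counts["both"],
                self.counts["MAR_only"],
                self.counts["SPR_only"],
                self.counts["none"],
            )
        )

    @property
    def n_discrepancy_blocks(self) -> int:
        return self.n_blocks - self.counts["none"]

    def discrepancy_block_shares(self, ndigits: int = 1) -> Optional[dict[str, float]]:
        """Among blocks with any discrepancy: shares by category, plus
        the share captured by SPRs at all (SPR-only or both).  None when
        no block has a discrepancy."""
        nd = self.n_discrepancy_blocks
        if nd == 0:
            return None
        return {
            "SPR_only": round_half_up(100.0 * self.counts["SPR_only"] / nd, ndigits),
            "MAR_only": round_half_up(100.0 * self.counts["MAR_only"] / nd, ndigits),
            "both": round_half_up(100.0 * self.counts["both"] / nd, ndigits),
            "spr_capture": round_half_up(
                100.0 * (self.counts["SPR_only"] + self.counts["both"]) / nd, ndigits
            ),
        }


def _summarize(
    medication: str,
    n_orders_all: int,
    included_blocks: Sequence[EventBlock],
    n_orders_included: int,
) -> ConcordanceResult:
    counts = {c: 0 for c in CATEGORIES}
    for b in included_blocks:
        if b.category is None:
            raise ValueError("blocks must be classified before summarizing")
        counts[b.category] += 1
    return ConcordanceResult(
        medication=medication,
        n_orders_all=n_orders_all,
        n_orders_included=n_orders_included,
        n_blocks=len(included_blocks),
        n_mar_discrepancies=sum(b.n_mar_discrepant for b in included_blocks),
        n_spr_discrepancies=sum(b.n_spr_discrepant for b in included_blocks),
        counts=counts,
    )


def concordance_summary(
    blocks_by_medication: Mapping[str, Sequence[EventBlock]],
    orders_by_medication: Mapping[str, int],
) -> list[ConcordanceResult]:
    """Build the per-medication concordance table plus an overall row.

    ``blocks_by_medication`` holds *classified* blocks for each
    medication (all blocks; the order-inclusion rule is applied here);
    ``orders_by_medication`` the total order counts per medication.
    The overall row's counts are column sums of the per-medication
    rows, and its kappa is computed from those sums.
    """
    rows: list[ConcordanceResult] = []
    for med in sorted(blocks_by_medication):
        blocks = blocks_by_medication[med]
        by_order: dict[str, list[EventBlock]] = {}
        for b in blocks:
            by_order.setdefault(b.order_id, []).append(b)
        included_ids = {oid for oid, obs in by_order.items() if include_order(obs)}
        included = [b for b in blocks if b.order_id in included_ids]
        rows.append(
            _summarize(med, orders_by_medication.get(med, len(by_order)), included, len(included_ids))
        )
    overall_counts = {c: sum(r.counts[c] for r in rows) for c in CATEGORIES}
    rows.append(
        ConcordanceResult(
            medication="Overall",
            n_orders_all=sum(r.n_orders_all for r in rows),
            n_orders_included=sum(r.n_orders_included for r in rows),
            n_blocks=sum(r.n_blocks for r in rows),
            n_mar_discrepancies=sum(r.n_mar_discrepancies for r in rows),
            n_spr_discrepancies=sum(r.n_spr_discrepancies for r in rows),
            counts=overall_counts,
        )
    )
    return rows
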