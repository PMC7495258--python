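"""End-to-end orchestration and report tables.

``run_streams`` executes the full chain — validity screening, pump-state
filtering, grouping, order linkage, discrepancy detection, event-block
segmentation and concordance — and returns a :class:`ReportBundle` with
the four summary tables:

* validity quadrants (pump records by ID/medication-name validity),
* per-medication discrepancy counts and rates,
* magnitude-of-discrepancy bins per source,
* per-medication block concordance with Cohen's kappa.

On synthetic cohorts, :func:`evaluate_against_ledger` scores the
detector against the generator's ground truth (sensitivity, precision,
magnitude recovery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as plio
from .alignment import LINKAGE_WINDOW_HOURS, align_group, filter_started, group_records
from .concordance import (
    CATEGORIES,
    ConcordanceResult,
    classify_block,
    concordance_summary,
    segment_event_blocks,
)
from .discrepancy import (
    DOSE_RTOL,
    GRACE_MINUTES,
    MOD_BIN_LABELS,
    Discrepancy,
    detect_discrepancies,
    discrepancy_rate,
    mod_bin_counts,
)
from .records import MAREntry, MedicationOrder, OrderEvent, SPREntry, Timeline
from .screen import PatientRegistry, QuadrantTable, ScreenResult, quadrant_table, screen_spr
from .synthetic import GroundTruthLedger
from .utils import round_half_up

log = logging.getLogger("pumplink")


@dataclass(frozen=True)
class PipelineConfig:
    """File-based pipeline configuration."""

    orders_path: str
    order_events_path: str
    mar_path: str
    spr_path: str
    registry_path: str
    drug_library: tuple[str, ...] = ()
    grace_minutes: float = GRACE_MINUTES
    linkage_window_hours: float = LINKAGE_WINDOW_HOURS
    symmetric_window: bool = True
    dose_rtol: float = DOSE_RTOL
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.grace_minutes < 0 or self.linkage_window_hours <= 0:
            raise ValueError("grace and linkage windows must be positive")


@dataclass
class ReportBundle:
    """Everything the pipeline produces for one run."""

    screen_results: list[ScreenResult]
    quadrants: QuadrantTable
    timelines: list[Timeline]
    discrepancies: list[Discrepancy]
    table3: pd.DataFrame
    table4: pd.DataFrame
    concordance: list[ConcordanceResult]
    stage_log: dict = field(default_factory=dict)

    @property
    def overall_kappa(self) -> Optional[float]:
        return self.concordance[-1].kappa if self.concordance else None

    def concordance_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.concordance:
            shares = r.discrepancy_block_shares() or {}
            rows.append(
                {
                    "medication": r.medication,
                    "orders_all": r.n_orders_all,
                    "orders_included": r.n_orders_included,
                    "analysis_blocks": r.n_blocks,
                    "mar_discrepancies": r.n_mar_discrepancies,
                    "spr_discrepancies": r.n_spr_discrepancies,
                    **{f"blocks_{c}": r.counts[c] for c in CATEGORIES},
                    "kappa": (
                        round_half_up(r.kappa, 2) if r.kappa is not None else ""
                    ),
                    "spr_capture_pct": shares.get("spr_capture", ""),
                }
            )
        return pd.DataFrame(rows)


def _screen_all(
    sprs: Sequence[SPREntry],
    registry: PatientRegistry,
    drug_library: Sequence[str],
) -> tuple[list[ScreenResult], list[SPREntry]]:
    results = [screen_spr(s, registry, drug_library) for s in sprs]
    usable = [
        s for s, r in zip(sprs, results) if r.id_valid and r.name_present
    ]
    return results, usable


def _discrepancy_table(
    timelines: Sequence[Timeline],
    discrepancies: Sequence[Discrepancy],
) -> pd.DataFrame:
    """Per-medication administration counts, discrepancy counts and
    rates, with an overall row."""
    meds = sorted({tl.medication for tl in timelines})
    flagged = {(d.source, d.record_id) for d in discrepancies}
    rows = []
    for med in meds + ["Overall"]:
        tls = [tl for tl in timelines if med == "Overall" or tl.medication == med]
        n_orders = sum(len(tl.orders) for tl in tls)
        n_mars = sum(len(tl.mars) for tl in tls)
        n_sprs = sum(len(tl.sprs) for tl in tls)
        n_mar_disc = sum(
            1 for tl in tls for m in tl.mars if ("MAR", m.mar_id) in flagged
        )
        n_spr_disc = sum(
            1 for tl in tls for s in tl.sprs if ("SPR", s.spr_id) in flagged
        )
        rows.append(
            {
                "medication": med,
                "orders": n_orders,
                "mars": n_mars,
                "mar_discrepancies": n_mar_disc,
                "mar_rate_pct": discrepancy_rate(n_mar_disc, n_mars) if n_mars else "",
                "sprs": n_sprs,
                "spr_discrepancies": n_spr_disc,
                "spr_rate_pct": discrepancy_rate(n_spr_disc, n_sprs) if n_sprs else "",
            }
        )
    return pd.DataFrame(rows)


def _mod_table(discrepancies: Sequence[Discrepancy]) -> pd.DataFrame:
    mar = mod_bin_counts(d for d in discrepancies if d.source == "MAR")
    spr = mod_bin_counts(d for d in discrepancies if d.source == "SPR")
    return pd.DataFrame(
        [{"source": "MAR", **mar}, {"source": "SPR", **spr}],
        columns=["source", *MOD_BIN_LABELS],
    )


def run_streams(
    orders: Sequence[MedicationOrder],
    order_events: Sequence[OrderEvent],
    mars: Sequence[MAREntry],
    sprs: Sequence[SPREntry],
    registry: PatientRegistry,
    drug_library: Sequence[str],
    grace_minutes: float = GRACE_MINUTES,
    linkage_window_hours: float = LINKAGE_WINDOW_HOURS,
    symmetric_window: bool = True,
    dose_rtol: float = DOSE_RTOL,
) -> ReportBundle:
    """Execute screen -> filter -> group -> align -> detect -> segment ->
    classify -> summarize on in-memory streams."""
    stage: dict[str, int] = {"sprs_in": len(sprs), "mars_in": len(mars), "orders_in": len(orders)}

    results, usable_sprs = _screen_all(sprs, registry, drug_library)
    stage["sprs_valid"] = len(usable_sprs)
    stage["sprs_excluded_screen"] = len(sprs) - len(usable_sprs)
    if not usable_sprs:
        log.warning("no pump record passed validity screening; report will be partial")
    quadrants = quadrant_table(results) if results else None

    started = filter_started(usable_sprs)
    stage["sprs_started"] = len(started)

    groups = group_records(orders, order_events, mars, started)
    timelines = [
        align_group(g, linkage_window_hours, symmetric_window) for g in groups
    ]
    stage["sprs_linked"] = sum(len(tl.sprs) for tl in timelines)
    stage["sprs_unlinked"] = sum(len(tl.unlinked_sprs) for tl in timelines)

    discrepancies = [
        d for tl in timelines for d in detect_discrepancies(tl, grace_minutes, dose_rtol)
    ]
    stage["discrepancies"] = len(discrepancies)

    blocks_by_med: dict[str, list] = {}
    orders_by_med: dict[str, int] = {}
    for tl in timelines:
        blocks = segment_event_blocks(tl)
        for b in blocks:
            classify_block(b, discrepancies)
        blocks_by_med.setdefault(tl.medication, []).extend(blocks)
        orders_by_med[tl.medication] = orders_by_med.get(tl.medication, 0) + len(tl.orders)
    conc = concordance_summary(blocks_by_med, orders_by_med) if blocks_by_med else []

    for key, value in stage.items():
        log.info("stage %s: %d", key, value)

    return ReportBundle(
        screen_results=results,
        quadrants=quadrants,
        timelines=timelines,
        discrepancies=discrepancies,
        table3=_discrepancy_table(timelines, discrepancies),
        table4=_mod_table(discrepancies),
        concordance=conc,
        stage_log=stage,
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """File-based entry point: read the four streams and the registry,
    run the chain, and (when ``out_dir`` is set) write the report CSVs."""
    orders = plio.read_orders(config.orders_path)
    events = plio.read_order_events(config.order_events_path)
    mars = plio.read_mars(config.mar_path)
    sprs = plio.read_sprs(config.spr_path)
    registry = plio.read_registry(config.registry_path)
    library = config.drug_library or tuple(sorted({o.medication for o in orders}))
    bundle = run_streams(
        orders, events, mars, sprs, registry, library,
        grace_minutes=config.grace_minutes,
        linkage_window_hours=config.linkage_window_hours,
        symmetric_window=config.symmetric_window,
        dose_rtol=config.dose_rtol,
    )
    if config.out_dir:
        write_report(bundle, config.out_dir)
    return bundle


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.quadrants is not None:
        q = bundle.quadrants
        pct = q.percentages()
        pd.DataFrame(
            {
                "quadrant": ["ID+ name+", "ID- name+", "ID+ name-", "ID- name-"],
                "n": [q.n_id_name, q.n_noid_name, q.n_id_noname, q.n_noid_noname],
                "pct_of_total": list(pct),
            }
        ).to_csv(out / "table1_validity.csv", index=False)
    bundle.table3.to_csv(out / "table3_discrepancy_rates.csv", index=False)
    bundle.table4.to_csv(out / "table4_mod_bins.csv", index=False)
    bundle.concordance_frame().to_csv(out / "table5_concordance.csv", index=False)
    pd.DataFrame(
        [
            {
                "record_id": d.record_id,
                "source": d.source,
                "timestamp": d.timestamp.strftime(plio.TIME_FORMAT),
                "administered": d.administered,
                "reference": d.reference,
                "mod_percent": d.mod_percent,
                "mod_bin": d.mod_bin,
                "documentation_only": d.documentation_only,
            }
            for d in bundle.discrepancies
        ],
        columns=[
            "record_id", "source", "timestamp", "administered", "reference",
            "mod_percent", "mod_bin", "documentation_only",
        ],
    ).to_csv(out / "discrepancies.csv", index=False)


@dataclass(frozen=True)
class LedgerEvaluation:
    """Detector performance against the generator's ground truth.

    Ratios are None when their denominator is zero (undefined, not 0).
    ``max_mod_error`` is the largest relative magnitude-recovery error
    over matched detections (absolute error where the injected
    magnitude is 0)."""

    n_injected: int
    n_detected: int
    n_matched: int

    @property
    def sensitivity(self) -> Optional[float]:
        return self.n_matched / self.n_injected if self.n_injected else None

    @property
    def precision(self) -> Optional[float]:
        return self.n_matched / self.n_detected if self.n_detected else None

    max_mod_error: Optional[float] = None
    all_late_documentation_only: Optional[bool] = None


def evaluate_against_ledger(
    bundle: ReportBundle, ledger: GroundTruthLedger
) -> LedgerEvaluation:
    """Score detected discrepancies against injected ones by record id."""
    injected = {e.record_id: e for e in ledger.dose_entries()}
    detected = {d.record_id: d for d in bundle.discrepancies}
    if len(detected) != len(bundle.discrepancies):
        raise ValueError("duplicate record ids among detected discrepancies")
    matched = sorted(set(injected) & set(detected))
    max_err: Optional[float] = None
    late_doc_flags = []
    for rid in matched:
        inj, det = injected[rid], detected[rid]
        denom = abs(inj.mod_percent) if inj.mod_percent else 1.0
        err = abs(det.mod_percent - inj.mod_percent) / denom
        max_err = err if max_err is None else max(max_err, err)
        if inj.source == "LATE_ORDER":
            late_doc_flags.append(det.documentation_only)
    return LedgerEvaluation(
        n_injected=len(injected),
        n_detected=len(detected),
        n_matched=len(matched),
        max_mod_error=max_err,
        all_late_documentation_only=(all(late_doc_flags) if late_doc_flags else None),
    )
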