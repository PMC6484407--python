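"""PSI quantification and differential alternative-splicing calls.

PSI (percent spliced in) = 100 * inclusion / (inclusion + exclusion)
junction reads. Differential splicing between two conditions is scored
with a Beta-posterior model: counts are pooled within condition, each
condition's inclusion fraction gets a Beta(inc + 1, exc + 1) posterior
(uniform prior), and Monte-Carlo draws of dPSI = PSI_B - PSI_A give a
point estimate (posterior median) and the directional posterior
probability p_dir. An event is called UP/DOWN when |dPSI| >= 10 and
p_dir >= 0.95 (both configurable).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    CALL_DOWN,
    CALL_NOT_TESTABLE,
    CALL_UNCHANGED,
    CALL_UP,
    DiffSpliceResult,
    SpliceEvent,
)

__all__ = [
    "compute_psi",
    "filter_events",
    "diff_splice",
    "diff_splice_all",
    "summarize_calls",
    "FilterReport",
    "events_to_frame",
    "frame_to_events",
    "results_to_frame",
]

DPSI_THRESHOLD = 10.0
P_MIN = 0.95
MIN_READS_IR = 15
MIN_READS_OTHER = 10
BALANCE_FOLD = 5.0


def compute_psi(inclusion: float, exclusion: float) -> float | None:
    """PSI = 100 * inc / (inc + exc); None (not testable) on zero total."""
    if inclusion < 0 or exclusion < 0:
        raise ValueError("read counts must be non-negative")
    total = inclusion + exclusion
    if total == 0:
        return None
    return 100.0 * inclusion / total


@dataclass(frozen=True)
class FilterReport:
    kept: list[SpliceEvent]
    dropped: dict[str, str]  # event_id -> reason


def filter_events(
    events: list[SpliceEvent],
    *,
    min_reads_ir: int = MIN_READS_IR,
    min_reads_other: int = MIN_READS_OTHER,
    balance_fold: float = BALANCE_FOLD,
) -> FilterReport:
    """Drop events with poor coverage or unbalanced inclusion junctions.

    Intron-retention events need >= ``min_reads_ir`` reads in every
    compared sample; all other classes need >= ``min_reads_other`` total
    reads per sample. Cassette/microexon events whose two inclusion
    junctions (when provided separately) differ by more than
    ``balance_fold``-fold in any sample are dropped.
    """
    kept, dropped = [], {}
    for ev in events:
        reason = None
        min_reads = min_reads_ir if ev.event_type == "IR" else min_reads_other
        for s in ev.samples:
            total = s.inc + s.exc
            if total < min_reads:
                reason = f"coverage {total} < {min_reads} reads in sample {s.sample}"
                break
            if (
                ev.event_type in ("CE", "MIC")
                and s.inc1 is not None
                and s.inc2 is not None
                and min(s.inc1, s.inc2) * balance_fold < max(s.inc1, s.inc2)
            ):
                reason = f"inclusion junctions unbalanced (> {balance_fold:g}-fold) in sample {s.sample}"
                break
        if reason is None:
            kept.append(ev)
        else:
            dropped[ev.event_id] = reason
    return FilterReport(kept=kept, dropped=dropped)


def diff_splice(
    event: SpliceEvent,
    cond_a: str,
    cond_b: str,
    *,
    n_mc: int = 10_000,
    seed: int = 0,
    dpsi_threshold: float = DPSI_THRESHOLD,
    p_min: float = P_MIN,
) -> DiffSpliceResult:
    """Beta-posterior differential-splicing call for one event.

    Counts are pooled within each condition; dPSI draws come from
    independent Beta(inc + 1, exc + 1) posteriors. The point estimate is
    the posterior median and p_dir the posterior probability that dPSI
    shares its sign. Deterministic given ``seed``.
    """
    if n_mc < 1_000:
        raise ValueError("n_mc must be >= 1000")
    inc_a, exc_a = event.counts(cond_a)
    inc_b, exc_b = event.counts(cond_b)
    psi_a = compute_psi(inc_a, exc_a)
    psi_b = compute_psi(inc_b, exc_b)
    if psi_a is None or psi_b is None:
        return DiffSpliceResult(event.event_id, event.event_type, event.gene_id,
                                psi_a, psi_b, None, None, CALL_NOT_TESTABLE)
    rng = np.random.default_rng(seed)
    draws_a = rng.beta(inc_a + 1, exc_a + 1, size=n_mc)
    draws_b = rng.beta(inc_b + 1, exc_b + 1, size=n_mc)
    dpsi_draws = 100.0 * (draws_b - draws_a)
    dpsi = float(np.median(dpsi_draws))
    if dpsi == 0.0:
        p_dir = 0.5
    else:
        p_dir = float(np.mean(np.sign(dpsi_draws) == np.sign(dpsi)))
    call = CALL_UNCHANGED
    if abs(dpsi) >= dpsi_threshold and p_dir >= p_min:
        call = CALL_UP if dpsi > 0 else CALL_DOWN
    return DiffSpliceResult(event.event_id, event.event_type, event.gene_id,
                            psi_a, psi_b, dpsi, p_dir, call)


def diff_splice_all(
    events: list[SpliceEvent],
    cond_a: str,
    cond_b: str,
    *,
    n_mc: int = 10_000,
    seed: int = 0,
    dpsi_threshold: float = DPSI_THRESHOLD,
    p_min: float = P_MIN,
    apply_filter: bool = True,
) -> list[DiffSpliceResult]:
    """Filter, then score every event; per-event seeds derive from ``seed``."""
    if apply_filter:
        events = filter_events(events).kept
    seeds = np.random.SeedSequence(seed).generate_state(len(events)) % (2**31)
    return [
        diff_splice(ev, cond_a, cond_b, n_mc=n_mc, seed=int(s),
                    dpsi_threshold=dpsi_threshold, p_min=p_min)
        for ev, s in zip(events, seeds)
    ]


def summarize_calls(
    results: list[DiffSpliceResult],
    *,
    fdr: bool = False,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """UP/DOWN call counts per event class.

    With ``fdr`` on, Benjamini-Hochberg is applied to the complements of
    p_dir across all testable events and only calls surviving at
    ``fdr_alpha`` are counted (the optional FDR mode; when off, the
    dPSI/p_dir double criterion alone defines calls).
    """
    rows = []
    if fdr and results:
        from statsmodels.stats.multitest import multipletests

        testable = [r for r in results if r.p_dir is not None]
        pvals = np.array([1.0 - r.p_dir for r in testable])
        reject = (
            multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")[0]
            if len(pvals)
            else np.array([], dtype=bool)
        )
        survives = {r.event_id for r, ok in zip(testable, reject) if ok}
    for r in results:
        call = r.call
        if fdr and call in (CALL_UP, CALL_DOWN) and r.event_id not in survives:
            call = CALL_UNCHANGED
        rows.append((r.event_type, call))
    table = (
        pd.DataFrame(rows, columns=["event_type", "call"])
        .groupby(["event_type", "call"])
        .size()
        .unstack(fill_value=0)
        if rows
        else pd.DataFrame()
    )
    for col in (CALL_UP, CALL_DOWN, CALL_UNCHANGED, CALL_NOT_TESTABLE):
        if col not in table.columns:
            table[col] = 0
    return table[[CALL_UP, CALL_DOWN, CALL_UNCHANGED, CALL_NOT_TESTABLE]].sort_index()


# ---------------------------------------------------------------------------
# TSV serialization (one row per event x sample)
# ---------------------------------------------------------------------------

def events_to_frame(events: list[SpliceEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        for s in ev.samples:
            rows.append({
                "event_id": ev.event_id, "gene_id": ev.gene_id, "type": ev.event_type,
                "sample": s.sample, "condition": s.condition,
                "inc_reads": s.inc, "exc_reads": s.exc,
                "chrom": ev.chrom if ev.chrom is not None else ".",
                "seg_start": ev.seg_start if ev.seg_start is not None else -1,
                "seg_end": ev.seg_end if ev.seg_end is not None else -1,
            })
    return pd.DataFrame(rows)


def frame_to_events(df: pd.DataFrame) -> list[SpliceEvent]:
    from .models import SampleCounts

    events = []
    for event_id, grp in df.groupby("event_id", sort=True):
        first = grp.iloc[0]
        seg_start = int(first["seg_start"]) if "seg_start" in grp.columns else -1
        seg_end = int(first["seg_end"]) if "seg_end" in grp.columns else -1
        events.append(
            SpliceEvent(
                event_id=str(event_id),
                gene_id=str(first["gene_id"]),
                event_type=str(first["type"]),
                samples=[
                    SampleCounts(sample=str(r["sample"]), condition=str(r["condition"]),
                                 inc=int(r["inc_reads"]), exc=int(r["exc_reads"]))
                    for _, r in grp.iterrows()
                ],
                chrom=None if first.get("chrom", ".") == "." else str(first["chrom"]),
                seg_start=None if seg_start < 0 else seg_start,
                seg_end=None if seg_end < 0 else seg_end,
            )
        )
    return events


def results_to_frame(results: list[DiffSpliceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": r.event_id, "event_type": r.event_type, "gene_id": r.gene_id,
            "psi_a": r.psi_a, "psi_b": r.psi_b, "dpsi": r.dpsi,
            "p_dir": r.p_dir, "call": r.call,
        }
        for r in results
    )
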