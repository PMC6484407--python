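"""Kinetic-coupling characterizations downstream of the rate and
splicing analyses: exon/intron length statistics of rate-sensitive
exons, motif RNA maps with permutation significance, dPSI-vs-expression
regression, gene-length sliding-window downregulation curves, and
gene-set overlap tests.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionRecord

__all__ = [
    "length_stats",
    "rna_map",
    "RnaMap",
    "dpsi_expression_correlation",
    "length_sliding_window",
    "overlap_fisher",
    "OverlapResult",
    "iupac_to_regex",
]

RNA_MAP_REGIONS = ("upstream_intron", "exon", "downstream_intron")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def iupac_to_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC nucleotide motif into an overlap-safe regex."""
    if not motif:
        raise ValueError("motif must be non-empty")
    try:
        body = "".join(_IUPAC[c] for c in motif.upper().replace("U", "T"))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in motif") from exc
    return re.compile(f"(?=({body}))")


# ---------------------------------------------------------------------------
# exon / intron length statistics
# ---------------------------------------------------------------------------

def length_stats(
    groups: Mapping[str, pd.DataFrame],
    background: str,
    features: Sequence[str] = ("exon_length", "upstream_intron_length", "downstream_intron_length"),
) -> pd.DataFrame:
    """Compare exon/flanking-intron lengths of event groups to background.

    ``groups`` maps a group name (e.g. "included", "skipped",
    "unchanged") to a frame with one row per event and the feature
    columns. For every non-background group and feature, reports group
    and background medians and quartiles plus the two-sided
    Mann-Whitney p (tie-corrected normal approximation; identical
    groups give p = 1).
    """
    if background not in groups:
        raise ValueError(f"background group {background!r} missing")
    for name, df in groups.items():
        if len(df) == 0:
            raise ValueError(f"group {name!r} is empty")
        if len(df) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 events")
    bg = groups[background]
    rows = []
    for name, df in groups.items():
        if name == background:
            continue
        for feat in features:
            a = df[feat].to_numpy(dtype=float)
            b = bg[feat].to_numpy(dtype=float)
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                             method="asymptotic", use_continuity=False).pvalue)
            rows.append({
                "group": name, "feature": feat, "n": len(a),
                "median": float(np.median(a)), "q1": float(np.quantile(a, 0.25)),
                "q3": float(np.quantile(a, 0.75)),
                "background_median": float(np.median(b)),
                "mw_p": min(p, 1.0),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNA maps
# ---------------------------------------------------------------------------

@dataclass
class RnaMap:
    """Positional motif-coverage profiles around regulated vs control exons.

    For each region, ``coverage[group]`` is the smoothed per-position
    fraction of events whose motif match covers that position;
    ``p_values`` are one-sided permutation p-values for enrichment of
    the regulated group over the control group, and ``significant``
    masks positions with p below the significance level (default 0.1,
    drawn as a bold line in the conventional display).
    """

    motif: str
    window: int
    regions: tuple[str, ...]
    coverage: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    p_values: dict[str, np.ndarray] = field(default_factory=dict)
    significant: dict[str, np.ndarray] = field(default_factory=dict)
    n_perm: int = 0
    p_mask: float = 0.1


def _motif_coverage_matrix(seqs: Sequence[str], pattern: re.Pattern, extent: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-event boolean coverage (events x positions) and position validity."""
    cov = np.zeros((len(seqs), extent), dtype=float)
    valid = np.zeros((len(seqs), extent), dtype=bool)
    for i, seq in enumerate(seqs):
        seq = seq[:extent].upper()
        valid[i, : len(seq)] = True
        for m in pattern.finditer(seq):
            lo = m.start()
            hi = min(lo + len(m.group(1)), extent)
            cov[i, lo:hi] = 1.0
    return cov, valid


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean along the last axis (edge-shrunk window)."""
    if window <= 1:
        return x
    kernel = np.ones(window)
    norm = np.convolve(np.ones(x.shape[-1]), kernel, mode="same")
    if x.ndim == 1:
        return np.convolve(x, kernel, mode="same") / norm
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), -1, x) / norm


def rna_map(
    groups: Mapping[str, Sequence[Mapping[str, str]]],
    motif: str,
    *,
    regulated: str,
    control: str,
    window: int = 31,
    n_perm: int = 1_000,
    flank: int = 200,
    exon_extent: int = 50,
    p_mask: float = 0.1,
    seed: int = 0,
) -> RnaMap:
    """Motif RNA map with pointwise permutation significance.

    ``groups`` maps a group name to its events, each a mapping of region
    name ("upstream_intron", "exon", "downstream_intron") to sequence.
    Intron flanks are analyzed over ``flank`` nt and exons truncated to
    ``exon_extent`` nt; positions beyond a shorter sequence are excluded
    from that event's denominator. Per position, coverage fraction =
    share of events whose motif match covers the position, smoothed by a
    centered running mean of ``window`` nt. Pointwise one-sided p-values
    come from permuting event-group labels between the regulated and
    control groups (statistic: smoothed regulated minus control
    coverage); p = (1 + #{perm >= obs}) / (n_perm + 1), so p is in (0, 1].
    """
    pattern = iupac_to_regex(motif)
    if n_perm < 500:
        raise ValueError("n_perm must be >= 500")
    for name in (regulated, control):
        if name not in groups:
            raise ValueError(f"group {name!r} missing")
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs >= 2 events")

    result = RnaMap(motif=motif, window=window, regions=RNA_MAP_REGIONS,
                    n_perm=n_perm, p_mask=p_mask)
    rng = np.random.default_rng(seed)
    for region in RNA_MAP_REGIONS:
        extent = exon_extent if region == "exon" else flank
        if len(motif) > extent:
            raise ValueError(f"motif longer than the {region} analysis extent ({extent} nt)")
        mats, valids, labels = [], [], []
        per_group_cov: dict[str, np.ndarray] = {}
        for name, events in groups.items():
            seqs = [ev.get(region, "") for ev in events]
            cov, valid = _motif_coverage_matrix(seqs, pattern, extent)
            with np.errstate(invalid="ignore"):
                frac = np.where(valid.sum(0) > 0, cov.sum(0) / np.maximum(valid.sum(0), 1), 0.0)
            per_group_cov[name] = _smooth(frac, window)
            if name in (regulated, control):
                mats.append(cov)
                valids.append(valid)
                labels.extend([name] * len(seqs))
        result.coverage[region] = per_group_cov

        cov = np.vstack(mats)
        valid = np.vstack(valids)
        labels = np.array(labels)
        is_reg = labels == regulated

        def group_diff(mask: np.ndarray) -> np.ndarray:
            def frac(sel: np.ndarray) -> np.ndarray:
                denom = np.maximum(valid[sel].sum(0), 1)
                return cov[sel].sum(0) / denom
            return _smooth(frac(mask) - frac(~mask), window)

        obs = group_diff(is_reg)
        exceed = np.zeros(extent)
        for _ in range(n_perm):
            exceed += group_diff(rng.permutation(is_reg)) >= obs
        pvals = (1.0 + exceed) / (n_perm + 1.0)
        result.p_values[region] = pvals
        result.significant[region] = pvals < p_mask
    return result


# ---------------------------------------------------------------------------
# dPSI vs expression change
# ---------------------------------------------------------------------------

def dpsi_expression_correlation(
    table: pd.DataFrame,
    *,
    class_column: str = "change_class",
    dpsi_column: str = "dpsi",
    log2fc_column: str = "log2fc",
) -> pd.DataFrame:
    """Least-squares regression of dPSI on log2FC per change class.

    ``table`` holds one row per event joined to its gene's expression
    change, with a class label (e.g. "changed_DE", "changed_AS",
    "both"). Classes with fewer than 3 events are skipped. Reports
    slope, intercept, r, r^2 and regression p per class; a class with
    zero dPSI variance reports r^2 = 0.
    """
    rows = []
    for cls, grp in table.groupby(class_column, sort=True):
        x = grp[log2fc_column].to_numpy(dtype=float)
        y = grp[dpsi_column].to_numpy(dtype=float)
        if len(grp) < 3:
            continue
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            rows.append({"change_class": cls, "n": len(grp), "slope": 0.0,
                         "intercept": float(np.mean(y)), "r": 0.0, "r2": 0.0, "p": 1.0})
            continue
        fit = stats.linregress(x, y)
        rows.append({
            "change_class": cls, "n": len(grp),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue), "r2": float(fit.rvalue**2), "p": float(fit.pvalue),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-length sliding-window downregulation
# ---------------------------------------------------------------------------

def length_sliding_window(
    records: Iterable[ExpressionRecord] | pd.DataFrame,
    window: int = 100,
) -> pd.DataFrame:
    """Fraction of downregulated genes in sliding windows of genes by length.

    Genes are sorted by length (ascending); each contiguous window of
    ``window`` genes contributes one row with the window's median gene
    length and the fraction of its genes called DOWN. Returns
    N - window + 1 rows.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["gene_id", "length", "direction"]].copy()
    else:
        df = pd.DataFrame(
            {"gene_id": r.gene_id, "length": r.length, "direction": r.direction}
            for r in records
        )
    if df["length"].isna().any():
        raise ValueError("every gene needs a length")
    n = len(df)
    if n < window:
        raise ValueError(f"need at least {window} genes, got {n}")
    df = df.sort_values(["length", "gene_id"], kind="mergesort").reset_index(drop=True)
    lengths = df["length"].to_numpy(dtype=float)
    down = (df["direction"] == "DOWN").to_numpy(dtype=float)
    kernel = np.ones(window)
    frac = np.convolve(down, kernel, mode="valid") / window
    medians = np.array([np.median(lengths[i:i + window]) for i in range(n - window + 1)])
    return pd.DataFrame({"median_length": medians, "frac_down": frac})


# ---------------------------------------------------------------------------
# gene-set overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap table with Fisher's exact test."""

    in_query_in_annot: int
    in_query_not_annot: int
    not_query_in_annot: int
    not_query_not_annot: int
    odds_ratio: float  # sample odds ratio ad/bc; inf when bc = 0
    p_value: float
    degenerate: bool = False

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.in_query_in_annot, self.in_query_not_annot),
                (self.not_query_in_annot, self.not_query_not_annot))


def overlap_fisher(query: set[str], annotation: set[str], universe: set[str]) -> OverlapResult:
    """Two-sided Fisher's exact test for overlap of two gene sets.

    Both sets must be subsets of the universe. The 2x2 table is emitted
    alongside the statistics; a degenerate table (zero off-diagonal
    margin, e.g. query = annotation = universe) is flagged, with the
    odds ratio reported as inf and p = 1.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query, annotation, universe = set(query), set(annotation), set(universe)
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not annotation <= universe:
        raise ValueError("annotation is not a subset of the universe")
    a = len(query & annotation)
    b = len(query - annotation)
    c = len(annotation - query)
    d = len(universe - query - annotation)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    degenerate = b * c == 0
    if degenerate:
        odds = float("inf") if a * d > 0 else float("nan")
    return OverlapResult(a, b, c, d, float(odds), float(p), degenerate)
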