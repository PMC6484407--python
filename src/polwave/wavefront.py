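"""Wave-front detection and elongation-rate estimation.

The transcription wave-front at harvest time t is the farthest
TSS-distal position reached by labeled nascent RNA. It is located by an
exact maximum-likelihood scan of a two-segment constant-mean Poisson
model over the binned profile: upstream of the breakpoint the signal is
high (transcribed since release), downstream it is background. The
per-gene elongation rate follows from the front's progression between
harvest times.
"""
from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping

import numpy as np
from scipy import stats

from .models import (
    QC_FRONT_AT_GENE_END,
    QC_LOW_COVERAGE,
    QC_NONE_DETECTED,
    QC_OK,
    BinnedCoverage,
    GeneRate,
    RateComparison,
    WaveFront,
)

__all__ = [
    "detect_front",
    "estimate_rate",
    "common_genes",
    "compare_rates",
    "correlate_rate_expression",
]

logger = logging.getLogger(__name__)


def _segment_loglik(total: float, n_bins: int) -> float:
    """Poisson profile log-likelihood of a segment at its ML mean.

    Up to terms constant in the breakpoint: C * log(C / m), with the
    0 * log 0 = 0 convention for empty segments.
    """
    if total <= 0:
        return 0.0
    return total * np.log(total / n_bins)


def two_segment_scan(counts: np.ndarray) -> tuple[int, float]:
    """Exact ML breakpoint of the two-segment constant-mean Poisson model.

    Returns (k, gain): the low segment starts at index k (1 <= k <= n-1)
    and gain is the log-likelihood improvement over the one-segment fit.
    Ties resolve to the smallest k (most conservative front). The
    breakpoint depends only on the profile's shape: scaling all counts
    by a constant does not move it.
    """
    x = np.asarray(counts, dtype=float)
    n = len(x)
    csum = np.cumsum(x)
    total = csum[-1]
    ks = np.arange(1, n)
    c1 = csum[:-1]
    c2 = total - c1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(c1 > 0, c1 * np.log(c1 / ks), 0.0) + np.where(
            c2 > 0, c2 * np.log(c2 / (n - ks)), 0.0
        )
    best = int(np.argmax(ll))  # first occurrence = smallest k on ties
    gain = float(ll[best] - _segment_loglik(total, n))
    return int(ks[best]), gain


def detect_front(
    profile: BinnedCoverage,
    *,
    scan_start: int = 1_000,
    min_reads: float = 50.0,
    epsilon: float = 0.25,
) -> WaveFront:
    """Locate the transcription wave-front in one binned profile.

    Bins before ``scan_start`` bp are excluded from the scan so the
    promoter-proximal signal present already at t = 0 cannot masquerade
    as a front. The ML breakpoint must leave the downstream segment mean
    at most ``epsilon`` times the upstream mean, otherwise no front is
    called; a breakpoint at the final bin means the wave may have run
    off the gene end. The reported position is the TSS-relative
    downstream edge of the last high bin.
    """
    bs = profile.bin_size
    s0 = int(np.ceil(scan_start / bs))
    x = profile.counts[s0:]
    n = len(x)

    def flagged(flag: str) -> WaveFront:
        return WaveFront(profile.gene_id, profile.time, None, 0.0, flag)

    if n < 4:
        return flagged(QC_LOW_COVERAGE)
    total = float(x.sum())
    if total <= 0 or total < min_reads:
        return flagged(QC_LOW_COVERAGE)

    k, gain = two_segment_scan(x)
    mu1 = x[:k].sum() / k
    mu2 = x[k:].sum() / (n - k)
    if mu2 > epsilon * mu1:
        return flagged(QC_NONE_DETECTED)
    if k == n - 1:
        return flagged(QC_FRONT_AT_GENE_END)
    position = float((s0 + k) * bs)
    gene_length_bound = profile.n_bins * bs
    position = min(position, float(gene_length_bound))
    return WaveFront(profile.gene_id, profile.time, position, gain, QC_OK)


def estimate_rate(
    fronts: Iterable[WaveFront],
    *,
    genotype: str = "",
    method: str = "two-point",
) -> GeneRate | None:
    """Per-gene elongation rate (bases/min) from its wave-fronts.

    two-point: v = (x_t2 - x_t1) / (t2 - t1) over the earliest and
    latest qc-passing times (the 5/15-min design gives exactly two).
    regression: least-squares slope of position on time (>= 3 points).
    Genes whose fronts do not strictly increase with time are excluded
    (returns None, reason logged) — never reported as rate 0.
    """
    ok = sorted((f for f in fronts if f.ok), key=lambda f: f.time)
    if len(ok) < 2:
        logger.info("rate excluded: fewer than 2 qc-passing fronts")
        return None
    gene_id = ok[0].gene_id
    times = np.array([f.time for f in ok])
    pos = np.array([f.position for f in ok])
    if np.any(np.diff(pos) <= 0):
        logger.info("%s: fronts not strictly increasing with time; gene excluded", gene_id)
        return None
    if method == "two-point":
        rate = (pos[-1] - pos[0]) / (times[-1] - times[0])
        used = (float(times[0]), float(times[-1]))
    elif method == "regression":
        if len(ok) < 3:
            logger.info("%s: regression needs >= 3 time points; gene excluded", gene_id)
            return None
        rate = float(np.polyfit(times, pos, 1)[0])
        used = tuple(float(t) for t in times)
    else:
        raise ValueError(f"unknown method {method!r}")
    if rate <= 0:
        logger.info("%s: non-positive fitted rate; gene excluded", gene_id)
        return None
    return GeneRate(gene_id=gene_id, genotype=genotype, rate=float(rate),
                    times_used=used, method=method)


def common_genes(rates_by_genotype: Mapping[str, Iterable[str | GeneRate]]) -> set[str]:
    """Genes with qc-passing rates in every genotype (set intersection)."""
    sets = []
    for genotype, items in rates_by_genotype.items():
        ids = {it.gene_id if isinstance(it, GeneRate) else str(it) for it in items}
        sets.append(ids)
    if not sets:
        raise ValueError("no genotypes provided")
    common = set.intersection(*sets)
    if not common:
        raise ValueError("no genes are common to all genotypes")
    return common


def compare_rates(
    rates_a: Iterable[float | GeneRate],
    rates_b: Iterable[float | GeneRate],
    *,
    label_a: str = "A",
    label_b: str = "B",
) -> RateComparison:
    """Two-sided Mann-Whitney comparison of two genotype rate sets.

    Normal approximation with tie correction and no continuity
    correction, so identical groups give p = 1. Degenerate all-tied
    input (zero variance) also reports p = 1, with a warning.
    """
    a = np.array([r.rate if isinstance(r, GeneRate) else float(r) for r in rates_a])
    b = np.array([r.rate if isinstance(r, GeneRate) else float(r) for r in rates_b])
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 rates per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all rates tied across both groups; Mann-Whitney p set to 1")
        u, p = len(a) * len(b) / 2.0, 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        u, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return RateComparison(
        label_a=label_a, label_b=label_b, n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        u_statistic=u, p_value=p,
    )


def correlate_rate_expression(rates: np.ndarray, expression: np.ndarray) -> dict:
    """Correlation of per-gene elongation rate with mean expression.

    Reports Spearman rho, Pearson r, r^2 and both p-values; genome-scale
    analyses of this kind yield tiny coefficients with small p, so both
    r and r^2 are emitted rather than adjudicating between them.
    """
    rates = np.asarray(rates, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if len(rates) != len(expression):
        raise ValueError("rates and expression must be paired")
    if len(rates) < 3:
        raise ValueError("need at least 3 paired records")
    rho, p_rho = stats.spearmanr(rates, expression)
    r, p_r = stats.pearsonr(rates, expression)
    return {
        "n": len(rates),
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
        "pearson_r": float(r),
        "pearson_r2": float(r**2),
        "pearson_p": float(p_r),
    }
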