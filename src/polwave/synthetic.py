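"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the DRB-release / 4sU-pulse nascent-RNA assay:
transcription is blocked with DRB (initiated RNAPII stalls promoter-
proximally), the block is released at t = 0, cells are pulsed with 4sU
for the last ``pulse_length`` minutes before each harvest, and the
labeled (nascent) RNA is sequenced. At harvest time t the labeled
signal of a gene transcribed at v bases/min extends to the wave front
at v*t; detecting that front at two times yields the per-gene
elongation rate.

Two polymerase populations contribute labeled RNA:

* the *released cohort* — polymerases that accumulated at the promoter-
  proximal pause during the DRB block and depart together at release.
  Each cohort transcript is labeled over the positions synthesized
  during the pulse window, so the cohort contributes a uniform band
  ending sharply at v*t (the wave front). At t = 0 the cohort is still
  sitting at the promoter, which is why the 0-min profile is confined
  to a narrow promoter-proximal zone.
* *post-release initiation* — polymerases initiated at constant rate
  after release, contributing a trapezoidal occupancy profile that also
  ends at v*t.

``cohort_weight`` sets the fraction of labeled reads contributed by the
released cohort (default 0.7); the sharp band edge it creates is what
makes the front detectable by changepoint methods, mirroring the real
assay.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import (
    BinnedCoverage,
    ExpressionRecord,
    GeneModel,
    QpcrSeries,
    SampleCounts,
    SpliceEvent,
)

__all__ = [
    "RatePreset",
    "PulseDesign",
    "LengthEffectPreset",
    "WT_RATE",
    "SLOW_RATE",
    "WT_FRONT",
    "SLOW_FRONT",
    "NEURON_LENGTH_EFFECT",
    "PRESETS",
    "make_genes",
    "draw_rates",
    "expected_wave_profile",
    "simulate_wave_coverage",
    "WaveCoverageSim",
    "simulate_qpcr_timecourse",
    "simulate_junction_counts",
    "simulate_expression",
]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatePreset:
    """A genotype-level distribution of per-gene elongation rates (bases/min).

    rate_law:
      constant           — every gene at ``mean``
      lognormal          — log-normal with the given arithmetic mean and
                           log-scale sigma
      lognormal-mixture  — mixture of log-normal components, each given
                           by (weight, component arithmetic mean)
    """

    name: str
    rate_law: str
    mean: float
    sigma: float = 0.0
    components: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.rate_law not in ("constant", "lognormal", "lognormal-mixture"):
            raise ValueError(f"unknown rate law {self.rate_law!r}")
        if self.mean <= 0:
            raise ValueError("mean rate must be strictly positive")
        if self.rate_law == "lognormal-mixture":
            if not self.components:
                raise ValueError("mixture preset needs components")
            w = sum(c[0] for c in self.components)
            if abs(w - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
            if any(c[1] <= 0 for c in self.components):
                raise ValueError("component means must be positive")


#: Wild-type genome-wide rates: bimodal, overall mean 2,450 bases/min.
#: Component means 1,500 and 3,400 (equal weights) are the 1,500/3,400
#: medians scaled by exp(-sigma^2/2) so the mixture mean is exactly 2,450.
WT_RATE = RatePreset(
    "wt_rate", "lognormal-mixture", mean=2450.0, sigma=0.35,
    components=((0.5, 1500.0), (0.5, 3400.0)),
)

#: Slow-mutant rates: unimodal, mean 1,780 bases/min, narrower spread.
SLOW_RATE = RatePreset("slow_rate", "lognormal", mean=1780.0, sigma=0.15)

#: Constant-rate presets for front-recovery scenarios. 2,200 b/min puts
#: the noise-free 5-min front at 11 kb; 1,780 b/min puts the 15-min
#: front at 26.7 kb (the matched harvest-time front positions).
WT_FRONT = RatePreset("wt_front", "constant", mean=2200.0)
SLOW_FRONT = RatePreset("slow_front", "constant", mean=1780.0)

PRESETS = {p.name: p for p in (WT_RATE, SLOW_RATE, WT_FRONT, SLOW_FRONT)}


@dataclass(frozen=True)
class PulseDesign:
    """DRB-release harvest schedule and 4sU labeling window."""

    harvest_times: tuple[float, ...] = (0.0, 5.0, 15.0)  # minutes after release
    pulse_length: float = 10.0                            # minutes of 4sU before harvest
    depth: float = 50.0                                   # expected reads per labeled kb

    def __post_init__(self) -> None:
        if self.pulse_length <= 0:
            raise ValueError("pulse_length must be positive")
        times = np.asarray(self.harvest_times, dtype=float)
        if np.any(times < 0):
            raise ValueError("harvest times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("harvest times must be strictly increasing")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass(frozen=True)
class LengthEffectPreset:
    """Monotone probability that a gene is downregulated, vs gene length.

    Linear in log10(length) through the two anchors — probability
    ``p_short`` at ``short_bp``, reaching the asymptotic ``p_long`` at
    ``long_bp`` — then flat at ``p_long`` beyond; below the short
    anchor the same slope continues (clipped at 0).
    """

    p_short: float = 0.40
    short_bp: float = 10_000.0
    p_long: float = 0.80
    long_bp: float = 1_000_000.0

    def __post_init__(self) -> None:
        for p in (self.p_short, self.p_long):
            if not 0.0 <= p <= 1.0:
                raise ValueError("anchor probabilities must be in [0, 1]")
        if self.p_long < self.p_short:
            raise ValueError("p_down must be non-decreasing in length")
        if not 0 < self.short_bp < self.long_bp:
            raise ValueError("anchor lengths must satisfy 0 < short < long")

    def p_down(self, length_bp) -> np.ndarray:
        length_bp = np.asarray(length_bp, dtype=float)
        frac = (np.log10(length_bp) - math.log10(self.short_bp)) / (
            math.log10(self.long_bp) - math.log10(self.short_bp)
        )
        frac = np.minimum(frac, 1.0)
        return np.clip(self.p_short + (self.p_long - self.p_short) * frac, 0.0, 1.0)


#: Neuron-like length effect: ~40% of 10-kb genes down, >80% of very long genes.
NEURON_LENGTH_EFFECT = LengthEffectPreset()


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------

def make_genes(
    n: int,
    *,
    length_median: float = 30_000.0,
    length_sigma: float = 1.0,
    min_length: int = 2_000,
    max_length: int = 2_500_000,
    chrom: str = "chrS1",
    gap: int = 10_000,
    seed: int = 0,
) -> list[GeneModel]:
    """Sample a non-overlapping gene universe with log-normal lengths.

    Lengths are drawn log-normal (median ``length_median``, log-sigma
    ``length_sigma``) and clipped to [min_length, max_length]; genes are
    laid end-to-end on one synthetic chromosome with ``gap`` bp between
    them, strands assigned at random. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = length_median * np.exp(length_sigma * rng.standard_normal(n))
    lengths = np.clip(np.round(lengths).astype(int), min_length, max_length)
    strands = rng.choice(["+", "-"], size=n)
    genes = []
    pos = gap
    width = len(str(n))
    for i in range(n):
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:0{width}d}",
                chrom=chrom,
                strand=str(strands[i]),
                start=pos,
                end=pos + int(lengths[i]),
            )
        )
        pos += int(lengths[i]) + gap
    return genes


def draw_rates(preset: RatePreset, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n per-gene elongation rates (bases/min) from a preset."""
    if preset.rate_law == "constant":
        return np.full(n, preset.mean)
    if preset.rate_law == "lognormal":
        mu = math.log(preset.mean) - preset.sigma**2 / 2  # arithmetic mean = preset.mean
        return rng.lognormal(mu, preset.sigma, size=n)
    weights = np.array([c[0] for c in preset.components])
    means = np.array([c[1] for c in preset.components])
    comp = rng.choice(len(weights), size=n, p=weights)
    mu = np.log(means[comp]) - preset.sigma**2 / 2
    return rng.lognormal(mu, preset.sigma)


# ---------------------------------------------------------------------------
# 4sU-DRB wave coverage
# ---------------------------------------------------------------------------

def _initiation_occupancy_integral(x: np.ndarray, v: float, t: float, pulse: float) -> np.ndarray:
    """Integral_0^x of min(t - u/v, pulse) du, for x within [0, v*t].

    min(t - u/v, pulse) is the labeled-occupancy density at position u
    contributed by constant-rate initiation since release: a polymerase
    initiated at time s covers u iff it passed u after the pulse began
    and before harvest, which happens for a window of initiation times
    of width min(t - u/v, pulse).
    """
    x = np.asarray(x, dtype=float)
    x_flat = v * max(t - pulse, 0.0)  # positions synthesized before the pulse window ends
    lo = np.minimum(x, x_flat)
    out = pulse * lo
    hi = np.clip(x, x_flat, v * t)
    out = out + t * (hi - x_flat) - (hi**2 - x_flat**2) / (2.0 * v)
    return out


def expected_wave_profile(
    length: int,
    v: float,
    t: float,
    *,
    pulse: float = 10.0,
    bin_size: int = 500,
    depth: float = 50.0,
    cohort_weight: float = 0.7,
    promoter_zone: int = 1_000,
) -> np.ndarray:
    """Expected labeled-read counts per TSS-relative bin at harvest time t.

    Expected total reads = depth * (labeled extent in kb). At t = 0 the
    signal is uniform over the promoter-proximal zone. At t > 0 the
    profile mixes the released-cohort band, uniform on
    [v*(t - pulse), v*t], with the post-release initiation trapezoid on
    [0, v*t]; both are truncated at the gene end. Front = min(v*t, length).
    """
    if v <= 0:
        raise ValueError("rate must be positive")
    if bin_size < 100:
        raise ValueError("bin_size must be >= 100 bp")
    if length < bin_size:
        raise ValueError(f"gene of {length} bp is shorter than one {bin_size} bp bin")
    if not 0.0 <= cohort_weight <= 1.0:
        raise ValueError("cohort_weight must be in [0, 1]")

    n_bins = math.ceil(length / bin_size)
    edges = np.minimum(np.arange(n_bins + 1, dtype=float) * bin_size, length)
    expected = np.zeros(n_bins)

    if t == 0:
        zone = min(promoter_zone, length)
        total = depth * zone / 1000.0
        overlap = np.clip(edges[1:], 0, zone) - np.clip(edges[:-1], 0, zone)
        return total * overlap / zone

    front = min(v * t, float(length))
    total = depth * front / 1000.0

    # post-release initiation component (trapezoid, truncated at gene end)
    occ = _initiation_occupancy_integral(np.clip(edges, 0, v * t), v, t, pulse)
    occ_bins = np.diff(occ)
    occ_norm = occ[-1]

    # released-cohort band, truncated at gene end
    band_lo = min(v * max(t - pulse, 0.0), float(length))
    band_hi = front
    w = cohort_weight
    if band_hi - band_lo <= 0:
        # cohort has run off the gene end: transcripts completed, left the
        # nascent pool; renormalize onto the initiation component alone
        w = 0.0
        band_frac = np.zeros(n_bins)
    else:
        overlap = np.clip(edges[1:], band_lo, band_hi) - np.clip(edges[:-1], band_lo, band_hi)
        band_frac = overlap / (band_hi - band_lo)

    if occ_norm > 0:
        expected = total * (w * band_frac + (1.0 - w) * occ_bins / occ_norm)
    else:
        expected = total * band_frac
    return expected


@dataclass
class WaveCoverageSim:
    """Result of simulate_wave_coverage: profiles plus generative truth."""

    genes: list[GeneModel]
    preset: RatePreset
    design: PulseDesign
    bin_size: int
    coverages: dict[tuple[str, float], BinnedCoverage] = field(default_factory=dict)
    true_rates: dict[str, float] = field(default_factory=dict)

    def profile(self, gene_id: str, time: float) -> BinnedCoverage:
        return self.coverages[(gene_id, time)]


def simulate_wave_coverage(
    genes: list[GeneModel],
    preset: RatePreset,
    design: PulseDesign = PulseDesign(),
    *,
    bin_size: int = 500,
    noise: bool = True,
    cohort_weight: float = 0.7,
    promoter_zone: int = 1_000,
    seed: int = 0,
) -> WaveCoverageSim:
    """Simulate binned nascent coverage for every gene x harvest time.

    Per-gene true rates are drawn from ``preset``; expected profiles
    follow :func:`expected_wave_profile`; with ``noise`` the bin counts
    are independent Poisson draws of the expectations, otherwise the
    exact expectations are returned. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rates = draw_rates(preset, len(genes), rng)
    sim = WaveCoverageSim(genes=list(genes), preset=preset, design=design, bin_size=bin_size)
    for gene, v in zip(genes, rates):
        sim.true_rates[gene.gene_id] = float(v)
        for t in design.harvest_times:
            expected = expected_wave_profile(
                gene.length,
                float(v),
                float(t),
                pulse=design.pulse_length,
                bin_size=bin_size,
                depth=design.depth,
                cohort_weight=cohort_weight,
                promoter_zone=promoter_zone,
            )
            counts = rng.poisson(expected).astype(float) if noise else expected
            sim.coverages[(gene.gene_id, float(t))] = BinnedCoverage(
                gene_id=gene.gene_id,
                time=float(t),
                genotype=preset.name,
                bin_size=bin_size,
                counts=counts,
                library_size=None,
            )
    return sim


# ---------------------------------------------------------------------------
# qPCR time courses
# ---------------------------------------------------------------------------

def simulate_qpcr_timecourse(
    v_kb_min: float,
    junction_distances_kb: list[float],
    times_min: list[float],
    *,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    gene_id: str = "gene",
    plateau: float = 1.0,
    rise_time: float = 0.0,
    seed: int = 0,
) -> list[QpcrSeries]:
    """Simulate DRB-release pre-mRNA qPCR series, one per junction.

    The signal at a junction d kb from the TSS is zero until the wave
    front crosses it at d / v minutes, then steps to ``plateau`` (or
    rises exponentially with time constant ``rise_time`` when > 0).
    Multiplicative Gaussian noise of SD ``noise_sd`` is applied per
    replicate and values are clipped at zero.
    """
    if v_kb_min <= 0:
        raise ValueError("elongation rate must be strictly positive")
    times = np.asarray(times_min, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for j, d in enumerate(junction_distances_kb):
        if d <= 0:
            raise ValueError("junction distances must be positive")
        t_cross = d / v_kb_min
        clean = np.where(times >= t_cross, plateau, 0.0)
        if rise_time > 0:
            dt = np.maximum(times - t_cross, 0.0)
            clean = np.where(times >= t_cross, plateau * (1.0 - np.exp(-dt / rise_time)), 0.0)
        reps = clean[:, None] * np.clip(
            1.0 + noise_sd * rng.standard_normal((len(times), n_replicates)), 0.0, None
        )
        out.append(
            QpcrSeries(
                gene_id=gene_id,
                junction=f"j{j + 1}",
                distance_kb=float(d),
                times=times,
                values=reps.mean(axis=1),
                replicate_values=reps,
            )
        )
    return out


# ---------------------------------------------------------------------------
# splice-junction counts
# ---------------------------------------------------------------------------

def simulate_junction_counts(
    n_events: int,
    *,
    psi_base: float | tuple[float, float] | None = None,
    dpsi_true: float | np.ndarray = 0.0,
    depth: int = 200,
    replicates: int = 3,
    cond_a: str = "WT",
    cond_b: str = "slow",
    event_types: tuple[str, ...] = ("CE", "MIC", "Alt5", "Alt3", "IR"),
    type_probs: tuple[float, ...] = (0.5, 0.1, 0.1, 0.1, 0.2),
    seed: int = 0,
) -> list[SpliceEvent]:
    """Simulate inclusion/exclusion junction counts for paired conditions.

    Per sample, inclusion reads ~ Binomial(depth, PSI/100) and exclusion
    reads are the remainder, with ``replicates`` samples per condition
    (default 3, the usual biological-replicate design). ``psi_base`` may
    be a scalar, a (lo, hi) uniform range, or None for the default
    uniform range clipped so PSI and PSI + dPSI stay within [5, 95].
    Each event stores its true dPSI for recovery tests.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    dpsi = np.broadcast_to(np.asarray(dpsi_true, dtype=float), (n_events,)).copy()

    if psi_base is None:
        lo = np.maximum(5.0, 5.0 - dpsi)
        hi = np.minimum(95.0, 95.0 - dpsi)
        if np.any(lo > hi):
            raise ValueError("dpsi_true leaves no feasible base PSI in [5, 95]")
        base = rng.uniform(lo, hi)
    elif isinstance(psi_base, tuple):
        base = rng.uniform(psi_base[0], psi_base[1], size=n_events)
    else:
        base = np.full(n_events, float(psi_base))
    if np.any((base < 0) | (base > 100)) or np.any((base + dpsi < 0) | (base + dpsi > 100)):
        raise ValueError("PSI and PSI + dPSI must lie within [0, 100]")

    types = rng.choice(event_types, size=n_events, p=type_probs)
    events = []
    for i in range(n_events):
        etype = str(types[i])
        seg_len = int(rng.integers(3, 28)) if etype == "MIC" else int(rng.integers(28, 300))
        samples = []
        for cond, psi in ((cond_a, base[i]), (cond_b, base[i] + dpsi[i])):
            for r in range(replicates):
                inc = int(rng.binomial(depth, psi / 100.0))
                samples.append(
                    SampleCounts(sample=f"{cond}_r{r + 1}", condition=cond, inc=inc, exc=depth - inc)
                )
        events.append(
            SpliceEvent(
                event_id=f"ev{i + 1:05d}",
                gene_id=f"g{i + 1:05d}",
                event_type=etype,
                samples=samples,
                chrom="chrS1",
                seg_start=1000,
                seg_end=1000 + seg_len,
                true_dpsi=float(dpsi[i]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# expression tables with a length-dependent downregulation effect
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: list[GeneModel],
    effect: LengthEffectPreset = NEURON_LENGTH_EFFECT,
    *,
    logfc_down_mean: float = 1.0,
    logfc_down_sd: float = 0.4,
    p_up: float = 0.05,
    logfc_null_sd: float = 0.15,
    seed: int = 0,
) -> list[ExpressionRecord]:
    """Simulate a differential-expression table over a gene universe.

    Each gene is flagged DOWN with probability p_down(length) from the
    preset; DOWN genes get a negative log2FC, a further ``p_up``
    fraction of the remainder get a positive log2FC (UP), everything
    else is unchanged. The true DOWN flag is stored for recovery tests.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    rng = np.random.default_rng(seed)
    lengths = np.array([g.length for g in genes], dtype=float)
    p_down = effect.p_down(lengths)
    down = rng.random(len(genes)) < p_down
    up = (~down) & (rng.random(len(genes)) < p_up)
    mean_expr = rng.lognormal(3.0, 1.0, size=len(genes))

    records = []
    for i, g in enumerate(genes):
        if down[i]:
            lfc = -abs(rng.normal(logfc_down_mean, logfc_down_sd))
            direction, sig = "DOWN", True
        elif up[i]:
            lfc = abs(rng.normal(logfc_down_mean, logfc_down_sd))
            direction, sig = "UP", True
        else:
            lfc = rng.normal(0.0, logfc_null_sd)
            direction, sig = "none", False
        records.append(
            ExpressionRecord(
                gene_id=g.gene_id,
                mean_expr=float(mean_expr[i]),
                log2fc=float(lfc),
                significant=sig,
                direction=direction,
                length=g.length,
                true_down=bool(down[i]),
            )
        )
    return records
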