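"""Core domain types shared across the pipeline.

Coordinate convention: internally every interval is 0-based half-open
(BED style). GTF output/input converts to/from 1-based closed. All
positions inside a gene are expressed relative to the TSS and increase
in the direction of transcription, regardless of strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "BinnedCoverage",
    "WaveFront",
    "GeneRate",
    "RateComparison",
    "QpcrSeries",
    "SpliceEvent",
    "SampleCounts",
    "DiffSpliceResult",
    "ExpressionRecord",
]

EVENT_TYPES = ("CE", "MIC", "Alt5", "Alt3", "IR")
#: cassette exons at or below this alternative-segment length are microexons
MICROEXON_MAX_NT = 27


@dataclass(frozen=True)
class GeneModel:
    """A gene's coordinates; the frame for all TSS-relative positions."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based, inclusive
    end: int    # exclusive

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start} >= {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    def to_tss_relative(self, genomic_start: int, genomic_end: int) -> tuple[int, int]:
        """Map a genomic half-open interval onto TSS-relative offsets."""
        if self.strand == "+":
            return genomic_start - self.start, genomic_end - self.start
        return self.end - genomic_end, self.end - genomic_start


@dataclass
class BinnedCoverage:
    """Per-gene nascent-read signal in fixed-width TSS-relative bins.

    ``counts[0]`` is the bin at the TSS; bins increase in the direction
    of transcription. Counts are integers when drawn with Poisson noise
    and floats (exact expectations, or bedGraph area) otherwise.
    """

    gene_id: str
    time: float            # minutes after DRB release
    genotype: str
    bin_size: int
    counts: np.ndarray
    library_size: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_size < 1:
            raise ValueError("bin_size must be positive")
        if np.any(self.counts < 0):
            raise ValueError("bin counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def cpm(self) -> np.ndarray:
        """Counts per million mapped reads (requires library_size)."""
        if not self.library_size:
            raise ValueError("library_size is required for CPM normalization")
        return self.counts * 1e6 / self.library_size


# qc_flag values for WaveFront
QC_OK = "ok"
QC_LOW_COVERAGE = "low_coverage"
QC_FRONT_AT_GENE_END = "front_at_gene_end"
QC_NONE_DETECTED = "none_detected"


@dataclass(frozen=True)
class WaveFront:
    """Detected transcription wave-front for one gene at one harvest time."""

    gene_id: str
    time: float
    position: float | None   # bp from TSS; None when not detected
    loglik_gain: float        # two-segment vs one-segment Poisson fit
    qc_flag: str

    @property
    def ok(self) -> bool:
        return self.qc_flag == QC_OK


@dataclass(frozen=True)
class GeneRate:
    """Per-gene elongation rate in bases/min."""

    gene_id: str
    genotype: str
    rate: float
    times_used: tuple[float, ...]
    method: str  # "two-point" or "regression"


@dataclass(frozen=True)
class RateComparison:
    """Genotype-level rate comparison (Mann-Whitney, two-sided)."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    u_statistic: float
    p_value: float


@dataclass
class QpcrSeries:
    """DRB-release qPCR time course at one exon-intron junction.

    Values are pre-mRNA levels relative to untreated cells; ``values``
    holds the per-time replicate means.
    """

    gene_id: str
    junction: str
    distance_kb: float
    times: np.ndarray
    values: np.ndarray
    replicate_values: np.ndarray | None = None  # shape (n_times, n_reps)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distance_kb <= 0:
            raise ValueError("junction distance must be positive")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")


@dataclass(frozen=True)
class SampleCounts:
    """Inclusion/exclusion junction reads for one sample of one event.

    ``inc1``/``inc2`` optionally carry the two inclusion junctions of a
    cassette exon separately (used by the junction-balance filter).
    """

    sample: str
    condition: str
    inc: int
    exc: int
    inc1: int | None = None
    inc2: int | None = None

    def __post_init__(self) -> None:
        if self.inc < 0 or self.exc < 0:
            raise ValueError("junction counts must be non-negative")


@dataclass
class SpliceEvent:
    """An alternative-splicing event with per-sample junction counts."""

    event_id: str
    gene_id: str
    event_type: str
    samples: list[SampleCounts] = field(default_factory=list)
    # coordinates of the alternative segment (0-based half-open), optional
    chrom: str | None = None
    seg_start: int | None = None
    seg_end: int | None = None
    true_dpsi: float | None = None  # generator truth, for recovery tests

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if (
            self.event_type == "MIC"
            and self.seg_start is not None
            and self.seg_end is not None
            and self.seg_end - self.seg_start > MICROEXON_MAX_NT
        ):
            raise ValueError("microexon alternative segment must be <= 27 nt")

    def counts(self, condition: str) -> tuple[int, int]:
        """Pooled (inclusion, exclusion) reads across samples of a condition."""
        inc = sum(s.inc for s in self.samples if s.condition == condition)
        exc = sum(s.exc for s in self.samples if s.condition == condition)
        return inc, exc

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen


# call values for DiffSpliceResult
CALL_UP = "UP"
CALL_DOWN = "DOWN"
CALL_UNCHANGED = "unchanged"
CALL_NOT_TESTABLE = "not_testable"


@dataclass(frozen=True)
class DiffSpliceResult:
    """Differential-splicing call for one event between two conditions.

    dPSI = PSI_B - PSI_A (point estimate: posterior median); p_dir is
    the posterior probability that dPSI shares the sign of its point
    estimate. UP means higher inclusion in condition B.
    """

    event_id: str
    event_type: str
    gene_id: str
    psi_a: float | None
    psi_b: float | None
    dpsi: float | None
    p_dir: float | None
    call: str


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression summary used by the length-bias statistics."""

    gene_id: str
    mean_expr: float
    log2fc: float            # slow vs WT
    significant: bool        # FDR < 0.05 in the upstream DE analysis
    direction: str           # "UP", "DOWN" or "none"
    length: int | None = None
    true_down: bool | None = None  # generator truth

    def __post_init__(self) -> None:
        if self.direction not in ("UP", "DOWN", "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.significant and self.direction == "DOWN" and self.log2fc > 0:
            raise ValueError("DOWN direction inconsistent with positive log2FC")
        if self.significant and self.direction == "UP" and self.log2fc < 0:
            raise ValueError("UP direction inconsistent with negative log2FC")


def genes_to_frame(genes: Sequence[GeneModel]):
    """Tabulate GeneModels (columns: gene_id, chrom, strand, start, end, length, tss)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "length": [g.length for g in genes],
            "tss": [g.tss for g in genes],
        }
    )
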