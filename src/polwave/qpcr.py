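"""Elongation rates from DRB-release qPCR time courses.

Pre-mRNA at an exon-intron junction d kb downstream of the TSS stays at
baseline until the released transcription wave crosses it at d / v
minutes; the rate follows from the first time point at which the signal
is detected.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .models import QpcrSeries

__all__ = [
    "detection_time",
    "rate_from_junction",
    "gene_rate_qpcr",
    "JunctionRate",
    "GeneQpcrRate",
    "series_to_frame",
    "frame_to_series",
]


def detection_time(series: QpcrSeries, threshold_fraction: float = 0.5) -> float | None:
    """Earliest sampled time at which the signal reaches the threshold.

    The plateau is estimated as the mean of the final two time points;
    detection is the first sampled time whose value is at or above
    ``threshold_fraction`` x plateau (no interpolation — the assay
    reports sampled times). Returns None ("undetected") when the series
    never crosses, including flat-zero series.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    plateau = float(np.mean(series.values[-2:]))
    if plateau <= 0:
        return None
    hit = np.nonzero(series.values >= threshold_fraction * plateau)[0]
    if len(hit) == 0:
        return None
    return float(series.times[hit[0]])


@dataclass(frozen=True)
class JunctionRate:
    """Elongation rate inferred from one junction (kb/min)."""

    junction: str
    distance_kb: float
    detection_min: float
    rate: float           # unrounded, kept for downstream computation
    rate_reported: float  # rounded half-up to one decimal, as printed

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.junction}: {self.rate_reported} kb/min ({self.distance_kb} kb @ {self.detection_min} min)"


def _round1(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def rate_from_junction(distance_kb: float, detection_min: float, junction: str = "") -> JunctionRate:
    """v = distance / detection time, with half-up one-decimal reporting."""
    if distance_kb <= 0:
        raise ValueError("distance must be positive")
    if detection_min <= 0:
        raise ValueError("detection time must be positive")
    rate = distance_kb / detection_min
    return JunctionRate(
        junction=junction, distance_kb=float(distance_kb),
        detection_min=float(detection_min), rate=rate, rate_reported=_round1(rate),
    )


@dataclass(frozen=True)
class GeneQpcrRate:
    """Per-gene qPCR rate summary.

    ``distal_rate`` is the rate at the most TSS-distal detectable
    junction (the default per-gene value); ``mean_rate`` averages the
    detectable junction rates. Both are labeled so downstream consumers
    know which convention they use.
    """

    gene_id: str
    distal_rate: JunctionRate
    mean_rate: float
    mean_rate_reported: float
    junction_rates: tuple[JunctionRate, ...]


def gene_rate_qpcr(
    series_list: list[QpcrSeries],
    threshold_fraction: float = 0.5,
) -> GeneQpcrRate:
    """Per-gene elongation rate from that gene's qPCR junction series.

    Junctions never reaching the detection threshold are skipped; at
    least one detectable junction is required.
    """
    if not series_list:
        raise ValueError("no qPCR series provided")
    gene_id = series_list[0].gene_id
    rates = []
    for series in series_list:
        t = detection_time(series, threshold_fraction)
        if t is None:
            continue
        rates.append(rate_from_junction(series.distance_kb, t, junction=series.junction))
    if not rates:
        raise ValueError(f"{gene_id}: no junction reaches the detection threshold")
    distal = max(rates, key=lambda r: r.distance_kb)
    mean_rate = float(np.mean([r.rate for r in rates]))
    return GeneQpcrRate(
        gene_id=gene_id, distal_rate=distal,
        mean_rate=mean_rate, mean_rate_reported=_round1(mean_rate),
        junction_rates=tuple(rates),
    )


# ---------------------------------------------------------------------------
# TSV serialization: gene_id, junction, distance_kb, time_min, replicate, value
# ---------------------------------------------------------------------------

def series_to_frame(series_list: list[QpcrSeries]):
    import pandas as pd

    rows = []
    for s in series_list:
        reps = s.replicate_values
        if reps is None:
            reps = s.values[:, None]
        for i, t in enumerate(s.times):
            for r in range(reps.shape[1]):
                rows.append({
                    "gene_id": s.gene_id, "junction": s.junction,
                    "distance_kb": s.distance_kb, "time_min": float(t),
                    "replicate": r + 1, "value": float(reps[i, r]),
                })
    return pd.DataFrame(rows)


def frame_to_series(df) -> list[QpcrSeries]:
    series = []
    for (gene_id, junction, distance), grp in df.groupby(
        ["gene_id", "junction", "distance_kb"], sort=True
    ):
        wide = grp.pivot_table(index="time_min", columns="replicate", values="value")
        wide = wide.sort_index()
        series.append(
            QpcrSeries(
                gene_id=str(gene_id), junction=str(junction), distance_kb=float(distance),
                times=wide.index.to_numpy(dtype=float),
                values=wide.mean(axis=1).to_numpy(dtype=float),
                replicate_values=wide.to_numpy(dtype=float),
            )
        )
    return series
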