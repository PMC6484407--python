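"""Reading/writing the standard genomic formats and TSS-relative binning.

Internal coordinates are 0-based half-open everywhere. GTF is converted
from/to its native 1-based closed convention at the file boundary; BED
and bedGraph are already 0-based half-open.
"""
from __future__ import annotations

import math
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .models import BinnedCoverage, GeneModel

__all__ = [
    "read_genes",
    "write_genes_bed",
    "write_genes_gtf",
    "read_bedgraph",
    "write_bedgraph",
    "bin_coverage",
    "bins_to_frame",
    "frame_to_bins",
]

_GTF_COLUMNS = [
    "chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attributes",
]
_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene records from a GTF or BED file (dialect by extension).

    GTF: keeps ``gene`` feature lines, converting 1-based closed
    coordinates to the internal convention. BED6: used as-is. Malformed
    lines raise with their line number; an empty file returns an empty
    list with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff"):
        return _read_gtf(path)
    if suffix == ".bed":
        return _read_bed(path)
    raise ValueError(f"unsupported annotation extension {suffix!r} (expected .gtf/.gff/.bed)")


def _read_gtf(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(parts)}")
            if parts[2] != "gene":
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: zero/negative-length feature")
            m = _GENE_ID_RE.search(parts[8])
            if not m:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            genes.append(
                GeneModel(gene_id=m.group(1), chrom=parts[0], strand=parts[6],
                          start=start1 - 1, end=end1)
            )
    if not genes:
        warnings.warn(f"no gene records found in {path}")
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: zero/negative-length feature")
            genes.append(
                GeneModel(gene_id=parts[3], chrom=parts[0], strand=parts[5],
                          start=start, end=end)
            )
    if not genes:
        warnings.warn(f"no gene records found in {path}")
    return genes


def write_genes_bed(genes: list[GeneModel], path: str | Path) -> None:
    """Write genes as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_genes_gtf(genes: list[GeneModel], path: str | Path, source: str = "polwave") -> None:
    """Write genes as GTF (1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame (chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    """Write a (chrom, start, end, value) frame as bedGraph."""
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def bin_coverage(
    coverage: pd.DataFrame | str | Path,
    gene: GeneModel,
    bin_size: int = 500,
    *,
    time: float = 0.0,
    genotype: str = "",
    library_size: float | None = None,
) -> BinnedCoverage:
    """Bin bedGraph coverage over a gene into TSS-relative bins.

    The binned signal is the area (value x overlapped bp) of the
    coverage intervals within each bin; an interval partially
    overlapping a bin contributes proportionally to the overlap length.
    Overlapping input intervals are summed. For minus-strand genes bin 0
    is anchored at the TSS (the gene's genomic end), so profiles always
    increase in the direction of transcription. A gene on a chromosome
    absent from the coverage yields an all-zero profile with a warning.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    if isinstance(coverage, (str, Path)):
        coverage = read_bedgraph(coverage)

    n_bins = math.ceil(gene.length / bin_size)
    counts = np.zeros(n_bins)
    sub = coverage[coverage["chrom"] == gene.chrom]
    if sub.empty:
        warnings.warn(f"chromosome {gene.chrom!r} absent from coverage; empty profile for {gene.gene_id}")
    else:
        starts = np.maximum(sub["start"].to_numpy(), gene.start)
        ends = np.minimum(sub["end"].to_numpy(), gene.end)
        values = sub["value"].to_numpy()
        keep = ends > starts
        for s, e, val in zip(starts[keep], ends[keep], values[keep]):
            lo, hi = gene.to_tss_relative(int(s), int(e))
            b0, b1 = lo // bin_size, (hi - 1) // bin_size
            for b in range(b0, b1 + 1):
                ov = min(hi, (b + 1) * bin_size) - max(lo, b * bin_size)
                counts[b] += val * ov
    return BinnedCoverage(
        gene_id=gene.gene_id, time=time, genotype=genotype,
        bin_size=bin_size, counts=counts, library_size=library_size,
    )


def bins_to_frame(profiles: list[BinnedCoverage]) -> pd.DataFrame:
    """Long-format table of binned profiles (one row per gene x time x bin)."""
    rows = []
    for p in profiles:
        for i, c in enumerate(p.counts):
            rows.append((p.gene_id, p.time, p.genotype, p.bin_size, i, c))
    return pd.DataFrame(rows, columns=["gene_id", "time", "genotype", "bin_size", "bin", "count"])


def frame_to_bins(df: pd.DataFrame) -> list[BinnedCoverage]:
    """Inverse of :func:`bins_to_frame`."""
    out = []
    for (gene_id, time, genotype, bin_size), grp in df.groupby(
        ["gene_id", "time", "genotype", "bin_size"], sort=True
    ):
        grp = grp.sort_values("bin")
        out.append(
            BinnedCoverage(
                gene_id=str(gene_id), time=float(time), genotype=str(genotype),
                bin_size=int(bin_size), counts=grp["count"].to_numpy(),
            )
        )
    return out


def coverage_to_bedgraph(profile: BinnedCoverage, gene: GeneModel) -> pd.DataFrame:
    """Map a TSS-relative binned profile back to genomic bedGraph intervals.

    Values are per-bp densities (count / bin span), so re-binning with
    :func:`bin_coverage` recovers the original bin counts exactly.
    """
    rows = []
    n = profile.n_bins
    for i, c in enumerate(profile.counts):
        lo = i * profile.bin_size
        hi = min((i + 1) * profile.bin_size, gene.length)
        if c == 0:
            continue
        if gene.strand == "+":
            gs, ge = gene.start + lo, gene.start + hi
        else:
            gs, ge = gene.end - hi, gene.end - lo
        rows.append((gene.chrom, gs, ge, c / (hi - lo)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)
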