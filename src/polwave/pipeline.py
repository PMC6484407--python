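"""End-to-end orchestration: configuration, staged synthetic runs,
run manifests and summary reports.

``run_all`` executes simulate -> bin -> wavefront -> qpcr -> splice ->
coupling in dependency order on synthetic inputs, writing one TSV per
stage plus a machine-readable manifest. Outputs are pure functions of
the configuration (seeds included), so a repeated run is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import coupling as cp
from . import genome_io as gio
from . import qpcr as qp
from . import splicing as sp
from . import synthetic as syn
from . import wavefront as wf
from .models import genes_to_frame

__all__ = ["RunConfig", "run_all", "report", "PipelineError"]

logger = logging.getLogger(__name__)

STAGE_OUTPUTS = {
    "simulate": ["genes.gtf", "genes.bed"],
    "bin": ["bins.tsv"],
    "wavefront": ["fronts.tsv", "rates.tsv", "rate_comparison.tsv"],
    "qpcr": ["qpcr_series.tsv", "rates_qpcr.tsv"],
    "splice": ["splice_events.tsv", "diff_splice.tsv", "as_summary.tsv"],
    "coupling": ["expression.tsv", "length_bias.tsv"],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed or its prerequisites are missing."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the analysis' standard values.

    The thresholds (dPSI >= 10, p_min 0.95, qPCR detection at 50% of
    plateau, IR coverage >= 15 reads, 100-gene sliding window) are the
    analysis constants; the synthetic sizes are chosen to keep a full
    run fast while leaving every stage statistically exercised.
    """

    # synthetic gene universe / coverage
    n_genes: int = 20
    genotypes: tuple[str, ...] = ("wt_rate", "slow_rate")
    bin_size: int = 500
    harvest_times: tuple[float, ...] = (0.0, 5.0, 15.0)
    pulse_length: float = 10.0
    depth: float = 50.0
    length_median: float = 120_000.0
    length_sigma: float = 0.4
    min_gene_length: int = 60_000
    max_gene_length: int = 300_000
    # wave-front detection
    scan_start: int = 1_000
    min_reads: float = 50.0
    epsilon: float = 0.25
    # qPCR stage
    qpcr_threshold: float = 0.5
    qpcr_rates_kb_min: tuple[float, ...] = (3.325, 1.478)
    qpcr_distances_kb: tuple[float, ...] = (20.0, 133.0)
    qpcr_times_min: tuple[float, ...] = tuple(float(t) for t in range(0, 130, 10))
    qpcr_noise_sd: float = 0.05
    # splicing stage
    n_events: int = 60
    event_depth: int = 200
    event_replicates: int = 3
    dpsi_threshold: float = 10.0
    p_min: float = 0.95
    min_reads_ir: int = 15
    min_reads_other: int = 10
    n_mc: int = 2_000
    # coupling stage
    n_expression_genes: int = 600
    window: int = 100
    # seeds
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.n_genes >= 1, "n_genes must be >= 1"),
            (self.bin_size >= 100, "bin_size must be >= 100 bp"),
            (self.pulse_length > 0, "pulse_length must be positive"),
            (self.depth > 0, "depth must be positive"),
            (0 <= self.dpsi_threshold <= 100, "dpsi_threshold must be within [0, 100]"),
            (0.5 < self.p_min <= 1.0, "p_min must be within (0.5, 1]"),
            (0 < self.qpcr_threshold <= 1.0, "qpcr_threshold must be within (0, 1]"),
            (self.min_reads_ir >= 0, "min_reads_ir must be non-negative"),
            (self.min_reads_other >= 0, "min_reads_other must be non-negative"),
            (self.window >= 1, "window must be >= 1"),
            (self.n_mc >= 1_000, "n_mc must be >= 1000"),
            (self.n_expression_genes >= self.window,
             "n_expression_genes must be at least the window size"),
            (len(self.harvest_times) >= 2, "need at least two harvest times"),
            (all(g in syn.PRESETS for g in self.genotypes),
             f"genotypes must be among {sorted(syn.PRESETS)}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full synthetic pipeline into ``out_dir``.

    Stages run in dependency order; any failure raises PipelineError
    naming the stage. The manifest records the package version, config
    (with hash), derived seeds, and the outputs of every stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ["genes", "coverage", "qpcr", "events", "diff", "expression"],
        _seeds(config.seed, 6),
    ))

    stage = "simulate"
    try:
        genes = syn.make_genes(
            config.n_genes,
            length_median=config.length_median, length_sigma=config.length_sigma,
            min_length=config.min_gene_length, max_length=config.max_gene_length,
            seed=seeds["genes"],
        )
        gio.write_genes_gtf(genes, out / "genes.gtf")
        gio.write_genes_bed(genes, out / "genes.bed")
        design = syn.PulseDesign(config.harvest_times, config.pulse_length, config.depth)
        sims = {}
        for i, name in enumerate(config.genotypes):
            sims[name] = syn.simulate_wave_coverage(
                genes, syn.PRESETS[name], design,
                bin_size=config.bin_size, noise=True,
                seed=seeds["coverage"] + i,
            )

        stage = "bin"
        # round-trip through bedGraph to exercise the genomic I/O path
        gene_by_id = {g.gene_id: g for g in genes}
        profiles = []
        for name, sim in sims.items():
            for t in config.harvest_times:
                frames = [
                    gio.coverage_to_bedgraph(sim.profile(g.gene_id, float(t)), g)
                    for g in genes
                ]
                bg = pd.concat(frames, ignore_index=True).sort_values(["chrom", "start"])
                path = out / f"coverage_{name}_t{t:g}.bedgraph"
                gio.write_bedgraph(bg, path)
                cov = gio.read_bedgraph(path)
                for g in genes:
                    profiles.append(gio.bin_coverage(
                        cov, g, config.bin_size, time=float(t), genotype=name,
                    ))
        gio.bins_to_frame(profiles).to_csv(out / "bins.tsv", sep="\t", index=False)

        stage = "wavefront"
        fronts_rows, rates = [], {name: [] for name in config.genotypes}
        by_key = {(p.genotype, p.gene_id, p.time): p for p in profiles}
        for name in config.genotypes:
            for g in genes:
                gene_fronts = []
                for t in config.harvest_times:
                    f = wf.detect_front(
                        by_key[(name, g.gene_id, float(t))],
                        scan_start=config.scan_start,
                        min_reads=config.min_reads, epsilon=config.epsilon,
                    )
                    gene_fronts.append(f)
                    fronts_rows.append({
                        "genotype": name, "gene_id": g.gene_id, "time": f.time,
                        "position": f.position if f.position is not None else "",
                        "loglik_gain": f.loglik_gain, "qc_flag": f.qc_flag,
                    })
                rate = wf.estimate_rate(
                    [f for f in gene_fronts if f.time > 0], genotype=name,
                )
                if rate is not None:
                    rates[name].append(rate)
        pd.DataFrame(fronts_rows).to_csv(out / "fronts.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"genotype": r.genotype, "gene_id": r.gene_id, "rate_b_min": r.rate,
             "method": r.method, "times_used": ",".join(f"{t:g}" for t in r.times_used),
             "true_rate_b_min": sims[r.genotype].true_rates[r.gene_id]}
            for name in config.genotypes for r in rates[name]
        ).to_csv(out / "rates.tsv", sep="\t", index=False)
        comp_rows = []
        names = list(config.genotypes)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if len(rates[names[i]]) >= 3 and len(rates[names[j]]) >= 3:
                    c = wf.compare_rates(rates[names[i]], rates[names[j]],
                                         label_a=names[i], label_b=names[j])
                    comp_rows.append(dataclasses.asdict(c))
        pd.DataFrame(comp_rows).to_csv(out / "rate_comparison.tsv", sep="\t", index=False)

        stage = "qpcr"
        all_series = []
        for i, v in enumerate(config.qpcr_rates_kb_min):
            all_series.extend(syn.simulate_qpcr_timecourse(
                v, list(config.qpcr_distances_kb), list(config.qpcr_times_min),
                noise_sd=config.qpcr_noise_sd, gene_id=f"qgene{i + 1}",
                seed=seeds["qpcr"] + i,
            ))
        qp.series_to_frame(all_series).to_csv(out / "qpcr_series.tsv", sep="\t", index=False)
        qpcr_rows = []
        by_gene: dict[str, list] = {}
        for s in all_series:
            by_gene.setdefault(s.gene_id, []).append(s)
        for gene_id, series in sorted(by_gene.items()):
            g = qp.gene_rate_qpcr(series, config.qpcr_threshold)
            qpcr_rows.append({
                "gene_id": gene_id,
                "distal_junction": g.distal_rate.junction,
                "distal_rate_kb_min": g.distal_rate.rate_reported,
                "mean_rate_kb_min": g.mean_rate_reported,
            })
        pd.DataFrame(qpcr_rows).to_csv(out / "rates_qpcr.tsv", sep="\t", index=False)

        stage = "splice"
        rng = np.random.default_rng(seeds["events"])
        dpsi_true = np.where(rng.random(config.n_events) < 0.3,
                             rng.choice([-20.0, 20.0], size=config.n_events), 0.0)
        events = syn.simulate_junction_counts(
            config.n_events, dpsi_true=dpsi_true,
            depth=config.event_depth, replicates=config.event_replicates,
            seed=seeds["events"],
        )
        sp.events_to_frame(events).to_csv(out / "splice_events.tsv", sep="\t", index=False)
        results = sp.diff_splice_all(
            events, "WT", "slow", n_mc=config.n_mc, seed=seeds["diff"],
            dpsi_threshold=config.dpsi_threshold, p_min=config.p_min,
        )
        sp.results_to_frame(results).to_csv(out / "diff_splice.tsv", sep="\t", index=False)
        sp.summarize_calls(results).to_csv(out / "as_summary.tsv", sep="\t")

        stage = "coupling"
        expr_genes = syn.make_genes(
            config.n_expression_genes, length_median=30_000.0, length_sigma=1.2,
            seed=seeds["expression"],
        )
        records = syn.simulate_expression(expr_genes, seed=seeds["expression"] + 1)
        pd.DataFrame(
            {"gene_id": r.gene_id, "length": r.length, "mean_expr": r.mean_expr,
             "log2fc": r.log2fc, "significant": r.significant, "direction": r.direction}
            for r in records
        ).to_csv(out / "expression.tsv", sep="\t", index=False)
        curve = cp.length_sliding_window(records, window=config.window)
        curve.to_csv(out / "length_bias.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - re-raise typed with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "polwave",
        "version": __version__,
        "config": config.as_dict(),
        "config_hash": config.digest(),
        "seeds": seeds,
        "stages": STAGE_OUTPUTS,
        "n_genes": len(genes),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def report(run_dir: str | Path) -> str:
    """Render a per-stage summary of a completed run directory.

    Raises PipelineError listing missing artifacts; re-running on the
    same directory produces the same text (idempotent).
    """
    run_dir = Path(run_dir)
    missing = [
        name for names in STAGE_OUTPUTS.values() for name in names
        if not (run_dir / name).exists()
    ]
    if not (run_dir / "manifest.json").exists():
        missing.append("manifest.json")
    if missing:
        raise PipelineError(f"incomplete run directory {run_dir}: missing {missing}")

    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    genes = pd.read_csv(run_dir / "genes.bed", sep="\t", header=None,
                        names=["chrom", "start", "end", "gene_id", "score", "strand"])
    bins = pd.read_csv(run_dir / "bins.tsv", sep="\t")
    rates = pd.read_csv(run_dir / "rates.tsv", sep="\t")
    comparison = pd.read_csv(run_dir / "rate_comparison.tsv", sep="\t")
    qpcr_rates = pd.read_csv(run_dir / "rates_qpcr.tsv", sep="\t")
    summary = pd.read_csv(run_dir / "as_summary.tsv", sep="\t", index_col=0)
    curve = pd.read_csv(run_dir / "length_bias.tsv", sep="\t")

    lines = [
        f"polwave run report  (config {manifest['config_hash']})",
        "",
        "== simulate ==",
        f"genes: {len(genes)}  length range: {int((genes.end - genes.start).min())}-"
        f"{int((genes.end - genes.start).max())} bp",
        "",
        "== bin ==",
        f"binned profiles: {bins.groupby(['genotype', 'gene_id', 'time']).ngroups} "
        f"(bin size {int(bins.bin_size.iloc[0])} bp)",
        "",
        "== wavefront ==",
    ]
    for name, grp in rates.groupby("genotype"):
        lines.append(
            f"{name}: n={len(grp)}  mean rate {grp.rate_b_min.mean():.0f} b/min  "
            f"median {grp.rate_b_min.median():.0f} b/min"
        )
    for _, row in comparison.iterrows():
        lines.append(
            f"{row.label_a} vs {row.label_b}: Mann-Whitney U={row.u_statistic:.0f}, "
            f"p={row.p_value:.3g}"
        )
    lines += ["", "== qpcr =="]
    for _, row in qpcr_rates.iterrows():
        lines.append(
            f"{row.gene_id}: distal-junction rate {row.distal_rate_kb_min} kb/min "
            f"(mean across junctions {row.mean_rate_kb_min})"
        )
    lines += ["", "== splice ==", summary.to_string()]
    lines += [
        "",
        "== coupling ==",
        f"length-bias windows: {len(curve)}  "
        f"down-fraction {curve.frac_down.iloc[0]:.2f} (shortest) -> "
        f"{curve.frac_down.iloc[-1]:.2f} (longest)",
        "",
    ]
    return "\n".join(lines)
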