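# polwave

Kinetic analysis of RNA polymerase II elongation from DRB-release
nascent-RNA time courses, and the downstream statistics that connect
elongation speed to alternative splicing and gene-length-dependent
expression.

## Who this is for

Transcription and splicing labs that measure elongation kinetics with
DRB synchronization — either genome-wide (4sU-DRB-seq) or gene-by-gene
(pre-mRNA qPCR at exon–intron junctions) — and want a tested, scriptable
implementation of the full analysis chain: wave-front calling, per-gene
rate estimation, differential percent-spliced-in (PSI) calls, motif RNA
maps, and gene-length expression-bias curves. A synthetic-data module
generates every input with known ground truth, so each stage is testable
without sequencing data.

## The model

DRB reversibly blocks the transition of initiated RNAPII into productive
elongation. On washout at *t* = 0, the accumulated promoter-proximal
polymerases are released as a synchronized wave; cells are pulsed with
4-thiouridine for the final 10 min before each harvest (0, 5, 15 min),
and the labeled nascent RNA is sequenced. For a gene transcribed at *v*
bases/min, labeled signal at harvest time *t* extends to the wave front
at *x*(*t*) = *v·t*.

- **Front calling.** Binned TSS-relative profiles are segmented with an
  exact maximum-likelihood scan of a two-segment constant-mean Poisson
  model (high upstream / background downstream); the breakpoint is the
  front. QC flags discard low-coverage profiles, profiles without a
  detectable step, and fronts that reach the gene end.
- **Rate estimation.** Two-point rate *v* = (*x*₁₅ − *x*₅)/10 bases/min
  (least-squares regression of position on time when more harvests
  exist). Genotypes are compared by two-sided Mann–Whitney on genes
  common to all genotypes.
- **qPCR variant.** Signal at a junction *d* kb from the TSS appears
  once the wave crosses it; the detection time is the first sampled time
  at ≥ 50% of the plateau, and *v* = *d*/*t*(detect) kb/min.
- **Differential splicing.** PSI = 100·inc/(inc + exc) junction reads.
  Counts are pooled within condition; each condition's inclusion
  fraction gets a Beta(inc+1, exc+1) posterior, and Monte-Carlo dPSI
  draws give a point estimate (posterior median) and a directional
  posterior probability. Events are called UP/DOWN when |dPSI| ≥ 10 and
  the directional probability is ≥ 0.95.
- **Kinetic coupling.** Exon/intron length statistics (Mann–Whitney),
  IUPAC-motif RNA maps with label-permutation significance (bold at
  *P* < 0.1), dPSI-vs-log2FC regression (r²), 100-gene sliding-window
  fraction of downregulated genes by gene length, and Fisher exact
  gene-set overlap tests.

## Worked example

```bash
python examples/02_qpcr_rates.py
```

```
fast (WT-like): junction 133 kb detected at 40 min -> 3.3 kb/min (exact 3.325)
slow mutant: junction 133 kb detected at 90 min -> 1.5 kb/min (exact 1.478)
```

A junction 133 kb into the gene becomes detectable at the 40-min sample
for a fast polymerase but only at 90 min for a slow one: the distance /
detection-time quotients, 3.3 and 1.5 kb/min, are the two elongation
rates at the sampling granularity of the assay.

The genome-wide analogue (`examples/01_wavefront_rates.py`) simulates
Poisson 4sU-DRB-seq coverage for 120 genes per genotype and recovers the
generative rate distributions from called wave-fronts:

```
wt_rate: n=120  mean 2440 b/min  median 2225 b/min  (generative mean 2450)
slow_rate: n=120  mean 1794 b/min  median 1800 b/min  (generative mean 1780)
WT vs slow: Mann-Whitney U=9036, p=0.00064
```

The other examples cover differential splicing
(`03_differential_splicing.py`), the coupling statistics
(`04_kinetic_coupling.py`), and an end-to-end staged run with manifest
and report (`05_full_pipeline.py`). The same stages are scriptable from
the shell via the `polwave` command
(`polwave run-all --seed 3 --out runs/demo`, `polwave report runs/demo`,
plus per-stage subcommands `simulate`, `bin`, `wavefront`, `qpcr`,
`splice`, `coupling`).

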