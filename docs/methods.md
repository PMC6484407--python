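# Methods

## The estimand and the measurement model

The quantity of interest is the per-gene RNAPII elongation rate *v*
(bases/min), defined operationally by the DRB-release design: after a
prolonged DRB block, initiated polymerases accumulate at the
promoter-proximal pause; washout at *t* = 0 releases them, and the
farthest position reached by labeled nascent RNA at harvest time *t*
(the wave front) is *x*(*t*) = *v·t*. The per-gene rate is the slope of
front position against time — by default the two-point slope between the
5- and 15-min harvests, because with two informative time points the
two-point estimator and the regression estimator coincide and the
two-point form makes the 10-minute baseline explicit.

## Synthetic coverage generator

`synthetic.simulate_wave_coverage` draws a true rate per gene from a
preset and produces binned TSS-relative expected profiles, optionally
with independent Poisson noise per bin. Two labeled populations are
modeled:

* **Released pause cohort** (weight `cohort_weight`, default 0.7 of
  labeled reads). Polymerases that accumulated at the promoter during
  the block depart together at *t* = 0; each cohort transcript is
  labeled over the positions synthesized during the pulse window, so
  the cohort contributes a uniform band on [*v*·max(*t* − *P*, 0), *v·t*]
  (pulse length *P* = 10 min) with a sharp edge at the front. At
  *t* = 0 the cohort is still promoter-proximal, which the generator
  represents as a uniform 1-kb promoter zone (configurable).
* **Post-release initiation** (weight 0.3), constant-rate initiation
  after washout. Position *u* is covered by the polymerases initiated in
  a window of width min(*t* − *u*/*v*, *P*), giving a trapezoid that
  also ends at *v·t*.

Both components truncate at the gene end; if the cohort band lies
entirely beyond it, the cohort mass is dropped (those transcripts have
completed and left the nascent pool). The cohort term matters: a
constant-initiation-only model produces a ramp with no discontinuity at
the front, and a two-segment changepoint detector places its maximum-
likelihood breakpoint roughly 60% into such a ramp rather than at its
foot. The sharp band edge is also what the real assay relies on — the
released cohort is the dominant labeled population after a multi-hour
block — so the mixture is the faithful model, not a convenience.

`depth` is the expected number of reads per labeled kilobase (expected
total reads = depth × labeled extent in kb); the default of 50 reads/kb
leaves roughly one expected read in the bin adjacent to the front, the
regime in which front calling is still reliable. Totals scale linearly
with depth, and Poisson draws conserve the expectation.

### Rate presets

| preset | law | parameters |
| --- | --- | --- |
| `wt_rate` | log-normal mixture | component means 1,500 and 3,400 b/min, equal weights, log-sigma 0.35; mixture mean exactly 2,450 |
| `slow_rate` | log-normal | mean 1,780 b/min, log-sigma 0.15 |
| `wt_front` | constant | 2,200 b/min (5-min front at 11 kb) |
| `slow_front` | constant | 1,780 b/min (15-min front at 26.7 kb) |

The wild-type mixture encodes a bimodal rate population with a fast
second mode; only the component means and the overall mean are
externally constrained, so the log-sigmas (0.35 and 0.15; slow narrower
than WT) are conventions of the generator, recorded in the run manifest.
The two constant presets pin the noise-free front positions at the
matched harvest times, for front-recovery scenarios in which the
expected detection is known exactly. Front-recovery and rate-recovery
scenarios sample gene lengths log-normally with median 150 kb within
60–300 kb so that a 15-minute wave rarely exits the gene body; genes it
does exit are QC-flagged and excluded from rate estimation, exactly as
in the real analysis.

## Front calling

Profiles are segmented with a two-segment constant-mean Poisson model
scanned exactly over all breakpoints (cumulative-sum implementation,
verified against exhaustive search). The scan starts 1 kb past the TSS
(`scan_start`) so the promoter-proximal zone — occupied already at
*t* = 0 — cannot masquerade as a front. Numerical choices:

* profile log-likelihood per segment is C·log(C/m) with the
  0·log 0 = 0 convention; the breakpoint depends only on profile shape
  (scale equivariance);
* ties resolve to the smallest breakpoint (most conservative front);
* QC: total counts below `min_reads` (50) → `low_coverage`; downstream
  mean above `epsilon` (0.25) × upstream mean → `none_detected`;
  breakpoint in the final bin → `front_at_gene_end`. Only `ok` fronts
  enter rate estimation; non-increasing fronts exclude the gene rather
  than reporting a zero rate.

Default bin size is 500 bp; detected positions are bin-edge quantized,
so a single front carries up to one bin of discretization error, which
the 10-minute two-point baseline reduces to ≤ ~100 b/min on the rate.

## qPCR kinetics

The generator models the junction signal as a step from 0 to plateau at
the crossing time *d*/*v* (an optional exponential `rise_time` is
available but defaults to 0), with multiplicative Gaussian noise per
replicate. Detection is the earliest *sampled* time at or above 50% of
the plateau — the plateau itself estimated from the final two samples —
with no interpolation, matching how such time courses are read out in
practice. Reported rates are rounded half-up to one decimal; the
unrounded value is retained for computation. On noise-free series the
estimate always lies in the sampling bracket
[*d*/ceil₁₀(*d*/*v*), *d*/floor₁₀(*d*/*v*)]. Because "overall" per-gene
rates can average junctions or use the most distal one, both values are
emitted, labeled; the distal junction is the default since it integrates
over the longest span.

## Differential splicing

The scoring implements the stated decision criteria — a point estimate
of |dPSI| above 10 with directional confidence — with a standard
Beta-binomial posterior rather than reproducing any particular tool's
internals. Replicates are pooled within condition (hierarchical
replicate modeling is out of scope); dPSI draws come from independent
Beta(inc+1, exc+1) posteriors per condition (uniform prior), the point
estimate is the posterior median, and `p_dir` is the posterior
probability of the point estimate's sign. `p_min` defaults to 0.95; the
threshold is exposed because the criterion is stated in the literature
in an inverted "p > 0.05" form whose intent is a 95% directional
requirement. Coverage filters: ≥ 15 reads in every sample for intron
retention, ≥ 10 reads otherwise, and a 5-fold balance rule for separate
cassette-exon inclusion junctions; microexons are cassette exons ≤ 27 nt
(community convention). At depth 200 × 3 replicates the double
criterion's null call rate is well under 1%, and events with a true
20-point shift are recovered with ≥ 90% recall. An optional
Benjamini–Hochberg FDR mode over 1 − p_dir is available and recorded
when used, since the published counting convention is ambiguous.

## Kinetic-coupling statistics

* **Length statistics**: group-vs-background two-sided Mann–Whitney
  (tie-corrected normal approximation, no continuity correction so
  identical groups give p = 1) on exon and flanking-intron lengths.
* **RNA maps**: motif coverage fraction per position (IUPAC motif,
  given strand, overlapping matches counted), smoothed by a 31-nt
  centered running mean; intron flanks analyzed over 200 nt and exons
  over 50 nt; positions beyond a shorter sequence drop out of that
  event's denominator. Pointwise one-sided significance by permuting
  event-group labels (statistic: smoothed regulated-minus-control
  coverage), p = (1 + #{perm ≥ obs})/(n_perm + 1) ∈ (0, 1], masked at
  p < 0.1. All four geometry constants are configuration keys; they are
  conventions of the display, not of the test.
* **Length-bias curve**: genes sorted by length; each 100-gene window
  contributes its median length and DOWN fraction (N − 99 windows).
  Because adjacent windows share 99 genes, the raw curve carries
  strongly autocorrelated binomial noise; monotonicity diagnostics are
  therefore computed on a 500-window running mean of the curve.
* **Overlap tests**: two-sided Fisher exact on the 2×2 membership
  table, emitted with the table; degenerate tables are flagged with an
  infinite sample odds ratio and p = 1.
* Gene length is the annotated TSS-to-TES span throughout.

## Length-effect preset

The downregulation probability is linear in log₁₀(length) through two
anchors — 0.40 at 10 kb, 0.80 at 1 Mb — flat beyond the long anchor and
continuing with the same slope (clipped at 0) below the short one, i.e.
~0.26 at 2 kb. A curve flat below 10 kb would make 40% of the synthetic
genome signal-free; a single slope through the anchors is the simplest
monotone curve consistent with them. Downregulated genes draw
log2FC = −|N(1.0, 0.4)|; 5% of the remainder are upregulated
symmetrically; unchanged genes get N(0, 0.15) and no significance flag.

## What the generators do and do not emulate

They reproduce the generative structure the analysis assumes — wave
geometry under the pulse design, Poisson counting noise, binomial
junction sampling, a length-dependent downregulation probability — with
known truth, so recovery tests certify the estimators, not the assay.
They do not model alignment artifacts, mappability, intronic signal
from co-transcriptional splicing intermediates, pause sites or
position-dependent velocity, overdispersed (non-Poisson) library noise,
batch effects, or correlated replicates. Passing tests therefore show
correctness of the inference chain under its stated model, not
robustness to every failure mode of real libraries.

## Problem sizes and determinism

Recovery scenarios use 100–200 genes per genotype, 1,000-event null
panels at depth 200, and 5,000-gene expression tables — sizes at which
the Monte-Carlo error of each recovered quantity is several-fold smaller
than its acceptance tolerance. Every stochastic routine takes an
explicit seed; derived seeds come from `numpy.random.SeedSequence`
children, and a fixed configuration reproduces every output byte for
byte (the run manifest records the configuration hash and all derived
seeds).

## Known limitations

* The two-segment Poisson front model assumes a single dominant step;
  genes with strong internal pause sites or multimodal profiles may be
  QC-rejected rather than segmented further (no per-position velocity).
* Fast genes in short gene bodies leave the gene before the last
  harvest and are excluded, slightly censoring the upper rate tail of a
  genotype mean (≲ 1% of genes under the default length law).
* Pooling replicates before front calling and before PSI estimation
  discards between-replicate variance; confidence statements are
  posterior/Monte-Carlo, not replicate-based.
* The qPCR step-rise model ignores amplification efficiency and
  saturation kinetics; only the crossing time is informative.
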