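# Methods

## Scope and data model

`zgapipe` implements a desk-scale reconstruction of RNAPII-guided ZGA
analysis: per-stage activation calling, maternal/zygotic classification,
LOF mis-regulation and synergy, regional dependency, and Hilbert genome
views. All genomic coordinates are 0-based half-open internally; GTF is
converted on read/write. When several transcript models exist per gene the
longest genomic span is kept, because the unit of occupancy analysis is
the span the elongating polymerase traverses (TSS→TES); "gene size" always
means this span.

## Occupancy calling

Tracks are ChIP and matched input coverage in fixed-width bins (default
50 bp), each scaled within-sample to counts-per-million. No cross-stage
(spike-in) normalization is attempted; absolute RNAPII levels are
therefore not comparable between stages, only the per-stage ChIP/input
contrast is used. The gene body is cut into `n_bins = 20` equal-width,
strand-oriented bins; per-bin fold = (chip mean + ε)/(input mean + ε)
with ε = 0.25 cpm, which bounds folds in zero-coverage bins of sparse
pre-MBT libraries. A gene is *full-length occupied* when ≥90% of bins
reach ≥2-fold and no sub-threshold run exceeds 10% of bins; all
comparisons are inclusive and all four parameters are exposed. This rule
is a declared operationalisation of "enriched across the entire gene
body": the exact statistic used for the original data is not public, so
the caller keeps every threshold configurable. The rule is monotone by
construction: raising `min_fold` or `min_fraction` can only retract calls.

## Temporal calling

The transcript time course is a 30-min grid of exonic and intronic TPM.
Thresholds: analysis set ≥3 TPM mean over a 1-h window, realised as three
consecutive samples (the only discretisation consistent with "any 1-h
window" on a 0.5-h grid); maternal flag ≥0.1 TPM mean over samples at
t ≤ 1.0 hpf; presence ≥0.1 TPM at the single sample nearest the stage
time, ties resolving to the earlier sample (the simplest deterministic
join between stage-resolved chromatin and a continuous time course). A
gene is active at a stage when occupied there and present; the activation
stage is the first such stage; the deactivation stage is the first later
profiled stage where occupancy is lost and never regained. The zygotic
contribution at a stage is the cumulative zygotic gene count divided by
the number of maternally detected genes; the pipeline emits this with two
denominators (maternal flags over the whole annotation and over the
analysis set) because either convention is defensible — the published
headline percentages reproduce with the analysis-set-sized denominator.

## LOF classification

Relative level = 100 × (condition mean cpm + ε)/(control mean cpm + ε),
ε = 0.5 cpm, computed separately for exonic and intronic counts and
combined as the more extreme deviation from 100% (mirroring the "exonic
and/or intronic" loss criterion). Exonic and intronic counts of one
replicate come from the same library, so both are scaled by that
replicate's combined total; this anchors the purely nascent intronic
scale to the maternally dominated exonic pool, without which a global
transcription block would be partially self-normalised away. Significance
is a two-sided exact conditional-binomial rate-ratio test on pooled
replicate counts with the doubling convention p = min(1, 2·min(P(X≤x),
P(X≥x))) — chosen because it vectorises over 10⁴-gene tables and is
mildly conservative — followed by Benjamini–Hochberg adjustment
(statsmodels). Calls: down iff level ≤ 100/1.5 ≈ 66.7%, up iff ≥150%,
inclusive. The α-amanitin reference set is genes with exonic and/or
intronic level ≤50% at q ≤ 0.10, intersected with the zygotic list.

Composition caveat: library-size normalization cannot distinguish a
uniform global loss from no loss. The synthetic study therefore keeps the
maternal pool dominant (as in a real late-blastula embryo), and the
residual inflation of relative levels under strong LOFs is small against
the 1.5-fold call margin.

## Synergy

δ = max(0, 1 − level/100), clipped to [0, 1]; synergy factor =
δ_double/(δ_a + δ_b) with 0/0 → 1 and a cap (default 10) when the double
shows loss over exactly-zero singles. The formula is this package's
definition — the source analyses plot synergy factors without printing
one. Because near-zero denominators make the raw factor noise-dominated,
the pipeline ranks synergy over genes down-called in the double LOF and
inside the α-amanitin reference set; the raw per-gene operation is still
available unfiltered.

## Regional assignment

Axis halves from dissection log2 ratios: |log2| ≥ 1 (2-fold between
opposite ends, exposed as a flag) assigns animal/vegetal or
dorsal/ventral, else uniform; a quadrant (e.g. dorso-vegetal) requires
both axes non-uniform. The left-right axis is excluded (no regional
expression differences at gastrula stages). Dependency fractions are
(# down-called)/(# zygotic genes) per region and condition; halves and
quadrants are reported as separate rows, quadrant rows being subsets of
both their halves.

## Rank-sum effect size

Group comparisons (e.g. pre-MBT-activated vs maternal gene lengths) use
the two-sided Wilcoxon rank-sum test with r_effect = |z|/√N, z from the
tie-corrected normal approximation with continuity correction. The
p-value switches to the exact permutation null when both groups have ≤8
tie-free observations, so small worked examples agree with exhaustive
enumeration; r on real-scale data may differ in the third decimal from
implementations with other tie conventions.

## Hilbert views

The d ↔ (x, y) map is the standard iterative bit-interleaving
construction with base-case visit order (0,0)→(0,1)→(1,1)→(1,0); any
fixed orientation preserves the locality that makes the plot readable.
Chromosomes are cut into 4^k bins of ceil(length/4^k) bp; cells beyond
the chromosome end are NaN.

## Synthetic study design

The generator emulates the study design with ground truth:

* **Stages**: 32-cell (2.5 hpf), 128-cell (3), 1,024-cell (4), MBT (4.5),
  mid-gastrula (7.5), late-gastrula (10).
* **Composition** (fractions of 2,000 genes): per-stage newly activated
  fractions scaled from the published 27/117/900/1854/724/1214 counts per
  13,042 analysed genes (≈37% zygotic in total); per-stage maternal
  shares 67–95% as published; 5% promoter-only decoys; 3% silent; the
  remainder maternal-only. 4% of zygotic genes deactivate at a uniformly
  chosen later stage.
* **Architecture**: pre-MBT classes log-normal with median 1 kb and a
  mean of 0.3 introns; later/maternal classes median 16 kb, mean 6
  introns. Half of the pre-MBT genes sit in tandem clusters (3 genes,
  2 kb gaps); other placements use 2 kb + Exp(50 kb) intergenic gaps over
  4 chromosomes. The two class medians (not a per-stage ramp) are a
  deliberate simplification; the 0.9 → 16 kb contrast the architecture
  comparison tests is preserved.
* **Coverage**: Poisson counts per 50-bp bin, background 50 (≈1×/bp),
  4-fold over the full body of occupied genes, promoter decoys enriched
  over the first 15% of the body only; input is background everywhere.
  At this depth the per-bin fold margin is ≈3σ, giving the caller ~99%
  gene-stage accuracy — high but not saturated (late stages lose ~2% to
  cpm dilution).
* **Time course**: maternal levels log-uniform 20–2,000 TPM decaying at
  0.2/h; zygotic amplitudes log-uniform 30–300 TPM with transcription
  onset 0.25 h before the profiled stage time (strictly between grid
  samples), intronic (nascent) signal stepping immediately to 50% of the
  amplitude for intron-bearing genes while the exonic signal rises with a
  1-h time constant — so nascent signal leads mature signal, and
  transcripts are already ≥0.1 TPM at the activation stage's own sample.
  Noise is multiplicative log-normal, σ = 0.2, chosen so recovery targets
  are achievable but not trivial.
* **LOF design**: 3 replicates of negative-binomial counts (dispersion
  0.01) at a 5-hpf assay point; signal dependence is assigned per pathway
  with region-conditional probabilities (e.g. P(Wnt-dependent | dorsal) =
  0.85, P(Nodal | vegetal) = 0.70, P(BMP | ventral) = 0.50), single-LOF
  level 55% of control acting on the zygotic component only (intronic
  carries the full effect; exonic is diluted by the maternal share);
  doubles/triples are additive on the δ scale except 12 planted
  Wnt/BMP-synergy genes (singles 90%, double 40% — DV-uniform,
  AV-regional, intron-bearing, active by the MBT so the effect is
  observable at the assay point); α-amanitin collapses the zygotic
  component to a 5% residual with intronic level 2%; up-regulated targets
  (e.g. ventral genes under Wnt LOF) get level 180%.
* **Regional table**: log2 ratios at ±2 ± N(0, 0.3) for enriched labels,
  N(0, 0.3) for uniform.

Everything is deterministic given the seed (NumPy Generator streams keyed
off it), and every emitted table is readable by the corresponding
pipeline reader.

What the generator does **not** emulate: mappability/GC bias, read-level
sampling, transcript isoforms, batch structure, dispersion trends, or
cross-stage antibody-efficiency differences. Passing recovery tests
therefore demonstrates the correctness and calibration of the pipeline's
logic under its stated model, not performance on real libraries.

## Problem sizes

Default study: 2,000 genes on a ~110-Mb genome, six stages, nine LOF
conditions × 3 replicates. The full pipeline runs in well under a minute;
the acceptance script (including a 10,000-gene × 20-replicate null FDR
simulation and a 16,400-gene additive-synergy calibration) in under a
minute.

## Known limitations

* The occupancy rule and the synergy-factor formula are declared
  conventions, parameterised so users can match other operationalisations.
* Within-sample normalization only; chromatin spike-ins would be needed
  for absolute cross-stage comparisons and are out of scope.
* The rate-ratio test ignores biological overdispersion (it pools
  replicates); with few replicates and strong planted effects this is
  adequate for classification, but a shrinkage GLM would be preferred for
  marginal effect sizes on real data.
* Deactivation precision is limited by late-stage occupancy false
  negatives (a missed last-stage call is indistinguishable from terminal
  loss); recall is the calibrated quantity.
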