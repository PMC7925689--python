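# hypoxpipe

Analysis stages for multi-omics studies of the **acute transcriptional
response to hypoxia** — and, more generally, for any stimulus-response design
that combines nascent-transcription readouts (PRO-seq), transcription-factor
binding (ChIP-seq peaks), steady-state mRNA, CRISPR fitness screens, and
patient survival cohorts.

The package is aimed at computational biologists who need the bespoke
quantification and classification steps of such a study as tested, reusable
functions rather than one-off scripts. Every stage ships with a synthetic-data
generator that plants known structure, so the full pipeline runs and is
scored end to end without any sequencing download.

## What it computes

**Pausing analysis over a one-TSS-per-gene annotation.** Transcript records
are filtered (length ≥ 1500 bp, standard chromosomes, unique start/stop per
gene), one "most-active" TSS per gene is chosen by sense/antisense reads in
candidate windows, and the TSS is combined with the shortest gene body.
Signal is quantified in a TSS window (−50 to +500) and gene body (+1001 to
end), normalized to cpm/bp, and the pausing index is

```
PI = (TSS cpm/bp) / (gene-body cpm/bp)
```

High PI means promoter-proximal pausing dominates; a drop in PI upon
stimulation indicates pause release into productive elongation. Genes with
< 0.5 cpm in all samples are excluded.

**Distance-decay peak-to-gene association.** A binding peak with normalized
read density `pnrd` at distance `dc` from a TSS gets association factor

```
AF = pnrd · exp(−|dc| / d0),   d0 = 500 bp
```

Links with AF > 0.1 are high-confidence proximal; peaks 5–50 kb from the
nearest TSS are distal, beyond 50 kb intergenic. Distal peaks whose linked
gene is transcriptionally upregulated are *productive* enhancer candidates
(bidirectional signal within ±250 bp of the peak center); the rest are
*unproductive*. Up-calls across assays partition into acute (nascent + mRNA),
late (mRNA only) and nascent-only response genes, and across cell types into
core / shared / reference-only conservation groups.

**Signature scoring and co-dependency.** A cohort is scored per sample by the
sum of gene-wise z-scores over a gene set; gene-effect (CRISPR fitness)
matrices are ranked by Spearman correlation against an anchor gene with
Benjamini–Hochberg FDR control.

**Iterative log-rank cutpoint scan.** For every percentile threshold of a
score from the 10th to the 90th, the cohort is split into high/low arms and
tested with a two-group log-rank statistic; duplicate partitions and arms
with < 10 events are skipped, BH correction runs across the considered
splits, and the lowest-p partition is retained. The PFI ratio (restricted
mean survival time, high/low) summarizes the direction of the association.

## Worked example

Simulate a complete study and run the survival arm:

```
$ hypoxpipe simulate all --out demo --seed 5
$ hypoxpipe build-annotation --transcripts demo/transcripts.bed12 \
      --tss-counts demo/tss_candidate_counts.tsv --out demo/models.tsv
300 gene models -> demo/models.tsv
$ hypoxpipe link-peaks --peaks demo/peaks.tsv --models demo/models.tsv \
      --out demo/links.tsv
klass
proximal      80
distal        80
intergenic    40
$ hypoxpipe score-signature --expr demo/expression.tsv \
      --geneset demo/sig_genes.txt --out demo/scores.tsv
scored 500 samples with 20 genes
$ hypoxpipe survival-scan --surv demo/survival.tsv --score demo/scores.tsv \
      --out demo/scan
best split at percentile 43 (p=4.13e-31, q=3.31e-29, n_high=285, n_low=215,
PFI ratio=0.292)
```

The simulated cohort plants a hazard change at the 40th percentile of a
latent score with hazard ratio 3; the scan recovers a split at the 43rd
percentile, and the PFI ratio of 0.292 says the high-score arm progresses
much earlier — the planted unfavorable-signature direction. The peak-class
counts match the planted 80/80/40 proximal/distal/intergenic design exactly.

Co-dependency ranking on the simulated gene-effect screen puts the planted
partner directly below the anchor:

```
$ hypoxpipe codependency --effects demo/gene_effects.tsv --anchor HIF1A \
      --out demo/codep.tsv
           rho              p    n              q  rank
HIF1A     1.000000  0.000000e+00  600            NaN     1
DDIT4     0.776406  5.30e-122     600  1.07e-119       2
```

(The planted Pearson correlation of 0.8 appears as a sample Spearman of
≈ 0.78, as expected for a Gaussian copula.)

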