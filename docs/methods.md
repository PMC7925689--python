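# Methods

This note documents the models, conventions and numerical choices behind
each stage of `hypoxpipe`, and what the synthetic-data generator does and
does not emulate.

## Coordinate conventions

All intervals are 0-based half-open (BED dialect), on disk and in memory.
"−50 to +500" around a TSS is realized as the 550 bp window
`[tss−50, tss+500)` on the plus strand and mirrored on the minus strand; the
gene body is `[tss+1001, end)` (mirrored for minus-strand genes), where
*end* is the gene-strand 3′ end of the shortest retained transcript. The
strict inclusive/exclusive reading of such window notations varies between
tools; the half-open realization is fixed here and used consistently by the
annotation builder, the quantifiers and the generator.

## Annotation: one record per gene

Transcripts shorter than 1500 bp are removed (this also eliminates
rRNA-scale genes and guarantees a non-empty body downstream of the +1001
offset), as are records on non-standard chromosomes (allow-list, default
chr1–22/X/Y) and duplicate (start, end) pairs per gene. Candidate TSS
windows are ranked **lexicographically**: sense reads desc, antisense reads
desc, then 5′-most position in transcription direction, then transcript id —
a deterministic total order. An alternative single-score ranking
(sense + antisense) is available (`ranking="combined"`); both agree whenever
sense counts alone separate the candidates, which is the typical case.
Genes whose shortest body would be empty are dropped with a log entry.

## Nascent quantification and the pausing index

cpm/bp = counts / library size × 10⁶ / region length. The library size is
the total reads assigned to counted regions per sample (TSS + body), so the
pausing index PI = TSS cpm/bp ÷ body cpm/bp is exactly invariant to any
per-sample depth scaling (asserted to 1e−12 in tests). PI is flagged
undefined (NaN) where the body density is zero and excluded from summary
statistics. The < 0.5 cpm expression filter operates on gene-level cpm (no
length normalization): a gene is kept if any sample reaches the threshold.

Fold changes between groups are log2((mean_B + ε)/(mean_A + ε)) of cpm/bp
values with ε = 0.25 (configurable) guarding zero-count genes; the PI fold
change is the pseudocount-free ratio of replicate-mean PIs, so "body
doubles, TSS unchanged ⇒ PI log2FC = −1" holds exactly. Note that at shallow
synthetic depths the ε used for the TSS/body fold changes is of the same
order as typical cpm/bp values and compresses those estimates; effect-size
readouts should prefer the DE test's count-scale estimates below.

## Built-in differential-transcription test

Significance is designed to be an **input** (a q-value table from a
negative-binomial fit); the built-in test exists only so synthetic
end-to-end runs are self-contained, and it is not equivalent to such a fit.
It is a moderated two-group z-test on log2(normalized count + 0.5):

- size factors are median-of-ratios against a geometric-mean reference,
  estimated **twice** — a first fit flags q < 0.1 genes, factors are
  re-estimated on the remaining (null) genes, and the test is refit. With a
  one-sided block of induced genes (20% of genes at log2FC 1.5), single-pass
  median-of-ratios is biased by ≈ 0.1 log2 because the contaminated upper
  tail shifts the mixture median; the two-pass estimate removes this
  (measured: induced median log2FC 1.42 vs planted 1.5; null median −0.05).
- per-gene pooled variances are shrunk toward their mean with 50
  pseudo-degrees of freedom (with a constant negative-binomial dispersion
  across genes the true log-scale variances are nearly common, so strong
  shrinkage is appropriate and the normal approximation is accurate).

Classification follows the study cutoffs: up iff q < 0.1 and FC > 1.5, down
iff q < 0.1 and FC < 1/1.5, else ns.

Mann–Whitney comparisons use the exact null distribution for untied groups
of ≤ 8, otherwise the tie-corrected normal approximation; the reported
effect size is the rank-biserial r = 2U/(n₁n₂) − 1, a monotone transform of
U in [−1, 1].

## Peak-to-gene association

The printed form of the association factor, pnrd·e^(dc/d0), *grows* with
distance, which contradicts its use for calling TSS-proximal high-confidence
links; the distance-weighting approach it derives from decays
exponentially. The package therefore uses AF = pnrd·exp(−|dc|/d0) (half
distance d0·ln2 ≈ 346.6 bp at d0 = 500), with `decay=False` available to
reproduce the printed form. Distances are measured from the **peak center**
to the annotated TSS (the peak anchor is not otherwise specified; summit
positions are not modeled). Class rules: proximal iff AF > 0.1 (this rule
takes precedence, so a hypothetical high-AF peak at 6 kb is proximal);
otherwise distal iff 5,000 ≤ dc ≤ 50,000 (closed bounds, as printed);
intergenic iff dc > 50,000; "other" for low-AF peaks within 5 kb. When a
peak's AF clears the threshold for several genes, all qualifying links are
retained (the nearest-TSS link is marked primary). Common-peak scaling
defines "common" as ≥ 1 bp overlap of merged peak calls across all samples
and rescales a base peak-calling threshold by each sample's share of tags
in common peaks — the mechanism for harmonizing IP efficiency across cell
lines.

Enhancer productivity is a property of genes carried to peaks: a distal peak
is productive iff any linked gene is classified up. Window signal is the
plus+minus strand sum over [center−250, center+250).

## Signature scores and co-dependency

"Detected" means expression > 0; genes detected in < 50% of samples are
removed per cohort. Z-scores use the sample standard deviation (n−1);
constant genes are dropped with a warning. The signature score is the plain
sum of z-scores over the (intersected) gene set — linear in the set and
invariant to per-gene affine rescaling of the raw expression. Missing set
members are dropped, never imputed, and the intersection size is reported.

Co-dependency uses Spearman correlation with average ranks for ties,
pairwise-complete observations (≥ 10 required), a two-sided t-approximation
p (exact permutation enumeration for n ≤ 9), and BH across all non-anchor
genes. An essentiality threshold flag is deliberately left without a
default.

## Survival analysis

Kaplan–Meier estimation and the log-rank test are implemented from first
principles (product-limit; observed-minus-expected with hypergeometric
variance per distinct event time, 1 df chi-square) and cross-checked in the
test suite against an independent reference implementation to 1e−6.

The cutpoint scan thresholds at nearest-rank percentiles (deterministic, no
interpolation), puts samples with score strictly above the threshold in the
high arm, tests each *new* sample partition once, and requires ≥ 10 events
in **both** arms (the looser "either arm" reading is available via
`both_arms=False`; the strict reading prevents degenerate arms). BH runs
within one scan across the considered partitions; when scans are run per
cohort, a second BH across the per-cohort best p-values is a separate step
(`bh_adjust` is exposed for it). Equal lowest raw p-values are broken by the
smallest percentile. "Mean survival time" for the PFI ratio is the KM-based
restricted mean to a common horizon (default: the maximum observed time);
the unrestricted mean is undefined under censoring.

## Synthetic data: what it emulates, and what it does not

No noise model is specified for any of the assays upstream; all
distributional choices are explicit stand-ins, chosen once:

- **Counts** are gamma-Poisson (negative binomial, var = μ + φμ², φ = 0.05)
  with per-gene lognormal abundance (σ = 0.4) and lognormal library factors
  (σ = 0.1) — standard sequencing-noise assumptions. Region means are
  density × length: 0.5 reads/bp in the TSS window vs 0.05 in bodies, giving
  pausing indices around 10.
- **Induction** multiplies body means by 2^1.5 under the induced condition;
  the TSS receives 25% of the body effect on the log2 scale (so PI falls by
  ≈ 1.1 log2 units at induced genes, the pause-release pattern), and the
  knockout genotype multiplies log2 effects by 0.3. 60% of induced genes are
  also induced at the mRNA level (acute); 15% of the remainder are mRNA-only
  (late).
- **Gene models** sit on a pseudo-genome of two standard chromosomes plus
  one `chrUn_random`, spaced 120 kb apart with 1–4 isoforms per gene; planted
  peak offsets (≤ 400 bp proximal, 5.1–45 kb distal, ≥ 55 kb intergenic)
  avoid the decision boundaries by ≥ 100 bp by construction.
- **Cohorts** (n = 500) draw a latent score u ~ N(0,1), express 20 signature
  genes as lognormal functions of u, and set the hazard to 3× baseline above
  the 40th percentile of u, with independent exponential censoring tuned to
  20%. The z-score signature of the 20 genes has rank correlation ≈ 0.99
  with u, so percentile splits of the score track the planted cutpoint.
- **Effect screens** are independent normal (CERES-like scale: mean −0.1,
  sd 0.4) over 600 cell lines, with planted pairs sharing a latent factor at
  the stated Pearson correlation (a planted 0.8 appears as sample Spearman
  ≈ 0.786 under the Gaussian copula).

All randomness flows from one root seed through named substreams, so every
output is byte-reproducible. The generator does **not** emulate read-level
data, sequence content, motif occurrences, peak-width variation, batch
effects, overdispersion heterogeneity across genes, correlated censoring, or
cohort covariates — so passing tests demonstrate correctness of the
computations and recoverability of planted structure under idealized noise,
not robustness to the full complexity of real sequencing or clinical data.

## Problem sizes

The shipped checks use 50–2,000 genes, 200–500 peaks, cohorts of 500
samples (100 replicates for recovery rates), 2,000 null cohorts for log-rank
calibration, and 600-cell-line screens — sizes at which every planted effect
is comfortably identifiable and the whole suite runs in a couple of minutes
on one core.

## Known limitations

- The built-in DE test is a convenience for synthetic runs; real analyses
  should supply q-values from a proper negative-binomial fit.
- Secondary (non-nearest) peak links are only generated for the proximal
  class; distal links always use the nearest TSS.
- The metagene profile uses simple binned means with a pointwise t-interval;
  no spline smoothing.
- Cox regression, peak calling, motif analysis and enrichment testing are
  out of scope; the pipeline consumes peak calls and produces gene sets.
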