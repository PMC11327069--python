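# Methods

`epilnc` implements a tumor-vs-normal multi-omics procedure for identifying
epigenetically dysregulated genes ("epi genes": epi-lncRNAs and epi-PCGs),
scoring their collective activity per sample, and deriving a prognostic risk
signature.  This note records the models, defaults, numerical choices, and
the deliberate design decisions, in that order of importance to a user.

## The epi-gene definition

A gene is called *epi* when both conditions hold:

1. it is differentially expressed between tumor and normal samples
   (BH FDR < 0.05 and |log2FC| > 1), and
2. its promoter or an associated enhancer overlaps at least one
   condition-specific histone peak (H3K27ac, H3K4me1 or H3K4me3) or one
   significant differentially methylated region (DMR).

The phrase behind condition 2 ("more than one ... region") is ambiguous
between >=1 and >=2 regions in the source methodology; we default to
`min_evidence=1` and expose the strict reading as a parameter.  Evidence is
recorded as (source x element) tuples over 4 sources
{H3K27ac, H3K4me1, H3K4me3, DMR} and 2 elements {promoter, enhancer},
giving the 8-category landscape matrix.

**Coordinates.** All interval arithmetic is 0-based half-open; GTF input
(1-based inclusive) is converted on read.  The promoter is the strand-aware
window from 2 kb upstream to 0.5 kb downstream of the canonical TSS, taken
as the 5' end of the gene span (one promoter per gene; per-transcript
promoters are out of scope).  Enhancers require an explicit enhancer->gene
association table (FANTOM5-style); nearest-gene assignment is deliberately
not offered because it invents linkages the catalogue does not assert.

## Differential expression

A self-contained negative-binomial Wald test, not a DESeq2 reimplementation:

- **Normalization** — median-of-ratios size factors over genes with
  all-positive counts, rescaled to geometric mean 1.
- **Dispersion** — per-gene method of moments on normalized counts, pooling
  within-group variances, floored at 1e-8.  The moment estimator is noisier
  than shrinkage estimation but conservative here (for true DE genes the
  pooled-mean denominator overestimates dispersion, inflating the SE).
- **Effect and test** — log2 fold change of group means with pseudocount
  0.5 (keeps zero-mean groups finite); delta-method SE from the NB variance
  of each group mean; two-sided normal p; BH adjustment over all tested
  genes.  Genes with zero counts everywhere are excluded and flagged.

No dispersion shrinkage, covariate adjustment or outlier handling: on
planted two-fold effects at 20 samples/arm the test has power ~1 and its
null false-positive fraction at FDR<0.05 is far below 0.05, which is what
the downstream classification needs.

## Condition-specific ("difference") peaks

A peak is condition-specific iff it overlaps no same-mark peak of the other
condition by >= `min_overlap` (default 1) bp, and is retained only if its
own calling p-value (narrowPeak column 8, stored as -log10 p) is < 0.05.
The p-filter is applied to the peak's calling p-value, not to a differential
statistic — quantitative differential binding is out of scope.  Plain BED6
peaks carry no p-value and require an explicit `no_p_filter` opt-in.
Overlap queries run on interval trees; tests pin them against a brute-force
all-pairs scan.

## DMR detection (bump hunting)

Per probe, the statistic is the tumor-minus-normal mean beta difference.
Probes are chained into clusters when consecutive gaps are <= `max_gap`
(default 500 bp) and smoothed within clusters by a centered running mean
over `w=5` probes (a fixed-window mean rather than loess: deterministic,
dependency-free, and adequate at array-like probe spacing).  Candidate
regions are maximal same-sign runs with |smoothed statistic| >= `delta_cut`
(default 0.1 beta units); single-probe runs are dropped.  A region's score
is its area (sum of |smoothed statistic| over member probes).  Note the
smoother widens a true bump by up to `w//2` probes per side; region
boundaries are therefore approximate to that resolution.

Significance comes from `B=100` full label permutations.  Null areas are
pooled over all permutations and a region's p-value is
`(1 + #{null areas >= observed}) / (1 + B)`, the standard bump-hunting
estimator; regions with p < 0.01 are significant.  The denominator is the
number of permutations, not the pooled-region count — with the latter the
minimum attainable p depends on how many null regions happen to arise, and
on quiet data a genuine single bump could never reach 0.01.  Calibration is
checked empirically: under a pure-noise null <=1% of candidate regions are
significant.

Missing beta values are imputed first by k-nearest-probe averaging
(`k=10`, nan-Euclidean distance over shared observed samples, backed by
scikit-learn's `KNNImputer`); probes with no observed value are an error.

## ssGSEA scoring

Per sample, genes are ranked by expression (average ranks on ties, highest
expression = rank N).  Walking the ranked list from the top, the enrichment
score is the running-sum integral of the difference between the
rank-weighted in-set ECDF (weights rank^alpha, `alpha=0.25`) and the
uniform out-of-set ECDF.  Scores are rank statistics: any strictly monotone
per-sample transform of expression leaves them bit-identical, which the
tests assert, and an independently coded running sum agrees to 1e-10.
A set covering every gene scores 0 by convention (the out-set ECDF is
empty).  The six primary score sets are {H3K27ac, H3K4me1, H3K4me3} x
{promoter, enhancer} membership among epi-lncRNAs; DMR-derived sets are
emitted with an `_aux` suffix.  Group comparisons use two-sided
Mann-Whitney with BH across sets; score-score and score-expression
correlations use Spearman (scores are ranks; a linear coefficient would
claim more than the data support).

## Survival layer

- **Cox fits** maximize the Breslow partial likelihood by Newton-Raphson to
  gradient norm < 1e-8 (max 100 iterations); SEs from the inverse observed
  information; Wald p; HR with 95% CI.  Breslow ties are the simplest
  correct choice at array-scale tie rates; diverging coefficients
  (|beta| > 50, monotone likelihood) raise rather than return garbage.
- **Screening** — per-candidate univariate Cox on standardized log2(TPM+1);
  keep Wald p < 0.05.
- **Risk model** — multivariate Cox over the screened panel; risk score =
  sum of beta_i x standardized expression; the per-gene mean/SD and the
  median risk score are frozen on the training cohort, so validation
  cohorts reuse them without leakage.  Median-split ties go to "low".
- **KM / log-rank** — product-limit estimator; k-group log-rank with
  hypergeometric variance (O-E vector form, chi-square with k-1 df).
- **Time-dependent AUC** — cumulative/dynamic AUC with IPCW: cases at
  horizon t are events by t weighted 1/G(T-), controls are event-free past
  t weighted 1/G(t), G the Kaplan-Meier estimate of the censoring
  distribution.  Horizons beyond the last follow-up are NaN.  A constant
  score gives exactly 0.5, a perfect ranking exactly 1, and a vectorized
  implementation is pinned to a double-loop oracle at 1e-10.

## The synthetic cohort

The generator emulates the full input stack on one linear chromosome
("chrS", one 20 kb slot per gene) with planted ground truth, so that every
downstream stage can be scored against a known answer.  Defaults are the
package's reference study conditions: 300 genes (half lncRNA), 20 tumor +
20 normal samples, planted |log2FC| = 2 in 10% epi + 10% DE-only genes,
NB dispersion 0.1, log-normal library sizes (sd 0.15), beta-value shift
0.3 in planted DMRs, logit-normal beta noise (sigma 0.25, ~0.05 beta-scale
SD), 2% missing betas, exponential survival with an 8-coefficient planted
log-hazard and ~20% independent uniform censoring.

Structural choices that make ground truth exact rather than approximate:
planted peaks/DMRs sit inside the target gene's promoter or an enhancer
owned by that gene alone (shared enhancers never carry planted signal, so
evidence cannot spill onto a co-associated gene); background peaks are
either identical in both conditions (never condition-specific), unique but
failing the p<0.05 filter, or unique and significant but outside every
regulatory region.  Probes tile promoters (12) and enhancers (10) at
spacing well under `max_gap`.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: genomic covariates (GC, mappability), probe-type
effects and realistic 450K manifests, cell-type composition, batch
structure, correlated gene expression, read-level noise, and peak-calling
artifacts.  Recovery of planted signal demonstrates the pipeline's logic
and calibration, not its field performance on TCGA-scale cohorts.

## Problem sizes and runtimes

The validation suite runs the reference cohort end-to-end (300 genes,
40 samples; a few seconds), 20-replicate null calibrations for DE and DMR,
50-replicate Cox recovery at n=500, and 50-100-instance oracle comparisons;
the whole suite completes in well under a minute on one CPU.  These sizes
were chosen as the smallest at which the law-of-large-numbers checks are
stable; all thresholds were fixed before measurement and are not tuned.

## Known limitations

- Moment-based NB dispersion is inefficient below ~8 samples per arm.
- DMR boundaries are only accurate to half a smoothing window.
- The permutation p-value has resolution 1/(B+1); B < 20 triggers a warning.
- With very small cohorts the multivariate Cox step may legitimately fail
  (few events, wide panel); the pipeline records the failure and continues.
- The univariate->multivariate funnel performs no further selection
  (no lasso/stepwise), matching the declared scope.
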