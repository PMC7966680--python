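# Methods

## Scope and model

`homingtrack` implements a blood-to-brain tracking analysis for a
CNS-homing T-cell population measured with CITE-seq (RNA + surface
markers) and spatial transcriptomics. The package assumes clustering has
already happened upstream: cluster labels are inputs, and the synthetic
cohort generator supplies ground-truth labels. The statistical chain is
(i) differential abundance of a gated surface phenotype, (ii)
pseudobulk differential expression defining a bidirectional gene
signature, and (iii) a rank-based enrichment statistic applied to
cells, pseudobulks and spatial spots.

## Synthetic cohorts

`simulate_cohort` draws a paired cohort: each donor contributes one
treated and one untreated sample; each sample contains every cluster
with Uniform[min, max] cells per (sample, cluster). Gene expression is
negative binomial with mean/dispersion parameterization
(var = μ + αμ², sampled as gamma–Poisson). Per-gene base means come
from normalized Gamma(shape = `nb_mean_shape`) weights scaled to
`mean_umi_per_cell` (so library depth is controlled directly); each
cluster applies an i.i.d. log2-normal perturbation (σ =
`cluster_lfc_sigma`) drawn once and shared across samples, so cluster
profiles are stable cohort-wide. Per-cell log-normal size factors
(σ = 0.3) give the QC filters realistic variation to act on, and a
`damaged_frac` of cells has mitochondrial means boosted to ≈ 35% of the
library so the mito filter is exercised.

Planted effects, confined to the homing cluster in treated samples:

* up/down signature genes (defaults 50 + 50, drawn from the
  better-expressed 70% of non-mito genes — detected signatures are, by
  construction, detectable genes) have means multiplied by 2^(±log2FC),
  default log2FC = 1;
* the double-positive fraction on the two gating markers rises from
  `dp_freq_base` = 0.3 to 0.5 (`dp_freq_shift` = 0.2).

Surface markers are bimodal: each cell is double-positive with the
configured probability, otherwise negative or single-positive; positive
and negative populations are NB with means 600 and 30 (CLR separation
≈ 3 natural-log units, i.e. clearly gateable but with overlap).
Effect-size defaults (log2FC = 1, +0.2 shift) are package choices —
no field estimates exist for the real shift.

All random streams are keyed by `(seed, label)` (CRC32 of stable string
labels), so adding a sample or cluster never perturbs the draws of
another, and identical configs are bit-reproducible across platforms.

Defaults (8 donors, 12 clusters, 400–600 cells per sample-cluster,
500 genes) are the package's study conditions. The Monte-Carlo studies
in `tests/test_acceptance.py` and `scripts/acceptance.py` scale the
*free* dimensions to each question while keeping the conditions that
define the experiments (donor count, ~500 cells per sample-cluster,
effect sizes, replicate counts): frequency-shift studies use a
150-gene universe because gating reads only the surface markers;
enrichment studies use a 2,000-gene universe because within-cell ranks
are compositional — when planted genes dominate a small universe,
their shift displaces the ranks of *all* genes, and even matched
random control signatures become genuinely non-null. Keeping the
50+50 signature a small fraction of the transcriptome (as in real
data) is what makes the random-control null meaningful; null
calibration studies, which plant no effect, use a 300-gene universe.

What the generator does **not** emulate: transcriptome-wide gene–gene
correlation, batch/chemistry effects, doublets, ambient RNA, and
donor-level biological variability beyond the blocked design. Passing
tests therefore demonstrate correctness and calibration of the
machinery under a clean NB world, not robustness to every real-data
pathology.

## QC and normalization

Cell filters follow the strict-inequality convention ("less than 500"
removes 499 but keeps 500): RNA UMI ∈ [500, 15000], detected genes ∈
[300, 5000], ADT UMI ∈ [100, 7000], mitochondrial fraction ≤ 0.20
(prefix-matched gene names, default `MT-`). Genes must be detected in
≥ 10 cells; name-pattern exclusion lists stand in for annotation-based
pseudogene/ribosomal removal, whose annotation source is external.
Removal counts are reported per rule, non-exclusively.

RNA normalization is log-CPM-style, `log(1 + scale·count/total)`
(scale 10⁴). The original workflow used variance-stabilizing
normalization plus anchor integration; those steps only matter for
clustering/visualization, which is out of scope — the enrichment
statistic downstream depends only on within-cell ranks, which log-CPM
preserves from raw counts. A manual "remaining strong outliers" removal
step is visual and irreproducible and is deliberately not implemented.

ADT normalization is CLR per marker across cells:
`value = log(x+1) − mean_cells(log(x+1))`; marker columns have exactly
zero mean (≤ 1e-12).

## Gating and frequency testing

The double-positive gate is a rectangle on CLR values. The original
gates were drawn by hand in flow-cytometry software; the reproducible
stand-in fits a 1-D two-component Gaussian mixture per marker (on at
most 20,000 subsampled values) and thresholds at the midpoint of the
component means, erroring when the means are closer than 0.5 CLR units
(effectively unimodal data); manual thresholds override.

Frequencies are per (sample, cluster); combinations with < 20 cells are
excluded *together with the same cluster's row of the paired sample*,
and clusters retaining < 5 donor pairs are excluded. The shift test is
a one-sample t-test on per-donor treated-minus-untreated frequency
deltas, BH-adjusted across clusters ("FDR" is interpreted as
Benjamini–Hochberg throughout — the field default). Zero-variance
deltas yield NaN with a warning rather than a sham p-value.

## Pseudobulk differential expression

Per sample, the target cluster's cells are resampled with replacement
to a fixed n (default 1,558) before gene-wise summation — this removes
the dependence of DEG counts on per-sample cell numbers (verified as an
acceptance property). Resampling uses one stream per (seed, sample id).

The NB Wald engine is authored here (no outlier refitting, no
independent filtering):

* size factors: median of count/geometric-mean ratios over genes
  positive in every sample;
* dispersion: per-gene method of moments on residuals from a Poisson
  GLM fit of the full design, with the residual sum of squares rescaled
  by n/(n−p) (fitted designs absorb p/n of the variance; without this
  the estimator is badly biased low at cohort-scale n). Gene estimates
  are shrunk halfway (log scale) toward a fitted a₀ + a₁/μ trend and
  clipped to [1e-8, 10];
* per-gene NB GLM (log link, size-factor offsets) fit by IRLS on
  `~ blocking + group` (donor blocking for paired designs, batch-pair
  for cross-sectional ones; incomplete blocks are an error);
* normal-quantile Wald p-values on the group coefficient, BH-adjusted.

Calibration was checked on zero-effect simulated cohorts: the fraction
of null genes at p < 0.05 is ≈ 0.06 (slightly liberal in the extreme
tail, a known Wald property at small n; the t(n−p) alternative proved
markedly conservative at ≈ 0.02 and was rejected).

Signatures take genes with padj ≤ 0.1 **or** raw p ≤ 0.05, split by
fold-change sign; zero fold changes are excluded, and an empty side is
an error because the AUC ratio would be undefined.

Cluster markers (for signature-style contrasts between clusters) use a
two-sided Wilcoxon rank-sum per gene — exact for small untied groups,
tie-corrected normal approximation otherwise — with the legacy
single-cell log-fold-change convention `ln((mean expm1 + 1)_target /
(mean expm1 + 1)_ref)`, under which the `logFC > 0.3` marker filter is
meaningful.

## AUC-ratio enrichment

Genes are ranked per profile by decreasing raw count (rank-equivalent
to log-CPM within a profile). Ties — dominated by the zero block — are
permuted uniformly at random by a stream keyed by `(seed, CRC32 of the
profile bytes)`: deterministic, content-addressed, and independent of
which other profiles are scored, so a spot and a pseudobulk with
identical counts score bit-identically. An "average rank" deterministic
mode is not needed because content-keying already makes results
reproducible.

The recovery AUC of a set over the top k = ⌈top_frac·n⌉ ranks is the
recovery-curve area normalized by the ideal curve (set genes at ranks
1, 2, …); it is 1 iff all reachable set genes occupy the top ranks and
0 iff none is in the window. The enrichment ratio is
AUC_pos / max(AUC_neg, 1e-6); floored denominators are flagged
`capped`. `top_frac` defaults to 0.05 on cells/pseudobulks (the common
default of rank-recovery scoring tools) and 0.10 on spatial spots: spot
transcriptomes are cell mixtures whose signature genes sit deeper in
the ranking, and on desk-scale universes a 5% window makes AUC_neg
exactly zero often enough to destabilize control percentiles.

Group comparisons draw 150 cluster cells per sample without replacement
(samples with fewer are excluded) and t-test per-sample mean ratios;
both paired and unpaired modes exist because the source analyses used
both, with `paired=False` as the constructor default and an explicit
flag. Matched-size random control signatures are drawn uniformly from
the universe minus the signature's own genes. Pseudobulk enrichment
sums counts per (sample, cluster), dropping < 20-cell combinations and
clusters with < 3 remaining samples.

## Spatial scoring

Spots below `min_spot_umi` (default 200 — low-UMI spots have unstable
ranks; the source protocol states no spot QC) are flagged, not scored.
The carried-over cutoff 11.5 is only meaningful for the original
signature and universe; the recommended data-driven alternative is
`control_percentile_cutoff` (default 99.9th percentile of
control-section ratios), which by construction bounds the control
false-positive fraction at ~0.1%. Simulated sections use a 1,000-gene
universe, 100+100 marker signature at 16-fold separation (cell-type
marker scale) and 5,000 expected UMI per spot.

## Numerical and design notes

* BH adjustment is applied within each test family (clusters, genes,
  signatures); padj ≥ p and padj ≤ 1 always.
* IRLS runs at most 50 iterations with η clipped to ±30; rank-deficient
  designs and no-residual-df designs are errors, not warnings.
* `ceil(top_frac·n)` guards against float artifacts with a 1e-9 slack.
* All-zero genes are excluded from DGE and reported; all-zero profiles
  rank as a pure random permutation.
* Pipeline runs write a manifest (config SHA-256 prefix, seed, file
  list) plus `run.log`; outputs are plain TSV/JSON readable by the
  package's own readers.

## Known limitations

The NB engine omits fold-change shrinkage, outlier replacement and
independent filtering; its extreme-tail p-values are mildly liberal.
The simulator's independence assumptions flatter rank-based statistics
(no correlated gene modules that could inflate random-signature
variance). Auto-gating assumes clear bimodality; noisy panels need
manual thresholds. Spatial scoring treats spots independently — no
spatial smoothing or neighborhood statistics.
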