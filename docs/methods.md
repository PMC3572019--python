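# Methods

## Data model

The central object is a probes x samples matrix of methylation beta values
(methylated fraction estimates in [0, 1]); probe annotations (chromosome,
position, symbol) and sample metadata (cell type SC/iPSC/ESC, sex, stage,
batch, platform) travel in separate tables keyed by ID.  All joins are by
probe/sample identifier — row and column order in input files never affects
a result.  Missing betas are allowed on input: probes with more than 20%
missing values are dropped (count logged), remaining gaps are filled with
the probe median.  The median choice is deliberately conservative — it
leaves a probe's rank statistics nearly untouched — but it does understate
probe variance when missingness is high; the 20% cap bounds that effect.

Four binary comparison schemes are built in: `SC_vs_PC` (pluripotent = iPSC
and ESC pooled), `ESC_vs_iPSC`, `F_vs_M_iPSC` and `fetal_vs_adult_SC`.

## Sample QC

Three independent per-sample checks run on the raw matrix, before
normalization (outliers should not influence the normalization target):

* **X-chromosome distribution.**  X-inactivation leaves one X copy
  methylated in female cells, so female X-probe betas concentrate at
  intermediate values while male X probes sit near the unmethylated mode.
  A sample recorded female whose mean X beta leaves [0.30, 0.70], or
  recorded male with mean X beta >= 0.30, is flagged.  With unknown sex the
  rule falls back to a robust z-score (median/MAD, scaled by 1.4826) within
  the cell-type group, flagging |z| > 3.  At least 10 X probes are
  required.
* **CpG distribution.**  Genome-wide beta distributions are bimodal.  The
  statistic is the extreme-bin fraction f = P(beta < 0.3) + P(beta > 0.7)
  per sample; samples falling more than 3 scaled MADs *below* the cohort
  median (degenerate, unimodal arrays) are flagged.  The inequality is
  strict, so an exactly-uniform cohort flags nobody.
* **Distance to group centre.**  Within each cell-type group, the Euclidean
  distance of every sample's beta vector to the group mean; samples beyond
  mean + k*SD are flagged (k = 2 by default, configurable).  Groups smaller
  than 3 are skipped with a warning.

In ~2000-probe data the distance distribution concentrates tightly (its
relative spread scales as 1/sqrt(2p)), so the k = 2 default flags roughly
the upper 2% of perfectly clean samples by chance; this keeps the check
sensitive.  Deterministic tests that need a zero false-positive guarantee
use k = 3, where the chance-flag probability is negligible while planted
outliers (a +0.3 shift on every probe lies hundreds of SDs out) are always
caught.  The thresholds and statistics here are this package's own
concrete choices for the three checks; the null flag rate at defaults
stays below 10%.

QC never removes probes, only samples, and refuses to return an empty
matrix.

## Normalization and batch adjustment

**Quantile normalization** forces every sample's value distribution onto
the across-sample mean of order statistics.  Ties within a column receive
the mean of the reference values over the tied rank span, which makes the
operation exactly idempotent (to 1e-12) and keeps output inside [0, 1].  A
single-sample matrix is returned unchanged with a warning.  The fitted
`QuantileNormalizer` also maps *new* samples onto a stored reference, for
scoring cohorts arriving after training.

**Batch adjustment** is the parametric empirical-Bayes location/scale
model.  Per probe, an OLS fit against batch indicators plus cell-type
dummies standardizes the data (pooled residual variance, batch-size
weighted grand mean); per batch and probe, location (gamma) and scale
(delta^2) estimates are shrunk toward batch-level priors — normal for
gamma, inverse gamma for delta^2, hyperparameters by method of moments
across probes — via the coupled posterior-mean iteration run to relative
convergence 1e-4 (the stopping rule matches the reference EB
implementation exactly, including its signed denominator on the location
term; one test verifies agreement with Bioconductor's `sva::ComBat` to
1e-6 on a shared fixture).  Cell type is included in the design by default
so biological differences are not absorbed into batch terms; a batch fully
confounded with cell type drops the covariate with a warning rather than
failing.

Because betas are bounded, adjustment operates on logit(beta) (guard
epsilon 1e-6) and maps back, clipping into [0, 1] and logging the clip
count; `scale="raw"` adjusts betas directly for comparability with
pipelines that do so.  A single batch makes the adjustment an exact
identity.

## Eigengene-score biomarker selection

An *eigengene* E_k is the k-th principal-component sample-score vector of
the probe-centered beta matrix.  Each probe is scored by
max_k |Cor(x_i, E_k)| over the supplied components, with the maximizing
component recorded; constant probes score 0 by convention.  Scoring
against a variance axis rather than a class-difference statistic
de-duplicates the evidence of correlated probes and is insensitive to
class imbalance.  Ranking sorts by score descending with probe-ID
tie-break (determinism); Y-chromosome probes are excluded (sex-linked
dosage confound), unannotated probes are excluded with a logged count.

The decomposition runs on the samples of the active comparison, and
eigengene signs are oriented so the correlation with the comparison's
first class is non-negative.  Because the decomposition is per-comparison,
the comparison's own axis is a *leading* component: SC-vs-PC, sex and
stage schemes default to component 1, ESC-vs-iPSC to components 1 and 2 —
its markers occupy two variance axes, one autosomal and one X-linked, and
`split_by_chromosome` partitions the ranking accordingly.  Component
choices are configurable everywhere.

## Classifiers

**Neural network.**  One hidden layer (default 5 logistic units), softmax
outputs, cross-entropy loss with L2 penalty `decay = 5e-4` on all weights
and biases; weights start uniform in [-0.1, 0.1] from the seed and BFGS
runs for at most 200 iterations with analytic gradients.  The predicted
class is the largest output unit.  The small-network/weight-decay regime
suits marker panels of a few dozen features; hidden-layer size is
configurable.

**SVM.**  RBF kernel; gamma in {2^-6..2^2} and cost in {2^-2..2^6} are
searched by stratified inner cross-validation (5 folds, reduced to the
minority-class count when needed), ties resolved toward the first grid
pair, and the winner refit on the full training set.

Features enter as raw beta (or converted percentage) values; a
`standardize` flag enables per-marker z-scoring.  Both models validate
that every class has at least 2 training samples and are deterministic
given their `random_state`.  The module-level `train`/`predict` wrappers
align feature columns by probe ID and refuse mismatched panels.

## Evaluation protocol

`repeated_split_evaluate` draws stratified random 70/30 train/test splits
(stratification keeps per-class proportions; a flag restores simple
sampling), trains on 70%, and records test accuracy and Cohen's kappa per
replicate.  Kappa is (p_o - p_e)/(1 - p_e) with chance agreement from the
marginal label frequencies; two identical constant sequences define kappa
= 1.  Replicate seeds derive from
`SeedSequence([master, model, k, replicate])`, so every cell of a sweep is
independently reproducible and whole sweeps are bit-stable.

`marker_sweep` evaluates rank-prefix marker sets at each requested count;
`detect_plateau` returns the smallest count whose next `window` evaluated
counts stay within `epsilon` (default 0.005) of its mean accuracy, or a
sentinel when the curve keeps rising.  `cross_platform_predict` trains
once per marker count on the full training cohort restricted to the
probes the test cohort shares, then scores many 90% subsamples of the test
cohort and reports pooled accuracy quantiles (0/25/50/75/100%).

One caution from the synthetic experiments: replicate metrics within a
single cohort share that cohort's chance structure, so on null data the
*expected* kappa is zero only across independent cohorts — averaging more
replicates of one dataset does not shrink its dataset-level chance
association.  The null tests therefore average over several independent
panels.

## Beta/percentage conversion

The conversion table maps beta intervals to the 13 discrete percentage
levels {0, 1, 2, 5, 10, 20, 25, 40, 60, 70, 80, 90, 100}.  The two printed
strict inequalities (beta > 0.90 for 100, beta < 0.17 for 0) fix the
boundary semantics: every listed breakpoint owns the half-open cell up to
the next one, so exactly 0.90 maps to 90 and 0.87 to 80.  The inverse map
(used for sequencing read counts: p = 100 * methylated/total) takes the
midpoint of each cell as the representative beta — 0.95 for 100, 0.085 for
0 — and interpolates linearly between levels; it is an explicit, monotone
stand-in for the empirical beta-vs-percentage calibration curve, and
round-trips every beta back into its own table cell.

## Synthetic panels

`simulate_panel` draws each observation from a Beta distribution in the
mean/concentration parameterization (a = m*c, b = (1-m)*c), which respects
the [0, 1] support and the bimodal background; concentration defaults to
30 (per-probe SD about 0.05-0.09 depending on the mean).  Defaults define
the flagship cohort: 2000 probes; 60 SC + 30 iPSC + 30 ESC samples; a
hypo/hyper background (means ~0.1/~0.9, half and half); 100 SC-vs-PC loci
at mean difference 0.3 (shifted away from the nearer boundary so the
planted difference is exact); 150 ESC-vs-iPSC loci at 0.15, one third on
the X chromosome; 80 fetal/adult loci at 0.2 (the stage axis is weaker and
broader than the somatic/pluripotent one, mirroring how much harder that
comparison is); optional additive batch shifts on the logit scale.

The X chromosome gets a 5% probe quota (near the array fraction).  Male X
means sit near 0.20; in females, 30% of X probes (fully X-inactivated)
gain the full sex shift of 0.30 and the rest (escape-like) a mild 0.075.
This keeps female mean X beta (~0.34) inside the QC window while leaving
the somatic/pluripotent axis the dominant variance component, as in real
cohorts — an X-structure in which every X probe shifts fully would make
sex the first principal component, which is not what methylation cohorts
of this composition look like.  The sex benchmark instead uses an
all-iPSC cohort where every X probe shifts fully (female means near 0.5,
male near 0.15), since within a single cell type sex *is* the dominant
axis.

What the generator does **not** emulate: realistic genome coordinates and
CpG-island structure, probe cross-reactivity, cell-line-specific
signatures, tissue heterogeneity within the somatic class, or
coverage-dependent noise in count data.  Passing tests therefore show
that the pipeline recovers the structure it assumes when that structure is
present at the stated effect sizes — not that real cohorts meet those
assumptions.

`simulate_second_platform` redraws fresh samples from the same planted
means on a random probe subset with extra logit-scale noise (an
independent-cohort stand-in); `simulate_outliers` injects one labeled
outlier per QC check (a sex mislabel, a mid-beta flood, a global +0.3
shift).

## Benchmark problem sizes

The repeated-subsampling benchmarks in `methylclass.workflows` (and
`scripts/acceptance.py`) use the flagship panel with 50 split replicates
and the top 20 markers (SC vs PC), and an 80-sample all-iPSC panel with 50
replicates and the top 2 markers (sex).  The test suite exercises the same
machinery on smaller panels (300-800 probes, 15-30 samples per group, 8-20
replicates), sizes at which every planted-recovery property is already
stable.

## Known limitations

* The EB batch model assumes approximate normality per probe, which the
  logit transform only approximates for betas near 0 or 1; clipped values
  are counted and logged but not otherwise tracked.
* The NNET objective is non-convex; different seeds can reach different
  optima.  All evaluation protocols seed each fit explicitly.
* `cross_platform_predict` assumes the overlapping probes measure the same
  quantity on both platforms; no cross-platform recalibration is applied
  beyond the optional percentage conversion.
* The conversion table's inverse is a fixed interpolation, not a fitted
  calibration; count-derived betas inherit its step-level resolution.
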