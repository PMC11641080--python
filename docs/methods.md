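# Methods

This note documents the models, defaults and numerical choices behind
`editsig`, in the order the pipeline runs them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohort model

The generator emulates a four-group psychiatric cohort (CTRL/BD/SZ/SA)
profiled for A-to-I editing over an 8-gene amplicon panel.

**Editing proportions.** Per-sample latent editing proportions follow a
logistic-normal model: a Gaussian vector on the logit scale with
per-class mean `baseline + group shift`, covariance
`D·C·D` where `C` is a unit-diagonal correlation matrix (default:
per-gene blocks with within-gene r = 0.3, zero across genes) and `D`
holds per-site latent SDs (default 0.6 logit units). The inverse logit
maps to (0, 1), clamped at ε = 1e−4 to keep the logit finite.
Observed values add beta-binomial read noise: `θ ~ Beta(pκ, (1−p)κ)`
with concentration κ = 300, then `Binomial(depth, θ)/depth` at depth
10,000 (mirroring the per-sample QC floor).

**Defaults as study conditions.** Class sizes (85/39/31/14), per-class
male fractions, the five ATC psychotropic-treatment prevalences
(controls untreated; all SA patients on antipsychotics) and age
moments (truncated normal on 18–65) reproduce the published cohort
margins. Per-site baseline editing cycles through
{3, 8, 15, 25, 6, 12, 20, 10}% — the range typical of targeted blood
editing panels. No per-site effect sizes are published, so the default
group effects are a calibration choice made once: a +1.2 logit shift
on the first two sites of each affected gene, with BD affected on
seven genes and SZ (KCNJ15, PRKCB) and SA (KCNJ15, LYN) on two each,
mirroring the qualitative group structure of the study. A +1.2 logit
shift against a 0.6-SD latent scale gives single-marker AUCs near
0.92, consistent with the strong reported separations.

**Reads.** `generate_reads` draws, per read, a joint (phased) editing
pattern with sites independent given the proportions; an edited
position reads as G (+ strand) or C (− strand). Sequencing error
(default 1e−3) replaces any call with a uniformly random other base.
Reads are "born aligned": no quality or alignment simulation.

**What the generator does not emulate.** Real cohorts have
batch/library-size effects, site-specific error profiles, linkage
between editing and covariates (treatment effects on editing), and
non-Gaussian latent structure. Passing tests therefore demonstrate
correctness of the *procedures* under the stated model, not clinical
performance on real data.

## Editing quantification

Editing at a site is `edited/(edited+reference)` counts — G/(A+G) on
the + strand, C/(T+C) on the − strand; other bases are excluded from
the denominator. Samples under 10,000 total reads fail QC (all values
missing); per-site fractions additionally require 50 covering reads
(the per-sample floor alone leaves single-site binomial noise
unbounded). Isoform biomarkers are per-read pattern frequencies over a
gene's sites; reads with an off-base call at any site are excluded
from pattern counting. Motif biomarkers average a declared site group
(the pipeline declares one all-sites motif per gene). Background
filtering drops biomarkers whose cohort median falls strictly below
0.005 — strictly, so a zero threshold disables the filter.
Normalization divides each biomarker by its gene's per-sample global
editing (pooled edited over pooled covered reads); zero global editing
yields a missing value rather than a division.

## Feature selection

The cascade runs cheapest-first: raw-p filter → correlation pruning →
Boruta; mutual information is recorded for ranking only.

- **Adaptive test.** Shapiro–Wilk per group at α = 0.05; if both
  groups pass, a two-sided F-test at α = 0.05 chooses Student vs
  Welch t; otherwise the two-sided Mann–Whitney with tie correction.
  A biomarker passes the filter when any pairwise group comparison has
  raw p ≤ 0.05 (one selection list serves all comparisons).
- **Correlation pruning** at |Pearson r| > 0.6 scans pairs in
  row-major order and removes the member with the larger mean absolute
  correlation to all features (ties remove the later column);
  zero-variance features are retained with a warning.
- **Boruta.** Each run appends one permuted shadow copy per undecided
  feature, fits a random forest (default 100 trees), and computes
  permutation importance on an internal stratified 30% held-out split
  (training-set permutation importance of a fully grown forest is
  uninformative). A feature scores a hit when it beats the best
  shadow. Hits are tested against Binomial(runs, ½) two-sided with
  Holm correction at α = 0.01; decided features leave the pool, and
  the loop stops early when none remain Tentative (cap 100 runs;
  leftover Tentative counts as not selected — conservative and
  reproducible).
- **Mutual information**: plug-in estimate in nats after
  equal-frequency binning into ⌈n^{1/3}⌉ bins.

## Target Editing Index

For each gene with selected variants: variants are z-scored (so
coefficients are comparable across editing scales), combined with the
Su–Liu direction `a ∝ (S_ref + S_case)^{-1}(μ_case − μ_ref)` — the
linear combination maximizing ROC AUC under Gaussian markers — fitted
on controls vs pooled patients (configurable via `reference`), and
Box-Cox transformed. The coefficient vector has unit L2 norm and is
oriented so cases score at least as high as references on the fit
data, making group-mean differences sign-stable. A ridge
`ε·I, ε = 1e−6·trace(S)/p` handles ill-conditioned covariance sums.
Box-Cox shifts by `max(0, 1e−6 − min)` and picks λ on a [−2, 2] grid
(step 0.01) by profile log-likelihood; the transform is strictly
monotone, so rank statistics (Mann–Whitney, empirical AUC) are
provably unchanged — asserted exactly in the tests. Group differences
are tested per pairwise comparison with BH adjustment across genes
within each comparison, flagged at FDR < 0.10.

Because the combination is fitted to the analyzed samples, its
in-sample AUC is optimistically biased (measurably so at n of a few
hundred with several variants); the null behaviour of the TEI is
therefore checked out-of-sample in the test suite, and reported
signature performance should be read as training-set performance.

## mROC virtual markers

Z1…Z6 use the same Su–Liu machinery on the globally-normalized
selected biomarkers, fitted per comparison on its two groups
(complete-case samples; a warning marks the ridge path when features
outnumber samples). The empirical AUC is the Mann–Whitney statistic
with half-credit ties — verified against brute-force pair enumeration.
The cutoff maximizes Youden's J = Se + Sp − 1 (ties → smaller cutoff;
"positive" means Z ≥ cutoff), a standard choice the study's summary
table does not name; PPV/NPV follow Bayes' rule at the observed
prevalence by default. Performance is fitted and reported on the full
comparison sample, without internal cross-validation — deliberately
mirroring an apparent training-set protocol, and documented as
optimistic. For the two 3-axis scatter exports every sample is
projected on every axis with that comparison's coefficients.

## Integrated random forest

Features are the selected biomarkers on their raw (0–1) scale plus a
6-column covariate block (sex, five ATC treatment flags). The split is
stratified per class: ⌈0.7·n⌉ training samples (for class sizes
85/39/31/14 this gives exactly 120/49). For each mtry in 1…20 (capped
at the feature count) a 1000-tree forest with minimum leaf size 1 is
fitted; the mtry maximizing out-of-bag accuracy wins, ties to the
smallest. Votes are tree fractions (rows sum to 1; argmax is the
prediction). Missing values are imputed with training-set medians
before fitting (logged). Test-set metrics are computed once and never
used for tuning. Importance combines four indicators: permutation
importance (accuracy drop on held-out data), Gini impurity decrease,
mean minimal depth (features absent from a tree are penalized with
that tree's depth + 1), and times-a-root counts.

## Monte-Carlo augmentation

Per class, biomarkers are clamped to [1e−4, 1−1e−4], logit-
transformed, and summarized by their mean and covariance; the
covariance is shrunk toward its diagonal, `(1−γ)S + γ·diag(S)`, with
the smallest γ (grid step 0.05) giving condition number ≤ 1e6.
Sampling draws multivariate normals per class and maps back through
the inverse logit, so synthetic biomarkers stay in (0, 1); covariates
are Bernoulli at class prevalences. The 500 default points are
allocated by largest-remainder apportionment of the class weights
(for weights 85/39/31/14 over 169: 252/115/92/41). The Gaussian-on-
logit law is an interpretation of "reproducing the dataset's structure
and statistical properties" as matching first/second moments and
correlation; no copulas or SMOTE variants.

Fidelity compares synthetic vs original per class and feature:
|Δmean| ≤ 0.3 pooled SDs, SD ratio in [0.7, 1.4], max |Δcorrelation|
≤ 0.25. These thresholds are calibrated for moderately sized groups;
with very small classes (the 14-sample SA group) original-moment
estimation noise alone produces some failing cells, which the
pipeline reports honestly rather than masking. Prediction error on
synthetic points carries exact Clopper–Pearson 95% intervals. Note
that a generator fitted to data without real class signal still
replicates the *sampled* class-mean fluctuations a forest may have
memorized, so synthetic error estimates are meaningful relative to
held-out error, not as an absolute null.

## Pipeline, I/O and determinism

Stages run strictly forward (no stage reads a later stage's outputs):
simulate → quantify → select → TEI → signatures → RF → augment →
summary. The simulate stage emits per-site base-count and per-read
pattern-count TSVs — the quantification module's documented count-
table input — rather than cohort-scale SAM files; SAM export/import is
provided for read-level interchange and covered by a round-trip test.
All tables are TSV ('.' decimal, `%.6g` floats), panels 6-column BED
(0-based half-open), reads SAM with minimal headers. One global seed
propagates to every stochastic stage with fixed offsets; identical
config + seed reruns are byte-identical (timestamps live only in
`log.txt`; the JSON manifest records versions, parameters and output
hashes). The default end-to-end run takes about a minute on one CPU.

Cohort summaries print counts before percentages, percentages to one
decimal rounded half away from zero. When built from per-group
summary cells, the overall age mean is the size-weighted group mean
and the overall SD combines within- and between-group sums of
squares. (Published cohort tables sometimes label dispersion
inconsistently — caption SEM vs column SD; this package reports SD.)

## Test-suite problem sizes

Simulation-based checks use sizes chosen to keep the whole suite
fast while leaving comfortable Monte-Carlo margins: the Gaussian
closed-form mROC check at n = 20,000/group (AUC tolerance ±0.01);
Boruta calibration at n = 200/class with 5 planted features at 1.5 SD
(20 seeds, default 100-tree forests) and 50 permuted-label cascade
seeds (50-tree forests — the decision rule and α are unchanged, only
the per-run forest is smaller); forest importance
ranks at n = 100/class over 10 seeds with 300-tree forests at fixed
mtry (the full 1000-tree, 20-point OOB grid is exercised once);
Monte-Carlo fidelity self-consistency at n = 5000 synthetic points
per seed for 50 seeds. Null-band checks are sized so the asserted
band is ≥ 3–4 Monte-Carlo standard errors.

## Known limitations

- Selection, TEI and signatures are fitted and reported in-sample, as
  in the emulated protocol; no nested cross-validation.
- The background-evaluation rule (cohort-median threshold) and motif
  definition (site-group mean) are configurable operationalizations;
  the original procedures are not fully specified publicly.
- Whether the published 32-marker list was selected jointly across all
  four classes or per comparison is not stated; this package selects
  jointly and uses one list for all comparisons.
- The logistic-normal + beta-binomial generator understates real
  biological and technical heterogeneity; absolute performance numbers
  on synthetic cohorts are not clinical claims.
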