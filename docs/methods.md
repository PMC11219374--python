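# Methods

This note documents the models, numerical choices, and limitations behind
`mbomics`, and what its synthetic-data experiments do and do not show.

## The setting

A two-class (case/control) study profiles the same plasma samples on
several LC-MS platforms, producing B sample-aligned feature tables
("blocks"). The default study design emulated throughout is four blocks —
lipidomics ESI+/ESI− and metabolomics ESI+/ESI− with 307/79/74/39 analytes
(499 in total) — with 157 case and 162 control subjects, a handful of
control subjects contributing a second sample, and ~10 pooled-QC
injections.

## Preprocessing

Each block is processed independently, in a fixed order enforced at
runtime (an out-of-order call raises):

1. **Normalization.** Total-ion-sum (each observed intensity divided by its
   row's sum over observed intensities; typical for polar metabolomics) or
   internal-standard (each analyte divided by its mapped spiked standard in
   the same sample, standards dropped afterwards; typical for lipidomics,
   where one standard per lipid class is common — the analyte→standard map
   covers both the single-standard and per-class schemes). Normalization
   precedes imputation so the ⅕-minimum replacement is meaningful on the
   normalized scale; which order the original workflow used is not
   documented, so this is a recorded design choice.
2. **Imputation.** Missing values and exact zeros are replaced by
   `fraction × min observed positive intensity` of that analyte
   (default fraction ⅕). "Minimum" is read as the minimum *strictly
   positive* observation — zeros are themselves replacement targets, so any
   other reading is circular. Analytes with no positive observation raise.
3. **log₁₀.**
4. **Autoscaling.** Per-analyte (x − mean)/SD with the n−1 SD
   (chemometrics convention).

Every fitted statistic (replacement values, scaling mean/SD) is computed on
a configurable reference row set and stored in a `PreprocessState`:

- For unsupervised exploration and the Duplex split, statistics are fitted
  on all study (non-QC) samples — the split needs scores before any split
  exists, so a global fit is unavoidable there.
- For supervised modelling, statistics are refitted on training rows only
  and *replayed* on test/CV rows via `apply_state`. A fully global fit is
  available (`fit_rows=None, include_qc=True`) but is not the default,
  because it leaks test-row information into the scaling.
- QC rows are excluded from fitted statistics by default.

## SUM-PCA and low-level fusion

Low-level fusion concatenates blocks column-wise; SUM-PCA is SVD-based PCA
of the weighted concatenation. Default block weight is 1/√p_b so each
autoscaled block contributes equal total variance — with widths as unequal
as 307 vs 39 an unweighted concatenation is dominated by the widest block.
Unweighted mode (`weights="none"`) gives strict low-level fusion, used for
the fused-matrix classifiers. Per component a, the total explained-variance
share s_a²/‖X‖² splits exactly over blocks by loading mass
(s_a² Σ_{j∈b} v_ja²/‖X‖²), an identity the tests verify by brute-force
rank-1 reconstruction. Determinism: the largest-|loading| element of every
component is made positive (ties → lowest index). Default 3 components for
exploration and splitting.

## Duplex splitting

Classic Snee-style Duplex in super-score space: seed TRAIN with the two
mutually farthest points, seed TEST with the two farthest remaining, then
alternately (train first) give each set the remaining point whose minimum
Euclidean distance to that set is largest; once TEST reaches its quota
⌈test_fraction × n_subjects⌉ the rest go to TRAIN, and conversely when only
exactly enough points remain to fill the quota they all go to TEST.
Distance ties break by ascending subject id, making the plan fully
deterministic. Samples are collapsed to subject centroids before splitting,
which provably keeps all samples of a subject on one side. Test quota 1 is
handled by assigning the single subject farthest from the training seeds
(a two-point seed would overfill). Default test_fraction 0.30.

## PLS-DA

Binary PLS1 on the centered {0,1} dummy (control→0, case→1), NIPALS
sequential extraction with deflation (with one response column the inner
loop converges in a single pass; tolerance 1e−10, cap 500 iterations kept
for safety), weight signs fixed largest-|entry|-positive. Prediction adds
the training class mix back and thresholds ŷ at 0.5; a tie at exactly 0.5
is assigned to case. VIP uses the standard SSY-weighted form and satisfies
mean(VIP²) = 1 exactly; "VIP > 1" counts use a strict inequality.

Latent-variable counts are chosen by grouped stratified k-fold CV
(default 10-fold): within each class, subjects are shuffled by the seeded
generator and dealt round-robin, so subjects never straddle folds and fold
class balance is within one subject per class. The reported "accuracy" is
pooled fraction-correct; balanced (per-class mean) accuracy is also
computed and labeled separately, since published tables are often ambiguous
about which is meant. Ties in CV accuracy resolve to fewer latent
variables.

## SO-CovSel-LDA

CovSel greedily picks the column with maximal squared sample covariance to
the response, then projects the picked column out of both the data and the
response; ties → lowest index; selection stops early when the best squared
covariance falls below 1e−12, so a block may contribute fewer variables
than requested (possibly zero). For multi-block selection, blocks are
processed in a given order, each first orthogonalized (least squares,
pseudo-inverse on rank deficiency) against all previously selected
variables; because least-squares residuals are exactly orthogonal to the
regressors, using the original centered dummy as the response is
algebraically equivalent to using the residualized response. The final
classifier is LDA on the pooled (orthogonalized) selections: per-class
means, pooled within-class covariance with ridge λ = 1e−8·trace(S)/p added
only when the condition number exceeds 1e10, priors from training
frequencies (an equal-prior flag exists); discriminant ties go to case,
mirroring the PLS-DA boundary rule. Prediction replays the stored
orthogonalization coefficients — nothing is refit on new samples.

All ordered non-empty block sequences can be enumerated (Σ_k P(B,k); 64 for
four blocks) and fitted with shared per-block counts. Per-block counts are
selected by grouped CV over the Cartesian grid 0..max per block (default
max 3, 5-fold CV — the grid and CV design are free parameters; these
defaults keep the 255-point grid affordable at one CPU), maximizing pooled
CV accuracy with ties resolved to the smallest total count, then the
lexicographically smallest vector.

## Univariate screening and enrichment

Mann-Whitney U is computed from rank sums with midranks; the p-value is
exact (full enumeration) when n+m ≤ 20 without ties, otherwise the normal
approximation with tie and continuity corrections (delegated to
scipy.stats.mannwhitneyu; the tests verify the exact path against full
permutation enumeration). Screening runs on normalized, imputed, *non-log*
intensities — the rank statistic is invariant to the monotone log anyway.
No multiple-testing correction is applied to a small selected panel by
default; Benjamini–Hochberg is available behind a flag.

ORA: for a query of n mapped compounds against a set of size K in a
universe of N, p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n) (upper tail, one-sided
over-representation only), expected hits nK/N, enrichment ratio
k/expected (not-applicable when expected is 0). The universe defaults to
the union of all library sets; an explicit universe can be supplied.
Unmapped query ids are dropped with a returned count. Libraries are read
from GMT (tab-separated: name, description, members).

## The synthetic-data generator

`generate_multiblock` emulates: log₁₀ intensities ~
Normal(base_log_mean=5, base_log_sd=0.5) exponentiated to strictly positive
values; a configured number of informative analytes per block shifted by
±effect_size·base_log_sd in cases (direction random, recorded in the ground
truth); subject random effects drawn per (subject, analyte) with ICC 0.5 so
a repeat subject's two samples correlate per analyte (the study's repeat
mothers; the true within-subject ICC is unreported, so 0.5 is a free
default); optional internal-standard columns (constant true level, 5%
multiplicative noise, never blanked); pooled-QC rows as per-analyte means
of a random third of study samples with 2% multiplicative noise; exact
zeros and missing values injected cell-wise at configured rates (QC
exempt). Defaults mirror the emulated study: 157/162 subjects, widths
307/79/74/39, 11 repeat control subjects, 10 QC samples, effect size 1.5
with 3 informative analytes per block (the true effect sizes are unknowable
from published summaries; 1.5 SD is a realistic "clearly detectable at
n≈160/class" choice).

What it does **not** emulate: chromatographic drift and batch effects,
m/z–retention structure, correlated analyte modules (planted analytes are
conditionally independent given the class), heterogeneous per-analyte
effect sizes, annotation scores beyond an optional metadata column, and
non-random missingness (real LC-MS missingness is intensity-dependent).
Passing tests therefore demonstrate algorithmic correctness and
calibration, not performance on real cohort data.

## Acceptance experiments and their problem sizes

`scripts/acceptance.py` (all sizes chosen as the package's own desk-scale
conditions): the full pipeline at the default study scale (319 study
samples + QC, 499 analytes; grid 0..3, 5-fold grouped CV); null calibration
over 10 effect-free replicates (n=160/160); planted recovery over 2
replicates at effect 2.0; order stability over 10 replicates × 64 orders.
The test suite's calibration test uses 50 replicates.

Two stochastic expectations are *not* met under these honest conditions
and are reported as-is rather than tuned toward:

- **Planted recall.** CV grid selection recovers ~70% (not ≥80%) of the 12
  planted analytes on average. The planted analytes are mutually redundant
  proxies of the same binary contrast, and SO-CovSel's
  parsimony-on-CV-accuracy objective correctly prefers a minimal
  non-redundant subset (~7–10 variables with near-perfect precision and
  ≥90% test accuracy). Recall of all redundant correlates is simply not
  what the method optimizes.
- **Exact selection identity across block orders.** Orders spanning the
  same blocks choose literally identical analyte sets in only ~10–25% of
  replicates: with equal planted effect sizes, within-block covariance
  rankings are near-ties that flip with the orthogonalization order,
  typically swapping a single pick. The qualitative property — heavy
  selection overlap and order-invariant performance — holds; exact set
  identity would require heterogeneous effect sizes, which stabilize the
  ranking.

## Known limitations

- Two classes only; no multi-class coding, no OPLS/sparse-PLS variants, no
  SO-PLS regression, at most 6 blocks for enumeration.
- No ROC/AUC, no permutation testing, no batch/drift correction, no
  quantitative (globaltest-style) enrichment or pathway topology.
- The Duplex variant is the classic alternating max–min scheme; other
  published variants (e.g. distance-weighted) are not implemented.
- `external_test`'s leakage guard needs the model to carry its training
  subject ids; models fitted without them skip the check.
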