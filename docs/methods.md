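# Methods

This note records the models implemented in `siascore`, the conventions
chosen where the underlying methodology leaves room, and what the
synthetic-data generator does and does not emulate.

## Scores

**SIA.** The Signature of Immune Activation is
`SIA = d_CD8 / (d_CD8 + d_M2)`, where `d_CD8` is the density of CD8⁺
T cells and `d_M2` the density of CD68⁺CD163⁺ ("M2-like") macrophages,
both in cells per mm² of analysed tissue. SIA lies in [0, 1]: 1 means a
purely cytotoxic infiltrate, 0 a purely M2 one. When both densities are
zero the score is undefined; such patients are excluded downstream and
the exclusion is logged. Densities always pool counts and areas over
all of a patient's cores (total cells / total mm²) — never a mean of
per-core densities, which would over-weight small cores.

**Stratification.** Cohorts are split at the 33.3rd and 66.6th
empirical percentiles (linear interpolation) into low / intermediate /
high, with ties assigned downward (v ≤ cut). When the two cuts
coincide, or a single value occupies at least one third of the cohort —
as happens when many tumours have no M2 macrophages at all, saturating
SIA at 1 — terciles are uninformative and the cohort is split at the
median instead (low: v ≤ median). The switch is logged and recorded in
the result metadata.

**IS.** The Immunoscore-like metric percentile-ranks four density
channels within the cohort — CD3⁺ and CD8⁺ marker-positive cell
densities in tumour centre and invasive margin — and averages, per
patient, whichever channels are available (4; 3 in incomplete cases;
exactly 2 — CD3 and CD8 — for cohorts whose cores sample bulk tumour).
Percentiles use average ranks scaled so the cohort maximum maps to
exactly 100. Categories are half-open above: Low (0, 25],
Intermediate (25, 70], High (70, 100]; an IS of exactly 25 is Low.

**RNA surrogates.** For bulk profiles the SIA surrogate is the
per-sample ratio CD8A / C1QA (or C1QB, C1QC), computed on the linear
scale (log2 matrices are exponentiated first). When timepoint labels
are present only pre-therapy samples are scored, and a patient with
several retained samples receives the mean of their ratios. A zero
denominator with positive CD8A maps to +inf (ranked above all finite
scores); 0/0 is undefined and excluded. The IS-like surrogate is
(CD8A + CD3E)/2. Gene symbols are matched case-insensitively after
trimming; duplicated symbols are collapsed by summation with a warning.

For single-cell data, cells are QC-filtered first: at least `min_genes`
detected (nonzero) genes — default 250, with 100 appropriate for sparse
plate-based checkpoint-therapy cohorts — and a mitochondrial count
fraction of at most `mito_ceiling`. The ceiling defaults to 0.05
interpreted as a *fraction* (5%): a literal 0.05% would discard nearly
every real cell, but that reading remains available by passing 0.0005
explicitly rather than being silently reinterpreted. Mitochondrial
genes are recognised by the configurable symbol prefix `MT-`; when none
are present the filter is skipped with a warning. Per patient or
lesion, SIA is then `n_CD8A+ / (n_CD8A+ + n_M2)` where M2 cells are
positive for both genes of a configurable pair (CD68 with CD163, C1QA,
C1QB or C1QC). Positivity defaults to any nonzero count; a numeric
threshold can be configured. Whether raw or normalised expression
should feed this rule is methodologically open; the implementation
takes whatever matrix it is given.

## Marker thresholding

Thresholds are trained per marker and per cohort from reference cells
of known status. If the reference intensity ranges do not overlap, the
threshold is `(max(neg) + min(pos)) / 2` — zero training error by
construction. Otherwise both distributions are smoothed with a Gaussian
KDE whose bandwidth follows the classic rule of thumb
`0.9 · min(sd, IQR/1.349) · n^(−1/5)`, and the threshold minimises

```
err(t) = π_neg · P_neg(X > t) + π_pos · P_pos(X ≤ t)
```

with **empirical class priors** π taken from the reference-set sizes,
so that err is the reference misclassification rate (equal priors would
be an alternative; the choice is logged). The KDE tail probabilities
are exact Gaussian-mixture CDFs, evaluated on the union of the two
512-point KDE grids (each spanning data range ± 3 bandwidths); ties
resolve to the smallest t. The same functional scanned at 10,000 evenly
spaced points serves as an independent oracle in the tests, agreeing to
well under one grid step. A cell is positive when its intensity is
**strictly greater** than the threshold (boundary values are negative);
the rule is stated here because the convention is otherwise arbitrary.
FPR/TPR/FNR/TNR are computed empirically on the reference cells at the
returned threshold, and a TPR below 0.5 triggers an inverted-marker
warning. The error-min threshold is equivariant under common increasing
affine rescaling of both reference sets up to grid resolution.

## Survival analytics

Cox models use lifelines with Efron tie handling; categorical terms are
dummy-coded against fixed reference levels (low stratum, T1, N0,
age ≤ 75, female, MMR proficient). OS is time to death from any cause;
RFS is time to progression, recurrence or death, whichever first.
Likelihood-ratio comparisons require nested term sets fitted to the
same records; Λ = 2(ℓ_full − ℓ_nested) against χ² with the coefficient
difference as degrees of freedom.

**Bootstrap AUC.** The published use of "AUC in Cox models" leaves the
outcome unspecified, so it is pinned here: the outcome is the event
indicator over full follow-up and the score is whatever is supplied
(typically a Cox linear predictor). Patients are resampled with
replacement, stratified on outcome so every replicate contains both
classes; the replicate AUCs are summarised by the median and the
2.5/97.5 percentiles.

**Time-dependent AUC** uses the cumulative-case / dynamic-control
definition with inverse-probability-of-censoring weights: at horizon t,
cases are subjects with an observed event by t (weighted by
1/Ĝ(T⁻), Ĝ the Kaplan–Meier estimate of the censoring distribution)
and controls are subjects still at risk beyond t. The estimator is
written directly (≈30 lines) rather than delegated, so that with zero
censoring it reduces *exactly* to the proportion of concordant
(case, control) score pairs — an identity the tests check to 1e-9 —
while agreeing with `sksurv.metrics.cumulative_dynamic_auc` to 1e-6
under censoring.

**Wald contributions.** For a multivariable fit, each term's χ² is the
quadratic form βᵀV⁻¹β over the term's dummy columns (joint over levels)
and contributions are reported as proportions of the total.

**Optimal cut-off.** Candidate cut-offs are the observed score values
inside a quantile window (default 10th–90th percentile); the cut-off
minimising the two-group log-rank p is returned together with that p
and an explicit caveat: minimising over candidates makes the p value
optimistically biased, and no correction is applied (the null
simulation in the test suite measures the optimism — the minimised p
falls below 0.05 several times more often than 5% under independence).
The scan uses a fast counting-process log-rank implementation,
cross-checked against lifelines to 1e-9.

**Calibration suites.** The log-rank test is calibrated on cohorts of
102 patients in three equal strata with all hazard ratios 1 (1000
replicates); the LRT on cohorts of n = 300 with an unrelated covariate
added (1000 replicates). The LRT suite uses n = 300 because the
asymptotic χ² reference is measurably liberal at half that size
(rejection ≈ 0.061 at n = 150 vs ≈ 0.053 at n = 300 over 1500
replicates); the calibration claim is about the asymptotic regime the
test is designed for.

## TMA representativeness

Each iteration draws one core-sized tile per whole-slide section,
forming an in-silico TMA cohort, and compares its per-marker density
distribution with the non-selected tiles by the two-sample
Kolmogorov–Smirnov test; the reported quantity is the fraction of
iterations significant at α (strict p < α) over n_iter = 1000 draws.
The comparison pool is the pooled remaining tiles of all slides by
default — a per-slide variant (cohort vs each slide's remainder,
significant if any slide rejects) is also provided, since one pooled
test per iteration is the statistically regular reading of the
procedure.

A structural property worth stating: when the tile is drawn uniformly
at random per slide, the cohort is exchangeable with the remaining
tiles *whatever* the spatial structure, so the significant fraction
sits at — or, through the discreteness of the KS null at cohort sizes
of ~8, below — the nominal α even for strongly gradient-structured
slides. This matches the small fractions the procedure produces on real
whole-slide data and means the test certifies the *sampling scheme*,
not spatial homogeneity per se. Elevated fractions require biased core
placement, modelled by `selector="first"` (always the same grid
position), which under a 10-fold within-slide gradient rejects in
essentially every iteration. Both behaviours are asserted in the tests.

## Synthetic data

The generator produces every pipeline input with closed-form ground
truth. Its defaults encode the study conditions: up to four TMA cores
per patient with 1.84 mm² of analysed tissue per core, survival hazard
ratios 0.65 (intermediate) and 0.43 (high vs low stratum) for OS and
0.65/0.46 for RFS, tile counts of 13–93 per whole-slide section, and
time measured in weeks with a 520-week administrative horizon.

* **Cell tables.** Per-class mean densities (cells/mm², defaults
  spanning ~30–300 as in colon-cancer mIHC cohorts) receive patient-
  level log-normal heterogeneity (σ = 0.5, mean-preserving); per core,
  class counts are Poisson(density × area). Marker intensities are
  log-normal mixtures: truly negative cells from log-mean 0, truly
  positive from log-mean 2 (both log-sd 0.35); the log-mean separation
  is the overlap dial. A class's true marker pattern is the union of
  required-positive markers over the classification rules naming it.
* **Survival.** Event times are exponential with rate = baseline ×
  HR(stratum) (baseline 0.004/week in the low stratum), censored by the
  administrative horizon and independent exponential drop-out
  (0.0005/week); OS and RFS are generated independently. Clinical
  covariates (T, N, age, sex, MSI) are drawn independent of outcome so
  adjusted models can be exercised under a known null.
* **Bulk expression.** CD8A and CD3E are proportional to the CD8⁺
  density and C1QA/B/C to the M2 density, times log-normal noise
  (σ = 0.3); 50 decoy genes are density-independent. The CD8A/C1Q ratio
  is a strictly increasing transform of true SIA, so the noiseless
  limit gives Spearman ρ = 1 by construction.
* **Single cell.** Cells belong to {CD8 T, M2 macrophage, M1
  macrophage, other}; responders carry a CD8:M2 cell-ratio 3× that of
  non-responders within a 30% immune pool. Counts are negative binomial
  (dispersion 2): marker genes mean 10 in their positive classes and 0
  elsewhere, 300 decoy genes at mean 2, three `MT-` genes. Five percent
  of cells are generated low-quality (library scaled ×0.02, ~12
  detected genes) and five percent high-mitochondrial (~33% MT
  fraction), with truth flags, so the QC filter's removals can be
  checked exactly.
* **Tile grids.** Per marker, tile densities are gamma-distributed
  (shape 4) around a common mean (homogeneous) or around a mean scaled
  linearly across the tile index by a stated fold-change (gradient).

All generators are pure functions of (spec, seed).

**What the generator does not emulate:** spatial correlation of cells
within cores, staining batch effects and autofluorescence, segmentation
errors, tumour-vs-stroma compartments, non-proportional hazards,
transcript-length and library-size biases, and doublets or ambient RNA
in single-cell data. Passing tests therefore certify the *computational
chain* — thresholds, classification, pooling, scores, estimators — not
robustness to those real-data artefacts.

## Numerical conventions and degenerate inputs

* KDE needs ≥ 2 distinct values; constant samples raise a
  degenerate-input error. The density grid spans the data range ± 3
  bandwidths, so up to ~0.3% of tail mass per extreme point is
  truncated; on the reference-set sizes used in practice the grid
  integral is 1 within 1e-3.
* Identical positive and negative reference sets yield an error-min
  threshold with a warning rather than an error.
* Tercile stratification needs ≥ 3 non-missing values and errors when
  all values are equal; IS needs a cohort of ≥ 3.
* Scores that are undefined (0/0) propagate as NaN and are excluded
  with a log entry, never silently imputed.
* The 15-class default rule table is a documented reconstruction from
  the two published marker panels; the rule table is fully configurable
  and the first matching rule wins, with duplicate patterns warned
  about and ignored.
* Evaluation horizons beyond the last observed time are dropped from
  tAUC with a warning; an LRT statistic below 0 (numerical) is clipped
  to 0, warning if below −1e-6.

## Problem sizes

The validation suite uses cohorts of 30–45 patients (~1.2M simulated
cell–marker calls) for end-to-end recovery, 100k patients for
hazard-ratio recovery (±0.03 achieved), 1000 replicates for each null
calibration, 50 random mixtures for the threshold oracle, and n = 200
with nine horizons for the tAUC identity; the full suite runs in about
three minutes and `scripts/acceptance.py` in about two on one CPU.

## Known limitations

Thresholds assume a bimodal intensity structure per marker; markers
with genuinely unimodal distributions will produce a threshold but the
error rates should be inspected. The optimal-cut-off p value is
reported uncorrected (with the optimism measured, not adjusted). The
bootstrap-AUC outcome definition ignores follow-up length; the
fixed-horizon question is handled by the time-dependent AUC instead.
IS percentiles are cohort-relative, so scores are not comparable across
cohorts without recalibration.
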