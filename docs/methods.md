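# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices that matter for reproducing results.

## Lifespan: Gompertz decomposition

**Model.**  Mortality hazard h(t) = α·e^{βt} with t = 0 at adult eclosion;
α > 0 is baseline mortality (per day), β ≥ 0 the aging rate (per day).
Survival is S(t) = exp(−(α/β)(e^{βt} − 1)), continuous in the exponential
limit β → 0.

**Census coarsening.**  Deaths are counted only at transfers every 3.5
days, so observed times are interval-censored.  The default imputation
places each death at its interval midpoint; the right-endpoint convention
is available.  Midpoint was chosen because at a 3.5-day cadence relative to
median lifespans of 30–60 days it minimizes systematic bias in both α and
β; the right-endpoint rule inflates times by ~1.75 days on average.  A full
interval-censored likelihood was considered and deliberately left out: at
this cadence the midpoint approximation changes β estimates by well under
one standard error in the simulation settings used here.

**Empirical-hazard diagnostic.**  Nelson–Aalen increments dH_j = d_j/n_j at
distinct death times are smoothed with an Epanechnikov kernel; mass is
reflected at both ends of the event range to curb boundary bias.  The
automatic bandwidth is the normal-reference rule 1.06·sd(death times)·
n^{−1/5} (days), user-overridable — the external smoother the field
typically uses performs comparable global bandwidth selection but
publishes no closed-form rule.  The Gompertz check is OLS of ln h(t) on t
over the grid with the outer 10% trimmed at each end and nonpositive
hazard values dropped; slope estimates β, intercept estimates ln α, and R²
near 0.9+ supports the parametric model.  The kernel estimate is only
trustworthy where deaths are dense; tests evaluate it between the 10th and
90th percentile death times.

**Maximum likelihood.**  Right-censored log-likelihood
ℓ = Σ_deaths[ln α + β t_i] − α Σ_all (e^{β t_i} − 1)/β, with the β → 0 term
computed via expm1 and a series below |β| < 1e−12.  Optimization runs over
(ln α, ln β) with the analytic gradient (L-BFGS-B, Nelder–Mead fallback,
gradient tolerance 1e−8), initialized from the log-hazard OLS when ≥ 10
deaths are available.  ln β is bounded below at ln(1e−9); exponential-like
data park there and recover the exponential MLE α = deaths/Σt.  Standard
errors come from inverting the observed information, obtained by central
differences of the analytic gradient on the natural (α, β) scale, so the
Wald z-tests compare parameters in their natural units.

**Comparisons.**  All pairwise z = (p₁ − p₂)/√(SE₁² + SE₂²) with two-sided
normal p-values; Holm correction is applied separately within the α family
and the β family, matching the all-pairwise design.  Holm is implemented
directly (vectorized step-down); BH uses statsmodels.

## Imaging traces: pH-corrected ratio analysis

**Signal model.**  Per ROI, the background-subtracted 488/405 ratio is
treated as (true ratio)·(bleach envelope)·(noise), with an additive pH
component proportional to the pHrodo deviation.  Bleach correction and
baseline normalization are a single step — an exponential A·e^{−kt}
(k ≥ 0) fitted to the pre-treatment ("premix") window and divided out — 
because a separate per-channel bleach model is not identifiable from
ROI-level data.  The fit is OLS on log ratios, which makes normalization
exactly idempotent (after division the log-slope is zero by construction);
a final rescale pins the premix mean to 1.  Traces with nonpositive premix
ratios fall back to a constant baseline and are flagged.

**pH calibration.**  Deviations are measured from the mean of the 30 s
(configurable) preceding NH₄Cl onset.  The pHrodo deviation is fractional
(ΔP/P̄), so the calibration — and the whole chain — is invariant to
rescaling any raw intensity channel.  The calibration line is fitted per
ROI by default, with a pooled fallback when an ROI's NH₄Cl response has
zero variance; correction subtracts slope × pHrodo deviation from the
normalized ratio.

**Counterfactual baseline.**  The published analysis used an external
Bayesian structural-time-series package; this package specifies its own
counterfactual model with the same contract (extrapolated mean plus
pointwise 95% band): a Gaussian local-level-plus-trend state space fitted
by maximum likelihood to the pre-treatment points (statsmodels
UnobservedComponents), with a deterministic OLS linear-trend fallback whose
band is the regression prediction interval.  Band width is nondecreasing
with horizon in both modes.  The integrated change is the trapezoidal AUC
of (trace − counterfactual) over [treatment, washout] divided by the window
length, so a sustained deflection of −0.2 reads out as −0.2 regardless of
window length.

**Group comparison.**  Medians with distribution-free binomial
order-statistic 95% CIs; two-sided Mann–Whitney U (tie-corrected), Holm
across pairs when more than two groups are supplied.

## Flux assays: random-intercept mixed models

Measurements are y = Xβ + u_well + u_batch + ε with independent Gaussian
random intercepts, fitted by REML (ML available) through statsmodels
MixedLM using variance components over a single all-encompassing group,
which yields crossed well and batch intercepts.  Two optimizers (L-BFGS-B
and BFGS, both at tight tolerance) are run and the better REML optimum
kept, because L-BFGS-B occasionally reports convergence on a spurious
stationary point; with this safeguard REML variance components match
closed-form ANOVA (expected-mean-squares) estimators on balanced
one-factor designs to numerical precision.  Single-level random factors
have their variance fixed at 0 with a warning; negative estimates truncate
at 0 with a boundary flag.

Estimated marginal means are equally weighted cell predictions from the
fixed effects; contrasts use the fixed-effect covariance with a normal (z)
reference.  A Satterthwaite t reference was considered and documented
away: degrees-of-freedom handling is unstated in the source analyses, and
at the plate sizes used here the difference is only visible at very small
n — outputs flag the normal reference.  Metric definitions: glycolytic
reserve = ECAR EMM(post rotenone/antimycin) − EMM(baseline); maximal ECAR =
genotype EMM within the rotenone/antimycin phase; 2DG response = genotype
slopes of ECAR on centered time within the post-2DG phase; ATP-linked
respiration = OCR EMM(baseline) − EMM(post-oligomycin); respiratory
reserve = EMM(post-FCCP) − EMM(baseline); peak respiratory capacity =
EMM(post-FCCP) − EMM(post rotenone/antimycin).  "Maximal ECAR" uses all
post-rotenone/antimycin, pre-2DG cycles and "basal" all pre-injection
cycles; dropping the first post-injection cycle as a mixing artifact is a
config option.

**A caution on 2-level batch factors.**  With only two batches the batch
variance has ~1 degree of freedom; its REML estimate routinely collapses
to zero (lme4 reports the same singular fits on identical data).  Point
estimates of phase differences are unaffected — the intercepts absorb any
constant batch offset exactly — but the batch variance itself should not
be interpreted at n_batches = 2.

## Transcriptome summaries

TPM: RPK = count/(length in kb), TPM = RPK/ΣRPK × 10⁶, so each sample sums
to 10⁶ exactly.  PCA/k-means QC: all-zero genes removed, gene-wise
z-scoring, PCA on samples, k-means with k = 2, a fixed seed and 50
restarts (best inertia).  DEG intersection: significance means adjusted
p < 0.05 strictly (p = 0.05 is non-significant); the high-confidence set
keeps only genes significant against both controls with matching log₂FC
sign.  Over-representation: 2×2 table over the gene universe, two-sided
Fisher exact p, sample (cross-product) odds ratio ad/bc — the conditional
MLE is available but the published "~15-fold" figure corresponds to the
cross-product form on its printed counts — with a Haldane 0.5 correction
only when a zero cell occurs (flagged), BH across a set collection, and
the score OR × −log₁₀(padj) for ranking (ties: smaller padj, then larger
overlap).  The default universe is the genes present in the DEG tables,
overridable.  The published overlap count appears as both 479 and 475 in
different places of the source material; the package computes whatever its
inputs give and its worked examples use 479.  2^−ΔΔCt: replicates averaged
per sample×gene, ΔCt against the housekeeping gene, ΔΔCt against the
reference-group mean.

DE testing itself is out of scope.  `stub_de_test` (Welch t on log₂(TPM+1)
with BH) exists only so synthetic end-to-end runs close the loop; it is
not a negative-binomial DE method and must not be applied to real counts.
Ortholog maps are ingested as (gene, ortholog, confidence) tables with a
configurable confidence cutoff, since no published threshold is available.

## Synthetic generators: what they emulate, and what they don't

All generators draw from one explicitly seeded numpy Generator each; no
global RNG state.  Defaults encode the study conditions: lifespans are
inverse-CDF Gompertz draws censused every 3.5 days in vials filled
round-robin to ≤ 15 flies, 100 flies per genotype (cohort sizes are not
published; 100 is a typical fly-room cohort); traces follow the imaging
protocol timing (2 min baseline, treatment to 8 min, 2 min washout, NH₄Cl
at 10–12 min, 2 s sampling) with bleach 5e−4/s, pH coupling 0.5, pHrodo
NH₄Cl amplitude 0.4 and ratio noise sd 0.01; flux plates use a canonical
stress-test OCR profile (100/40/150/10) and give the tau genotype higher
basal ECAR with a smaller glycolytic reserve than control, with σ_well = 2,
σ_batch = 1, σ_resid = 1 in flux units; counts are negative-binomial
(variance μ + μ²/size, size = 10) with 20% DEGs and log-normal baseline
means.  `min_abs_lfc` shifts DEG effect sizes away from zero for
strong-effect simulations.

Not emulated: imaging physics (PSF, shot noise — Gaussian noise suffices
for ratio-level analysis), focal drift, vial-to-vial environmental
heterogeneity (no frailty), plate-position effects, library-composition
biases, and real DE sampling distributions.  Passing tests therefore
demonstrate correctness of the estimators under their assumed models, not
robustness to the full messiness of real recordings.

## Numerical choices and degenerate inputs

Ratio timepoints with nonpositive denominators are masked with a warning
(error if all are).  Hazard estimation requires ≥ 10 deaths; the log-hazard
fit requires ≥ 5 positive trimmed points.  The Gompertz fitter requires ≥ 2
distinct death times and flags non-convergence while still reporting
parameters.  Counterfactual extrapolation requires ≥ 10 pre-treatment
points; the state-space route falls back to OLS on any failure.  Enrichment
requires a nonempty universe and drops (with a warning) genes outside it.
All CSV/TSV schemas are validated on construction of the container types.

## Known limitations

- Interval-censored likelihood is approximated by midpoint imputation.
- Normal-reference inference in the mixed models is slightly liberal at
  very small well counts; the type-I error of genotype contrasts measured
  by simulation in the test suite stays ≤ 7.5% at a nominal 5% in the
  plate sizes used.
- Batch variance components are not interpretable at two batches (above).
- The state-space counterfactual is a different (simpler) model family
  than the published Bayesian structural-time-series tool; only the
  contract (mean + 95% band) is matched, not its posterior.
- The kernel hazard has boundary bias despite reflection; the outer-grid
  trim handles the log-hazard fit, but hazard values near the extreme
  event times should not be read quantitatively.

## Problem sizes used in tests and the acceptance script

Hazard-diagnostic replication uses 50 cohorts of n = 300; MLE recovery 100
replicates at n = 2000 exact times; z-test calibration 400 null replicate
pairs at n = 500; trace recovery 20–50 ROIs; LMM type-I calibration 400
null plates of 4 wells × 2 batches × 3 cycles; multiple-testing oracles
1,000 random p-vectors.  These sizes give binomial standard errors of
~1% on the reported rates while keeping the full suite around half a
minute on one CPU.
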