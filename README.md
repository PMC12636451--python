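# flymet

Quantitative analysis tools for *Drosophila* tauopathy experiments: does a
short-lived genotype die early because it is frailer from the start, or
because it ages faster?  Is its neuronal ATP supply shifted from oxidative
phosphorylation toward glycolysis?  `flymet` implements the full analysis
chain used to answer those questions — lifespan decomposition, live-imaging
ratio correction, extracellular-flux mixed models, and transcriptome
summaries — together with seeded synthetic-data generators so every stage
is testable end to end without raw data.

## What it computes

**Gompertz mortality decomposition** (`flymet.survival`).  The mortality
hazard is modelled as

    h(t) = α · exp(β t)

where α (per day) is baseline mortality at eclosion and β (per day) is the
aging rate.  Vial-census counts (deaths observed only at twice-weekly
transfers) are expanded to per-fly event times, the Gompertz assumption is
checked by OLS on a kernel-smoothed log-hazard (Epanechnikov smoothing of
Nelson–Aalen increments), parameters are estimated by right-censored
maximum likelihood with standard errors from the observed information, and
genotypes are compared by Wald z-tests, z = (p₁ − p₂)/√(SE₁² + SE₂²), with
Holm correction.  Kaplan–Meier curves and median lifespans come from
lifelines.

**pH-corrected ATP/ADP traces** (`flymet.traces`).  PercevalHR is a
ratiometric ATP/ADP sensor (488/405 nm excitation ratio) whose signal is
pH-sensitive; pHrodo reports pH, and an NH₄Cl pulse at the end of each
recording provides a pure pH perturbation.  The chain: background
subtraction → ratio → exponential premix-baseline normalization (bleach
removal, premix mean pinned to 1) → linear pHrodo-deviation regression in
the NH₄Cl window → pH correction → counterfactual baseline extrapolation
(local-linear-trend state space, or OLS trend) → integrated change =
AUC(trace − counterfactual)/window length.  Groups are compared with
medians ± binomial 95% CIs and Mann–Whitney tests.

**Extracellular-flux metrics** (`flymet.flux`).  OCR/ECAR measurements from
a mitochondrial/glycolytic stress test are analysed with random-intercept
linear mixed models, e.g.

    ECAR ~ phase × genotype + (1|well) + (1|batch)

fitted by REML; every metric (glycolytic reserve, maximal ECAR, post-2DG
decline slope, ATP-linked respiration, respiratory reserve, peak
respiratory capacity) is a difference of estimated marginal means between
injection phases, with genotype contrasts from the interaction terms.

**Transcriptome summaries** (`flymet.transcriptome`).  TPM normalization
(TPM = RPK/ΣRPK × 10⁶), PCA + k-means sample QC, dual-control DEG
intersection with directional concordance, Fisher-exact gene-set
over-representation scored as odds ratio × −log₁₀(adjusted p), and
2^−ΔΔCt qRT-PCR summaries.

**Synthetic data** (`flymet.simulate`).  Seeded generators emit
Gompertz-censused lifespan tables, dual-excitation traces with bleach/pH/
treatment structure, flux plates with well/batch random intercepts, and
negative-binomial count matrices with ground-truth DEG labels.

## Worked example

```python
from flymet import simulate as sim, survival as surv

spec = sim.LifespanSimSpec(
    genotypes=[("control", 0.002, 0.08, 150), ("tau", 0.002, 0.16, 150)], seed=42)
table = sim.simulate_lifespans(spec)              # vial-census death counts
events = surv.impute_event_times(table)           # census -> per-fly times
fits = [surv.fit_gompertz(ev) for ev in events.values()]
print(surv.fits_to_frame(fits).round(4).to_string(index=False))
print(surv.comparisons_to_frame(surv.compare_parameters(fits, "beta"))
      .round(4).to_string(index=False))
```

prints

```
genotype  alpha  se_alpha   beta  se_beta    loglik  converged   n
 control 0.0017    0.0004 0.0858   0.0064 -594.4957       True 150
     tau 0.0027    0.0008 0.1457   0.0110 -516.6808       True 150
 group1 group2 parameter       z  p_raw  p_adj method
control    tau      beta -4.7035    0.0    0.0   holm
```

Both cohorts were simulated with the same baseline mortality (α = 0.002)
but the "tau" cohort ages twice as fast (β = 0.16 vs 0.08/day); the fit
recovers both parameters within sampling error, and the Wald z-test flags
the aging-rate difference while the α estimates stay compatible.  The same
enrichment machinery reproduces the published gene-set arithmetic: a 2×2
table over 23,932 genes with 4,519 DEGs, a 627-gene comparison set and 479
overlapping genes gives

```python
res = tx.enrich(deg_set, itpr_set, universe)   # overlap=479, OR=15.43, p=1.4e-221
```

i.e. an overlap ~15-fold above chance.

Run the whole chain on synthetic data from the shell:

```sh
flymet run --config run.yaml        # stages: simulate, surv, traces, flux, tx
flymet surv fit --input census.csv --rule interval_midpoint --out fits.csv
flymet tx enrich --sets disease.gmt --degs degs.txt --universe genes.txt --out enr.csv
```

Every run writes a `manifest.json` with the config hash, seeds and
per-output SHA-256 checksums; identical configs reproduce identical
checksums.

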