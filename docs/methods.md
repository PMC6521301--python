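# Methods

## The model

The analysis concerns the change in fasting plasma triglycerides over a
supplementation period, ΔTG = TG_post − TG_pre (mg/dL), in adults
genotyped at a panel of biallelic SNPs in TG-response candidate loci
(IQCJ-SCHIP1, NXPH1, PHF17, MYB, NELL1, SLIT2 and TG-associated genes).
Participants are dichotomised at ΔTG = 0: a drop is a *response* to the
omega-3 dose, a rise (or exactly zero) is *non-response*. Non-response
is treated as the adverse outcome throughout.

The genetic risk score of a panel P is

    GRS_i = Σ_{j ∈ P} d_j · g_ij ,   d_j ∈ {−1, 0, +1},  g_ij ∈ {0, 1, 2}

with g the minor-allele dosage and d the risk direction from the
allelic odds ratio OR_j of the minor allele in non-responders versus
responders (2×2 table on 2n alleles). The score is an integer in
[−2|P|, 2|P|]; a heterozygote contributes ±1 and a minor homozygote ±2.
A carrier-coded variant (±1 per carrier) is available behind a flag.
The contribution of the GRS to ΔTG is estimated by OLS of ΔTG on
GRS + age + sex + BMI. "Percent of TG variance explained by the GRS"
is the incremental R², 100·(R²_full − R²_covariates-only), identical to
the squared semi-partial correlation of GRS with ΔTG given the
covariates (a property test asserts this closed form). Partial η²
(= t²/(t² + df_resid) for the 1-df GRS term) is reported alongside,
since the two readings of "variance explained" differ slightly and
published values rarely say which was used.

### Assumptions and conventions

- **OR orientation.** OR > 1 ⇔ minor allele enriched among
  non-responders ⇔ "at-risk", so positive GRS means more at-risk
  alleles. The convention is a modelling choice; inverting the outcome
  labels inverts every OR and negates every score (tested invariant).
- **Allelic, not genotypic, tables.** ORs and cross-cohort MAF
  comparisons use allele counts (2n), the convention of standard
  allelic association tests. No continuity correction anywhere; zero
  cells get Haldane–Anscombe +0.5 (flagged).
- **HWE is diagnostic, not a filter.** SNPs failing the 1-df Pearson
  HWE test at α = 0.05 are listed but retained in all downstream
  analyses.
- **Missing genotypes** are excluded SNP-wise from MAF/HWE/OR
  denominators; a participant missing any genotype of a scored panel is
  dropped from that panel's GRS vector (no mean imputation). This is
  why a k-SNP panel can score n−1 of n participants.
- **Weights are frozen.** Risk directions are estimated once on the
  full cohort; stepwise refinement and retrenchment refit the *model*,
  never the weights.
- **Sex** enters as one 0/1 indicator (female reference); the reference
  choice does not change the GRS statistics (tested invariant).
- Complete-case analysis over phenotype + GRS columns; all fits plain
  OLS (no robust errors).

## Stepwise refinement

Bidirectional stepwise selection over individual SNP dosage terms with
age, sex and BMI forced into every model. Each iteration adds the
candidate with the smallest p-value below the entry threshold (ties:
smaller p, then lexicographic rsid), then repeatedly removes the
included SNP with the largest p-value above the stay threshold, until
no action is possible (a visited-state guard precludes cycling).
Thresholds default to entry = stay = 0.15, the conventional stepwise
defaults; both are settable. The procedure is deterministic given the
data. At n ≈ 191 with ~100 candidates and liberal thresholds the
procedure typically retains 20–30 SNPs — stepwise over many weak
candidates overfits, which is the reason the refined panel's in-sample
incremental R² can exceed the planted signal. A brute-force oracle test
verifies the per-step log against an exhaustive statsmodels refit of
every candidate model on small fixtures.

## Retrenchment

`default_schedule(n_resp, n_nonresp, step=10, min_n=30)` first removes
the group-size difference from the larger group (reaching 50:50), then
`step` more per group per row, stopping before fewer than `min_n`
participants would remain; with a 113/78 split this yields exclusion
rows (35,0), (45,10) … (95,60), i.e. 156, 136, …, 36 included.
"Weakest" participants are those with the smallest response magnitude:
responders with ΔTG closest to zero from below, non-responders closest
to zero from above (an alternative ordering ranking non-responders from
the largest ΔTG down is available; ties break on participant id, so the
sweep is order-independent). The model is refit per row with the GRS
panel and weights frozen.

Interpretation caveat: selecting extremes of the *outcome* mechanically
inflates an outcome–score correlation even when the underlying effect
is homogeneous, and the finite-sample null expectation of incremental
R² is ≈ (1 − R²_cov)/(n − 4), which grows as n shrinks along the sweep
(≈0.5% at n=191, ≈3% at n=36). A rising percentage along the sweep is
therefore expected for any truly associated score and is not by itself
evidence of effect concentration in extreme responders; the null-trend
test in the suite subtracts the analytic bias before asserting a flat
slope.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
individual-level data:

- **Genotypes**: independent per SNP and participant,
  g ~ Binomial(2, MAF) — HWE by construction, no LD. Default panel: the
  91 published Mexican reference MAFs (folded to ≤ 0.5), padded
  deterministically to 103 SNPs by cycling those frequencies under
  synthetic rsids.
- **Covariates**: sex ~ Bernoulli(0.37 male); age ~ N(26.5, 6.2²)
  truncated to the inclusion range 18–40 y; BMI ~ N(23.6, 2.7²)
  truncated to 18.5–30 kg/m².
- **Baseline TG**: log-normal, moment-matched to mean 97.9, SD
  53.6 mg/dL (the pooled values implied by the responder/non-responder
  subgroup moments); TG is right-skewed, so a log-normal is the natural
  two-moment choice.
- **ΔTG** = intercept + Σ β_j·g_j + covariate terms + c·(TG_pre − μ) +
  ε. Defaults: five causal SNPs at the rsids a published refinement
  retained (rs10265408, rs10486228, rs17150341, rs6974252, rs2595241),
  effects ±12 mg/dL per allele with mixed signs; covariate effects
  (0.3, 5.0, 1.0) mg/dL per (year, male, kg/m²); baseline coupling
  c = −0.15 (high-baseline participants tend to respond, reproducing
  the observed direction of the baseline gap between groups).
- **Noise calibration**: Var(ε) is solved analytically so the planted
  genetic fraction of Var(ΔTG) equals `target_grs_partial_r2`
  (default 0.11); a target that would need negative noise variance is a
  configuration error naming the offending parameters. With equal
  |β_j|, the true-direction GRS is exactly collinear with the planted
  term, so regressing ΔTG on it recovers the target (mean over 200
  replicates within ±2 points of 11 in the acceptance suite). With no
  causal SNPs the residual SD defaults to 45 mg/dL.
- **Intercept calibration**: chosen so the expected non-responder
  proportion under the Gaussian approximation is 40.8%. The published
  subgroup moments imply a pooled mean ΔTG ≈ −4 mg/dL, which under a
  Gaussian with the implied total SD would give ≈47% non-response;
  the two printed facts are only compatible with a skewed ΔTG, and the
  generator privileges the classification split since that is the
  quantity the pipeline is built around. Simulated cohorts realize
  ≈40% non-responders.
- `tg_post = max(tg_pre + ΔTG, 1)` (floor rarely binds); missing
  genotype calls masked i.i.d. at `missing_rate` (default 0).
- One RNG stream per cohort from the config seed; identical config +
  seed is bit-identical, including written VCF/PED/CSV artifacts.

What the generator does **not** emulate — LD between SNPs, population
admixture, genotyping error, skewed/heteroscedastic ΔTG noise, and any
real effect-size spectrum — bounds what green tests show: they validate
the *pipeline arithmetic and statistics* under the stated generative
assumptions, not biological claims about real cohorts.

## Numerical choices

- HWE χ² uses the sample allele frequency with 1 df; monomorphic SNPs
  return statistic 0 and a flag rather than erroring.
- Cohorts supplied as printed (MAF, n) instead of raw counts have
  allele counts reconstructed as round(MAF·2n); such comparison rows
  are flagged approximate, since printed two-decimal frequencies cannot
  recover exact counts.
- Zero-variance paired t-tests report p = 1 with a degenerate flag to
  keep batch reports total.
- A constant GRS yields a fit flagged `grs_inestimable` with 0%
  variance attributed rather than an exception.
- Stepwise p-values come from a lightweight lstsq-based OLS (the
  hot loop); the reported model fits use statsmodels.
- Percentages in classification summaries are rounded to 1 decimal.

## Problem sizes in the test and acceptance suites

Simulation-backed checks use the default cohort size (191×103) with
replicate counts chosen for stable Monte-Carlo means: 200 seeds for
parameter recovery, 1,000 permutations for the type-I rate, 60 seeds
for the null retrenchment slope, 25–30 seeds for power-style
properties. The full suite runs in well under a minute per module.
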