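# Methods

This note records the statistical model behind `mrmediate`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that were genuinely open.

## Model and assumptions

Two-sample summary-data MR treats each independent SNP *j* as an instrument:
γ̂<sub>j</sub> (SE σ<sub>Xj</sub>) is its effect on the exposure from one
GWAS, Γ̂<sub>j</sub> (SE σ<sub>Yj</sub>) its effect on the outcome from
another, with non-overlapping samples so the two errors are independent.
Identification needs the three instrument assumptions (relevance,
no confounding of the instrument, exclusion restriction); only relevance is
testable (F-statistics). Exclusion is probed, never proven, by the
sensitivity battery: Egger's intercept (directional pleiotropy under
InSIDE), the weighted median (valid if <50% of weight is pleiotropic),
Cochran's Q and MR-PRESSO (outlier pleiotropy), leave-one-out (single-SNP
influence).

Estimates for binary traits are on the log-odds scale and exponentiate to
odds ratios; mediated *proportions* are invariant to linear rescaling of
exposure, mediator or outcome, which is why a liability-scale truth is
recoverable from log-odds-scale GWAS in the synthetic studies.

### Estimators

* **IVW (multiplicative random effects).** Weighted through-origin
  regression of Γ on γ, weights 1/σ²<sub>Y</sub>. The fixed-effect SE is
  inflated by √max(1, Q/(J−1)): heterogeneity widens, never narrows, the
  interval. P-values are two-sided normal. With one SNP this is exactly the
  Wald ratio with first-order SE σ<sub>Y</sub>/|γ| (the second-order term in
  σ<sub>X</sub> is negligible for the instrument strengths enforced here).
* **MR-Egger.** Same regression with a free intercept, instruments oriented
  to γ ≥ 0 first (the intercept is only defined up to this convention).
  Slope and intercept use a t reference with J−2 df and the same floored
  inflation. The floor makes the test measurably conservative under
  homogeneity (about 0.038 empirical size at α = 0.05 with 50 instruments);
  we accept this deliberately — an anti-conservative pleiotropy test is the
  worse failure mode. Egger additionally needs the NOME condition
  (σ²<sub>X</sub> small against the spread of γ, I²<sub>GX</sub> near 1);
  with weak instruments its slope attenuates and no flag can fully rescue
  it.
* **Weighted median.** The 50% point of the inverse-variance-weighted,
  midpoint-interpolated CDF of the per-SNP ratios. The SE is a seeded
  parametric bootstrap (default 1000 draws) resampling γ* about the observed
  γ̂ and Γ* about the fitted line θ̂γ̂. Centring Γ* on the *fit* rather than
  on Γ̂ matters: for a median-type statistic, resampling around values that
  already contain sampling scatter convolves the noise twice and inflates
  the SE by up to √2 (empirically: size 0.027 instead of 0.050 at α = 0.05);
  the fitted centring restores nominal size. A subtlety of the midpoint
  interpolation: the estimate is not a pure function of the weighted CDF, so
  duplicating the entire instrument set can move it by up to one inter-ratio
  gap. Aggregating ties would restore exact duplication-invariance but
  breaks majority-weight robustness (interpolating across an aggregated
  75% mass at a single ratio value drags the estimate toward an outlier), so
  the standard interpolation is kept.
* **MR-PRESSO.** Observed residual sum of squares uses leave-one-out
  predictions Γ̂<sub>j</sub> = θ̂<sub>(−j)</sub>γ̂<sub>j</sub>; the null
  distribution re-draws both γ* ~ N(γ̂, σ²<sub>X</sub>) and
  Γ* ~ N(θ̂<sub>(−j)</sub>γ̂, σ²<sub>Y</sub>) (full parametric scheme),
  default 10,000 draws, α = 0.05. Per-SNP outlier p-values are Bonferroni
  adjusted across J. The distortion test compares
  (θ̂<sub>corrected</sub> − θ̂<sub>raw</sub>)/|θ̂<sub>raw</sub>| against the
  same statistic under random removal of equally many SNPs — the null scheme
  was an open choice; random same-size subsets are the simplest exchangeable
  reference. Outlier and distortion results are computed even when the
  global test is null, flagged `advisory`.
* **MVMR.** Weighted regression of Γ on the J×K matrix of exposure effects,
  no intercept (IVW) or free intercept (Egger variant, rows oriented to the
  first exposure), inflation floored at 1 with df J−K (or J−K−1). IVW
  p-values use the normal reference so that K = 1 reproduces univariable IVW
  to machine precision. An all-zero exposure column is dropped from the fit
  and reported with coefficient 0 and infinite SE rather than raising (the
  nested-model reading); genuine collinearity raises. Conditional
  instrument strength is the Q-statistic approximation
  F<sub>k</sub> = Q<sub>xk</sub>/(J−K+1), where Q<sub>xk</sub> is the
  weighted residual sum from regressing exposure k's instrument effects on
  the other exposures'; it reduces to the mean F at K = 1 and ignores
  cross-exposure sampling covariance.

### Mediation

Mediated effect β₁β₂ with delta SE √(β₂²se₁² + β₁²se₂²) — the covariance
term is zero by the non-overlapping two-sample design. Mediated proportion
β₁β₂/β_T with the first-order ratio expansion for its SE; the expansion is
accurate when se_T/β_T is modest (≲0.15) and degrades for near-null total
effects, whose true ratio distribution is heavy-tailed. Proportions outside
[0, 1] (inconsistent mediation) are reported with a warning and never
truncated, and proportions of several mediators are never renormalised to
sum to one — correlated mediators legitimately overlap. β₂ is the mediator's
MVMR coefficient adjusting for the exposure; the unadjusted UVMR coefficient
is carried alongside for transparency. FDR families: the mediator→outcome
screen is corrected over the whole candidate panel; the exposure→mediator
step over the survivors of the first screen only.

## Defaults

| parameter | default | rationale |
|---|---|---|
| instrument p-threshold | 5e-6 exposure-side, 5e-8 outcome-side | relaxed exposure threshold keeps enough instruments for modestly powered disease GWAS; the stricter outcome-side threshold keeps reverse-direction instruments free of contamination by exposure signal |
| clumping | r² < 0.001 within 10,000 kb | near-independence; window in base pairs on the same chromosome, positions 1-based |
| palindromic window | drop if either EAF in 0.5 ± 0.08 | A/T, C/G SNPs are strand-ambiguous; frequency resolves them only away from 0.5 and on the same side in both studies |
| MR-PRESSO | Nb = 10,000, α = 0.05 | enough draws for stable p ≈ 0.05 decisions |
| weighted-median bootstrap | 1000 draws, seeded | SE stable to ~2% |
| weak-instrument flag | mean F ≤ 10 | conventional bound |
| evidence tiers | strong p<.05 & q<.05; indicative p<.05 & q≥.05 | two-level FDR grading of the screen |

## The synthetic generator

`simulate_chain` draws individual-level data from an explicit structural
chain — genotypes Binomial(2, maf) (Gaussian-copula AR(1) within declared LD
blocks), exposure X with its own instruments (default 30 SNPs, h² = 0.10),
each mediator M<sub>k</sub> = θ<sub>XM,k</sub>X + own instruments (default
20 SNPs, h² = 0.08) + noise, outcome Y = Σθ<sub>MY,k</sub>M<sub>k</sub> +
θ<sub>XY</sub>X + outcome-specific loci (20 SNPs, h² = 0.08, the
reverse-direction instruments) + configurable per-SNP pleiotropy — then
reduces *disjoint* cohorts (default n = 20,000 per GWAS) to per-SNP
univariable summary statistics. Binary traits threshold the liability at a
configured prevalence and emit log-odds effects via the per-SNP logistic
score approximation. Unlinked SNPs are placed >10 Mb apart so the clump
window only ever engages declared LD. The default chain
(θ<sub>XM</sub>, θ<sub>MY</sub>, θ<sub>XY</sub>) = (0.3, 0.5, 0.35) has a
true mediated proportion of exactly 0.30. All randomness flows from one
seeded generator; identical configs are bit-identical.

What it does **not** emulate: realistic human LD maps or allele-frequency
spectra (the copula is controllable, not coalescent), polygenic backgrounds
beyond the declared loci, sample overlap between GWAS (a design guarantee
here, an estimated nuisance in real data), population stratification, or
consortium-scale sample sizes. Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness to
everything real summary statistics can contain.

## Known limitations

* **Regression-dilution attenuation of the two-step proportion.** All
  summary-data estimators here use estimated instrument effects as
  regressors, so every coefficient attenuates by roughly 1/F. In the
  mediated proportion the attenuations of β₁ and β_T cancel almost exactly
  (shared instruments and exposure GWAS), but the MVMR β₂ attenuation passes
  straight through: at the default conditions (mean F ≈ 70–80) the
  proportion estimator centres near 0.294 for a true 0.30, about a 2%
  relative shortfall. This is intrinsic to the method class; corrections
  (MR-RAPS-style) are out of scope. Interval coverage for null mediators is
  unaffected.
* The Egger test's deliberate conservatism (floored inflation) is described
  above; under strong heterogeneity the multiplicative model is itself an
  approximation to additive pleiotropy variance.
* Palindromic handling and missing-SNP handling (drop, no proxy look-up) are
  declared defaults, not universal conventions; both are configurable.
* The delta-method proportion CI is symmetric and can cross 0 or 1; for
  weak total effects a bootstrap on the full pipeline would be preferable.
* Screening uses marginal decisions per criterion; reason codes record every
  failed criterion, but no multiplicity adjustment spans the three screens
  jointly.
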