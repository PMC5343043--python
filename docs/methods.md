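# Methods

This note documents the generative model behind the synthetic cohorts, the
estimation machinery, the numerical choices, and what the packaged tests do
and do not establish about real data.

## Synthetic cohort model

Each subject carries: age from a truncated Normal(36, 16²) on [16, 74] years
(so ~25% fall at or above the 48-year cut, the cohort's 75th percentile);
sex (85.3% male, never modelled as a covariate); GCS uniform on {3,…,8}
(the real distribution is unstated beyond a median of 7 — severity enters
the hazard, so only its spread matters here); and two independently drawn
carrier-class genotypes, P(Val/Val) = 0.581 at rs6265 and P(T/T) = 0.521 at
rs7124442. Drawing the SNPs independently ignores any linkage
disequilibrium between the two haplotype blocks; nothing downstream uses
joint genotype structure beyond the additive GRS, so this simplification is
immaterial to the estimands but worth remembering if the generator is
reused.

**BDNF.** A latent quarter of subjects are "BDNF-high". Subject-level weekly
means are Normal(0.322, 0.040²) ng/mL for the high group and
Normal(0.146, 0.022²) for the rest (mixture mean exactly 0.19 ng/mL); daily
values add Normal(0, 0.02²) noise around the subject mean, reflecting the
observed temporal stability of CSF BDNF. The two groups are separated by
~4 group-level SDs, so the analysis-side 75th-percentile dichotomization
recovers the latent group almost perfectly and the configured
BDNF→trajectory log-odds is attenuated only negligibly.

**Cortisol trajectories.** Two latent classes with marginal high-class
probability 44/117. Log daily means are exact quadratics in the day index —
the same family the trajectory model fits, so "recovery" is well defined:
the high class peaks on day 2 (51.3 ng/mL) and declines, the low class
peaks mildly on day 1 (12.2 ng/mL) and drifts down. Residual sd is 0.4 on
the log scale (minimum daily class separation ≈ 3 sd). The high-class level
is solved so the pooled expected weekly mean is 24.28 ng/mL given the class
mix and the log-normal noise correction exp(sd²/2).

**Class membership.** P(high class) = logit⁻¹(a + β·BDNF-high) with
β = ln 4.12 by default; the intercept *a* is solved at configuration time so
the marginal class share equals `class_mixing`. This keeps cohort-level
calibration invariant when β is changed.

**Sampling process.** Each observed day yields one sample, or two with
probability 0.3 (both carry the day value, so daily means stay unbiased);
days are missing independently with probability 0.3, roughly matching the
2–3 samples per subject implied by the reported assay counts. 15% of
cortisol samples are emitted on the ELISA scale by inverting the
cross-calibration (only where the inverse is positive), so harmonization has
real work to do without disturbing calibration.

**Survival.** Exponential event times with hazard
h₀·exp(0.457·BDNF-high + 1.115·trajectory-high + 0.916·age≥48 −
0.25·(GCS−5.5)), right-censored at 180 days; boundary deaths count as
events. The BDNF and trajectory coefficients are the conditional
(direct-path) values ln 1.58 and ln 3.05; the age and GCS coefficients are
package choices sized to reproduce the older, lower-GCS profile of
non-survivors. h₀ is solved analytically (enumeration over the discrete
covariate lattice plus the truncated-normal age tail) so the expected death
fraction is 26/117 ≈ 0.222; the solver ships as
`calibrate_baseline_hazard`.

**Non-collapsibility and the 30% scenario.** Hazard ratios do not
marginalize over a mediator: with the default conditional effects the
*marginal* total-effect HR of BDNF is ≈ 2.27, implying a true proportion
mediated of ≈ 43% on the log-hazard scale. The reference estimates
(total 1.94 against direct 1.58, ~30% mediated) therefore cannot all be
generative constants of one coherent model. The packaged `mediated30`
profile lowers the BDNF→class log-odds to 0.8, which brings the marginal
total effect to ≈ 1.94 and the true proportion mediated to ≈ 30% (verified
against a large-sample maximum-likelihood oracle); cohort-level calibration
is unchanged because the class intercept re-solves. The default profile
keeps the OR-4.12 class link; the mediation-recovery studies use
`mediated30`.

## Estimation machinery

**Trajectory mixture.** EM on the K-class quadratic growth mixture with
class-specific residual sd, subjects contributing only observed days.
E-step responsibilities come from per-subject joint log densities
(log-sum-exp); the M-step is weighted polynomial least squares with an sd
floor of 1e-4. Initialization is a quantile split on per-subject mean
levels; later restarts (default 10) randomly perturb 25% of the initial
assignments; convergence when the log-likelihood gain drops below 1e-8
(cap 500 iterations, warning on non-convergence). The log-likelihood is
asserted monotone in tests. BIC uses K·(order+1) + K + (K−1) parameters.
The residual family is uncensored Normal on the log scale: the 0.001 floor
on harmonized values makes left-censoring negligible, so the censored-Normal
variant some trajectory software offers is not needed. K is fixed at 2 in
the pipeline (BIC comparison is available and prefers K=2 on two-class
data). Group imbalance (> 85% in one class, strict) flags poor
discrimination and triggers the percentile fallback used for BDNF.

**Logistic and Cox engines.** Newton–Raphson with analytic score and
observed information, step-halving on any step that would reduce the
likelihood, convergence at max|score| < 1e-8 (relaxed proportionally to
|log L| for very large n, where float rounding of the log-likelihood
dominates), 100-iteration cap. Coefficients diverging past 20 raise a
separation error; nothing is silently penalized. The Cox partial likelihood
supports Efron (default) and Breslow ties via a precomputed risk-set
structure (`CoxProblem`) that evaluates in O(n) — the MCMC sampler calls it
tens of thousands of times. Efron is the default because it is the better
tie approximation; some legacy software defaults to Breslow, and the switch
is exposed for comparison.

**Prior transfer and MCMC.** Priors are Normal(β̂, SE²) per coefficient from
frequentist fits on the prior cohort; only the focal pathway coefficient is
informed by default (nuisance coefficients get Normal(0, 10²); an
`inform_all` switch exists because the original choice is ambiguous). The
sampler is random-walk Metropolis–Hastings over the full coefficient vector,
proposal scales set from the MLE standard errors and adapted every 50
burn-in iterations toward a 0.2–0.4 acceptance window; ≥ 2 chains, seeded
per pathway from one root seed so total/direct draws are pairable.
Defaults: 4 chains × 5000 retained draws after 2000 burn-in. The Cox
posterior uses the partial likelihood as its target — a standard
approximation that ignores baseline-hazard uncertainty. Split-chain R̂ and
ESS come from arviz; R̂ > 1.1 attaches a warning, post-adaptation acceptance
below 0.05 is an error. Reported "P-values" are two-sided posterior tail
probabilities 2·min{P(β>0), P(β<0)}.

**Mediation.** Criteria 1–3 are tail probabilities below α = 0.05 on the
total, exposure→mediator and mediator→outcome pathways; criterion 4 is
attenuation of the direct log effect relative to the total. Classification:
*none* if any of 1–3 fails; *full* if additionally the direct effect is
non-significant **and** the mediation percentage reaches 80 — significance
alone cannot define full mediation, since a non-significant direct effect
can coexist with ~30% mediation in a small cohort; otherwise *partial*. The
mediation-percentage interval applies the log-ratio formula per paired
posterior draw and takes equal-tail 2.5/97.5 percentiles; draws whose total
log effect sits within ±0.01 of zero are excluded from the ratio, and more
than 5% of them raises an instability warning. Negative percentages are
reported, not clipped. Within age strata the binary age indicator is
dropped from adjustment (it is constant or nearly so inside a stratum;
keeping it would be degenerate), and any other constant adjuster is dropped
with a warning. On the printed-precision pair (1.94, 1.58) the formula
gives 30.97%; published analyses quoting ~29.9% evidently used unrounded
estimates — both numbers are consistent at rounding accuracy.

**GRS moderation.** Per-GRS logistic models (age-adjusted) for
BDNF-high → high trajectory, with strata under 5 subjects flagged unstable;
Cox mortality models with a BDNF × GRS product term per age stratum,
adjusted for GCS and trajectory group. "P trend" style summaries are emitted
as the Wald p of the focal coefficient — an interpretation, flagged as such.

## Problem sizes in the packaged studies

The replication studies run at the scale of the design they emulate:
calibration uses 120–150 replicate cohorts of n = 117; trajectory recovery
uses n = 117 (labels) and n = 500 (curves, ±0.1 log-units pointwise); BIC
selection uses 50 replicates at 2-sd class separation; end-to-end mediation
recovery uses 20 replicates of the full chain (185-subject prior cohort +
117-subject analysis cohort) with 2 chains × 1500 draws against a
120 000-subject maximum-likelihood oracle; the null BDNF × GRS calibration
uses 200 frequentist replicates.

## What the tests do and do not show

Passing tests establish that the estimators recover the parameters of the
generative model above, at the stated cohort sizes, under correctly
specified pathway models. Real CSF data differ in ways the generator does
not emulate: informative missingness (sampling via ventricular drain stops
when the drain is pulled or the patient dies), assay plate effects and
drift, LD between the variants, continuous confounding by age, non-quadratic
trajectory shapes, and unmeasured confounding of the mediator–outcome
relationship — the Baron–Kenny chain here is associational, not a
counterfactual mediation analysis. Single-cohort mediation percentages at
n = 117 are extremely noisy (the worked example's interval spans zero);
only their distribution across replicates is calibrated.

## Numerical details and edge cases

- Percentiles use linear interpolation; the BDNF cut is ≥, so an all-equal
  cohort is entirely "high".
- Equal fitted class levels break the high/low tie toward labelling the
  lower class index "low".
- Detection limits are analyte-specific config values (synthetic defaults
  1.0 ng/mL cortisol, 0.08 ng/mL BDNF); there is deliberately no silent
  default for real data.
- The VCF channel requires the REF=major orientation to be declared;
  genotype columns in the subjects table are the primary path.
- Subjects with zero observed cortisol days are excluded from trajectory
  fitting and listed in the run log; weekly means never impute absent days.
- All randomness flows from one root seed, split per stage by SHA-256, so
  pipeline re-runs are byte-identical.
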