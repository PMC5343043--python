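# cortmed

Trajectory-mediated survival analysis of cerebrospinal-fluid (CSF) cortisol
and brain-derived neurotrophic factor (BDNF) after severe traumatic brain
injury (TBI), built as a fully synthetic, reproducible re-implementation of
the inference chain for biostatisticians who want to study or extend it.

## The scientific problem

After severe TBI (Glasgow Coma Scale ≤ 8), CSF cortisol and BDNF are both
elevated and both predict 6-month mortality. The question this pipeline
addresses is *mediation*: does the acute cortisol response carry part of the
BDNF–mortality association? The analysis chain is:

1. **Assay harmonization** — ELISA-assayed cortisol is mapped onto the RIA
   scale with a linear cross-calibration, `C_RIA = 6.32 + 0.76 · C_ELISA`;
   below-range samples take the detection limit, undetectable samples take
   0.001 ng/mL; up-to-twice-daily samples are averaged per day (days 0–6)
   and into a weekly mean.
2. **Group-based trajectory modelling (TRAJ)** — a K = 2 finite mixture of
   quadratic growth curves with Normal residuals, fit by EM to log daily
   cortisol, labels each subject *high* or *low* trajectory. BDNF, which is
   temporally stable and poorly discriminated by TRAJ, is instead
   dichotomized at the 75th percentile of the weekly mean.
3. **Gene risk score (GRS)** — count (0–2) of hypothesized risk alleles:
   rs6265 Met carriage and rs7124442 C carriage; Hardy–Weinberg checked by
   1-df χ².
4. **Bayesian prior transfer** — the four Baron–Kenny pathway models
   (logistic for BDNF→trajectory; Cox for trajectory→mortality and for the
   total and direct BDNF→mortality effects, all censored at 180 days,
   adjusted for binary age ≥ 48, GCS and GRS) are estimated by random-walk
   Metropolis–Hastings with Normal(β, SE²) priors taken from maximum-
   likelihood fits on a larger *prior cohort* that passed the same
   preprocessing.
5. **Mediation percentage** —
   `100 · [ln(HR_total) − ln(HR_direct)] / ln(HR_total)`,
   with a 95% interval from paired posterior draws; age-stratified and
   GRS-moderation (BDNF × GRS) analyses repeat the chain in subgroups.

Because no subject-level data are deposited anywhere, the package ships a
**synthetic cohort generator** whose defaults reproduce the reference
cohort's statistics (n = 117; 26 expected deaths by day 180; 44 high-
trajectory subjects; 68 rs6265 Val/Val; mean weekly cortisol
24.28 ng/mL; mean weekly BDNF 0.19 ng/mL) and association structure
(BDNF-high → high trajectory OR ≈ 4; trajectory → mortality HR ≈ 3;
conditional direct BDNF HR ≈ 1.6). The logistic and Cox engines are written
from scratch (Newton–Raphson on the analytic score/information; Efron or
Breslow ties) so they can double as MCMC likelihood kernels; `statsmodels`
and `lifelines` serve only as independent oracles in the test suite.

## Worked example

```bash
python analysis/01_simulate_cohort.py        # cohort -> results/cohort/
python analysis/02_preprocess.py             # harmonize + TRAJ + GRS
python analysis/03_derive_priors.py          # n=185 prior cohort -> priors
python analysis/04_mediation.py --draws 2000 --chains 2
python analysis/05_moderation.py
```

The preprocessing step prints, for the default seed:

```
analysis frame: 117 subjects (0 excluded without cortisol)
trajectory groups: 42 high / 75 low (balanced: True; BIC 797.4)
BDNF >=75th pct: 30; GRS counts: {0: 45, 1: 45, 2: 27}
```

i.e. the mixture recovers a high-trajectory group of about the expected
44/117 share, and roughly a quarter of subjects sit above the BDNF cut.
The mediation step then reports, for all 117 subjects (2 chains × 2000
draws):

```
[all] n=117 events=40
  bdnf_total: 2.18 (1.34-3.52)  P=0.001
  bdnf_to_cortisol: 4.31 (2.52-7.85)  P=0.000
  cortisol_to_mortality: 3.17 (2.03-5.16)  P=0.000
  bdnf_direct: 1.54 (0.96-2.47)  P=0.075
  criteria met: {1: True, 2: True, 3: True, 4: True} -> partial
  mediation percentage: 44.26% (-81.43, 104.69)
```

Read this as: BDNF-high subjects have about twice the mortality hazard in
total; the effect attenuates (HR 1.54, no longer significant) once the
cortisol trajectory group enters the model, so the four mediation criteria
classify the cortisol trajectory as a *partial* mediator, carrying ~44% of
the total log-hazard effect in this replicate (single-cohort mediation
percentages are noisy — the interval spans zero; the recovery studies in the
test suite characterize the estimator across replicates). The same pattern
repeats within age strata, and the moderation step reports per-GRS odds
ratios and the BDNF × GRS interaction coefficient per age stratum.

Equivalently, `cortmed all --out-dir results/pipeline --seed 7` runs every
stage through the CLI with a reproducibility manifest.

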