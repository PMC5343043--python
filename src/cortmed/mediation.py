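"""Baron-Kenny mediation with Bayesian pathway estimates, plus moderation.

The four pathway models (all censored at 180 days):

1. total effect      Cox   mortality ~ BDNF-high + age>=48 + GCS + GRS
2. exposure->mediator Logistic high-trajectory ~ BDNF-high + age>=48 + GCS + GRS
3. mediator->outcome Cox   mortality ~ trajectory + BDNF-high + age>=48 + GCS + GRS
4. direct effect     Cox   mortality ~ BDNF-high + trajectory + age>=48 + GCS + GRS

Mediation percentage = 100 * [ln(OR_total) - ln(OR_direct)] / ln(OR_total),
evaluated per paired posterior draw for its interval.  Criteria 1-3 are judged
by posterior tail probability; criterion 4 by attenuation of the direct
relative to the total log effect.  The analysis is repeated within age strata
(cut at 48, the cohort's 75th percentile) and the GRS moderation models add a
BDNF x GRS product term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import regression as reg
from .bayes import MCMCSettings, PathwayPrior, PosteriorSummary, mcmc_sample, summarize_posterior
from .genetics import compute_grs
from .harmonize import harmonize
from .trajectory import (
    TrajectorySpec,
    assign_groups,
    check_group_balance,
    dichotomize_at_percentile,
    fit_trajectory_mixture,
)

__all__ = [
    "PATHWAYS",
    "MediationResult",
    "ModerationResult",
    "build_analysis_frame",
    "derive_priors",
    "run_pathway_models",
    "assess_baron_kenny",
    "mediation_percentage",
    "mediation_percentage_interval",
    "stratified_mediation",
    "grs_moderation",
]

PATHWAYS = ("bdnf_total", "bdnf_to_cortisol", "cortisol_to_mortality", "bdnf_direct")

_FOCAL = {
    "bdnf_total": "bdnf_high",
    "bdnf_to_cortisol": "bdnf_high",
    "cortisol_to_mortality": "traj_high",
    "bdnf_direct": "bdnf_high",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class MediationResult:
    stratum: str
    summaries: dict              # pathway -> PosteriorSummary
    criteria_met: dict           # {1: bool, 2: bool, 3: bool, 4: bool}
    classification: str          # none | partial | full
    mediation_pct: float
    mediation_pct_interval: tuple
    n: int
    events: int


@dataclass
class ModerationResult:
    per_grs: pd.DataFrame        # OR of BDNF-high -> high trajectory per GRS stratum
    interaction: pd.DataFrame    # BDNF x GRS Cox coefficient per age stratum
    warnings: list = field(default_factory=list)


# ------------------------------------------------------------ preprocessing

def build_analysis_frame(
    subjects: pd.DataFrame,
    biomarkers: pd.DataFrame,
    traj_spec: TrajectorySpec | None = None,
    detection_limits: dict | None = None,
    gcs_center: float = 5.5,
    age_cut: float = 48.0,
) -> tuple[pd.DataFrame, dict]:
    """Harmonize, fit cortisol trajectories, dichotomize BDNF, score GRS.

    Returns the per-subject analysis frame plus a log with the trajectory fit,
    balance flag and harmonization audit.  Subjects without a single cortisol
    day, or with missing genotypes, are excluded and listed in the log.
    """
    daily, audit = harmonize(biomarkers, detection_limits=detection_limits)
    day_cols = [f"day{d}" for d in range(7)]

    cort = daily[daily["analyte"] == "cortisol"].set_index("subject_id")
    bdnf = daily[daily["analyte"] == "BDNF"].set_index("subject_id")

    frame = subjects.set_index("id").copy()
    excluded = sorted(set(frame.index) - set(cort.index))
    frame = frame.loc[frame.index.intersection(cort.index)]
    cort = cort.loc[frame.index]

    logY = np.log(cort[day_cols].to_numpy(dtype=float))
    spec = traj_spec or TrajectorySpec()
    fit = fit_trajectory_mixture(logY, spec)
    balanced = check_group_balance(fit)
    groups = assign_groups(fit)
    frame["traj_high"] = (groups == "high").astype(int)

    weekly = bdnf["weekly_mean"].reindex(frame.index)
    frame["bdnf_weekly"] = weekly
    frame["bdnf_high"] = (
        dichotomize_at_percentile(weekly.to_numpy(dtype=float)) == "high"
    ).astype(int)

    grs = []
    for sid, row in frame.iterrows():
        grs.append(compute_grs(row["rs6265"], row["rs7124442"]).grs)
    frame["grs"] = grs
    frame["age_high"] = (frame["age"] >= age_cut).astype(int)
    frame["gcs_c"] = frame["gcs"] - gcs_center

    log = {
        "trajectory_fit": fit,
        "trajectory_balanced": balanced,
        "harmonization": audit,
        "excluded_no_cortisol": excluded,
    }
    return frame.reset_index().rename(columns={"index": "id"}), log


def _design_for(frame: pd.DataFrame, pathway: str, drop_age: bool = False):
    """Design matrix, outcome pieces and covariate names for one pathway.

    Adjustment covariates that are constant in this frame (e.g. the binary age
    indicator inside an age stratum, or GCS in a single-severity cohort) are
    dropped with a warning — their coefficient would be inestimable.
    """
    adjust = ["age_high", "gcs_c", "grs"]
    if drop_age:
        adjust = ["gcs_c", "grs"]
    degenerate = [c for c in adjust if frame[c].nunique() <= 1]
    if degenerate:
        warnings.warn(f"dropping constant adjustment covariates: {degenerate}")
        adjust = [c for c in adjust if c not in degenerate]
    if pathway == "bdnf_to_cortisol":
        covs = ["intercept", "bdnf_high"] + adjust
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in covs[1:]]
        )
        return X, covs, frame["traj_high"].to_numpy(dtype=int), None, None
    if pathway == "bdnf_total":
        covs = ["bdnf_high"] + adjust
    elif pathway == "cortisol_to_mortality":
        covs = ["traj_high", "bdnf_high"] + adjust
    elif pathway == "bdnf_direct":
        covs = ["bdnf_high", "traj_high"] + adjust
    else:
        raise PipelineError(f"unknown pathway {pathway!r}")
    X = np.column_stack([frame[c].to_numpy(dtype=float) for c in covs])
    return X, covs, None, frame["time"].to_numpy(dtype=float), frame["event"].to_numpy(dtype=int)


def _frequentist_fit(frame, pathway, drop_age=False, ties="efron"):
    X, names, y, time, event = _design_for(frame, pathway, drop_age)
    if pathway == "bdnf_to_cortisol":
        return reg.fit_logistic(X, y, names)
    return reg.fit_cox(time, event, X, names, ties=ties)


# ------------------------------------------------------------------ priors

def derive_priors(prior_frame: pd.DataFrame, drop_age: bool = False,
                  inform_all: bool = False) -> dict:
    """Fit the four pathway models on the prior cohort and record beta/SE.

    Only the focal coefficient is informed unless ``inform_all``; nuisance
    covariates keep diffuse Normal(0, 10^2) priors.
    """
    priors = {}
    for pathway in PATHWAYS:
        try:
            fit = _frequentist_fit(prior_frame, pathway, drop_age)
        except reg.FitError as exc:
            raise PipelineError(f"prior fit failed for pathway {pathway!r}: {exc}") from exc
        if inform_all:
            priors[pathway] = PathwayPrior(pathway, list(fit.names), fit.coef.copy(),
                                           fit.se.copy())
        else:
            b, se = fit.coefficient(_FOCAL[pathway])
            priors[pathway] = PathwayPrior.from_fit(pathway, fit, _FOCAL[pathway], b, se)
    return priors


def diffuse_priors(frame: pd.DataFrame, drop_age: bool = False) -> dict:
    """Diffuse Normal(0, 10^2) priors on every coefficient of every pathway."""
    out = {}
    for pathway in PATHWAYS:
        _, names, *_ = _design_for(frame, pathway, drop_age)
        out[pathway] = PathwayPrior(pathway, names, np.zeros(len(names)),
                                    np.full(len(names), 10.0))
    return out


# ----------------------------------------------------------- pathway models

def run_pathway_models(
    frame: pd.DataFrame,
    priors: dict,
    settings: MCMCSettings | None = None,
    drop_age: bool = False,
    ties: str = "efron",
) -> dict:
    """Sample all four pathway posteriors.

    Returns pathway -> {"summary": PosteriorSummary, "focal_draws": (chains, draws),
    "fit": frequentist ModelFit} with seeds split deterministically per pathway
    so total/direct draws are pairable.
    """
    settings = settings or MCMCSettings()
    root = np.random.SeedSequence(settings.seed)
    path_seeds = {p: s.generate_state(1)[0] % (2**31) for p, s in
                  zip(PATHWAYS, root.spawn(len(PATHWAYS)))}
    results = {}
    for pathway in PATHWAYS:
        X, names, y, time, event = _design_for(frame, pathway, drop_age)
        prior = priors[pathway]
        if list(prior.names) != list(names):
            raise PipelineError(
                f"prior covariates {prior.names} do not match design {names} "
                f"for pathway {pathway!r}"
            )
        mle = _frequentist_fit(frame, pathway, drop_age, ties)
        if pathway == "bdnf_to_cortisol":
            def loglik(beta, X=X, y=y):
                return reg.logistic_loglik(beta, X, y)
        else:
            prob = reg.CoxProblem(time, event, X, ties=ties)
            loglik = prob.loglik
        s = MCMCSettings(**{**settings.__dict__, "seed": int(path_seeds[pathway])})
        out = mcmc_sample(loglik, prior, s, init=mle.coef, base_scales=mle.se)
        focal = names.index(_FOCAL[pathway])
        focal_draws = out["draws"][:, :, focal]
        results[pathway] = {
            "summary": summarize_posterior(focal_draws),
            "focal_draws": focal_draws,
            "fit": mle,
            "accept": out["accept"],
        }
    return results


# -------------------------------------------------------- mediation algebra

def mediation_percentage(or_total: float, or_direct: float) -> float:
    """100 * [ln(OR_total) - ln(OR_direct)] / ln(OR_total).

    May be negative or exceed 100; undefined when the total effect is null.
    """
    if or_total <= 0 or or_direct <= 0:
        raise ValueError("odds/hazard ratios must be positive")
    if or_total == 1.0:
        raise ValueError("mediation percentage undefined at a null total effect")
    return 100.0 * (np.log(or_total) - np.log(or_direct)) / np.log(or_total)


def mediation_percentage_interval(total_draws, direct_draws) -> tuple:
    """Equal-tail 95% interval of the per-draw mediation percentage.

    Draws must be paired (same run schedule and length).  Draws with total
    log effect within +-0.01 of zero make the ratio unstable; more than 5%
    of them raises a warning.
    """
    t = np.asarray(total_draws, dtype=float).ravel()
    d = np.asarray(direct_draws, dtype=float).ravel()
    if t.size != d.size:
        raise ValueError("total and direct draws must be paired")
    near_null = np.abs(t) < 0.01
    if near_null.mean() > 0.05:
        warnings.warn(
            "over 5% of total-effect draws are near zero; the mediation "
            "percentage interval is unstable"
        )
    pct = 100.0 * (t - d) / np.where(near_null, np.nan, t)
    lo, hi = np.nanpercentile(pct, [2.5, 97.5])
    return float(lo), float(hi)


def assess_baron_kenny(summaries: dict, alpha: float = 0.05) -> tuple[dict, str, float]:
    """Four-criterion assessment from the pathway posterior summaries.

    Criteria 1-3: posterior tail probability below alpha for the total,
    exposure->mediator and mediator->outcome pathways.  Criterion 4:
    attenuation, |ln direct| < |ln total|.  Classification: none if 1-3 fail;
    full if additionally the direct effect is non-significant and the
    mediation percentage reaches 80; else partial.
    """
    tot = summaries["bdnf_total"]
    a_ = summaries["bdnf_to_cortisol"]
    b_ = summaries["cortisol_to_mortality"]
    dire = summaries["bdnf_direct"]
    crit = {
        1: bool(tot.tail_prob < alpha),
        2: bool(a_.tail_prob < alpha),
        3: bool(b_.tail_prob < alpha),
        4: bool(abs(np.log(dire.point)) < abs(np.log(tot.point))),
    }
    pct = np.nan
    if tot.point != 1.0:
        pct = mediation_percentage(tot.point, dire.point)
    if not (crit[1] and crit[2] and crit[3]):
        cls = "none"
    elif crit[4] and dire.tail_prob >= alpha and not np.isnan(pct) and pct >= 80:
        cls = "full"
    else:
        cls = "partial"
    return crit, cls, float(pct)


def _mediate_one(frame, priors, settings, stratum, drop_age):
    res = run_pathway_models(frame, priors, settings, drop_age=drop_age)
    summaries = {p: res[p]["summary"] for p in PATHWAYS}
    crit, cls, pct = assess_baron_kenny(summaries)
    interval = mediation_percentage_interval(
        res["bdnf_total"]["focal_draws"], res["bdnf_direct"]["focal_draws"]
    )
    return MediationResult(
        stratum=stratum, summaries=summaries, criteria_met=crit,
        classification=cls, mediation_pct=pct, mediation_pct_interval=interval,
        n=len(frame), events=int(frame["event"].sum()),
    ), res


def stratified_mediation(
    frame: pd.DataFrame,
    priors_all: dict,
    priors_by_stratum: dict | None = None,
    settings: MCMCSettings | None = None,
    age_cut: float = 48.0,
) -> dict:
    """Mediation for the whole cohort and within age strata.

    Within strata the (degenerate) age indicator is dropped from adjustment.
    Strata without events are skipped with a warning.  priors_by_stratum maps
    stratum label -> pathway priors fit on the matching prior-cohort stratum;
    without it the all-subject priors' focal information is reused.
    """
    out = {}
    out["all"], _ = _mediate_one(frame, priors_all, settings, "all", drop_age=False)
    strata = {
        "age<48": frame[frame["age_high"] == 0],
        "age>=48": frame[frame["age_high"] == 1],
    }
    for label, sub in strata.items():
        if len(sub) == 0 or sub["event"].sum() == 0:
            warnings.warn(f"stratum {label} has no events; skipped")
            continue
        if priors_by_stratum and label in priors_by_stratum:
            pri = priors_by_stratum[label]
        else:
            pri = {
                p: PathwayPrior(
                    p,
                    [n for n in priors_all[p].names if n != "age_high"],
                    np.asarray([l for n, l in zip(priors_all[p].names, priors_all[p].loc)
                                if n != "age_high"]),
                    np.asarray([s for n, s in zip(priors_all[p].names, priors_all[p].scale)
                                if n != "age_high"]),
                )
                for p in PATHWAYS
            }
        try:
            out[label], _ = _mediate_one(sub, pri, settings, label, drop_age=True)
        except (reg.FitError, PipelineError) as exc:
            warnings.warn(f"stratum {label} skipped: {exc}")
    return out


# ---------------------------------------------------------------- moderation

def grs_moderation(frame: pd.DataFrame, age_cut: float = 48.0,
                   min_stratum: int = 5, ties: str = "efron") -> ModerationResult:
    """GRS-stratified BDNF->trajectory ORs and the BDNF x GRS mortality term.

    The per-GRS logistic models adjust for binary age only; the interaction
    Cox models (one per age stratum) adjust for GCS and trajectory group.
    """
    if frame["grs"].nunique() < 2:
        raise PipelineError("BDNF x GRS interaction inestimable: single GRS value")
    warns = []
    rows = []
    for g in (0, 1, 2):
        sub = frame[frame["grs"] == g]
        row = {"grs": g, "n": len(sub),
               "n_high": int(sub["traj_high"].sum()) if len(sub) else 0}
        if len(sub) < min_stratum:
            warns.append(f"GRS={g} stratum has {len(sub)} subjects (<{min_stratum}); unstable")
        if len(sub) < 2:
            row.update(OR=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan)
            rows.append(row)
            continue
        try:
            X = np.column_stack([
                np.ones(len(sub)),
                sub["bdnf_high"].to_numpy(dtype=float),
                sub["age_high"].to_numpy(dtype=float),
            ])
            fit = reg.fit_logistic(X, sub["traj_high"].to_numpy(dtype=int),
                                   ["intercept", "bdnf_high", "age_high"])
            b, se = fit.coefficient("bdnf_high")
            z = 1.959963984540054
            row.update(OR=float(np.exp(b)), ci_low=float(np.exp(b - z * se)),
                       ci_high=float(np.exp(b + z * se)),
                       p=float(fit.p_values[fit.names.index("bdnf_high")]))
        except reg.FitError as exc:
            warns.append(f"GRS={g} logistic fit failed: {exc}")
            row.update(OR=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan)
        rows.append(row)
    per_grs = pd.DataFrame(rows)

    inter_rows = []
    for label, sub in (("age<48", frame[frame["age_high"] == 0]),
                       ("age>=48", frame[frame["age_high"] == 1])):
        if len(sub) == 0 or sub["event"].sum() == 0:
            warns.append(f"interaction model skipped for {label}: no events")
            continue
        X = np.column_stack([
            sub["bdnf_high"].to_numpy(dtype=float),
            sub["grs"].to_numpy(dtype=float),
            (sub["bdnf_high"] * sub["grs"]).to_numpy(dtype=float),
            sub["gcs_c"].to_numpy(dtype=float),
            sub["traj_high"].to_numpy(dtype=float),
        ])
        names = ["bdnf_high", "grs", "bdnf_x_grs", "gcs_c", "traj_high"]
        try:
            fit = reg.fit_cox(sub["time"].to_numpy(dtype=float),
                              sub["event"].to_numpy(dtype=int), X, names, ties=ties)
            b, se = fit.coefficient("bdnf_x_grs")
            inter_rows.append({
                "stratum": label, "n": len(sub), "events": int(sub["event"].sum()),
                "beta": b, "se": se,
                "p": float(fit.p_values[names.index("bdnf_x_grs")]),
            })
        except reg.FitError as exc:
            warns.append(f"interaction model failed for {label}: {exc}")
    interaction = pd.DataFrame(inter_rows)
    return ModerationResult(per_grs=per_grs, interaction=interaction, warnings=warns)
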