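"""Simulation configuration and self-calibration.

The configuration describes a synthetic severe-TBI cohort: two latent
log-scale cortisol trajectory classes over post-injury days 0–6, temporally
stable CSF BDNF, two biallelic BDNF SNPs (rs6265, rs7124442) coded as
carrier classes, and an exponential survival mechanism right-censored at
180 days.  Two quantities are solved rather than stated:

* the intercept of the BDNF→trajectory-class logistic link, so that the
  marginal probability of the high class equals ``class_mixing``;
* (optionally) the baseline hazard, so that the expected death fraction
  matches a target — the packaged ``paper_calibrated`` profile uses 26/117.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "SimulationConfig",
    "class_intercept",
    "expected_death_fraction",
    "calibrate_baseline_hazard",
    "paper_calibrated",
    "mediated30_profile",
    "load_config",
    "save_config",
]

#: Daily mean cortisol (ng/mL), days 0..6, log-quadratic so the curves lie in
#: the order-2 growth-curve family the trajectory model fits.  The high class
#: peaks on day 2 and declines; the low class spikes modestly on day 1 and
#: stays low.  The high-class level is solved so the pooled expected weekly
#: mean is 24.28 ng/mL at the default class mix and residual sd.
_HIGH_CURVE = [42.850675, 49.044174, 51.301572, 49.044174, 42.850675,
               34.216959, 24.971156]
_LOW_CURVE = [12.0, 12.242416, 12.0, 11.301174, 10.225725, 8.889819, 7.425401]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    n_subjects: int = 117
    # carrier-class frequencies per SNP (Val/Val vs Met-carrier; T/T vs C-carrier)
    genotype_freqs: dict = field(
        default_factory=lambda: {
            "rs6265": {"Val/Val": 0.581, "Met-carrier": 0.419},
            "rs7124442": {"T/T": 0.521, "C-carrier": 0.479},
        }
    )
    # marginal probability of the high cortisol trajectory class
    class_mixing: float = 44 / 117
    # per-class mean daily cortisol on the natural scale (ng/mL); logged internally
    trajectory_means: dict = field(
        default_factory=lambda: {"high": list(_HIGH_CURVE), "low": list(_LOW_CURVE)}
    )
    trajectory_sd: float = 0.4  # within-class residual sd, ln ng/mL
    # latent BDNF level group: fraction high and group means/sds (ng/mL)
    bdnf_high_frac: float = 0.25
    bdnf_mean_by_level: dict = field(
        default_factory=lambda: {"high": 0.322, "low": 0.146}
    )
    bdnf_between_sd: dict = field(default_factory=lambda: {"high": 0.040, "low": 0.022})
    bdnf_sd: float = 0.02  # daily within-subject noise (ng/mL)
    # BDNF-high → high trajectory class, log odds
    log_or_bdnf_to_class: float = math.log(4.12)
    baseline_hazard: float = 5.0592752e-4  # events/day; see calibrate_baseline_hazard
    log_hr: dict = field(
        default_factory=lambda: {
            "bdnf_high": math.log(1.58),
            "traj_high": math.log(3.05),
            "age_high": math.log(2.5),
            "gcs": -0.25,
        }
    )
    gcs_center: float = 5.5  # GCS covariate is centred here in the hazard
    age_mean: float = 36.0
    age_sd: float = 16.0
    age_range: tuple = (16.0, 74.0)
    age_cut: float = 48.0
    male_frac: float = 0.853
    censor_day: float = 180.0
    missingness_rate: float = 0.3
    twice_daily_rate: float = 0.3  # chance an observed day has two samples
    elisa_fraction: float = 0.15  # cortisol samples re-assayed on the ELISA scale
    cortisol_detection_limit: float = 1.0  # synthetic kit lower bound (ng/mL)
    bdnf_detection_limit: float = 0.08  # assay sensitivity 80 pg/mL
    seed: int = 20170309

    def validate(self) -> None:
        for snp, fr in self.genotype_freqs.items():
            total = sum(fr.values())
            if any(p < 0 or p > 1 for p in fr.values()) or abs(total - 1.0) > 1e-9:
                raise ConfigError(f"genotype frequencies for {snp} must be a probability vector")
        for p, name in [
            (self.class_mixing, "class_mixing"),
            (self.bdnf_high_frac, "bdnf_high_frac"),
            (self.missingness_rate, "missingness_rate"),
            (self.twice_daily_rate, "twice_daily_rate"),
            (self.elisa_fraction, "elisa_fraction"),
            (self.male_frac, "male_frac"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.censor_day <= 0:
            raise ConfigError("censor_day must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.trajectory_sd < 0 or self.bdnf_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        for lab in ("high", "low"):
            if len(self.trajectory_means[lab]) != 7:
                raise ConfigError("trajectory mean curves must cover days 0-6")
            if any(v <= 0 for v in self.trajectory_means[lab]):
                raise ConfigError("trajectory means are ng/mL and must be positive")
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def class_intercept(cfg: SimulationConfig) -> float:
    """Logistic intercept making marginal P(high class) equal class_mixing."""
    pb = cfg.bdnf_high_frac
    lor = cfg.log_or_bdnf_to_class

    def gap(a):
        return (1 - pb) * _sigmoid(a) + pb * _sigmoid(a + lor) - cfg.class_mixing

    return float(optimize.brentq(gap, -30.0, 30.0))


def age_high_probability(cfg: SimulationConfig) -> float:
    lo, hi = cfg.age_range
    a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    tn = stats.truncnorm(a, b, loc=cfg.age_mean, scale=cfg.age_sd)
    return float(1.0 - tn.cdf(cfg.age_cut))


def expected_death_fraction(cfg: SimulationConfig, baseline_hazard: float | None = None) -> float:
    """Exact expected death fraction under the generative model.

    Enumerates the discrete covariate lattice (BDNF group x trajectory class x
    age>=cut x GCS 3..8) and integrates the exponential event time against the
    censoring day.
    """
    h0 = cfg.baseline_hazard if baseline_hazard is None else baseline_hazard
    a = class_intercept(cfg)
    p_age = age_high_probability(cfg)
    b = cfg.log_hr
    total = 0.0
    for bd, pb in ((0, 1 - cfg.bdnf_high_frac), (1, cfg.bdnf_high_frac)):
        p_high = _sigmoid(a + cfg.log_or_bdnf_to_class * bd)
        for cl, pc in ((0, 1 - p_high), (1, p_high)):
            for ah, pa in ((0, 1 - p_age), (1, p_age)):
                for g in range(3, 9):
                    lam = h0 * math.exp(
                        b["bdnf_high"] * bd
                        + b["traj_high"] * cl
                        + b["age_high"] * ah
                        + b["gcs"] * (g - cfg.gcs_center)
                    )
                    total += pb * pc * pa * (1 / 6) * (1 - math.exp(-lam * cfg.censor_day))
    return total


def calibrate_baseline_hazard(cfg: SimulationConfig, target_fraction: float) -> float:
    """Solve the baseline hazard so expected deaths hit target_fraction."""
    if not 0 < target_fraction < 1:
        raise ConfigError("target death fraction must be in (0, 1)")
    return float(
        optimize.brentq(
            lambda h: expected_death_fraction(cfg, h) - target_fraction, 1e-10, 1.0
        )
    )


def paper_calibrated(**overrides) -> SimulationConfig:
    """The packaged default profile.

    Calibrated so that, in expectation over replicate cohorts of n=117:
    26 deaths by day 180, 44 high-trajectory subjects, 68 Val/Val subjects,
    mean weekly cortisol 24.28 ng/mL and mean weekly BDNF 0.19 ng/mL.
    """
    cfg = SimulationConfig(**overrides)
    if "baseline_hazard" not in overrides:
        cfg.baseline_hazard = calibrate_baseline_hazard(cfg, 26 / 117)
    cfg.validate()
    return cfg


def mediated30_profile(**overrides) -> SimulationConfig:
    """Variant profile with a true proportion mediated of ~30%.

    Hazard ratios are non-collapsible: with the default profile's conditional
    effects (trajectory HR 3.05 and direct BDNF HR 1.58) the *marginal*
    total-effect hazard ratio of BDNF is about 2.27, so the true proportion
    mediated on the log-hazard scale is ~43%.  Lowering the BDNF->class
    log-odds to 0.8 brings the marginal total effect to ~1.94 and the true
    proportion mediated to ~30%, the regime the mediation-recovery studies
    target.  Cohort-level calibration (death count, class share, genotype
    frequencies, biomarker means) is unchanged because the class-model
    intercept re-solves against class_mixing.
    """
    overrides.setdefault("log_or_bdnf_to_class", 0.8)
    return paper_calibrated(**overrides)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    profile = data.pop("profile", None)
    if profile == "paper_calibrated":
        return paper_calibrated(**data)
    if profile == "mediated30":
        return mediated30_profile(**data)
    if profile is not None:
        raise ConfigError(f"unknown profile {profile!r}")
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
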