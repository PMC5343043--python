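"""Synthetic severe-TBI cohort generator.

Generates a subjects table (demographics, genotypes, right-censored survival)
and a long-format CSF biomarker table (cortisol and BDNF, days 0-6, up to two
samples per day) with the statistical structure the downstream mediation
analysis assumes: two latent log-scale cortisol trajectory classes, stable
BDNF, a logistic BDNF->class link, and an exponential mortality mechanism
censored at 180 days.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig, ConfigError, class_intercept
from .harmonize import CrossCalibration

__all__ = [
    "generate_genotypes",
    "generate_trajectory_series",
    "generate_survival",
    "generate_cohort",
    "write_cohort",
    "write_vcf",
]

SUBJECT_COLUMNS = [
    "id", "age", "age_high", "sex", "gcs", "rs6265", "rs7124442",
    "time", "event", "true_class", "true_bdnf_high",
]
BIOMARKER_COLUMNS = [
    "subject_id", "analyte", "day", "value", "assay",
    "below_detection", "undetectable",
]


def generate_genotypes(n: int, freqs: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Draw carrier-class genotypes independently per SNP.

    freqs maps SNP name -> {category: probability}; probabilities must sum to 1.
    """
    out = {}
    for snp, fr in freqs.items():
        cats = list(fr)
        p = np.asarray([fr[c] for c in cats], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(f"invalid genotype frequency vector for {snp}")
        out[snp] = rng.choice(cats, size=n, p=p)
    return pd.DataFrame(out)


def generate_trajectory_series(
    class_label: str, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """One subject's daily cortisol (ng/mL) over days 0-6; NaN where missing.

    Values are exp(ln mean + Normal noise) so they are strictly positive;
    days drop out independently at missingness_rate.
    """
    mu = np.log(np.asarray(cfg.trajectory_means[class_label], dtype=float))
    vals = np.exp(mu + cfg.trajectory_sd * rng.standard_normal(7))
    missing = rng.random(7) < cfg.missingness_rate
    vals[missing] = np.nan
    return vals


def generate_survival(
    linear_predictor: float, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[float, int]:
    """Exponential event time with hazard baseline*exp(lp), censored at censor_day.

    An event landing exactly on the censoring day counts as an event.
    """
    if cfg.baseline_hazard <= 0:
        raise ConfigError("baseline_hazard must be positive")
    lam = cfg.baseline_hazard * math.exp(linear_predictor)
    t = rng.exponential(1.0 / lam) if lam > 0 else math.inf
    if t <= cfg.censor_day:
        return float(t), 1
    return float(cfg.censor_day), 0


def _linear_predictor(cfg, bdnf_high, traj_high, age_high, gcs):
    b = cfg.log_hr
    return (
        b["bdnf_high"] * bdnf_high
        + b["traj_high"] * traj_high
        + b["age_high"] * age_high
        + b["gcs"] * (gcs - cfg.gcs_center)
    )


def _biomarker_frame(ids, analyte, day_matrix, cfg, rng, elisa_ok):
    """Expand an (n, 7) daily matrix into raw sample rows.

    Observed days yield one sample, or two with probability twice_daily_rate
    (both carry the day's value, so the daily mean is unbiased).  Cortisol
    samples may be re-expressed on the ELISA scale by inverting the default
    cross-calibration, but only where the inverse stays positive.
    """
    cal = CrossCalibration()
    subj_idx, day = np.nonzero(~np.isnan(day_matrix))
    value = day_matrix[subj_idx, day]
    dup = rng.random(len(value)) < cfg.twice_daily_rate
    rep = np.where(dup, 2, 1)
    subj_idx = np.repeat(subj_idx, rep)
    day = np.repeat(day, rep)
    value = np.maximum(np.repeat(value, rep), 0.001)
    assay = np.full(len(value), "ELISA" if analyte == "BDNF" else "RIA", dtype=object)
    if elisa_ok:
        as_elisa = (rng.random(len(value)) < cfg.elisa_fraction) & (value > cal.intercept)
        value = np.where(as_elisa, (value - cal.intercept) / cal.slope, value)
        assay[as_elisa] = "ELISA"
    return pd.DataFrame({
        "subject_id": ids[subj_idx],
        "analyte": analyte,
        "day": day,
        "value": value,
        "assay": assay,
        "below_detection": False,
        "undetectable": False,
    })


def generate_cohort(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Generate (subjects table, biomarker table) under the configured model."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    geno = generate_genotypes(n, cfg.genotype_freqs, rng)
    lo, hi = cfg.age_range
    a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    age = stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                              size=n, random_state=rng)
    age_high = (age >= cfg.age_cut).astype(int)
    sex = np.where(rng.random(n) < cfg.male_frac, "M", "F")
    gcs = rng.integers(3, 9, size=n)

    bdnf_high = (rng.random(n) < cfg.bdnf_high_frac).astype(int)
    a0 = class_intercept(cfg)
    p_high = 1.0 / (1.0 + np.exp(-(a0 + cfg.log_or_bdnf_to_class * bdnf_high)))
    traj_high = (rng.random(n) < p_high).astype(int)
    ids = np.array([f"S{i + 1:04d}" for i in range(n)])

    log_mu = np.log(np.vstack([
        np.asarray(cfg.trajectory_means["low"], dtype=float),
        np.asarray(cfg.trajectory_means["high"], dtype=float),
    ]))
    cort = np.exp(log_mu[traj_high] + cfg.trajectory_sd * rng.standard_normal((n, 7)))
    cort[rng.random((n, 7)) < cfg.missingness_rate] = np.nan

    means = np.where(bdnf_high == 1, cfg.bdnf_mean_by_level["high"],
                     cfg.bdnf_mean_by_level["low"])
    sds = np.where(bdnf_high == 1, cfg.bdnf_between_sd["high"],
                   cfg.bdnf_between_sd["low"])
    subj_mean = rng.normal(means, sds)
    bdnf = subj_mean[:, None] + cfg.bdnf_sd * rng.standard_normal((n, 7))
    bdnf[rng.random((n, 7)) < cfg.missingness_rate] = np.nan

    lp = (cfg.log_hr["bdnf_high"] * bdnf_high
          + cfg.log_hr["traj_high"] * traj_high
          + cfg.log_hr["age_high"] * age_high
          + cfg.log_hr["gcs"] * (gcs - cfg.gcs_center))
    lam = cfg.baseline_hazard * np.exp(lp)
    draw = rng.exponential(1.0 / lam)
    event = (draw <= cfg.censor_day).astype(int)  # boundary deaths count as events
    time = np.minimum(draw, cfg.censor_day)

    subjects = pd.DataFrame({
        "id": ids,
        "age": np.round(age, 2),
        "age_high": age_high,
        "sex": sex,
        "gcs": gcs,
        "rs6265": geno["rs6265"],
        "rs7124442": geno["rs7124442"],
        "time": np.round(time, 4),
        "event": event,
        "true_class": np.where(traj_high == 1, "high", "low"),
        "true_bdnf_high": bdnf_high,
    }, columns=SUBJECT_COLUMNS)

    bio_parts = [
        _biomarker_frame(ids, "cortisol", cort, cfg, rng, elisa_ok=True),
        _biomarker_frame(ids, "BDNF", bdnf, cfg, rng, elisa_ok=False),
    ]
    biomarkers = (
        pd.concat(bio_parts, ignore_index=True)
        .sort_values(["subject_id", "analyte", "day"], kind="stable")
        .reset_index(drop=True)
    )[BIOMARKER_COLUMNS]
    return subjects, biomarkers


def write_cohort(subjects: pd.DataFrame, biomarkers: pd.DataFrame, out_dir) -> dict:
    """Write the two tables as tab-delimited text; returns their paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out / "subjects.tsv",
        "biomarkers": out / "biomarkers.tsv",
    }
    subjects.to_csv(paths["subjects"], sep="\t", index=False)
    biomarkers.to_csv(paths["biomarkers"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


_VCF_HEADER = """##fileformat=VCFv4.2
##source=cortmed-synthetic
##contig=<ID=11>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

# REF is the major allele by convention here: rs6265 REF=G (Val), ALT=A (Met);
# rs7124442 REF=T, ALT=C.  Carrier classes collapse to 0/0 vs 0/1.
_VCF_SITES = [
    ("11", 27679916, "rs6265", "G", "A", "rs6265", "Val/Val"),
    ("11", 27700125, "rs7124442", "T", "C", "rs7124442", "T/T"),
]


def write_vcf(subjects: pd.DataFrame, path) -> str:
    """Write a minimal two-record VCF carrying the cohort genotypes."""
    ids = list(subjects["id"])
    lines = [_VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids))
    for chrom, pos, rsid, ref, alt, col, homref in _VCF_SITES:
        gts = ["0/0" if g == homref else "0/1" for g in subjects[col]]
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)
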