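"""Assay harmonization: cross-calibration, detection limits, day aggregation.

CSF cortisol was assayed on two platforms; ELISA readings are mapped onto the
RIA scale with a linear cross-calibration (default C_RIA = 6.32 + 0.76 * C_ELISA)
before pooling.  Samples below the kit's reporting range take the detection
limit value; undetectable samples take 0.001.  Up-to-twice-daily samples are
combined by arithmetic mean into one value per subject, analyte and day, and a
weekly mean is taken over the days actually present (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CrossCalibration",
    "fit_cross_calibration",
    "convert_elisa_to_ria",
    "apply_detection_limits",
    "daily_aggregate",
    "harmonize",
]

DAYS = range(7)
UNDETECTABLE_VALUE = 0.001


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CrossCalibration:
    intercept: float = 6.32  # ng/mL
    slope: float = 0.76

    def __post_init__(self):
        if self.slope <= 0:
            raise CalibrationError("cross-calibration slope must be positive")


def fit_cross_calibration(paired) -> CrossCalibration:
    """OLS fit of RIA on ELISA from paired re-assayed samples."""
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise CalibrationError("need >=3 (ELISA, RIA) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate design: ELISA values all equal")
    X = np.column_stack([np.ones_like(x), x])
    (b0, b1), *_ = np.linalg.lstsq(X, y, rcond=None)
    return CrossCalibration(intercept=float(b0), slope=float(b1))


def convert_elisa_to_ria(value, cal: CrossCalibration = CrossCalibration()):
    """Affine map of ELISA readings (ng/mL) onto the RIA scale."""
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("biomarker concentrations must be non-negative")
    out = cal.intercept + cal.slope * v
    return float(out) if np.isscalar(value) else out


def apply_detection_limits(samples: pd.DataFrame, limit: float) -> pd.DataFrame:
    """Assign the detection limit to below-range samples and 0.001 to undetectable.

    ``below_detection`` marks samples under the kit's reporting range;
    ``undetectable`` (which implies below_detection in real data) marks samples
    with no measurable signal at all.
    """
    if limit <= 0:
        raise ValueError("detection limit must be positive")
    out = samples.copy()
    below = out["below_detection"].astype(bool) & ~out["undetectable"].astype(bool)
    out.loc[below, "value"] = limit
    out.loc[out["undetectable"].astype(bool), "value"] = UNDETECTABLE_VALUE
    return out


def daily_aggregate(samples: pd.DataFrame) -> pd.DataFrame:
    """Per subject/analyte daily means and the weekly mean over present days.

    Returns a frame with columns subject_id, analyte, day0..day6 (NaN where no
    sample) and weekly_mean.  Input values must already be on a single scale.
    """
    required = {"subject_id", "analyte", "day", "value"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"biomarker table missing columns: {sorted(missing)}")
    if samples.empty:
        return pd.DataFrame(
            columns=["subject_id", "analyte", *[f"day{d}" for d in DAYS], "weekly_mean"]
        )
    bad_day = ~samples["day"].isin(list(DAYS))
    if bad_day.any():
        raise ValueError("sample days must be integers 0-6")
    daily = (
        samples.groupby(["subject_id", "analyte", "day"], as_index=False)["value"].mean()
    )
    # dropna=True so a subject/analyte pair appears only if it has >=1 sample
    # (dropna=False would expand to the full subject x analyte product)
    wide = daily.pivot_table(
        index=["subject_id", "analyte"], columns="day", values="value"
    )
    wide = wide.reindex(columns=list(DAYS))
    wide.columns = [f"day{d}" for d in DAYS]
    wide["weekly_mean"] = wide[[f"day{d}" for d in DAYS]].mean(axis=1, skipna=True)
    return wide.reset_index()


def harmonize(
    biomarkers: pd.DataFrame,
    cal: CrossCalibration = CrossCalibration(),
    detection_limits: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full harmonization: convert ELISA cortisol, clip, day-aggregate.

    detection_limits maps analyte -> limit (ng/mL); analytes without a limit
    are passed through (their below-range flags must then be clean).
    Returns (daily table, audit log).
    """
    df = biomarkers.copy()
    audit = {"n_samples": len(df), "n_converted": 0, "n_below_detection": 0,
             "n_undetectable": 0, "subjects_no_cortisol": []}
    is_elisa_cort = (df["analyte"] == "cortisol") & (df["assay"] == "ELISA")
    df.loc[is_elisa_cort, "value"] = convert_elisa_to_ria(
        df.loc[is_elisa_cort, "value"].to_numpy(), cal
    )
    df.loc[is_elisa_cort, "assay"] = "RIA"
    audit["n_converted"] = int(is_elisa_cort.sum())
    for analyte, limit in (detection_limits or {}).items():
        mask = df["analyte"] == analyte
        df.loc[mask, :] = apply_detection_limits(df.loc[mask, :], limit)
    audit["n_below_detection"] = int(
        (df["below_detection"].astype(bool) & ~df["undetectable"].astype(bool)).sum()
    )
    audit["n_undetectable"] = int(df["undetectable"].astype(bool).sum())
    daily = daily_aggregate(df)
    have_cort = set(daily.loc[daily["analyte"] == "cortisol", "subject_id"])
    audit["subjects_no_cortisol"] = sorted(set(df["subject_id"]) - have_cort)
    return daily, audit
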