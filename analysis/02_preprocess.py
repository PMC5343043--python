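#!/usr/bin/env python
"""Harmonize assays, fit cortisol trajectories, score genotypes.

Reads the cohort written by 01_simulate_cohort.py, converts ELISA cortisol to
the RIA scale, aggregates to daily values, fits the two-class growth mixture
on log cortisol, dichotomizes weekly BDNF at the 75th percentile and computes
the gene risk score.  Writes the per-subject analysis frame, a trajectory
summary and (if matplotlib is present) the group-mean daily cortisol curves.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from cortmed.mediation import build_analysis_frame
from cortmed.trajectory import TrajectorySpec

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=20170309)
parser.add_argument("--in-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--out-dir", type=Path, default=Path("results/preprocessed"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

subjects = pd.read_csv(args.in_dir / "subjects.tsv", sep="\t")
biomarkers = pd.read_csv(args.in_dir / "biomarkers.tsv", sep="\t")

with warnings.catch_warnings(record=True) as caught:
    warnings.simplefilter("always")
    frame, log = build_analysis_frame(subjects, biomarkers,
                                      TrajectorySpec(seed=args.seed))
frame.to_csv(args.out_dir / "analysis_frame.tsv", sep="\t", index=False)

fit = log["trajectory_fit"]
pd.DataFrame({
    "class": range(len(fit.mixing)),
    "label": [fit.labels.get(k, "") for k in range(len(fit.mixing))],
    "mixing": fit.mixing,
    "residual_sd": fit.class_sd,
}).to_csv(args.out_dir / "trajectory_summary.tsv", sep="\t", index=False)

n_high = int(frame["traj_high"].sum())
print(f"analysis frame: {len(frame)} subjects "
      f"({len(log['excluded_no_cortisol'])} excluded without cortisol)")
print(f"trajectory groups: {n_high} high / {len(frame) - n_high} low "
      f"(balanced: {log['trajectory_balanced']}; BIC {fit.bic:.1f})")
print(f"BDNF >=75th pct: {int(frame['bdnf_high'].sum())}; "
      f"GRS counts: {frame['grs'].value_counts().sort_index().to_dict()}")
print(f"harmonization: {log['harmonization']['n_converted']} ELISA cortisol "
      f"samples converted to the RIA scale")
for w in caught:
    print(f"warning: {w.message}")

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = np.arange(7)
    curves = np.exp(fit.fitted_curves())
    fig, ax = plt.subplots(figsize=(6, 4))
    for k in range(2):
        ax.plot(days, curves[k], marker="o", label=f"{fit.labels[k]} trajectory")
    ax.set_xlabel("day post-injury")
    ax.set_ylabel("CSF cortisol (ng/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(args.out_dir / "trajectory_curves.png", dpi=120)
    print(f"curves plotted to {args.out_dir / 'trajectory_curves.png'}")
except ImportError:
    print("matplotlib not installed; skipping the trajectory plot")
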