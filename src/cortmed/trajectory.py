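"""Group-based trajectory modelling of log daily cortisol.

A K-class finite mixture of polynomial growth curves with Normal residuals on
the log scale, fit by EM with multiple seeded restarts.  Subjects contribute
only their observed days, so missing slots need no imputation.  For K=2 the
class with the larger day-averaged fitted level is labelled "high".

When trajectory modelling discriminates poorly (one class swallowing >85% of
subjects, as happened for BDNF), the pipeline falls back to dichotomizing the
weekly mean at the 75th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "TrajectorySpec",
    "TrajectoryFit",
    "fit_trajectory_mixture",
    "assign_groups",
    "check_group_balance",
    "dichotomize_at_percentile",
]

_SD_FLOOR = 1e-4
_LOG2PI = np.log(2 * np.pi)


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectorySpec:
    n_classes: int = 2
    poly_order: int = 2
    max_iter: int = 500
    tol: float = 1e-8
    n_starts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise TrajectoryError("n_classes must be >= 1")
        if self.poly_order < 0:
            raise TrajectoryError("poly_order must be >= 0")
        if self.tol <= 0:
            raise TrajectoryError("tol must be positive")


@dataclass
class TrajectoryFit:
    class_coefficients: np.ndarray  # (K, order+1), ln ng/mL
    class_sd: np.ndarray            # (K,)
    mixing: np.ndarray              # (K,)
    posterior: np.ndarray           # (n, K)
    assignment: np.ndarray          # (n,) modal class index
    loglik: float
    loglik_trace: np.ndarray
    bic: float
    n_params: int
    converged: bool
    labels: dict = field(default_factory=dict)  # class index -> "high"/"low" (K=2)

    def fitted_curves(self, days=None) -> np.ndarray:
        """Per-class fitted log-mean over the given days (default 0-6)."""
        d = np.arange(7) if days is None else np.asarray(days, dtype=float)
        X = np.vander(d, self.class_coefficients.shape[1], increasing=True)
        return self.class_coefficients @ X.T


def _design(order: int) -> np.ndarray:
    return np.vander(np.arange(7, dtype=float), order + 1, increasing=True)


def _log_density_matrix(Y, obs, coefs, sds, X):
    """(n, K) per-subject class log likelihood over observed days."""
    n, K = Y.shape[0], coefs.shape[0]
    out = np.empty((n, K))
    for k in range(K):
        mu = X @ coefs[k]
        resid = np.where(obs, Y - mu, 0.0)
        n_obs = obs.sum(axis=1)
        out[:, k] = (
            -0.5 * (resid**2).sum(axis=1) / sds[k] ** 2
            - n_obs * (np.log(sds[k]) + 0.5 * _LOG2PI)
        )
    return out


def _m_step(Y, obs, resp, X, order):
    """Weighted polynomial LS and residual sd per class."""
    K = resp.shape[1]
    coefs = np.empty((K, order + 1))
    sds = np.empty(K)
    for k in range(K):
        w = np.where(obs, resp[:, [k]], 0.0)  # (n, 7)
        sw = w.sum()
        # normal equations over all observed (i, d) cells, weight resp_ik
        A = np.einsum("id,dp,dq->pq", w, X, X)
        b = np.einsum("id,dp,id->p", w, X, np.nan_to_num(Y))
        try:
            coefs[k] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            coefs[k], *_ = np.linalg.lstsq(A, b, rcond=None)
        mu = X @ coefs[k]
        rss = (w * np.nan_to_num(Y - mu) ** 2).sum()
        sds[k] = max(np.sqrt(rss / sw) if sw > 0 else _SD_FLOOR, _SD_FLOOR)
    pi = resp.mean(axis=0)
    return coefs, sds, pi


def _initial_assignment(Y, obs, K, rng, start_index):
    """Quantile split on per-subject mean levels; later starts get random flips."""
    means = np.where(obs, np.nan_to_num(Y), 0.0).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
    order = np.argsort(means, kind="stable")
    groups = np.array_split(order, K)
    assign = np.empty(len(means), dtype=int)
    for k, idx in enumerate(groups):
        assign[idx] = k
    if start_index > 0:
        flip = rng.random(len(means)) < 0.25
        assign[flip] = rng.integers(0, K, size=flip.sum())
    return assign


def _em_once(Y, obs, spec, rng, start_index):
    n = Y.shape[0]
    K, order = spec.n_classes, spec.poly_order
    X = _design(order)
    assign = _initial_assignment(Y, obs, K, rng, start_index)
    resp = np.zeros((n, K))
    resp[np.arange(n), assign] = 1.0
    coefs, sds, pi = _m_step(Y, obs, resp, X, order)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(spec.max_iter):
        logdens = _log_density_matrix(Y, obs, coefs, sds, X)
        joint = logdens + np.log(np.maximum(pi, 1e-300))
        ll = float(logsumexp(joint, axis=1).sum())
        trace.append(ll)
        resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        coefs, sds, pi = _m_step(Y, obs, resp, X, order)
        if ll - prev < spec.tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    logdens = _log_density_matrix(Y, obs, coefs, sds, X)
    joint = logdens + np.log(np.maximum(pi, 1e-300))
    ll = float(logsumexp(joint, axis=1).sum())
    trace.append(ll)
    resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    return coefs, sds, pi, resp, ll, np.asarray(trace), converged


def fit_trajectory_mixture(series: np.ndarray, spec: TrajectorySpec | None = None) -> TrajectoryFit:
    """Fit the K-class growth mixture to a subjects x 7 log-value matrix.

    ``series`` holds natural-log biomarker values with NaN for missing days;
    every row must have at least one observed day.  The best of ``n_starts``
    EM runs by log-likelihood is returned.
    """
    spec = spec or TrajectorySpec()
    Y = np.asarray(series, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 7:
        raise TrajectoryError("series must be an (n, 7) matrix")
    obs = ~np.isnan(Y)
    if np.any(obs.sum(axis=1) == 0):
        raise TrajectoryError("every subject needs >=1 observed day")
    n = Y.shape[0]
    if spec.n_classes > n:
        raise TrajectoryError("more classes than subjects")

    rng = np.random.default_rng(spec.seed)
    best = None
    for s in range(spec.n_starts):
        coefs, sds, pi, resp, ll, trace, conv = _em_once(Y, obs, spec, rng, s)
        if best is None or ll > best[4]:
            best = (coefs, sds, pi, resp, ll, trace, conv)
    coefs, sds, pi, resp, ll, trace, conv = best
    if not conv:
        warnings.warn("EM did not converge within max_iter; best iterate returned")
    n_params = spec.n_classes * (spec.poly_order + 1) + spec.n_classes + (spec.n_classes - 1)
    bic = -2.0 * ll + n_params * np.log(n)
    fit = TrajectoryFit(
        class_coefficients=coefs, class_sd=sds, mixing=pi, posterior=resp,
        assignment=resp.argmax(axis=1), loglik=ll, loglik_trace=trace,
        bic=float(bic), n_params=n_params, converged=conv,
    )
    if spec.n_classes == 2:
        fit.labels = _high_low_labels(fit)
    return fit


def _high_low_labels(fit: TrajectoryFit) -> dict:
    levels = fit.fitted_curves().mean(axis=1)
    # tie-break: lower class index labelled low
    hi = int(np.argmax(levels)) if levels[0] != levels[1] else 1
    return {hi: "high", 1 - hi: "low"}


def assign_groups(fit: TrajectoryFit) -> np.ndarray:
    """Per-subject {high, low} labels from the modal posterior class (K=2)."""
    if fit.class_coefficients.shape[0] != 2:
        raise TrajectoryError("high/low grouping requires a K=2 fit")
    labels = fit.labels or _high_low_labels(fit)
    return np.array([labels[k] for k in fit.assignment])


def check_group_balance(fit: TrajectoryFit, threshold: float = 0.85) -> bool:
    """False when any class holds strictly more than ``threshold`` of subjects.

    An imbalanced fit signals poor discrimination and triggers the
    75th-percentile fallback downstream.
    """
    shares = np.bincount(fit.assignment, minlength=fit.mixing.size) / fit.posterior.shape[0]
    return bool(np.all(shares <= threshold))


def dichotomize_at_percentile(weekly_means, pct: float = 75.0) -> np.ndarray:
    """Label subjects high iff weekly mean >= the linear-interpolation percentile."""
    x = np.asarray(weekly_means, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size == 0:
        raise ValueError("no weekly means available to dichotomize")
    if finite.size < 4:
        raise ValueError("need >=4 subjects for a percentile split")
    cutoff = np.percentile(finite, pct)
    out = np.where(x >= cutoff, "high", "low")
    out = np.where(np.isnan(x), None, out)
    return out
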