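"""Removal of CpG sites whose trimodal methylation betrays a germline C-to-T
variant rather than a true methylation signal.

A site where a C-to-T allele segregates shows apparent methylation clustering
near 1.0 (CC homozygotes), 0.5 (CT heterozygotes) and ~0 (TT homozygotes,
which contribute no methylatable cytosine). Such sites are detected by
comparing a 1-component to a 3-component univariate Gaussian mixture via BIC:
a site is flagged when BIC(1) - BIC(3) exceeds a threshold AND at least one
sample shows a vanishingly small value (the TT fingerprint).

The mixture fits run as a single EM vectorised across all sites at once,
which is what makes whole-matrix screening cheap; the per-site interface
`fit_gmm_1d` wraps the same code path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MethylationMatrix

__all__ = [
    "GmmFitResult",
    "fit_gmm_1d",
    "bic",
    "flag_artifact_sites",
    "apply_artifact_filter",
    "DELTA_BIC_THRESHOLD",
    "MIN_BETA_CUTOFF",
]

logger = logging.getLogger(__name__)

DELTA_BIC_THRESHOLD = 90.0
MIN_BETA_CUTOFF = 0.006

_VARIANCE_FLOOR = 1e-6
_LOG2PI = float(np.log(2.0 * np.pi))


def bic(loglik: float, n_params: int, n: int) -> float:
    """Bayesian Information Criterion: n_params * ln(n) - 2 * loglik."""
    if n < 1:
        raise ValueError("BIC requires n >= 1")
    return n_params * np.log(n) - 2.0 * loglik


def n_gmm_params(k: int) -> int:
    """Free parameters of a univariate k-component GMM: k means + k variances
    + (k-1) weights."""
    return 3 * k - 1


def _kmeanspp_init(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """D^2-weighted seeding of k initial means per site (vectorised).

    values: (S, n). Returns (S, k) initial means.
    """
    S, n = values.shape
    means = np.empty((S, k))
    first = rng.integers(0, n, size=S)
    means[:, 0] = values[np.arange(S), first]
    d2 = (values - means[:, [0]]) ** 2
    for j in range(1, k):
        total = d2.sum(axis=1, keepdims=True)
        # Degenerate (all points identical): fall back to uniform sampling.
        probs = np.where(total > 0, d2 / np.maximum(total, 1e-300), 1.0 / n)
        cum = np.cumsum(probs, axis=1)
        u = rng.uniform(size=(S, 1)) * cum[:, [-1]]
        idx = np.minimum((cum < u).sum(axis=1), n - 1)
        means[:, j] = values[np.arange(S), idx]
        d2 = np.minimum(d2, (values - means[:, [j]]) ** 2)
    return means


def _em_batch(
    values: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
    variance_floor: float = _VARIANCE_FLOOR,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM for univariate k-component GMMs, batched over sites.

    values: (S, n). Returns (loglik (S,), means (S,k), variances (S,k),
    weights (S,k)), each the best over ``n_init`` seeded restarts. The
    convergence check mirrors the usual per-iteration change in mean
    log-likelihood per sample; variances are floored, never zero.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-D (sites x samples)")
    S, n = values.shape
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")

    if k == 1:
        # Closed-form maximum: sample mean and biased (1/n) variance.
        mean = values.mean(axis=1)
        var_mle = values.var(axis=1)
        var = np.maximum(var_mle, variance_floor)
        ll = -0.5 * n * (_LOG2PI + np.log(var) + var_mle / var)
        return ll, mean[:, None], var[:, None], np.ones((S, 1))

    rng = np.random.default_rng(seed)
    best_ll = np.full(S, -np.inf)
    best_means = np.zeros((S, k))
    best_vars = np.ones((S, k))
    best_w = np.full((S, k), 1.0 / k)

    for _ in range(n_init):
        means = _kmeanspp_init(values, k, rng)  # (S, k)
        var = np.maximum(values.var(axis=1), variance_floor)[:, None].repeat(k, axis=1)
        w = np.full((S, k), 1.0 / k)
        ll = np.full(S, -np.inf)
        # Active-set EM: converged sites drop out of the batch, which is what
        # keeps whole-matrix screening fast (most sites converge early).
        active = np.arange(S)
        prev_ll = np.full(S, -np.inf)
        for _it in range(max_iter):
            va = values[active][:, :, None]  # (A, n, 1)
            ma, vva, wa = means[active], var[active], w[active]
            logpdf = -0.5 * (
                _LOG2PI
                + np.log(vva)[:, None, :]
                + (va - ma[:, None, :]) ** 2 / vva[:, None, :]
            )
            joint = logpdf + np.log(np.maximum(wa, 1e-300))[:, None, :]
            mx = joint.max(axis=2, keepdims=True)
            lse = mx[:, :, 0] + np.log(np.exp(joint - mx).sum(axis=2))
            ll_a = lse.sum(axis=1)
            resp = np.exp(joint - lse[:, :, None])
            nk = resp.sum(axis=1)  # (A, k)
            nk_safe = np.maximum(nk, 1e-12)
            ma = (resp * va).sum(axis=1) / nk_safe
            vva = (resp * (va - ma[:, None, :]) ** 2).sum(axis=1) / nk_safe
            means[active], var[active] = ma, np.maximum(vva, variance_floor)
            w[active] = nk / n
            ll[active] = ll_a
            done = np.abs(ll_a - prev_ll[active]) < tol * n
            prev_ll[active] = ll_a
            active = active[~done]
            if active.size == 0:
                break
        improved = ll > best_ll
        best_ll = np.where(improved, ll, best_ll)
        best_means = np.where(improved[:, None], means, best_means)
        best_vars = np.where(improved[:, None], var, best_vars)
        best_w = np.where(improved[:, None], w, best_w)
    return best_ll, best_means, best_vars, best_w


def fit_gmm_1d(
    values: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Fit a univariate k-component GMM by EM, best of ``n_init`` restarts.

    Returns (loglik, means, variances, weights). Deterministic given seed.
    """
    values = np.asarray(values, dtype=float).ravel()
    ll, means, var, w = _em_batch(
        values[None, :], k, seed=seed, n_init=n_init, tol=tol, max_iter=max_iter
    )
    return float(ll[0]), means[0], var[0], w[0]


@dataclass
class GmmFitResult:
    """Per-site mixture comparison underlying the artifact flags."""

    table: pd.DataFrame  # site_id-indexed: loglik_1, loglik_3, bic_1, bic_3,
    #                      delta_bic, min_beta, flagged, fit_failed
    delta_bic_threshold: float
    min_beta_cutoff: float
    seed: int

    @property
    def flagged(self) -> pd.Series:
        return self.table["flagged"]


def flag_artifact_sites(
    m: MethylationMatrix,
    delta_bic_threshold: float = DELTA_BIC_THRESHOLD,
    min_beta_cutoff: float = MIN_BETA_CUTOFF,
    seed: int = 0,
) -> GmmFitResult:
    """Flag trimodal genotype-artifact sites.

    A site is flagged iff BIC(1-component) - BIC(3-component) exceeds
    ``delta_bic_threshold`` AND its minimum beta value is below
    ``min_beta_cutoff`` (at least one apparent TT homozygote). Sites whose
    values are constant cannot be trimodal and are never flagged.
    """
    vals = m.beta.to_numpy()
    S, n = vals.shape
    if n < 3:
        raise ValueError("artifact flagging requires at least 3 samples")

    constant = vals.std(axis=1) == 0
    ll1, *_ = _em_batch(vals, 1, seed=seed)
    ll3 = np.full(S, np.nan)
    ok = ~constant
    if ok.any():
        ll3_ok, *_ = _em_batch(vals[ok], 3, seed=seed)
        ll3[ok] = ll3_ok
    if constant.any():
        logger.warning(
            "%d constant site(s) skipped by the 3-component fit (never flagged)",
            int(constant.sum()),
        )

    p1, p3 = n_gmm_params(1), n_gmm_params(3)
    bic1 = p1 * np.log(n) - 2.0 * ll1
    bic3 = p3 * np.log(n) - 2.0 * ll3
    delta = bic1 - bic3
    min_beta = vals.min(axis=1)
    flagged = ok & (delta > delta_bic_threshold) & (min_beta < min_beta_cutoff)

    table = pd.DataFrame(
        {
            "loglik_1": ll1,
            "loglik_3": ll3,
            "bic_1": bic1,
            "bic_3": bic3,
            "delta_bic": delta,
            "min_beta": min_beta,
            "flagged": flagged,
            "fit_failed": constant,
        },
        index=m.site_ids,
    )
    return GmmFitResult(
        table=table,
        delta_bic_threshold=delta_bic_threshold,
        min_beta_cutoff=min_beta_cutoff,
        seed=seed,
    )


def apply_artifact_filter(m: MethylationMatrix, fits: GmmFitResult) -> MethylationMatrix:
    """Drop flagged sites, preserving site order."""
    if not fits.table.index.equals(m.site_ids):
        raise ValueError("fit result is not aligned to the matrix's sites")
    keep = ~fits.table["flagged"].to_numpy()
    if not keep.any():
        warnings.warn("all sites flagged as artifacts; returning empty matrix")
    return m.subset_sites(keep)
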