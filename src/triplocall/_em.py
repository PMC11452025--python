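"""Bivariate Gaussian-mixture EM for per-marker clustering.

Specialized to 2-D (contrast, signal-strength) points: 2x2 covariance
algebra is closed-form, so a full EM run on a few hundred points costs
microseconds per iteration.

The components share a single full covariance matrix (a homoscedastic
mixture) with free mixing proportions.  Under over-clustering this matters:
with per-component free covariances, maximum likelihood rewards a component
that inflates itself to absorb the stray members of a low-frequency
genotype, which later poisons the spread of a merged cluster; with a common
covariance such degenerate components are impossible and the likelihood
instead favours placing a component on the minor genotype itself.  Genotype
clouds on the contrast axis have similar spread, so the shared-covariance
assumption is mild.

A restart is initialized with the component means at k sampled individuals,
the covariance at the diagonal data covariance split k ways, and uniform
weights.  Convergence: relative log-likelihood change below ``tol``.

The fit is reported as failed when EM does not converge within the
iteration cap, when any component ends with fewer than two assigned points,
or when the covariance is near-singular (condition number > 1e8).  The
covariance is floored at the variance of the three-decimal rounding noise
of the input coordinates, so even a marker whose points are nearly
coincident yields a well-defined (if degenerate-looking) fit that the
failure test can judge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

_LOG2PI = np.log(2.0 * np.pi)
# coordinates are quantized to 3 decimals; the covariance floor is the
# variance of that rounding noise, step^2 / 12
_REG = 0.001 ** 2 / 12.0
_COND_MAX = 1e8


@dataclass
class EMFit:
    means: np.ndarray        # (k, 2)
    cov: np.ndarray          # (2, 2), shared across components
    weights: np.ndarray      # (k,)
    resp: np.ndarray         # (n, k) posterior membership probabilities
    log_likelihood: float
    converged: bool


def _log_gauss(pts: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Component-wise log density under the shared covariance, shape (n, k)."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    det = a * c - b * b
    dx = pts[:, None, 0] - means[None, :, 0]
    dy = pts[:, None, 1] - means[None, :, 1]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad


def cond_2x2(cov: np.ndarray) -> float:
    """Condition number of a symmetric positive 2x2 matrix via eigenvalues."""
    t = 0.5 * (cov[0, 0] + cov[1, 1])
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    disc = max(t * t - det, 0.0)
    lo, hi = t - np.sqrt(disc), t + np.sqrt(disc)
    if lo <= 0.0:
        return np.inf
    return hi / lo


def em_fit(pts: np.ndarray, init_means: np.ndarray, tol: float = 1e-6,
           max_iter: int = 500) -> EMFit | None:
    """One EM run from the given means; None on numerical breakdown."""
    n, k = len(pts), len(init_means)
    means = init_means.astype(float).copy()
    var0 = pts.var(axis=0) / max(k, 1) + _REG
    cov = np.diag(var0)
    weights = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    converged = False
    resp = np.full((n, k), 1.0 / k)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        for _ in range(max_iter):
            log_p = _log_gauss(pts, means, cov) + np.log(weights)[None, :]
            norm = logsumexp(log_p, axis=1)
            ll = float(norm.sum())
            if not np.isfinite(ll):
                return None
            resp = np.exp(log_p - norm[:, None])
            if abs(ll - ll_prev) < tol * abs(ll):
                converged = True
                break
            ll_prev = ll
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                return None
            weights = nk / n
            means = (resp.T @ pts) / nk[:, None]
            dx = pts[:, None, 0] - means[None, :, 0]
            dy = pts[:, None, 1] - means[None, :, 1]
            cov = np.array([
                [(resp * dx * dx).sum() / n + _REG, (resp * dx * dy).sum() / n],
                [(resp * dx * dy).sum() / n, (resp * dy * dy).sum() / n + _REG],
            ])
    return EMFit(means, cov, weights, resp, ll, converged)


def fit_passes(fit: EMFit) -> bool:
    """The failure test: convergence, >= 2 assigned points per component,
    a non-degenerate covariance."""
    if not fit.converged:
        return False
    labels = np.argmax(fit.resp, axis=1)
    counts = np.bincount(labels, minlength=fit.resp.shape[1])
    if (counts < 2).any():
        return False
    return cond_2x2(fit.cov) <= _COND_MAX
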