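"""Per-marker mixture clustering with over-clustering and contrast-distance merging.

The strategy: ask the EM algorithm for more clusters than the ploidy admits
genotypes (``n_clus_init``, default twice the number of possible genotypes) so
that low-frequency genotypes get their own component, then merge clusters that
are too close along the contrast axis to be distinct genotypes.  Two clusters
with mean contrasts ``c1, c2`` are merged when

    |c1 - c2| < dmin * (1 + |(c1 + c2) / 2|)

because the within-genotype spread of contrast grows with distance from zero.
The coefficient ``dmin`` (default 0.28) can be re-derived for a new platform
with :func:`calibrate_dmin`.

EM failures (a component collapsing onto fewer than two points, a degenerate
covariance, or hitting the iteration cap) trigger a retry with one fewer
cluster and two fewer restarts (floor 1); a marker on which even a single
component cannot be fitted falls back to one cluster with sample moments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from ._em import em_fit, fit_passes

__all__ = [
    "ClusteringConfig",
    "ClusterModel",
    "fit_mixture",
    "cluster_marker",
    "should_merge",
    "merge_loop",
    "calibrate_dmin",
    "boundary_from_labelled_ratios",
    "boundary_from_ratios",
    "marker_seed",
]

_EM_TOL = 1e-6
_EM_MAX_ITER = 500


@dataclass(frozen=True)
class ClusteringConfig:
    """Clustering parameters.

    ``n_clus_init`` defaults to twice the number of possible genotypes,
    ``2 * (ploidy + 1)``; ``n_init`` is the number of EM restarts from random
    starting individuals; ``dmin`` the merge coefficient.
    """

    ploidy: int = 3
    n_clus_init: int | None = None
    n_init: int = 5
    dmin: float = 0.28
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clus_init is None:
            object.__setattr__(self, "n_clus_init", 2 * (self.ploidy + 1))
        if self.n_clus_init < self.ploidy + 1:
            raise ValueError("n_clus_init must be >= ploidy + 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if not self.dmin > 0:
            raise ValueError("dmin must be > 0")


@dataclass
class ClusterModel:
    """A fitted (and possibly merged) per-marker clustering.

    Cluster statistics are always recomputed from member points: ``mean_x`` is
    the mean contrast of members (the quantity the merge rule and genotype
    assignment operate on), ``sd_x`` their sample standard deviation along
    contrast (feeds the QC cluster-spread rule).  ``P`` holds per-sample
    membership probabilities; merging sums columns, so row sums are conserved.
    """

    marker_id: str
    x: np.ndarray            # member contrasts, shape (n,)
    y: np.ndarray            # member signal strengths, shape (n,)
    mean_x: np.ndarray       # shape (K,)
    mean_y: np.ndarray
    sd_x: np.ndarray
    weight: np.ndarray
    n_members: np.ndarray    # int, shape (K,)
    P: np.ndarray            # shape (n, K)
    assignment: np.ndarray   # int, shape (n,)

    @property
    def K(self) -> int:
        return len(self.mean_x)

    @property
    def n_samples(self) -> int:
        return len(self.x)

    def assigned_probability(self) -> np.ndarray:
        """Per-sample membership probability of the assigned cluster."""
        return self.P[np.arange(self.n_samples), self.assignment]


def _cluster_stats(x: np.ndarray, y: np.ndarray, assignment: np.ndarray,
                   K: int) -> tuple[np.ndarray, ...]:
    mean_x = np.empty(K)
    mean_y = np.empty(K)
    sd_x = np.empty(K)
    n_members = np.empty(K, dtype=int)
    for k in range(K):
        mask = assignment == k
        n = int(mask.sum())
        n_members[k] = n
        mean_x[k] = x[mask].mean() if n else np.nan
        mean_y[k] = y[mask].mean() if n else np.nan
        sd_x[k] = x[mask].std(ddof=1) if n > 1 else 0.0
    weight = n_members / len(x)
    return mean_x, mean_y, sd_x, weight, n_members


def _model_from_assignment(marker_id: str, x: np.ndarray, y: np.ndarray,
                           P: np.ndarray) -> ClusterModel:
    assignment = np.argmax(P, axis=1)
    K = P.shape[1]
    mean_x, mean_y, sd_x, weight, n_members = _cluster_stats(x, y, assignment, K)
    return ClusterModel(marker_id, x, y, mean_x, mean_y, sd_x, weight,
                        n_members, P, assignment)


def fit_mixture(x: np.ndarray, y: np.ndarray, k: int, n_init: int,
                seed: int, marker_id: str = "") -> ClusterModel | None:
    """Fit a k-component bivariate Gaussian mixture by EM with random restarts.

    Components share one full covariance (see :mod:`triplocall._em` for why).
    Each restart seeds the component means from ``k`` points sampled without
    replacement, favouring points far from centres already chosen; the restart
    with the highest log-likelihood that passes the failure test wins.
    Returns ``None`` when every restart fails (caller retries with fewer
    components).

    A restart fails if EM does not converge within the iteration cap, any
    component ends with fewer than two assigned points, or the covariance is
    near-singular (condition number > 1e8).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n == 0 or k < 1 or k > n:
        return None
    pts = np.column_stack([x, y])
    rng = np.random.default_rng(seed)
    best = None
    best_ll = -np.inf
    for _ in range(n_init):
        idx = _seed_individuals(pts, k, rng)
        fit = em_fit(pts, pts[idx], tol=_EM_TOL, max_iter=_EM_MAX_ITER)
        if fit is None or not fit_passes(fit):
            continue
        if fit.log_likelihood > best_ll:
            best, best_ll = fit, fit.log_likelihood
    if best is None:
        return None
    return _model_from_assignment(marker_id, x, y, best.resp)


def _seed_individuals(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Pick k individuals as starting component means.

    The first is uniform; each further individual is drawn with probability
    proportional to its squared distance to the nearest centre already chosen
    (k-means++ style).  Distance weighting makes a restart likely to place a
    centre on the handful of individuals of a low-frequency genotype, which a
    uniform draw would almost always miss.
    """
    n = len(pts)
    idx = np.empty(k, dtype=int)
    idx[0] = rng.integers(n)
    d2 = np.sum((pts - pts[idx[0]]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a centre
            remaining = np.setdiff1d(np.arange(n), idx[:j])
            idx[j:] = rng.choice(remaining, size=k - j, replace=False)
            break
        idx[j] = rng.choice(n, p=d2 / total)
        d2 = np.minimum(d2, np.sum((pts - pts[idx[j]]) ** 2, axis=1))
    return idx


def _degenerate_model(marker_id: str, x: np.ndarray, y: np.ndarray) -> ClusterModel:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    P = np.ones((len(x), 1))
    return _model_from_assignment(marker_id, x, y, P)


def cluster_marker(x: np.ndarray, y: np.ndarray, cfg: ClusteringConfig,
                   seed: int | None = None, marker_id: str = "") -> ClusterModel:
    """Cluster one marker: over-clustered EM with retries, then the merge loop.

    Attempts ``n_clus_init`` components; on failure retries with one fewer,
    reducing the restart count by 2 (floor 1) each time.  If even one
    component cannot be fitted, returns the single all-points cluster with
    sample moments.  Total by construction — never raises.
    """
    if seed is None:
        seed = cfg.seed
    n_init = cfg.n_init
    for k in range(cfg.n_clus_init, 0, -1):
        model = fit_mixture(x, y, k, n_init, seed, marker_id)
        if model is not None:
            return merge_loop(model, cfg.ploidy, cfg.dmin)
        n_init = max(1, n_init - 2)
    return _degenerate_model(marker_id, x, y)


def should_merge(mean_x1: float, mean_x2: float, dmin: float) -> bool:
    """Contrast-distance merge criterion.

    True iff ``|c1 - c2| < dmin * (1 + |(c1 + c2)/2|)``: the allowed distance
    between clusters of the same genotype grows as their mean contrast moves
    away from zero.
    """
    d = abs(mean_x1 - mean_x2)
    m = abs((mean_x1 + mean_x2) / 2.0)
    return d < dmin * (1.0 + m)


def _merge_pair(model: ClusterModel, i: int, j: int) -> ClusterModel:
    """Merge cluster j into i: sum probability columns, pool members,
    recompute statistics from the pooled points."""
    keep = [k for k in range(model.K) if k != j]
    P = model.P.copy()
    P[:, i] += P[:, j]
    P = P[:, keep]
    relabel = {old: new for new, old in enumerate(keep)}
    relabel[j] = relabel[i]
    assignment = np.array([relabel[a] for a in model.assignment])
    mean_x, mean_y, sd_x, weight, n_members = _cluster_stats(
        model.x, model.y, assignment, len(keep))
    return ClusterModel(model.marker_id, model.x, model.y, mean_x, mean_y,
                        sd_x, weight, n_members, P, assignment)


def merge_loop(model: ClusterModel, ploidy: int, dmin: float) -> ClusterModel:
    """Merge clusters until at most ``ploidy + 1`` remain and no pair is
    closer than the merge criterion allows.

    While the cluster count exceeds the number of possible genotypes, the
    globally closest pair (smallest contrast distance D) is merged; once the
    count is within bounds, the closest pair among those satisfying the
    criterion is merged, until none does.  Ties on D are broken toward the
    pair with the smaller absolute mean contrast, then lower cluster index.
    """
    while model.K > 1:
        pairs = list(itertools.combinations(range(model.K), 2))
        d = np.array([abs(model.mean_x[i] - model.mean_x[j]) for i, j in pairs])
        m = np.array([abs((model.mean_x[i] + model.mean_x[j]) / 2.0) for i, j in pairs])
        candidates = range(len(pairs)) if model.K > ploidy + 1 else \
            [q for q in range(len(pairs)) if d[q] < dmin * (1.0 + m[q])]
        if not candidates:
            break
        q = min(candidates, key=lambda q: (d[q], m[q], pairs[q]))
        model = _merge_pair(model, *pairs[q])
    return model


def boundary_from_labelled_ratios(same: np.ndarray, different: np.ndarray) -> float:
    """Midpoint between the largest same-genotype ratio and the smallest
    different-genotype ratio of D/(1+M)."""
    same = np.asarray(same, float)
    different = np.asarray(different, float)
    if len(same) < 2 or len(different) < 2:
        raise ValueError("need at least 2 cluster pairs in each class to calibrate")
    return float((same.max() + different.min()) / 2.0)


def boundary_from_ratios(ratios: np.ndarray) -> float:
    """Two-class split of the D/(1+M) ratios without labels.

    The optimal two-class partition (exhaustive 1-D 2-means over sorted split
    points) is computed on the log scale — ratios of same-genotype pairs and
    of increasingly distant genotype pairs differ multiplicatively — and the
    boundary is the midpoint between the largest ratio of the lower class and
    the smallest of the upper class, mirroring the labelled definition.
    """
    r = np.sort(np.asarray(ratios, float))
    r = r[r > 0]
    if len(r) < 4:
        raise ValueError("need at least 4 cluster-pair ratios to calibrate")
    lr = np.log(r)
    csum = np.cumsum(lr)
    total = csum[-1]
    best_cost, best_split = np.inf, None
    for s in range(2, len(r) - 1):  # >=2 pairs per class
        lo, hi = csum[s - 1] / s, (total - csum[s - 1]) / (len(r) - s)
        cost = np.sum((lr[:s] - lo) ** 2) + np.sum((lr[s:] - hi) ** 2)
        if cost < best_cost:
            best_cost, best_split = cost, s
    s = best_split
    return float((r[s - 1] + r[s]) / 2.0)


def _pair_ratios(model: ClusterModel) -> tuple[np.ndarray, np.ndarray]:
    """D/(1+M) for every cluster pair, with the pair index list."""
    pairs = list(itertools.combinations(range(model.K), 2))
    out = np.empty(len(pairs))
    for q, (i, j) in enumerate(pairs):
        d = abs(model.mean_x[i] - model.mean_x[j])
        m = abs((model.mean_x[i] + model.mean_x[j]) / 2.0)
        out[q] = d / (1.0 + m)
    return out, pairs


def calibrate_dmin(transformed, truth_dosage: np.ndarray | None = None,
                   n_markers_sample: int | None = None, forced_k: int = 8,
                   n_init: int = 5, seed: int = 0) -> float:
    """Re-derive the merge coefficient for a dataset.

    Each sampled marker is over-clustered into ``forced_k`` components (no
    merging) and every cluster pair contributes its ratio D/(1+M).  With
    ``truth_dosage`` (markers x samples, from the simulator) pairs are
    labelled same- or different-genotype by the majority true dosage of each
    cluster and the boundary is the midpoint between the two classes;
    without labels, a reproducible two-class split of the ratios is used.

    Parameters
    ----------
    transformed : TransformedSignals
    truth_dosage : optional int matrix aligned with ``transformed``
    n_markers_sample : number of markers to draw (default: all)
    """
    rng = np.random.default_rng(seed)
    n_m = transformed.n_markers
    idx = np.arange(n_m)
    if n_markers_sample is not None and n_markers_sample < n_m:
        idx = np.sort(rng.choice(n_m, size=n_markers_sample, replace=False))
    same, diff, unlabelled = [], [], []
    for i in idx:
        x, y = transformed.marker_points(i)
        model = None
        n_try = n_init
        for k in range(forced_k, 1, -1):
            model = fit_mixture(x, y, k, n_try, int(rng.integers(2**31 - 1)))
            if model is not None:
                break
            n_try = max(1, n_try - 2)
        if model is None or model.K < 2:
            continue
        ratios, pairs = _pair_ratios(model)
        if truth_dosage is None:
            unlabelled.extend(ratios)
        else:
            genos = [_majority(truth_dosage[i][model.assignment == k])
                     for k in range(model.K)]
            for q, (a, b) in enumerate(pairs):
                (same if genos[a] == genos[b] else diff).append(ratios[q])
    if truth_dosage is not None:
        return boundary_from_labelled_ratios(np.array(same), np.array(diff))
    return boundary_from_ratios(np.array(unlabelled))


def _majority(values: np.ndarray) -> int:
    vals, counts = np.unique(values, return_counts=True)
    return int(vals[np.argmax(counts)])


def marker_seed(global_seed: int, marker_index: int) -> int:
    """Per-marker seed derived from the run seed and the marker's index, so
    results do not depend on how markers are distributed over workers."""
    ss = np.random.SeedSequence([int(global_seed), int(marker_index)])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))
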