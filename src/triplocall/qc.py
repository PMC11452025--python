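"""Quality control of genotype calls and marker categorization.

Three no-call rules blank individual samples or whole clusters:

1. membership probability of the assigned cluster below ``prob_min``;
2. contrast distance to the cluster centre beyond ``dist_sd_mult`` cluster
   standard deviations (2.8 by default — under normality ~99.5% of members
   fall within that band, so roughly 0.5% of a clean cluster is blanked);
3. a cluster whose contrast spread exceeds ``sd_cap_base * (1 +
   sd_cap_slope * |mean contrast|)`` is blanked wholesale, guarding against a
   single cluster that actually covers several genotypes.

Cluster-level rule 3 runs first, then 1, then 2.

Four marker-level filters follow: call rate, Fisher's linear discriminant
between the two nearest genotypes (FLD), the heterozygote signal-strength
offset (HetSO — a heterozygote sitting below the homozygotes marks an
off-target variant), and the homozygote contrast position (HomRO).  Markers
passing all filters are accepted and categorized by the number of genotypes
observed; failing markers are labelled by the filter they failed.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .calling import NA_DOSAGE, MarkerCalls
from .clustering import ClusterModel

__all__ = [
    "QCThresholds",
    "QCMetrics",
    "MarkerCategory",
    "apply_nocall_rules",
    "compute_fld",
    "compute_hetso",
    "compute_homro",
    "compute_metrics",
    "categorize",
]


class MarkerCategory(str, enum.Enum):
    """Exactly one per marker; the first three are accepted, the rest rejected."""

    POLY_HIGH_RESOLUTION = "PolyHighResolution"
    NO_MINOR_HOMOZYGOTE = "NoMinorHomozygote"
    MONO_HIGH_RESOLUTION = "MonoHighResolution"
    CALL_RATE_BELOW_THRESHOLD = "CallRateBelowThreshold"
    OFF_TARGET_VARIANT = "OffTargetVariant"
    OTHERS = "Others"

    @property
    def accepted(self) -> bool:
        return self in (MarkerCategory.POLY_HIGH_RESOLUTION,
                        MarkerCategory.NO_MINOR_HOMOZYGOTE,
                        MarkerCategory.MONO_HIGH_RESOLUTION)


@dataclass(frozen=True)
class QCThresholds:
    prob_min: float = 0.85
    dist_sd_mult: float = 2.8
    sd_cap_base: float = 0.28
    sd_cap_slope: float = 0.5
    cr_min: float = 0.97
    fld_min: float = 3.4
    hetso_min: float = -0.3
    # keyed by post-QC genotype count; 1..ploidy+1 for triploids
    homro_min_by_k: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.3, 4: -0.9})

    def homro_min(self, n_genotypes: int, ploidy: int) -> float:
        """Threshold lookup; beyond the tabulated counts the maximal-count
        entry is reused for ploidy+1 genotypes and 0.3 for intermediates
        (an extrapolation beyond the triploid table)."""
        if n_genotypes in self.homro_min_by_k:
            return self.homro_min_by_k[n_genotypes]
        k_max = max(self.homro_min_by_k)
        if n_genotypes >= ploidy + 1:
            return self.homro_min_by_k[k_max]
        return 0.3


@dataclass(frozen=True)
class QCMetrics:
    """Marker-level QC metrics; a metric is None when inapplicable (e.g. FLD
    with fewer than two genotypes)."""

    call_rate: float
    fld: float | None
    hetso: float | None
    homro: float | None
    n_genotypes: int


def apply_nocall_rules(model: ClusterModel, calls: MarkerCalls,
                       thr: QCThresholds) -> MarkerCalls:
    """Blank low-confidence calls (rules 3, then 1, then 2)."""
    dosage = calls.dosage.copy()
    # rule 3: over-dispersed clusters are blanked wholesale
    cap = thr.sd_cap_base * (1.0 + thr.sd_cap_slope * np.abs(model.mean_x))
    bad_cluster = model.sd_x > cap
    if bad_cluster.any():
        dosage[bad_cluster[model.assignment]] = NA_DOSAGE
    # rule 1: weak cluster membership
    dosage[model.assigned_probability() < thr.prob_min] = NA_DOSAGE
    # rule 2: far from the cluster centre along contrast
    dist = np.abs(model.x - model.mean_x[model.assignment])
    dosage[dist > thr.dist_sd_mult * model.sd_x[model.assignment]] = NA_DOSAGE
    return replace(calls, dosage=dosage)


def _genotype_groups(model: ClusterModel, calls: MarkerCalls,
                     min_members: int = 1) -> dict[int, np.ndarray]:
    """Masks of called samples per genotype, keeping genotypes with at least
    ``min_members`` non-NA calls."""
    groups: dict[int, np.ndarray] = {}
    for d in calls.genotypes_present():
        mask = calls.dosage == d
        if int(mask.sum()) >= min_members:
            groups[d] = mask
    return groups


def compute_fld(model: ClusterModel, calls: MarkerCalls) -> float | None:
    """Fisher's linear discriminant of the two nearest genotypes.

    FLD = |C1 - C2| / SD_pooled over the pair of genotypes with closest mean
    contrasts, with the two-sample pooled standard deviation of member
    contrasts.  None with fewer than two genotypes having >= 2 called members.
    """
    groups = _genotype_groups(model, calls, min_members=2)
    if len(groups) < 2:
        return None
    stats = {d: (model.x[m].mean(), model.x[m].var(ddof=1), int(m.sum()))
             for d, m in groups.items()}
    best = None
    for d1, d2 in itertools.combinations(sorted(stats), 2):
        c1, v1, n1 = stats[d1]
        c2, v2, n2 = stats[d2]
        dist = abs(c1 - c2)
        if best is None or dist < best[0]:
            sd_pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
            best = (dist, sd_pooled)
    dist, sd_pooled = best
    if sd_pooled == 0.0:
        return np.inf
    return float(dist / sd_pooled)


def compute_hetso(model: ClusterModel, calls: MarkerCalls) -> float | None:
    """Heterozygote signal-strength offset.

    For each heterozygous genotype, the offset of its mean signal strength
    below/above the line joining the two homozygote (contrast, sigstren)
    centroids, evaluated at the heterozygote's mean contrast (with one
    homozygote, its mean signal strength serves as baseline).  HetSO is the
    minimum over heterozygotes; None when no heterozygote or no homozygote
    is present.
    """
    groups = _genotype_groups(model, calls)
    ploidy = calls.ploidy
    homs = {d: m for d, m in groups.items() if d in (0, ploidy)}
    hets = {d: m for d, m in groups.items() if 0 < d < ploidy}
    if not homs or not hets:
        return None
    hom_pts = sorted((model.x[m].mean(), model.y[m].mean()) for m in homs.values())
    offsets = []
    for m in hets.values():
        hx, hy = model.x[m].mean(), model.y[m].mean()
        if len(hom_pts) == 2:
            (x0, y0), (x1, y1) = hom_pts
            yhat = y0 + (y1 - y0) * (hx - x0) / (x1 - x0)
        else:
            yhat = hom_pts[0][1]
        offsets.append(hy - yhat)
    return float(min(offsets))


def compute_homro(model: ClusterModel, calls: MarkerCalls) -> float | None:
    """Homozygote contrast position: min over homozygous genotypes of the
    mean contrast signed toward its expected side (+ for all-A, − for all-B).
    None when no homozygote is called."""
    groups = _genotype_groups(model, calls)
    ploidy = calls.ploidy
    vals = []
    for d, m in groups.items():
        if d == ploidy:
            vals.append(model.x[m].mean())
        elif d == 0:
            vals.append(-model.x[m].mean())
    return float(min(vals)) if vals else None


def compute_metrics(model: ClusterModel, calls: MarkerCalls) -> QCMetrics:
    """All marker-level metrics, computed after the no-call rules."""
    call_rate = float(np.mean(calls.dosage != NA_DOSAGE))
    return QCMetrics(
        call_rate=call_rate,
        fld=compute_fld(model, calls),
        hetso=compute_hetso(model, calls),
        homro=compute_homro(model, calls),
        n_genotypes=len(calls.genotypes_present()),
    )


def categorize(calls: MarkerCalls, metrics: QCMetrics, thr: QCThresholds,
               ploidy: int) -> MarkerCategory:
    """Place the marker into exactly one category.

    Filters are checked in a fixed order so labels are deterministic: call
    rate, then HetSO (off-target variant), then the remaining filters (FLD,
    HomRO, multi-population collision) which all map to "Others".  Markers
    passing every filter are accepted and categorized by genotype count:
    1 -> mono high resolution, ploidy+1 -> poly high resolution, in between
    -> no minor homozygote.
    """
    if metrics.call_rate < thr.cr_min:
        return MarkerCategory.CALL_RATE_BELOW_THRESHOLD
    if metrics.hetso is not None and metrics.hetso < thr.hetso_min:
        return MarkerCategory.OFF_TARGET_VARIANT
    fld_fail = metrics.fld is not None and metrics.fld <= thr.fld_min
    homro_fail = (metrics.homro is not None and metrics.n_genotypes >= 1
                  and metrics.homro < thr.homro_min(metrics.n_genotypes, ploidy))
    if fld_fail or homro_fail or calls.collision:
        return MarkerCategory.OTHERS
    if metrics.n_genotypes >= ploidy + 1:
        return MarkerCategory.POLY_HIGH_RESOLUTION
    if metrics.n_genotypes == 1:
        return MarkerCategory.MONO_HIGH_RESOLUTION
    if metrics.n_genotypes == 0:
        return MarkerCategory.OTHERS
    return MarkerCategory.NO_MINOR_HOMOZYGOTE
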