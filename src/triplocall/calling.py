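"""Assigning allele dosages to merged clusters.

A genotype at ploidy p is the A-allele dosage 0..p, rendered as a string of
that many ``A``s followed by ``B``s (dosage 2 at ploidy 3 -> "AAB").  Clusters
separate along the contrast axis with dosage increasing monotonically, so
calling reduces to anchoring one cluster as a homozygote and walking adjacent
dosages outward.

Two sampling situations are supported.  When all samples come from one
population, two clusters can never be the two homozygotes (under
Hardy-Weinberg both homozygotes cannot segregate without a heterozygote), so
the most extreme cluster anchors a homozygote and the rest take consecutive
adjacent dosages.  When populations may differ, per-genotype reference
contrasts are first averaged over markers that show all p+1 genotypes and
each cluster takes the genotype of its nearest reference.

Markers whose signal is shifted wholesale toward one side risk a heterozygote
posing as a homozygote; for three clusters at ploidy 3 a count-based
correction relabels the marker when the extreme cluster holds fewer than half
the members of the opposing extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clustering import ClusterModel

__all__ = [
    "NA_DOSAGE",
    "dosage_to_label",
    "label_to_dosage",
    "MarkerCalls",
    "ReferenceContrasts",
    "assign_single_pop",
    "correct_shifted_three_cluster",
    "build_reference_contrasts",
    "assign_multi_pop",
]

NA_DOSAGE = -1  # sentinel for no-call


def dosage_to_label(dosage: int, ploidy: int) -> str:
    """Render an A-allele dosage as a genotype string ('NA' for the no-call
    sentinel)."""
    if dosage == NA_DOSAGE:
        return "NA"
    if not 0 <= dosage <= ploidy:
        raise ValueError(f"dosage {dosage} outside [0, {ploidy}]")
    return "A" * dosage + "B" * (ploidy - dosage)


def label_to_dosage(label: str, ploidy: int) -> int:
    if label == "NA":
        return NA_DOSAGE
    if len(label) != ploidy or set(label) - {"A", "B"}:
        raise ValueError(f"invalid genotype label {label!r} for ploidy {ploidy}")
    return label.count("A")


@dataclass
class MarkerCalls:
    """Per-sample dosage calls for one marker.

    ``dosage`` holds the A-allele dosage per sample (NA_DOSAGE for no-call);
    ``cluster_dosage`` maps each cluster index of the originating model to its
    genotype.  ``collision`` flags an unresolvable reference-contrast
    collision in multi-population mode (the marker is rejected downstream).
    """

    marker_id: str
    ploidy: int
    dosage: np.ndarray               # int, shape (n_samples,)
    cluster_dosage: np.ndarray       # int, shape (K,)
    genotype_mean_x: dict[int, float]
    collision: bool = False

    def labels(self) -> list[str]:
        return [dosage_to_label(int(d), self.ploidy) for d in self.dosage]

    def genotypes_present(self) -> list[int]:
        """Dosages retaining at least one non-NA call, sorted."""
        return sorted(int(d) for d in np.unique(self.dosage) if d != NA_DOSAGE)


@dataclass(frozen=True)
class ReferenceContrasts:
    """Per-genotype reference mean contrasts, index = A-dosage 0..ploidy.

    Contrast must be strictly increasing with A-dosage (equivalently strictly
    decreasing with B-dosage).
    """

    values: np.ndarray
    n_markers: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.any(np.diff(v) <= 0):
            raise ValueError("reference contrasts must increase strictly with A-dosage")
        object.__setattr__(self, "values", v)

    @property
    def ploidy(self) -> int:
        return len(self.values) - 1


def _calls_from_cluster_dosage(model: ClusterModel, ploidy: int,
                               cluster_dosage: np.ndarray,
                               collision: bool = False) -> MarkerCalls:
    dosage = cluster_dosage[model.assignment]
    genotype_mean_x = {int(cluster_dosage[k]): float(model.mean_x[k])
                       for k in range(model.K) if cluster_dosage[k] != NA_DOSAGE}
    return MarkerCalls(model.marker_id, ploidy, dosage.astype(int),
                       cluster_dosage.astype(int), genotype_mean_x, collision)


def _extreme_is_positive(mean_x: np.ndarray) -> bool:
    """True when the cluster of maximal |mean contrast| lies on the positive
    side; an exactly symmetric tie between two clusters goes to the positive
    side."""
    lo, hi = mean_x.min(), mean_x.max()
    if abs(hi) != abs(lo):
        return abs(hi) > abs(lo)
    return hi > 0


def assign_single_pop(model: ClusterModel, ploidy: int) -> MarkerCalls:
    """Single-population dosage assignment.

    The cluster with the largest absolute mean contrast is the homozygote of
    the matching sign (all-A if positive, all-B if negative); the remaining
    clusters, ordered by proximity to it, take consecutively adjacent dosages
    toward the other homozygote.  A lone cluster is therefore always called
    homozygous, and two clusters are a homozygote plus its nearest
    heterozygote — never two homozygotes.  For exactly three clusters at
    ploidy 3 the shifted-signal correction is applied.
    """
    if model.K > ploidy + 1:
        raise ValueError(f"model has {model.K} clusters, more than ploidy+1={ploidy + 1}")
    order = np.argsort(model.mean_x)  # ascending contrast
    cluster_dosage = np.empty(model.K, dtype=int)
    if _extreme_is_positive(model.mean_x):
        # anchor the all-A homozygote at the top, walk down
        for rank, k in enumerate(order[::-1]):
            cluster_dosage[k] = ploidy - rank
    else:
        for rank, k in enumerate(order):
            cluster_dosage[k] = rank
    calls = _calls_from_cluster_dosage(model, ploidy, cluster_dosage)
    if model.K == 3 and ploidy == 3:
        calls = correct_shifted_three_cluster(model, calls)
    return calls


def correct_shifted_three_cluster(model: ClusterModel,
                                  calls: MarkerCalls) -> MarkerCalls:
    """Shifted-signal correction for three clusters at ploidy 3.

    When the whole marker is shifted toward one side, the extreme cluster is
    really a heterozygote mislabelled as a homozygote.  If the extreme cluster
    (currently called homozygous) has fewer than half the members of the
    opposing extreme cluster, every cluster's dosage is stepped one genotype
    toward the opposing side, making the opposing extreme the homozygote.
    Idempotent: once the extreme cluster is heterozygous nothing fires.
    """
    if model.K != 3 or calls.ploidy != 3:
        return calls
    order = np.argsort(model.mean_x)
    lo, hi = order[0], order[-1]
    if _extreme_is_positive(model.mean_x):
        extreme, opposing, step = hi, lo, -1
    else:
        extreme, opposing, step = lo, hi, +1
    if calls.cluster_dosage[extreme] not in (0, calls.ploidy):
        return calls  # already corrected
    if model.n_members[extreme] < 0.5 * model.n_members[opposing]:
        new = calls.cluster_dosage + step
        return _calls_from_cluster_dosage(model, calls.ploidy, new)
    return calls


def build_reference_contrasts(results: list[MarkerCalls],
                              ploidy: int) -> ReferenceContrasts:
    """Average per-genotype mean contrasts over markers showing all ploidy+1
    genotypes."""
    full = [c for c in results
            if len(c.genotype_mean_x) == ploidy + 1 and not c.collision]
    if not full:
        raise ValueError(
            "no marker attained the maximum cluster count; reference contrasts "
            "cannot be built — run in single-population mode instead")
    values = np.array([[c.genotype_mean_x[d] for d in range(ploidy + 1)]
                       for c in full])
    return ReferenceContrasts(values.mean(axis=0), len(full))


def _resolve_collisions(dosages: list[int], mean_x_sorted: np.ndarray,
                        refs: ReferenceContrasts) -> list[int] | None:
    """Enforce strictly increasing dosages over contrast-sorted clusters.

    Duplicated targets are resolved outward: on the B side the most negative
    cluster keeps the genotype and the others step toward the centre; the A
    side mirrors.  Returns None when no valid assignment exists — a cluster
    would have to move beyond the genotype adjacent to its nearest reference,
    i.e. there are more clusters than genotypes on one side.
    """
    p = refs.ploidy
    d = list(dosages)
    mid = p / 2.0
    for _ in range(len(d) * (p + 2)):
        dup = None
        for i in range(len(d) - 1):
            if d[i] >= d[i + 1]:
                dup = i
                break
        if dup is None:
            break
        v = d[dup]
        if v <= mid:
            d[dup + 1] = d[dup] + 1  # most negative keeps; bump the other up
        else:
            d[dup] = d[dup + 1] - 1  # most positive keeps; bump the other down
    if any(d[i] >= d[i + 1] for i in range(len(d) - 1)):
        return None
    if d[0] < 0 or d[-1] > p:
        return None
    if any(abs(df - dn) > 1 for df, dn in zip(d, dosages)):
        return None
    return d


def assign_multi_pop(model: ClusterModel, refs: ReferenceContrasts) -> MarkerCalls:
    """Multi-population dosage assignment via nearest reference contrast.

    Each cluster takes the genotype of the closest reference value; if two
    clusters point to the same reference, the more extreme cluster keeps the
    genotype and the other takes the adjacent one toward the centre, applied
    iteratively outward.  Two clusters near the two homozygote references are
    thus called as the two homozygotes — a configuration single-population
    mode forbids.  An unresolvable collision flags the marker for rejection
    and produces all-NA calls.
    """
    ploidy = refs.ploidy
    if model.K > ploidy + 1:
        raise ValueError(f"model has {model.K} clusters, more than ploidy+1={ploidy + 1}")
    order = np.argsort(model.mean_x)
    mean_sorted = model.mean_x[order]
    nearest = [int(np.argmin(np.abs(refs.values - c))) for c in mean_sorted]
    resolved = _resolve_collisions(nearest, mean_sorted, refs)
    cluster_dosage = np.full(model.K, NA_DOSAGE, dtype=int)
    if resolved is None:
        return _calls_from_cluster_dosage(model, ploidy, cluster_dosage,
                                          collision=True)
    for pos, k in enumerate(order):
        cluster_dosage[k] = resolved[pos]
    return _calls_from_cluster_dosage(model, ploidy, cluster_dosage)
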