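"""Two-phase pipeline: per-marker clustering, then genotyping + QC.

The phases are strictly separated by a serialized clustering output
(JSON-lines, one marker per line), so QC thresholds can be re-tuned without
re-running EM.  Markers are embarrassingly parallel; determinism is
guaranteed by per-marker seeds derived from the run seed and the marker
index, never by execution order.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import calling, qc
from .calling import MarkerCalls, NA_DOSAGE, build_reference_contrasts
from .clustering import ClusteringConfig, ClusterModel, cluster_marker, marker_seed
from .qc import MarkerCategory, QCThresholds
from .signal_io import TransformedSignals

__all__ = ["RunConfig", "MarkerResult", "run_clustering", "run_genotyping",
           "serialize_models", "load_models", "default_workers"]


def default_workers() -> int:
    return max(1, (os.cpu_count() or 1) - 2)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters with their default values."""

    ploidy: int = 3
    n_clus_init: int | None = None     # default 2*(ploidy+1)
    n_init: int = 5
    dmin: float = 0.28
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    same_population: bool = True
    n_workers: int = field(default_factory=default_workers)
    seed: int = 0

    def clustering(self) -> ClusteringConfig:
        return ClusteringConfig(ploidy=self.ploidy, n_clus_init=self.n_clus_init,
                                n_init=self.n_init, dmin=self.dmin, seed=self.seed)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["n_clus_init"] = self.clustering().n_clus_init
        return json.dumps(d, indent=2, default=str)


@dataclass
class MarkerResult:
    """Final per-marker outcome: calls after no-call rules, QC metrics and
    the category."""

    calls: MarkerCalls
    metrics: qc.QCMetrics
    category: MarkerCategory


def run_clustering(transformed: TransformedSignals,
                   config: RunConfig) -> list[ClusterModel]:
    """Cluster every marker (parallel over markers, deterministic per seed)."""
    if transformed.n_markers == 0:
        raise ValueError("no markers to cluster after subsetting")
    cfg = config.clustering()

    def one(i: int) -> ClusterModel:
        x, y = transformed.marker_points(i)
        return cluster_marker(x, y, cfg, seed=marker_seed(config.seed, i),
                              marker_id=transformed.marker_ids[i])

    if config.n_workers > 1 and transformed.n_markers > 1:
        return Parallel(n_jobs=config.n_workers)(
            delayed(one)(i) for i in range(transformed.n_markers))
    return [one(i) for i in range(transformed.n_markers)]


def _model_to_dict(m: ClusterModel) -> dict:
    return {
        "marker_id": m.marker_id,
        "K": int(m.K),
        "mean_x": [round(float(v), 6) for v in m.mean_x],
        "mean_y": [round(float(v), 6) for v in m.mean_y],
        "sd_x": [round(float(v), 6) for v in m.sd_x],
        "weight": [round(float(v), 6) for v in m.weight],
        "n_members": [int(v) for v in m.n_members],
        "x": [float(v) for v in m.x],
        "y": [float(v) for v in m.y],
        "assignment": [int(a) for a in m.assignment],
        "P": [[round(float(p), 6) for p in row] for row in m.P],
    }


def _model_from_dict(d: dict) -> ClusterModel:
    return ClusterModel(
        marker_id=d["marker_id"],
        x=np.array(d["x"], float), y=np.array(d["y"], float),
        mean_x=np.array(d["mean_x"], float), mean_y=np.array(d["mean_y"], float),
        sd_x=np.array(d["sd_x"], float), weight=np.array(d["weight"], float),
        n_members=np.array(d["n_members"], int),
        P=np.array(d["P"], float),
        assignment=np.array(d["assignment"], int),
    )


def serialize_models(models: list[ClusterModel], path: str | Path,
                     sample_ids: list[str] | None = None) -> None:
    """JSON-lines clustering output — the contract between the two phases.

    The first line is a header with the sample ids; each following line is
    one marker's fitted model (cluster statistics plus per-sample coordinates,
    assignments and membership probabilities)."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"sample_ids": sample_ids or []}) + "\n")
        for m in models:
            fh.write(json.dumps(_model_to_dict(m)) + "\n")


def load_models(path: str | Path) -> tuple[list[ClusterModel], list[str]]:
    with open(path) as fh:
        header = json.loads(fh.readline())
        models = [_model_from_dict(json.loads(line)) for line in fh if line.strip()]
    return models, header.get("sample_ids", [])


def genotype_marker(model: ClusterModel, config: RunConfig,
                    refs: calling.ReferenceContrasts | None = None) -> MarkerResult:
    """Call, blank and categorize a single clustered marker."""
    if refs is not None:
        calls = calling.assign_multi_pop(model, refs)
    else:
        calls = calling.assign_single_pop(model, config.ploidy)
    calls = qc.apply_nocall_rules(model, calls, config.thresholds)
    metrics = qc.compute_metrics(model, calls)
    category = qc.categorize(calls, metrics, config.thresholds, config.ploidy)
    return MarkerResult(calls, metrics, category)


def run_genotyping(models: list[ClusterModel],
                   config: RunConfig) -> list[MarkerResult]:
    """Genotype all clustered markers.

    In multi-population mode, markers showing all ploidy+1 clusters are
    called first by position; their per-genotype mean contrasts are averaged
    into reference values used to call the remaining markers by nearest
    reference.
    """
    refs = None
    if not config.same_population:
        full = [calling.assign_single_pop(m, config.ploidy)
                for m in models if m.K == config.ploidy + 1]
        refs = build_reference_contrasts(full, config.ploidy)
    results = []
    for m in models:
        use_refs = refs if (refs is not None and m.K < config.ploidy + 1) else None
        results.append(genotype_marker(m, config, use_refs))
    return results


def calls_table(results: list[MarkerResult], sample_ids: list[str]) -> pd.DataFrame:
    """Genotype-string matrix, markers x samples."""
    return pd.DataFrame(
        [r.calls.labels() for r in results],
        index=pd.Index([r.calls.marker_id for r in results], name="marker_id"),
        columns=sample_ids)


def dosage_table(results: list[MarkerResult], sample_ids: list[str]) -> pd.DataFrame:
    """Integer A-dosage matrix (-1 = NA), markers x samples."""
    return pd.DataFrame(
        [r.calls.dosage for r in results],
        index=pd.Index([r.calls.marker_id for r in results], name="marker_id"),
        columns=sample_ids)


def qc_table(results: list[MarkerResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        m = r.metrics
        rows.append({
            "marker_id": r.calls.marker_id,
            "call_rate": round(m.call_rate, 4),
            "fld": None if m.fld is None else round(m.fld, 4),
            "hetso": None if m.hetso is None else round(m.hetso, 4),
            "homro": None if m.homro is None else round(m.homro, 4),
            "n_genotypes": m.n_genotypes,
            "category": r.category.value,
        })
    return pd.DataFrame(rows)


def render_nucleotides(calls: pd.DataFrame,
                       correspondence: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Re-render A/B genotype strings with each marker's actual nucleotides
    (markers without a correspondence entry keep A/B coding)."""
    out = calls.copy()
    for marker in out.index:
        if marker in correspondence:
            a, b = correspondence[marker]
            out.loc[marker] = [g.replace("A", a).replace("B", b) if g != "NA" else g
                               for g in out.loc[marker]]
    return out


def apply_edits(calls: pd.DataFrame, edits: pd.DataFrame,
                ploidy: int) -> pd.DataFrame:
    """Apply a manual-edit table (marker_id, sample_id, new_genotype) to a
    genotype-string matrix; replaces the interactive editing step."""
    from .calling import label_to_dosage

    out = calls.copy()
    required = {"marker_id", "sample_id", "new_genotype"}
    if not required.issubset(edits.columns):
        raise ValueError(f"edit file must have columns {sorted(required)}")
    for _, row in edits.iterrows():
        g = str(row["new_genotype"])
        label_to_dosage(g, ploidy)  # validates
        if row["marker_id"] not in out.index or row["sample_id"] not in out.columns:
            raise ValueError(f"edit refers to unknown marker/sample: "
                             f"{row['marker_id']}/{row['sample_id']}")
        out.loc[row["marker_id"], row["sample_id"]] = g
    return out


def summarize(results: list[MarkerResult]) -> dict:
    counts = {c.value: 0 for c in MarkerCategory}
    for r in results:
        counts[r.category.value] += 1
    n = len(results)
    accepted = sum(counts[c.value] for c in MarkerCategory if c.accepted)
    return {
        "n_markers": n,
        "categories": counts,
        "accepted": accepted,
        "accepted_fraction": round(accepted / n, 4) if n else None,
    }
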