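"""Reading, writing and transforming two-channel SNP-array luminescence signals.

A genotyping platform reports, for every marker and every sample, two raw
luminescence intensities: one for the probe targeting allele A and one for the
probe targeting allele B.  The exported "summary" table is tab-separated with
one row per probeset: the row for marker ``M`` and probe A is named ``M-A``,
the B-probe row ``M-B``, and the remaining columns are samples.

Genotype clusters separate along two derived axes::

    contrast   x = log2(SA / SB)
    sigstren   y = (log2(SA) + log2(SB)) / 2

Both are rounded to three decimal places once, at transform time; every
downstream statistic operates on the rounded values, which makes runs
bit-reproducible across platforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalMatrix",
    "TransformedSignals",
    "load_luminescence",
    "load_allele_correspondence",
    "transform",
    "write_transformed",
    "read_transformed",
    "write_axas_summary",
]

_VALID_BASES = frozenset("ACGTID")


@dataclass
class SignalMatrix:
    """Raw A/B probe intensities, one row per marker, one column per sample.

    Intensities are arbitrary positive luminescence units; positivity is
    required so the log2 transform is defined.
    """

    marker_ids: list[str]
    sample_ids: list[str]
    SA: np.ndarray
    SB: np.ndarray

    def __post_init__(self) -> None:
        self.SA = np.asarray(self.SA, dtype=float)
        self.SB = np.asarray(self.SB, dtype=float)
        if self.SA.shape != self.SB.shape:
            raise ValueError("SA and SB must have identical shapes")
        if self.SA.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError("intensity matrices must be n_markers x n_samples")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class TransformedSignals:
    """Per-marker, per-sample (contrast, signal-strength) coordinates.

    ``x`` is the log2 A/B ratio (the axis along which genotype clusters
    separate), ``y`` the mean log2 intensity.  Values are stored rounded to
    three decimals.
    """

    marker_ids: list[str]
    sample_ids: list[str]
    x: np.ndarray
    y: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def marker_points(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) vectors for the marker at row ``i``."""
        return self.x[i], self.y[i]


def _subset(df: pd.DataFrame, marker_ids: list[str], samples: Sequence[str] | None,
            markers: Sequence[str] | None) -> tuple[list[str], pd.DataFrame]:
    if samples is not None:
        missing = [s for s in samples if s not in df.columns]
        if missing:
            raise ValueError(f"requested samples absent from file: {missing}")
        df = df[list(samples)]
    if markers is not None:
        missing = [m for m in markers if m not in marker_ids]
        if missing:
            raise ValueError(f"requested markers absent from file: {missing}")
        marker_ids = list(markers)
    return marker_ids, df


def _check_positive(values: np.ndarray, marker_ids: list[str], sample_ids: list[str],
                    channel: str) -> None:
    bad = ~(np.isfinite(values) & (values > 0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive or non-numeric intensity for marker {marker_ids[i]}, "
            f"sample {sample_ids[j]}, channel {channel}"
        )


def load_luminescence(path: str | Path, format: str = "axas_summary",
                      markers: Sequence[str] | None = None,
                      samples: Sequence[str] | None = None) -> SignalMatrix:
    """Read a luminescence export into a :class:`SignalMatrix`.

    Parameters
    ----------
    path
        Input file.
    format
        ``"axas_summary"`` — tab-separated, first column ``probeset_id``,
        channel rows named ``<marker>-A`` / ``<marker>-B``, ``#`` comment lines
        skipped; or ``"long_table"`` — CSV with columns
        ``marker_id, sample_id, SA, SB``.
    markers, samples
        Optional inclusion lists; output rows/columns follow the request order,
        else file order.

    Raises
    ------
    ValueError
        On a marker missing one of its two channel rows, a non-positive or
        non-numeric intensity (named by marker/sample/channel), or a requested
        id absent from the file.
    """
    path = Path(path)
    if format == "axas_summary":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        a_rows = {m[:-2]: m for m in df.index if m.endswith("-A")}
        b_rows = {m[:-2]: m for m in df.index if m.endswith("-B")}
        marker_ids = [m for m in (r[:-2] for r in df.index) if m in a_rows]
        # preserve first-appearance order, dedup
        marker_ids = list(dict.fromkeys(marker_ids))
        for m in sorted(set(a_rows) ^ set(b_rows)):
            raise ValueError(f"marker {m} is missing one of its -A/-B channel rows")
        marker_ids, df = _subset(df, marker_ids, samples, markers)
        sample_ids = list(df.columns)
        sa = df.loc[[a_rows[m] for m in marker_ids]].apply(pd.to_numeric, errors="coerce")
        sb = df.loc[[b_rows[m] for m in marker_ids]].apply(pd.to_numeric, errors="coerce")
        SA, SB = sa.to_numpy(float), sb.to_numpy(float)
    elif format == "long_table":
        long = pd.read_csv(path)
        required = {"marker_id", "sample_id", "SA", "SB"}
        if not required.issubset(long.columns):
            raise ValueError(f"long table must have columns {sorted(required)}")
        marker_ids = list(dict.fromkeys(long["marker_id"]))
        sample_ids_all = list(dict.fromkeys(long["sample_id"]))
        wide_a = long.pivot(index="marker_id", columns="sample_id", values="SA")
        wide_b = long.pivot(index="marker_id", columns="sample_id", values="SB")
        if wide_a.isna().any().any() or wide_b.isna().any().any():
            na = wide_a.isna() | wide_b.isna()
            m = na.any(axis=1).idxmax()
            raise ValueError(f"marker {m} is missing a channel record for some sample")
        wide_a = wide_a.loc[marker_ids, sample_ids_all]
        marker_ids, wide_a = _subset(wide_a, marker_ids, samples, markers)
        wide_b = wide_b.loc[marker_ids, wide_a.columns]
        sample_ids = list(wide_a.columns)
        SA = wide_a.loc[marker_ids].to_numpy(float)
        SB = wide_b.to_numpy(float)
    else:
        raise ValueError(f"unknown format {format!r}")

    _check_positive(SA, marker_ids, sample_ids, "A")
    _check_positive(SB, marker_ids, sample_ids, "B")
    return SignalMatrix(marker_ids, sample_ids, SA, SB)


def load_allele_correspondence(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the CSV mapping each marker's A/B channels to nucleotide alleles.

    Columns: ``marker_id, allele_A, allele_B``; alleles must be one of
    A/C/G/T/I/D (I and D denote insertion/deletion alleles).
    """
    df = pd.read_csv(path)
    required = {"marker_id", "allele_A", "allele_B"}
    if not required.issubset(df.columns):
        raise ValueError(f"allele correspondence CSV must have columns {sorted(required)}")
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate correspondence entry for marker {dup}")
    out: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        a, b = str(row["allele_A"]).upper(), str(row["allele_B"]).upper()
        if a not in _VALID_BASES or b not in _VALID_BASES:
            raise ValueError(f"invalid allele for marker {row['marker_id']}: {a}/{b}")
        out[str(row["marker_id"])] = (a, b)
    return out


def transform(signals: SignalMatrix) -> TransformedSignals:
    """Compute contrast and signal strength from raw intensities.

    ``x = log2(SA/SB)``, ``y = (log2(SA)+log2(SB))/2``, each rounded to three
    decimal places.  Positivity must have been screened at load time.
    """
    if not (np.all(signals.SA > 0) and np.all(signals.SB > 0)):
        raise ValueError("all intensities must be strictly positive")
    la, lb = np.log2(signals.SA), np.log2(signals.SB)
    x = np.round(la - lb, 3)
    y = np.round((la + lb) / 2.0, 3)
    return TransformedSignals(list(signals.marker_ids), list(signals.sample_ids), x, y)


def write_transformed(ts: TransformedSignals, path: str | Path) -> None:
    """Serialize to the long TSV consumed by the clustering stage."""
    n_m, n_s = ts.n_markers, ts.n_samples
    df = pd.DataFrame({
        "marker_id": np.repeat(ts.marker_ids, n_s),
        "sample_id": np.tile(ts.sample_ids, n_m),
        "contrast": ts.x.ravel(),
        "sigstren": ts.y.ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_transformed(path: str | Path) -> TransformedSignals:
    df = pd.read_csv(path, sep="\t")
    marker_ids = list(dict.fromkeys(df["marker_id"].astype(str)))
    sample_ids = list(dict.fromkeys(df["sample_id"].astype(str)))
    n_m, n_s = len(marker_ids), len(sample_ids)
    if len(df) != n_m * n_s:
        raise ValueError("transformed table is not a complete marker x sample grid")
    x = df["contrast"].to_numpy(float).reshape(n_m, n_s)
    y = df["sigstren"].to_numpy(float).reshape(n_m, n_s)
    return TransformedSignals(marker_ids, sample_ids, x, y)


def write_axas_summary(signals: SignalMatrix, path: str | Path) -> None:
    """Write raw intensities in the summary-export dialect (round-trips with
    :func:`load_luminescence`)."""
    rows, index = [], []
    for i, m in enumerate(signals.marker_ids):
        index.append(f"{m}-A")
        rows.append(signals.SA[i])
        index.append(f"{m}-B")
        rows.append(signals.SB[i])
    df = pd.DataFrame(rows, index=pd.Index(index, name="probeset_id"),
                      columns=signals.sample_ids)
    df.to_csv(path, sep="\t")
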