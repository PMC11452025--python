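"""Synthetic two-channel luminescence datasets with known genotype truth.

The generative model works directly on the (contrast, signal-strength) plane
where genotype clusters live, then inverts the log-ratio transform to emit
raw intensities:

* each marker draws an A-allele frequency; per-sample dosages follow
  Hardy-Weinberg proportions ``C(p, d) f^d (1-f)^(p-d)``;
* a sample at dosage d lands at ``x ~ N(centre_d + shift, sd_x)``,
  ``y ~ N(base_y, sd_y)``, with genotype contrast centres at
  {+1.5, +0.5, -0.5, -1.5} for ploidy 3 by default;
* an optional per-marker contrast shift (``shift_sd``) emulates markers whose
  whole signal is displaced to one side;
* a fraction ``p_off_target`` of markers has heterozygote signal strength
  depressed below the homozygotes, the signature of an off-target variant;
* intensities are recovered as ``SA = 2^(y + x/2)``, ``SB = 2^(y - x/2)``.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .signal_io import SignalMatrix

__all__ = ["SimConfig", "TruthTable", "hwe_genotype_freqs", "simulate_dataset",
           "write_truth", "read_truth"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic dataset.

    ``maf_lo, maf_hi`` bound the uniform minor-allele-frequency draw (the A
    allele is the minor one with probability 1/2).  ``off_target_depression``
    is how far an off-target marker's heterozygote strength sits below
    ``base_y``.
    """

    n_markers: int = 100
    n_samples: int = 200
    ploidy: int = 3
    maf_lo: float = 0.1
    maf_hi: float = 0.5
    genotype_centres: tuple[float, ...] | None = None  # index = A-dosage
    sd_x: float = 0.12
    sd_y: float = 0.1
    base_y: float = 1.0
    shift_sd: float = 0.0
    p_off_target: float = 0.0
    off_target_depression: float = 0.6
    seed: int = 0

    def centres(self) -> np.ndarray:
        if self.genotype_centres is not None:
            c = np.asarray(self.genotype_centres, float)
        else:
            # evenly spaced, homozygotes at ±1.5 for any ploidy
            c = np.linspace(-1.5, 1.5, self.ploidy + 1)
        if len(c) != self.ploidy + 1 or np.any(np.diff(c) <= 0):
            raise ValueError("genotype centres must be ploidy+1 values, strictly "
                             "increasing with A-dosage")
        return c


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset: per-sample dosage plus per-marker
    frequency, shift and off-target flag."""

    dosage: np.ndarray           # int, (n_markers, n_samples)
    freq_a: np.ndarray           # (n_markers,)
    shift: np.ndarray            # (n_markers,)
    off_target: np.ndarray       # bool, (n_markers,)
    marker_ids: list[str]
    sample_ids: list[str]


def hwe_genotype_freqs(p: float, ploidy: int) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies for an autopolyploid locus.

    Frequency of A-dosage d is ``C(ploidy, d) p^d (1-p)^(ploidy-d)``;
    the vector sums to 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    return binom.pmf(np.arange(ploidy + 1), ploidy, p)


def simulate_dataset(cfg: SimConfig) -> tuple[SignalMatrix, TruthTable]:
    """Draw a dataset under ``cfg``; returns raw intensities and the truth."""
    rng = np.random.default_rng(cfg.seed)
    p = cfg.ploidy
    centres = cfg.centres()
    n_m, n_s = cfg.n_markers, cfg.n_samples

    maf = rng.uniform(cfg.maf_lo, cfg.maf_hi, size=n_m)
    flip = rng.random(n_m) < 0.5
    freq_a = np.where(flip, 1.0 - maf, maf)
    shift = (rng.normal(0.0, cfg.shift_sd, size=n_m)
             if cfg.shift_sd > 0 else np.zeros(n_m))
    off_target = rng.random(n_m) < cfg.p_off_target

    dosage = np.empty((n_m, n_s), dtype=int)
    x = np.empty((n_m, n_s))
    y = np.empty((n_m, n_s))
    for i in range(n_m):
        freqs = hwe_genotype_freqs(freq_a[i], p)
        dosage[i] = rng.choice(p + 1, size=n_s, p=freqs)
        x[i] = rng.normal(centres[dosage[i]] + shift[i], cfg.sd_x)
        base = np.full(n_s, cfg.base_y)
        if off_target[i]:
            het = (dosage[i] > 0) & (dosage[i] < p)
            base[het] -= cfg.off_target_depression
        y[i] = rng.normal(base, cfg.sd_y)

    sa = np.exp2(y + x / 2.0)
    sb = np.exp2(y - x / 2.0)
    marker_ids = [f"M{i + 1:05d}" for i in range(n_m)]
    sample_ids = [f"S{j + 1:04d}" for j in range(n_s)]
    signals = SignalMatrix(marker_ids, sample_ids, sa, sb)
    truth = TruthTable(dosage, freq_a, shift, off_target, marker_ids, sample_ids)
    return signals, truth


def write_truth(truth: TruthTable, path: str | Path) -> None:
    """Truth TSV: one row per marker x sample with the true dosage."""
    n_m, n_s = truth.dosage.shape
    pd.DataFrame({
        "marker_id": np.repeat(truth.marker_ids, n_s),
        "sample_id": np.tile(truth.sample_ids, n_m),
        "dosage": truth.dosage.ravel(),
    }).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
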