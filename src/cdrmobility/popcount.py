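"""Dynamic population counts and normalized seasonal signatures.

Counting users per location label per time bin turns an IT-Matrix into a
dynamic population count; z-scoring each location's count series gives its
normalized seasonal signature.  Because interpolation places every user
somewhere on every day, counts from an interpolated matrix conserve the
population (each column sums to N); comparing them with the raw counts
quantifies the presence added by interpolation.  A spectral check verifies
that seasonal (low-frequency) variation dominates a signature, which is
what justifies aggregating daily trajectories to coarse time bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, RegionPartition
from .itmatrix import ITMatrix

__all__ = [
    "PopulationCount",
    "population_count",
    "zscore",
    "zscore_signature",
    "interpolation_bias",
    "low_frequency_fraction",
]


@dataclass
class PopulationCount:
    """Location × time-bin occupancy counts derived from one IT-Matrix."""

    values: np.ndarray          # (n_labels, n_bins) int64, row i = label i+1
    labels: list                # external labels, aligned with rows
    resolution: str
    level: str
    interpolated: bool

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def population_count(m: ITMatrix,
                     partition: RegionPartition) -> PopulationCount:
    """Count users per location label per bin; missing cells count nowhere."""
    n_labels = partition.n_labels(m.level)
    counts = np.zeros((n_labels, m.n_bins), dtype=np.int64)
    for t in range(m.n_bins):
        col = np.bincount(m.values[:, t], minlength=n_labels + 1)
        counts[:, t] = col[1:n_labels + 1]
    return PopulationCount(values=counts, labels=partition.labels(m.level),
                           resolution=m.resolution, level=m.level,
                           interpolated=m.interpolated)


def zscore(x: np.ndarray) -> np.ndarray:
    """(x − mean)/sd with population sd; a constant series maps to zeros."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("series must have length >= 2")
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)       # ddof=0
    out = np.zeros_like(x, dtype=float)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def zscore_signature(c: PopulationCount) -> np.ndarray:
    """Per-location z-scored count series (the seasonal signatures)."""
    return zscore(c.values)


def interpolation_bias(raw: PopulationCount, interp: PopulationCount,
                       denominator: str = "interp"):
    """Per-location mean percentage of presence added by interpolation.

    bias(z) = 100 · mean_t (interp(z,t) − raw(z,t)) / interp(z,t), skipping
    bins where the denominator is 0.  Also returns the per-bin added-user
    series (interp − raw) so the early-year concentration of the bias can
    be inspected.  ``denominator="raw"`` switches the reference series.
    """
    if raw.values.shape != interp.values.shape:
        raise ValueError("count shapes differ")
    if raw.resolution != interp.resolution or raw.level != interp.level:
        raise ValueError("counts are at different resolutions/levels")
    diff = interp.values - raw.values
    if (diff < 0).any():
        raise ValueError("interpolated counts must dominate raw counts")
    den = interp.values if denominator == "interp" else raw.values
    valid = den > 0
    frac = np.where(valid, diff / np.where(valid, den, 1), 0.0)
    n_valid = valid.sum(axis=1)
    bias = 100.0 * frac.sum(axis=1) / np.maximum(n_valid, 1)
    return bias, diff


def low_frequency_fraction(series: np.ndarray,
                           cutoff_fraction: float = 0.1) -> float:
    """Fraction of spectral power in the lowest frequencies of a signature.

    The series is z-scored, transformed with a real DFT, and the power of
    the zero-frequency term discarded; the returned value is the share of
    the remaining power carried by the lowest ``cutoff_fraction`` of the
    positive frequencies (at least one).  Values near 1 mean seasonal
    trends dominate; a flat (white) spectrum gives ≈ cutoff_fraction.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("series must have length >= 4")
    z = zscore(x)
    power = np.abs(np.fft.rfft(z)) ** 2
    pos = power[1:]
    total = pos.sum()
    if total == 0:
        return 0.0
    n_low = max(1, int(np.floor(cutoff_fraction * pos.size)))
    return float(pos[:n_low].sum() / total)
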