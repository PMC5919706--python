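"""Fusing mobility signatures with external environmental series.

Zone-level environmental series (monthly rainfall, vegetation index,
digitized income calendars) are rescaled to the same z-score scale as the
population-count signatures, correlated against profile signatures over a
range of lags, and summarized by an event-alignment report that compares
the onset month of the external series (first bin reaching a fraction of
its peak) with the month of each profile curve's largest month-over-month
change.  A lag of 0 means the profile switches in the onset month itself —
e.g. rural out-migration triggered by the start of the rainy season.

Correlations are plain Pearson coefficients on the overlapping window and
are descriptive; no multiple-testing correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import ExternalSeries
from .popcount import zscore
from .profiles import MobilityProfileSet

__all__ = [
    "rescale_to_signature",
    "correlate",
    "event_alignment_report",
    "series_onset_month",
]


def rescale_to_signature(series: ExternalSeries, zone,
                         expected_length: int | None = None) -> np.ndarray:
    """Z-score one zone's external series onto the signature scale."""
    x = series.zone_series(zone)
    if expected_length is not None and x.size != expected_length:
        raise ValueError(f"series length {x.size} does not match calendar "
                         f"length {expected_length}")
    return zscore(x)


def correlate(a: np.ndarray, b: np.ndarray, lag_range: int,
              method: str = "pearson") -> pd.DataFrame:
    """Correlation of a against b shifted by each lag in [-L, L].

    At lag ℓ, a[t] is paired with b[t+ℓ] over the overlapping window (no
    wrap-around); a positive lag means b trails a.  Rows where the window
    is shorter than 3 bins or either windowed series is constant are
    flagged undefined (NaN correlation).  Columns: lag, correlation, n.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series lengths differ")
    n = a.size
    rows = []
    for lag in range(-lag_range, lag_range + 1):
        if lag >= 0:
            x, y = a[:n - lag or None], b[lag:]
        else:
            x, y = a[-lag:], b[:n + lag]
        m = x.size
        if m < 3 or x.std() == 0 or y.std() == 0:
            rows.append((lag, np.nan, m))
            continue
        if method == "spearman":
            x = pd.Series(x).rank().to_numpy()
            y = pd.Series(y).rank().to_numpy()
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((lag, r, m))
    return pd.DataFrame(rows, columns=["lag", "correlation", "n"])


def series_onset_month(values: np.ndarray, onset_fraction: float = 0.5) -> int:
    """1-based first bin reaching ``onset_fraction`` of the series peak."""
    x = np.asarray(values, dtype=float)
    peak = np.nanmax(x)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("series has no positive peak; onset undefined")
    return int(np.flatnonzero(x >= onset_fraction * peak)[0]) + 1


def _largest_change_month(curve: np.ndarray) -> tuple[int, float]:
    """(1-based month of the largest |month-over-month change|, its value)."""
    d = np.diff(np.asarray(curve, dtype=float))
    j = int(np.argmax(np.abs(d)))
    return j + 2, float(d[j])     # change lands on the later month


def event_alignment_report(profile_sets: dict,
                           external: ExternalSeries,
                           onset_fraction: float = 0.5) -> pd.DataFrame:
    """Align profile switches with an external series onset, per zone.

    ``profile_sets`` maps zone label → MobilityProfileSet (monthly).  For
    each zone present in the external series, each profile contributes one
    row: the series onset month, the month of the profile curve's largest
    signed change, that change, and their lag (change − onset) in months.
    """
    if external.resolution != "monthly":
        raise ValueError("alignment report requires a monthly series")
    rows = []
    for zone, pset in profile_sets.items():
        if zone not in external.zones:
            continue
        onset = series_onset_month(external.zone_series(zone), onset_fraction)
        for c in range(1, pset.k + 1):
            change_month, change = _largest_change_month(pset.curves[c - 1])
            rows.append((zone, c, onset, change_month, change,
                         change_month - onset))
    return pd.DataFrame(rows, columns=["zone", "profile", "onset_month",
                                       "change_month", "change", "lag"])
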