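"""Individual-trajectory matrices: regularized multi-resolution mobility.

The central object is the IT-Matrix: a users × time-bins integer matrix
whose cell (p, t) is the label of user p's preferential region (or zone)
during bin t, with 0 marking bins where the user produced no events.  The
canonical pipeline is

1. per-user event vectors → daily preferential region (mode of the day's
   events), the estimator of the latent daily home location;
2. forward-fill interpolation of missing days (last known position), with
   the leading gap back-filled from the first active day;
3. time aggregation to weekly/biweekly/monthly bins by per-window mode,
   always recomputed from the daily matrix;
4. space aggregation from regions to zones through the partition map.

Time regularization is applied before space aggregation; the two orders do
not commute in general and the daily-first order is the one fixed here.
Ties in any "most frequent" reduction go to the label observed earliest in
time within the day or window, which is deterministic and independent of
label numbering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_io import MISSING, EventTable, RegionPartition, StudyCalendar

__all__ = [
    "Trajectory",
    "ITMatrix",
    "build_trajectories",
    "daily_preferential",
    "interpolate_missing",
    "aggregate_time",
    "aggregate_space",
    "write_itmatrix",
    "read_itmatrix",
]


@dataclass
class Trajectory:
    """One user's ordered (tick, region-code) event sequence."""

    user_id: object
    ticks: np.ndarray
    regions: np.ndarray

    def __len__(self) -> int:
        return len(self.ticks)


@dataclass
class ITMatrix:
    """Users × time-bins matrix of 1-based location labels (0 = missing)."""

    values: np.ndarray           # (N, n_bins) int64
    user_ids: np.ndarray         # (N,) row order
    resolution: str              # one of RESOLUTIONS
    level: str                   # 'region' | 'zone'
    interpolated: bool
    calendar: StudyCalendar

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("ITMatrix values must be 2-D")
        n_bins = self.calendar.n_bins(self.resolution)
        if self.values.shape[1] != n_bins:
            raise ValueError(f"{self.resolution} matrix needs {n_bins} "
                             f"columns, got {self.values.shape[1]}")
        if self.interpolated and (self.values == MISSING).any():
            raise ValueError("interpolated matrix contains missing cells")

    @property
    def n_users(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row(self, user_id) -> np.ndarray:
        idx = np.flatnonzero(self.user_ids == user_id)
        if idx.size == 0:
            raise KeyError(user_id)
        return self.values[idx[0]]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def build_trajectories(events: EventTable) -> dict:
    """Per-user event vectors, exact duplicates collapsed.

    Duplicate (tick, region) pairs for a user are kept once; two events at
    the same tick in different regions are both kept (both count as
    visits).  Returns a dict mapping user_id → Trajectory, keys sorted.
    """
    df = events.df.drop_duplicates(["user_id", "tick", "region"])
    out: dict = {}
    for uid, grp in df.groupby("user_id", sort=True):
        out[uid] = Trajectory(user_id=uid,
                              ticks=grp["tick"].to_numpy(),
                              regions=grp["region"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Daily preferential location
# ---------------------------------------------------------------------------

def daily_preferential(events: EventTable, calendar: StudyCalendar,
                       partition: RegionPartition) -> ITMatrix:
    """Most-visited region per user per day (the daily home estimator).

    Visit counts are event-record counts (not distinct ticks); a day with
    no events is MISSING.  Ties: the label of the day's earliest tied
    event wins.
    """
    df = events.df
    user_ids = np.asarray(sorted(df["user_id"].unique()))
    n_days = calendar.n_days
    values = np.zeros((len(user_ids), n_days), dtype=np.int64)
    if len(df) == 0:
        return ITMatrix(values, user_ids, "daily", "region", False, calendar)

    work = pd.DataFrame({
        "user": df["user_id"].to_numpy(),
        "day": calendar.day_of_tick(df["tick"].to_numpy()),
        "region": df["region"].to_numpy(),
        "tick": df["tick"].to_numpy(),
    })
    per = (work.groupby(["user", "day", "region"], sort=False)
               .agg(count=("tick", "size"), first_tick=("tick", "min"))
               .reset_index())
    # winner per (user, day): max count, then earliest first occurrence,
    # then smallest label (two regions can share a 10-minute tick)
    per = per.sort_values(["user", "day", "count", "first_tick", "region"],
                          ascending=[True, True, False, True, True],
                          kind="stable")
    win = per.drop_duplicates(["user", "day"], keep="first")

    row_of = {u: i for i, u in enumerate(user_ids)}
    rows = win["user"].map(row_of).to_numpy()
    values[rows, win["day"].to_numpy()] = win["region"].to_numpy()
    return ITMatrix(values, user_ids, "daily", "region", False, calendar)


# ---------------------------------------------------------------------------
# Interpolation of missing days
# ---------------------------------------------------------------------------

def interpolate_missing(m: ITMatrix, max_gap: int | None = None) -> ITMatrix:
    """Fill missing days with the last known position.

    Each missing cell takes the nearest previous non-missing value in its
    row; a leading missing run is back-filled with the row's first observed
    value.  Observed cells are never altered, so the operation is
    idempotent.  ``max_gap`` optionally caps forward-fill run length (cells
    beyond the cap stay missing and the result is left non-interpolated);
    by default gaps of any length are filled.
    """
    values = m.values
    if (values != MISSING).sum(axis=1).min() == 0:
        bad = m.user_ids[(values != MISSING).sum(axis=1) == 0]
        raise ValueError(f"row(s) with no observed location: {bad[:5]} "
                         "(exclude inactive users upstream)")

    n, t = values.shape
    observed = values != MISSING
    # forward fill: index of the most recent observed column
    idx = np.where(observed, np.arange(t), 0)
    idx = np.maximum.accumulate(idx, axis=1)
    filled = values[np.arange(n)[:, None], idx]
    # leading gap: before the first observation, idx stuck at 0 which may
    # itself be missing → backfill with first observed value
    first_obs = np.argmax(observed, axis=1)
    first_val = values[np.arange(n), first_obs]
    lead = np.arange(t)[None, :] < first_obs[:, None]
    filled = np.where(lead, first_val[:, None], filled)

    if max_gap is not None:
        # distance (in days) back to the sourcing observation
        dist = np.arange(t)[None, :] - idx
        dist = np.where(lead, 0, dist)   # head backfill is never capped
        filled = np.where(dist > max_gap, MISSING, filled)
        interpolated = not (filled == MISSING).any()
    else:
        interpolated = True
    return replace(m, values=filled, interpolated=interpolated)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _window_mode(sub: np.ndarray) -> np.ndarray:
    """Row-wise most frequent non-missing label, earliest-first tie-break."""
    n, w = sub.shape
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        row = sub[i]
        nz = row[row != MISSING]
        if nz.size == 0:
            continue
        counts = np.bincount(nz)
        top = counts.max()
        for v in row:
            if v != MISSING and counts[v] == top:
                out[i] = v
                break
    return out


def aggregate_time(m: ITMatrix, target_resolution: str,
                   calendar: StudyCalendar | None = None) -> ITMatrix:
    """Reduce a daily matrix to a coarser resolution by per-window mode.

    Coarser bins are always computed from the daily matrix (never from
    intermediate weekly/biweekly matrices), so e.g. the monthly value is
    the mode over the month's days.  Missing days are ignored; a bin is
    missing only when all its days are.  Ties go to the label of the
    earliest day attaining the top count.
    """
    calendar = calendar or m.calendar
    if m.resolution != "daily":
        raise ValueError("time aggregation is defined from the daily matrix")
    if target_resolution == "daily":
        raise ValueError("target resolution must be coarser than daily")
    calendar._check_resolution(target_resolution)

    bin_of = calendar.bin_of_day(target_resolution)
    n_bins = calendar.n_bins(target_resolution)
    out = np.zeros((m.n_users, n_bins), dtype=np.int64)
    for b in range(n_bins):
        out[:, b] = _window_mode(m.values[:, bin_of == b])
    return replace(m, values=out, resolution=target_resolution)


def aggregate_space(m: ITMatrix, partition: RegionPartition) -> ITMatrix:
    """Map region labels to zone labels through the partition (0 stays 0)."""
    if m.level != "region":
        raise ValueError("space aggregation expects a region-level matrix")
    zmap = partition.zone_of_region_code
    if (zmap[1:] == MISSING).any():
        raise ValueError("partition has regions without a zone")
    lut = np.concatenate(([MISSING], zmap[1:]))
    if m.values.max(initial=0) >= lut.size:
        raise ValueError("matrix contains region codes outside the partition")
    return replace(m, values=lut[m.values], level="zone")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_itmatrix(m: ITMatrix, path) -> None:
    """CSV with a metadata comment line; 0 encodes a missing cell."""
    header = (f"# resolution={m.resolution} level={m.level} "
              f"interpolated={int(m.interpolated)} year={m.calendar.year}\n")
    df = pd.DataFrame(m.values,
                      columns=[f"b{j}" for j in range(m.n_bins)])
    df.insert(0, "user_id", m.user_ids)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_itmatrix(path) -> ITMatrix:
    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("#"):
            raise ValueError("missing IT-matrix metadata header")
        meta = dict(tok.split("=") for tok in meta_line[1:].split())
        body = fh.read()
    df = pd.read_csv(io.StringIO(body))
    calendar = StudyCalendar(int(meta["year"]))
    return ITMatrix(values=df.drop(columns="user_id").to_numpy(),
                    user_ids=df["user_id"].to_numpy(),
                    resolution=meta["resolution"],
                    level=meta["level"],
                    interpolated=bool(int(meta["interpolated"])),
                    calendar=calendar)
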