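"""Trajectory selection: occupancy classes, movement filters, constraints.

For a target zone, the selection stage narrows the population to the
moving users whose seasonal occupancy is worth profiling:

* occupancy statistics classify each zone's visitors by months stayed —
  occasional (1 month), moving/migratory (2-11), permanent (12);
* the radius of gyration r_g (root-mean-square distance of daily positions
  from the visit-weighted mean) scales each user's typical movement, and
  users whose largest single inter-day move stays within ``ratio × r_g``
  are flagged "regular travelers" and removed — their moves are routine at
  their own scale rather than migratory;
* residents of urban-flagged regions can be excluded;
* four temporal constraints on the monthly zone sequence (minimum
  consecutive months in the target, maximum total months, minimum months
  in some other zone, required presence months) finish the selection.

The selected rows are then binarized against the target zone (1 iff the
month's preferential zone is the target), ready for profile clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MISSING, RegionPartition
from .itmatrix import ITMatrix

__all__ = [
    "OccupancyStats",
    "SelectionConfig",
    "SelectionResult",
    "BinaryProfileMatrix",
    "occupancy_stats",
    "radius_of_gyration",
    "flag_regular_travelers",
    "select_users",
    "binarize",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate pairs (degrees)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _planar_xy(lat, lon, lat0: float):
    """Equirectangular projection (km) around reference latitude lat0."""
    x = np.radians(np.asarray(lon)) * EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    y = np.radians(np.asarray(lat)) * EARTH_RADIUS_KM
    return x, y


def radius_of_gyration(daily_row: np.ndarray,
                       partition: RegionPartition) -> float:
    """RMS distance (km) of a user's daily positions from their mean.

    Computed from the interpolated daily region row with equal day
    weights, in a local planar approximation around the visit-weighted
    mean position.  A user who never leaves one region has r_g = 0.
    """
    row = np.asarray(daily_row)
    row = row[row != MISSING]
    if row.size == 0:
        return 0.0
    lat_by_code, lon_by_code = partition.centroids_by_code()
    counts = np.bincount(row, minlength=partition.n_regions + 1)[1:]
    visited = np.flatnonzero(counts) + 1
    w = counts[visited - 1] / counts.sum()
    lat0 = float(np.sum(w * lat_by_code[visited]))
    x, y = _planar_xy(lat_by_code[visited], lon_by_code[visited], lat0)
    xm, ym = np.sum(w * x), np.sum(w * y)
    return float(np.sqrt(np.sum(w * ((x - xm) ** 2 + (y - ym) ** 2))))


# ---------------------------------------------------------------------------
# Occupancy statistics
# ---------------------------------------------------------------------------

@dataclass
class OccupancyStats:
    """Per-zone months-stayed histogram and visitor class ratios."""

    zones: list                       # zone labels, aligned with rows below
    histogram: np.ndarray             # (n_zones, 12): visitors staying m+1 months
    n_visitors: np.ndarray            # (n_zones,)
    ratio_occasional: np.ndarray      # stayed exactly 1 month
    ratio_moving: np.ndarray          # stayed 2-11 months
    ratio_permanent: np.ndarray       # stayed all 12 months

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "zone": self.zones,
            "visitors": self.n_visitors,
            "occasional": self.ratio_occasional,
            "moving": self.ratio_moving,
            "permanent": self.ratio_permanent,
        })


def months_in_zone(mpl: ITMatrix, partition: RegionPartition) -> np.ndarray:
    """(N, n_zones) months each user spent in each zone (monthly matrix)."""
    if mpl.resolution != "monthly" or mpl.level != "zone":
        raise ValueError("expected a monthly zone-level matrix")
    n_zones = partition.n_zones
    out = np.zeros((mpl.n_users, n_zones), dtype=np.int64)
    for z in range(1, n_zones + 1):
        out[:, z - 1] = (mpl.values == z).sum(axis=1)
    return out


def occupancy_stats(mpl: ITMatrix,
                    partition: RegionPartition) -> OccupancyStats:
    """Histogram of months stayed, and visitor class ratios, per zone."""
    months = months_in_zone(mpl, partition)
    n_zones = partition.n_zones
    hist = np.zeros((n_zones, 12), dtype=np.int64)
    for z in range(n_zones):
        col = months[:, z]
        col = col[col > 0]
        hist[z] = np.bincount(col, minlength=13)[1:13]
    visitors = hist.sum(axis=1)
    with np.errstate(invalid="ignore"):
        denom = np.where(visitors > 0, visitors, 1)
        occ = hist[:, 0] / denom
        perm = hist[:, 11] / denom
        mov = hist[:, 1:11].sum(axis=1) / denom
    return OccupancyStats(zones=list(partition.zones), histogram=hist,
                          n_visitors=visitors, ratio_occasional=occ,
                          ratio_moving=mov, ratio_permanent=perm)


# ---------------------------------------------------------------------------
# Regular travelers
# ---------------------------------------------------------------------------

def flag_regular_travelers(daily: ITMatrix, partition: RegionPartition,
                           ratio_threshold: float = 3.0) -> np.ndarray:
    """True for users whose largest inter-day move ≤ threshold × r_g.

    Moves are measured between consecutive days' regions as centroid
    (haversine) distances.  A user with no region change is regular; a
    user with a change but r_g = 0 is not.
    """
    if daily.resolution != "daily" or daily.level != "region":
        raise ValueError("expected a daily region-level matrix")
    lat_by_code, lon_by_code = partition.centroids_by_code()
    flags = np.zeros(daily.n_users, dtype=bool)
    for i in range(daily.n_users):
        row = daily.values[i]
        obs = row[row != MISSING]
        changes = np.flatnonzero(obs[:-1] != obs[1:])
        if changes.size == 0:
            flags[i] = True
            continue
        a, b = obs[changes], obs[changes + 1]
        dist = haversine_km(lat_by_code[a], lon_by_code[a],
                            lat_by_code[b], lon_by_code[b])
        rg = radius_of_gyration(row, partition)
        flags[i] = rg > 0 and float(dist.max()) <= ratio_threshold * rg
    return flags


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionConfig:
    """Constraints defining the moving population of one target zone."""

    target_zone: object
    min_consecutive_months_in_target: int = 1
    max_months_in_target: int = 11
    min_months_elsewhere: int = 1
    required_period: tuple = ()          # 1-based months; empty = unused
    rog_ratio_threshold: float = 3.0
    exclude_urban: bool = False
    exclude_nonmoving: bool = True
    elsewhere_mode: str = "single"       # 'single' (max over one zone) | 'sum'

    def __post_init__(self) -> None:
        if not (1 <= self.min_consecutive_months_in_target
                <= self.max_months_in_target <= 12):
            raise ValueError("need 1 <= min_consecutive <= max_months <= 12")
        if self.rog_ratio_threshold <= 0:
            raise ValueError("rog_ratio_threshold must be positive")
        if self.elsewhere_mode not in ("single", "sum"):
            raise ValueError("elsewhere_mode must be 'single' or 'sum'")


@dataclass
class SelectionResult:
    user_ids: np.ndarray         # selected users, row order of input matrices
    mask: np.ndarray             # boolean over input rows
    audit: pd.DataFrame          # stage, removed, remaining
    n_visitors: int
    target_zone: object = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def _longest_run(bools: np.ndarray) -> np.ndarray:
    """Row-wise longest run of True (non-wrapping)."""
    n, t = bools.shape
    best = np.zeros(n, dtype=np.int64)
    cur = np.zeros(n, dtype=np.int64)
    for j in range(t):
        cur = np.where(bools[:, j], cur + 1, 0)
        best = np.maximum(best, cur)
    return best


def select_users(mpl: ITMatrix, daily_region: ITMatrix,
                 partition: RegionPartition,
                 cfg: SelectionConfig) -> SelectionResult:
    """Staged selection of the target zone's profiling population.

    Stages, applied in order to the users who ever visited the target
    zone: drop non-movers (12/12 months in target), drop regular
    travelers, drop urban residents (modal daily region urban-flagged),
    then the four temporal constraints.  The audit lists users removed at
    each stage; removed counts sum to visitors − selected.
    """
    if not np.array_equal(mpl.user_ids, daily_region.user_ids):
        raise ValueError("monthly and daily matrices cover different users")
    months = months_in_zone(mpl, partition)
    z = partition.zone_code(cfg.target_zone)
    in_target = mpl.values == z
    m_target = months[:, z - 1]

    mask = m_target >= 1
    n_visitors = int(mask.sum())
    audit_rows = []

    def stage(name: str, keep: np.ndarray) -> None:
        nonlocal mask
        removed = int((mask & ~keep).sum())
        mask = mask & keep
        audit_rows.append((name, removed, int(mask.sum())))

    if cfg.exclude_nonmoving:
        stage("nonmoving", m_target < 12)
    stage("regular_traveler",
          ~flag_regular_travelers(daily_region, partition,
                                  cfg.rog_ratio_threshold))
    if cfg.exclude_urban and partition.urban is not None:
        urban = partition.urban_by_code()
        residence = np.zeros(daily_region.n_users, dtype=np.int64)
        for i in range(daily_region.n_users):
            row = daily_region.values[i]
            obs = row[row != MISSING]
            if obs.size:
                residence[i] = np.bincount(obs).argmax()
        stage("urban_resident", ~urban[residence])
    stage("min_consecutive",
          _longest_run(in_target) >= cfg.min_consecutive_months_in_target)
    stage("max_months", m_target <= cfg.max_months_in_target)
    others = np.delete(months, z - 1, axis=1)
    if cfg.elsewhere_mode == "single":
        elsewhere = others.max(axis=1) if others.shape[1] else np.zeros(len(months), dtype=np.int64)
    else:
        elsewhere = others.sum(axis=1)
    stage("min_elsewhere", elsewhere >= cfg.min_months_elsewhere)
    if cfg.required_period:
        req = np.asarray(cfg.required_period, dtype=int) - 1
        stage("required_period", in_target[:, req].all(axis=1))

    audit = pd.DataFrame(audit_rows, columns=["stage", "removed", "remaining"])
    if mask.sum() == 0:
        import warnings
        warnings.warn(f"selection for zone {cfg.target_zone!r} is empty")
    return SelectionResult(user_ids=mpl.user_ids[mask], mask=mask,
                           audit=audit, n_visitors=n_visitors,
                           target_zone=cfg.target_zone)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

@dataclass
class BinaryProfileMatrix:
    """Selected users × months indicator of presence in the target zone."""

    values: np.ndarray           # (n_selected, 12) uint8
    user_ids: np.ndarray
    target_zone: object

    @property
    def n_users(self) -> int:
        return self.values.shape[0]


def binarize(mpl: ITMatrix, selection: SelectionResult,
             partition: RegionPartition) -> BinaryProfileMatrix:
    """1 iff the user's monthly preferential zone is the target zone."""
    if selection.n_selected == 0:
        raise ValueError("selection is empty; nothing to binarize")
    z = partition.zone_code(selection.target_zone)
    rows = mpl.values[selection.mask]
    B = (rows == z).astype(np.uint8)
    if (B.sum(axis=1) == 0).any():
        raise ValueError("selected user never in target zone "
                         "(selection contract violated)")
    return BinaryProfileMatrix(values=B, user_ids=selection.user_ids,
                               target_zone=selection.target_zone)
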