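"""Synthetic CDR scenarios with planted ground-truth mobility structure.

The generator emulates a year-long, region-quantized, anonymized CDR
release: a partition of regions grouped into zones (by default 123 regions
in 13 zones, the first zone urban), behavioral user groups with planted
monthly itineraries (permanent residents, occasional visitors, seasonal
migrants), per-user call events at Poisson daily rates on 10-minute ticks,
per-day inactivity, and a minimum-active-days floor mirroring upstream
operator filters (default 256 days).  An optional synthetic monthly
rainfall series peaks shortly after a configurable onset month per zone.

Everything is drawn from a single seeded pseudo-random stream in a fixed
order, so a scenario's outputs — including emitted files — are
byte-identical across runs with the same spec.

Default study conditions
------------------------
* 365-day year (2013 calendar), 123 regions / 13 zones;
* Poisson mean 4 events per active day, per-day inactivity 0.2,
  minimum 256 active days per user;
* within a month a user keeps one region, drawn uniformly from their
  zone's regions (month-to-month churn stays within the zone);
* rainfall onset month 7 (July) with the peak the month after.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (TICKS_PER_DAY, EventTable, ExternalSeries,
                      RegionPartition, StudyCalendar, write_events,
                      write_external_series, write_partition)

__all__ = [
    "GroupSpec",
    "ScenarioSpec",
    "GroundTruth",
    "SyntheticScenario",
    "permanent_group",
    "occasional_group",
    "seasonal_group",
    "generate",
    "emit_files",
    "clustering_scenario",
    "occupancy_scenario",
    "alignment_scenario",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One behavioral group: a monthly zone itinerary shared by its users.

    ``flip_zones``, when given, is the alternate zone per month; with
    scenario flip-noise probability q each user-month independently takes
    the alternate instead of the template zone (used to blur planted
    binary profiles).
    """

    name: str
    size: int
    monthly_zones: tuple          # 12 zone labels
    flip_zones: tuple | None = None

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("group size must be >= 0")
        if len(self.monthly_zones) != 12:
            raise ValueError("monthly_zones must list 12 zones")
        if self.flip_zones is not None and len(self.flip_zones) != 12:
            raise ValueError("flip_zones must list 12 zones")


def permanent_group(name: str, size: int, zone) -> GroupSpec:
    """Users resident in one zone all 12 months."""
    return GroupSpec(name, size, (zone,) * 12)


def occasional_group(name: str, size: int, home, visit_zone,
                     visit_month: int) -> GroupSpec:
    """Users visiting ``visit_zone`` for exactly one month (1-based)."""
    zones = [home] * 12
    zones[visit_month - 1] = visit_zone
    return GroupSpec(name, size, tuple(zones))


def seasonal_group(name: str, size: int, home, dest, depart_month: int,
                   return_month: int = 13) -> GroupSpec:
    """Migrants in ``dest`` from ``depart_month`` until ``return_month``.

    Months are 1-based; the user is in ``dest`` for months
    depart_month..return_month-1 and at ``home`` otherwise.  A
    ``return_month`` of 13 means the user stays away through December.
    Flip zones swap home and destination, so flip noise toggles single
    months of presence.
    """
    if not 1 <= depart_month < return_month <= 13:
        raise ValueError("need 1 <= depart_month < return_month <= 13")
    zones = [dest if depart_month <= m + 1 < return_month else home
             for m in range(12)]
    flips = [home if z == dest else dest for z in zones]
    return GroupSpec(name, size, tuple(zones), tuple(flips))


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic study."""

    groups: tuple
    year: int = 2013
    n_regions: int = 123
    n_zones: int = 13
    urban_zones: tuple = (1,)
    daily_rate: float = 4.0          # Poisson mean events per active day
    inactivity_prob: float = 0.2     # per-day probability of no events
    min_active_days: int = 256
    flip_noise: float = 0.0          # per-user-month itinerary flip prob.
    rain_onset_month: int = 7        # 1-based; peak lands the month after
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.inactivity_prob <= 1:
            raise ValueError("inactivity_prob must be in [0, 1]")
        if not 0 <= self.flip_noise <= 1:
            raise ValueError("flip_noise must be in [0, 1]")
        if self.n_zones > self.n_regions:
            raise ValueError("more zones than regions")
        cal = StudyCalendar(self.year)
        if self.min_active_days > cal.n_days:
            raise ValueError("min_active_days exceeds the calendar length")
        for g in self.groups:
            for z in g.monthly_zones + (g.flip_zones or ()):
                if not 1 <= z <= self.n_zones:
                    raise ValueError(f"group {g.name!r} uses unknown zone {z}")


@dataclass
class GroundTruth:
    """Planted per-user truth, consistent with the emitted events."""

    user_ids: np.ndarray          # (N,)
    group_names: list
    group_index: np.ndarray       # (N,) index into group_names
    monthly_zone: np.ndarray      # (N, 12) zone labels
    daily_region: np.ndarray      # (N, n_days) region labels
    occupancy: np.ndarray         # (n_zones, 12) planted monthly counts


@dataclass
class SyntheticScenario:
    spec: ScenarioSpec
    calendar: StudyCalendar
    partition: RegionPartition
    events: EventTable
    truth: GroundTruth
    rainfall: ExternalSeries


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _make_partition(spec: ScenarioSpec,
                    rng: np.random.Generator) -> RegionPartition:
    """Zones on a coarse grid near Senegal, regions jittered within zones."""
    r, nz = spec.n_regions, spec.n_zones
    cols = int(np.ceil(np.sqrt(nz)))
    zone_lat = 13.0 + 0.9 * (np.arange(nz) // cols)
    zone_lon = -17.0 + 0.9 * (np.arange(nz) % cols)
    zone_of_region = (np.arange(r) * nz) // r        # contiguous blocks
    lat = zone_lat[zone_of_region] + rng.uniform(-0.15, 0.15, r)
    lon = zone_lon[zone_of_region] + rng.uniform(-0.15, 0.15, r)
    urban = np.isin(zone_of_region + 1, spec.urban_zones)
    return RegionPartition(region_ids=list(range(1, r + 1)),
                           lat=lat, lon=lon,
                           zone_ids=list(zone_of_region + 1),
                           urban=urban)


def _make_rainfall(spec: ScenarioSpec) -> ExternalSeries:
    onset = spec.rain_onset_month
    profile = {0: 60.0, 1: 100.0, 2: 70.0, 3: 30.0}
    values = np.full((spec.n_zones, 12), 2.0)
    for off, v in profile.items():
        m = onset - 1 + off
        if m < 12:
            values[:, m] = v
    return ExternalSeries(name="rainfall", zones=list(range(1, spec.n_zones + 1)),
                          values=values, missing=np.zeros_like(values, bool),
                          resolution="monthly", units="mm")


def generate(spec: ScenarioSpec) -> SyntheticScenario:
    """Realize a scenario: partition, events, ground truth, rainfall.

    Sampling order (one stream): partition jitter, itinerary flips,
    within-zone region choices, activity masks, activity top-ups, daily
    event counts, event ticks.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    calendar = StudyCalendar(spec.year)
    partition = _make_partition(spec, rng)
    n_days = calendar.n_days
    month_of_day = calendar.bin_of_day("monthly")

    sizes = [g.size for g in spec.groups]
    n = int(sum(sizes))
    if n == 0:
        raise ValueError("scenario has no users")
    group_index = np.repeat(np.arange(len(spec.groups)), sizes)
    user_ids = np.arange(1, n + 1)

    # monthly zone itineraries (+ flip noise where a group defines flips)
    monthly_zone = np.empty((n, 12), dtype=np.int64)
    for gi, g in enumerate(spec.groups):
        rows = np.flatnonzero(group_index == gi)
        base = np.tile(np.asarray(g.monthly_zones, dtype=np.int64),
                       (rows.size, 1))
        if g.flip_zones is not None and spec.flip_noise > 0:
            flips = rng.random((rows.size, 12)) < spec.flip_noise
            alt = np.tile(np.asarray(g.flip_zones, dtype=np.int64),
                          (rows.size, 1))
            base = np.where(flips, alt, base)
        monthly_zone[rows] = base

    # within-zone region per user-month (fixed inside the month)
    zone_regions = {z + 1: np.flatnonzero(partition.zone_of_region_code[1:]
                                          == z + 1) + 1
                    for z in range(spec.n_zones)}
    monthly_region = np.empty((n, 12), dtype=np.int64)
    for z, regs in zone_regions.items():
        cells = monthly_zone == z
        monthly_region[cells] = rng.choice(regs, size=int(cells.sum()))
    daily_region = monthly_region[:, month_of_day]

    # activity: per-day Bernoulli, then top up to the minimum active days
    active = rng.random((n, n_days)) >= spec.inactivity_prob
    deficit = spec.min_active_days - active.sum(axis=1)
    for i in np.flatnonzero(deficit > 0):
        off = np.flatnonzero(~active[i])
        add = rng.choice(off, size=int(deficit[i]), replace=False)
        active[i, add] = True

    counts = np.where(active,
                      np.maximum(1, rng.poisson(spec.daily_rate,
                                                (n, n_days))), 0)
    total = int(counts.sum())
    flat = counts.ravel()
    cell = np.repeat(np.arange(n * n_days), flat)
    ev_user = user_ids[cell // n_days]
    ev_day = cell % n_days
    ev_tick = ev_day * TICKS_PER_DAY + rng.integers(0, TICKS_PER_DAY, total)
    ev_region = daily_region.ravel()[cell]

    df = pd.DataFrame({"user_id": ev_user, "tick": ev_tick,
                       "region": ev_region})
    df = df.sort_values(["user_id", "tick"], kind="stable",
                        ignore_index=True)
    events = EventTable(df, calendar, n_rejected=0)

    occupancy = np.zeros((spec.n_zones, 12), dtype=np.int64)
    for m in range(12):
        occupancy[:, m] = np.bincount(monthly_zone[:, m],
                                      minlength=spec.n_zones + 1)[1:]
    truth = GroundTruth(user_ids=user_ids,
                        group_names=[g.name for g in spec.groups],
                        group_index=group_index,
                        monthly_zone=monthly_zone,
                        daily_region=daily_region,
                        occupancy=occupancy)
    return SyntheticScenario(spec=spec, calendar=calendar,
                             partition=partition, events=events,
                             truth=truth, rainfall=_make_rainfall(spec))


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def emit_files(scenario: SyntheticScenario, directory) -> dict:
    """Write events, partition, rainfall and ground truth as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": directory / "events.csv",
        "partition": directory / "partition.csv",
        "rainfall": directory / "rainfall.csv",
        "truth_monthly": directory / "truth_monthly.csv",
        "truth_daily": directory / "truth_daily.csv",
        "groups": directory / "groups.csv",
    }
    write_events(scenario.events, paths["events"], scenario.partition)
    write_partition(scenario.partition, paths["partition"])
    write_external_series(scenario.rainfall, paths["rainfall"])

    t = scenario.truth
    n, n_days = t.daily_region.shape
    pd.DataFrame({
        "user_id": np.repeat(t.user_ids, 12),
        "month": np.tile(np.arange(1, 13), n),
        "zone_id": t.monthly_zone.ravel(),
    }).to_csv(paths["truth_monthly"], index=False)
    pd.DataFrame({
        "user_id": np.repeat(t.user_ids, n_days),
        "day": np.tile(np.arange(1, n_days + 1), n),
        "region_id": t.daily_region.ravel(),
    }).to_csv(paths["truth_daily"], index=False)
    pd.DataFrame({"user_id": t.user_ids,
                  "group": [t.group_names[i] for i in t.group_index]}
                 ).to_csv(paths["groups"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------------

def clustering_scenario(seed: int, users_per_group: int = 100,
                        flip_noise: float = 0.05,
                        target_zone: int = 11) -> ScenarioSpec:
    """Three planted profile groups for one target rural zone.

    Group templates (presence in the target zone by month): residents
    present January-June, second-half visitors (July-December) and
    mid-year visitors (April-September).  Each profile spans six months,
    so flip noise cannot plausibly erase a user's overlap with their own
    group; pairwise template Jaccard distances are 1, 2/3 and 2/3.
    """
    groups = (
        seasonal_group("first_half", users_per_group,
                       home=target_zone, dest=1, depart_month=7),
        seasonal_group("second_half", users_per_group,
                       home=2, dest=target_zone, depart_month=7),
        seasonal_group("mid_year", users_per_group,
                       home=3, dest=target_zone, depart_month=4,
                       return_month=10),
    )
    return ScenarioSpec(groups=groups, flip_noise=flip_noise, seed=seed)


def occupancy_scenario(seed: int, n_users: int = 2000,
                       target_zone: int = 5) -> ScenarioSpec:
    """Visitor classes of one zone: 10% occasional, 40% moving, 50% permanent."""
    n_occ = round(0.10 * n_users)
    n_mov = round(0.40 * n_users)
    n_perm = n_users - n_occ - n_mov
    groups = (
        permanent_group("permanent", n_perm, target_zone),
        seasonal_group("moving", n_mov, home=target_zone, dest=1,
                       depart_month=6, return_month=10),
        occasional_group("occasional", n_occ, home=2,
                         visit_zone=target_zone, visit_month=3),
    )
    return ScenarioSpec(groups=groups, seed=seed)


def alignment_scenario(seed: int, users_per_zone: int = 60,
                       rural_zones: tuple = (10, 11, 12, 13),
                       rain_onset_month: int = 7) -> ScenarioSpec:
    """Rural out-migration departing at the rainfall onset month."""
    groups = tuple(
        seasonal_group(f"migrants_z{z}", users_per_zone, home=z, dest=1,
                       depart_month=rain_onset_month)
        for z in rural_zones
    ) + (permanent_group("urban", users_per_zone, 1),)
    return ScenarioSpec(groups=groups, rain_onset_month=rain_onset_month,
                        seed=seed)
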