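"""Tabular IO and static geography for region-quantized call-detail records.

The data model mirrors year-long, anonymized CDR releases in which each call
event carries an opaque user id, a timestamp quantized to 10-minute ticks and
the administrative region (e.g. Senegalese arrondissement) serving the call.
Regions are grouped many-to-one into coarser analysis zones (e.g. livelihood
zones), and every derived matrix lives on a fixed study calendar whose
supported time resolutions are daily, weekly, biweekly and monthly.

File dialects (all plain delimited text, header row required):

* events:        ``user_id,timestamp,region_id`` with ISO-8601 timestamps;
* partition:     ``region_id,lat,lon,zone_id[,urban]``;
* external series: ``zone_id,bin,value`` with 1-based bin indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "TICKS_PER_DAY",
    "RESOLUTIONS",
    "StudyCalendar",
    "RegionPartition",
    "EventTable",
    "ExternalSeries",
    "read_events",
    "write_events",
    "read_partition",
    "write_partition",
    "read_external_series",
    "write_external_series",
]

#: Sentinel for "no location observed"; real labels are 1-based.
MISSING = 0

#: 10-minute ticks per day.
TICKS_PER_DAY = 144

#: Supported time resolutions, finest first.
RESOLUTIONS = ("daily", "weekly", "biweekly", "monthly")


# ---------------------------------------------------------------------------
# Study calendar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyCalendar:
    """One calendar year partitioned into daily/weekly/biweekly/monthly bins.

    Weekly bins are consecutive 7-day blocks anchored at Jan 1; the final
    short block (1 day in a 365-day year) is its own bin, giving 53 bins.
    Biweekly bins split each calendar month at day 15 (days 1-15 and
    16-end), giving 24 bins; fixed 14-day blocks would give 27 and are not
    compatible with the published bin count.  Monthly bins are calendar
    months.  A single timezone is assumed throughout.
    """

    year: int = 2013

    def __post_init__(self) -> None:
        start = np.datetime64(f"{self.year}-01-01")
        end = np.datetime64(f"{self.year + 1}-01-01")
        n_days = int((end - start) / np.timedelta64(1, "D"))
        dates = pd.date_range(str(start), periods=n_days, freq="D")
        object.__setattr__(self, "_start", pd.Timestamp(str(start)))
        object.__setattr__(self, "_n_days", n_days)
        object.__setattr__(self, "_month_of_day",
                           np.asarray(dates.month - 1, dtype=np.int64))
        biweek = (dates.month - 1) * 2 + (dates.day > 15)
        object.__setattr__(self, "_biweek_of_day",
                           np.asarray(biweek, dtype=np.int64))
        object.__setattr__(self, "_week_of_day", np.arange(n_days) // 7)

    # -- basic geometry ----------------------------------------------------

    @property
    def start(self) -> pd.Timestamp:
        return self._start

    @property
    def n_days(self) -> int:
        return self._n_days

    @property
    def n_ticks(self) -> int:
        return self._n_days * TICKS_PER_DAY

    def n_bins(self, resolution: str) -> int:
        """Number of time bins at *resolution* (365/53/24/12 for 2013)."""
        self._check_resolution(resolution)
        if resolution == "daily":
            return self._n_days
        if resolution == "weekly":
            return -(-self._n_days // 7)
        if resolution == "biweekly":
            return 24
        return 12

    def bin_of_day(self, resolution: str) -> np.ndarray:
        """Map each day index 0..n_days-1 to its bin at *resolution*."""
        self._check_resolution(resolution)
        if resolution == "daily":
            return np.arange(self._n_days)
        if resolution == "weekly":
            return self._week_of_day
        if resolution == "biweekly":
            return self._biweek_of_day
        return self._month_of_day

    # -- timestamps --------------------------------------------------------

    def tick_of_timestamp(self, ts: pd.Series | pd.DatetimeIndex) -> np.ndarray:
        """Quantize timestamps to 10-minute ticks from the study start."""
        delta = pd.DatetimeIndex(ts) - self._start
        return (delta // pd.Timedelta(minutes=10)).to_numpy()

    def timestamp_of_tick(self, ticks: np.ndarray) -> pd.DatetimeIndex:
        return self._start + pd.to_timedelta(np.asarray(ticks) * 10, unit="m")

    def day_of_tick(self, ticks: np.ndarray) -> np.ndarray:
        return np.asarray(ticks) // TICKS_PER_DAY

    @staticmethod
    def _check_resolution(resolution: str) -> None:
        if resolution not in RESOLUTIONS:
            raise ValueError(f"unknown resolution {resolution!r}; "
                             f"expected one of {RESOLUTIONS}")


# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Disjoint region partition with centroids and a total region→zone map.

    Regions and zones keep their external labels; internally each is given a
    1-based integer code (0 is the MISSING sentinel), with region codes in
    input order and zone codes in sorted label order.
    """

    region_ids: list
    lat: np.ndarray
    lon: np.ndarray
    zone_ids: list                     # zone label per region (aligned)
    urban: np.ndarray | None = None    # bool per region, optional

    zones: list = field(init=False)            # unique zone labels, sorted
    _region_code: dict = field(init=False, repr=False)
    _zone_code: dict = field(init=False, repr=False)
    zone_of_region_code: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region_id in partition")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (np.all(np.abs(self.lat) <= 90) and np.all(np.abs(self.lon) <= 180)):
            raise ValueError("centroid coordinates out of range")
        if len(self.zone_ids) != len(self.region_ids):
            raise ValueError("zone_of must be total over regions")
        self.zones = sorted(set(self.zone_ids))
        self._region_code = {r: i + 1 for i, r in enumerate(self.region_ids)}
        self._zone_code = {z: i + 1 for i, z in enumerate(self.zones)}
        zmap = np.zeros(len(self.region_ids) + 1, dtype=np.int64)
        for i, z in enumerate(self.zone_ids):
            zmap[i + 1] = self._zone_code[z]
        self.zone_of_region_code = zmap
        if self.urban is not None:
            self.urban = np.asarray(self.urban, dtype=bool)

    # -- sizes -------------------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    def n_labels(self, level: str) -> int:
        if level == "region":
            return self.n_regions
        if level == "zone":
            return self.n_zones
        raise ValueError(f"unknown space level {level!r}")

    def labels(self, level: str) -> list:
        return list(self.region_ids) if level == "region" else list(self.zones)

    # -- code lookups ------------------------------------------------------

    def region_code(self, region_id) -> int:
        return self._region_code[region_id]

    def zone_code(self, zone_id) -> int:
        return self._zone_code[zone_id]

    def region_codes(self, region_ids) -> np.ndarray:
        return np.asarray([self._region_code[r] for r in region_ids])

    def urban_by_code(self) -> np.ndarray:
        """Urban flag indexed by region code (index 0 unused, False)."""
        flags = np.zeros(self.n_regions + 1, dtype=bool)
        if self.urban is not None:
            flags[1:] = self.urban
        return flags

    # -- centroids ---------------------------------------------------------

    def centroids_by_code(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays indexed by region code; index 0 is NaN."""
        lat = np.full(self.n_regions + 1, np.nan)
        lon = np.full(self.n_regions + 1, np.nan)
        lat[1:] = self.lat
        lon[1:] = self.lon
        return lat, lon

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionPartition":
        required = {"region_id", "lat", "lon", "zone_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"partition table missing columns {sorted(missing)}")
        if df["region_id"].isna().any() or df["zone_id"].isna().any():
            raise ValueError("partition table has null region_id/zone_id")
        urban = None
        if "urban" in df.columns:
            urban = df["urban"].astype(int).astype(bool).to_numpy()
        return cls(region_ids=df["region_id"].tolist(),
                   lat=df["lat"].to_numpy(),
                   lon=df["lon"].to_numpy(),
                   zone_ids=df["zone_id"].tolist(),
                   urban=urban)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "region_id": self.region_ids,
            "lat": self.lat,
            "lon": self.lon,
            "zone_id": self.zone_ids,
        })
        if self.urban is not None:
            out["urban"] = self.urban.astype(int)
        return out


def read_partition(path) -> RegionPartition:
    """Read a ``region_id,lat,lon,zone_id[,urban]`` table."""
    return RegionPartition.from_frame(pd.read_csv(path))


def write_partition(partition: RegionPartition, path) -> Path:
    path = Path(path)
    partition.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Validated call events: columns ``user_id``, ``tick``, ``region``.

    ``region`` holds 1-based region codes from the partition; rows are
    sorted by (user_id, tick).  ``n_rejected`` counts input records dropped
    during validation.
    """

    df: pd.DataFrame
    calendar: StudyCalendar
    n_rejected: int = 0

    @property
    def n_events(self) -> int:
        return len(self.df)

    @property
    def user_ids(self) -> np.ndarray:
        return np.asarray(sorted(self.df["user_id"].unique()))

    @property
    def n_users(self) -> int:
        return self.df["user_id"].nunique()


def read_events(path, partition: RegionPartition, calendar: StudyCalendar,
                strict: bool = False) -> EventTable:
    """Read and validate a ``user_id,timestamp,region_id`` event file.

    Records with an unknown region, an unparseable timestamp or a timestamp
    outside the study year are rejected with a warning (or raise, when
    ``strict``).  An empty file yields an empty table with a warning.
    """
    df = pd.read_csv(path)
    required = {"user_id", "timestamp", "region_id"}
    if not required <= set(df.columns):
        raise ValueError(f"event file missing columns "
                         f"{sorted(required - set(df.columns))}")
    n_in = len(df)
    if n_in == 0:
        warnings.warn(f"event file {path} is empty")
        empty = pd.DataFrame({"user_id": [], "tick": [], "region": []})
        return EventTable(empty.astype({"tick": np.int64, "region": np.int64}),
                          calendar, n_rejected=0)

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    ticks = np.where(bad_ts, -1,
                     ((ts - calendar.start) // pd.Timedelta(minutes=10))
                     .fillna(-1).astype(np.int64))
    out_of_period = (ticks < 0) | (ticks >= calendar.n_ticks)

    code_map = pd.Series({r: partition.region_code(r)
                          for r in partition.region_ids})
    region = df["region_id"].map(code_map)
    unknown = region.isna()

    ok = ~(bad_ts.to_numpy() | out_of_period | unknown.to_numpy())
    n_rejected = int(n_in - ok.sum())
    if n_rejected:
        msg = (f"{n_rejected} of {n_in} event records rejected "
               f"(unknown region, bad or out-of-period timestamp)")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)

    out = pd.DataFrame({
        "user_id": df.loc[ok, "user_id"].to_numpy(),
        "tick": ticks[ok],
        "region": region[ok].astype(np.int64).to_numpy(),
    })
    out = out.sort_values(["user_id", "tick"], kind="stable",
                          ignore_index=True)
    return EventTable(out, calendar, n_rejected=n_rejected)


def write_events(events: EventTable, path, partition: RegionPartition) -> Path:
    """Write an event table back to the ISO-timestamp file dialect."""
    path = Path(path)
    labels = np.asarray([None] + list(partition.region_ids), dtype=object)
    ts = events.calendar.timestamp_of_tick(events.df["tick"].to_numpy())
    out = pd.DataFrame({
        "user_id": events.df["user_id"],
        "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
        "region_id": labels[events.df["region"].to_numpy()],
    })
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# External zone-level series
# ---------------------------------------------------------------------------

@dataclass
class ExternalSeries:
    """A named zone × time-bin table of environmental/contextual values.

    Holds directly measurable external variables (rainfall, vegetation
    index) or derived indicators, already aggregated per analysis zone at
    one of the calendar's resolutions.  ``missing`` flags cells absent from
    the input.
    """

    name: str
    zones: list
    values: np.ndarray           # (n_zones, n_bins) float
    missing: np.ndarray          # (n_zones, n_bins) bool
    resolution: str
    units: str = ""

    def zone_series(self, zone_id) -> np.ndarray:
        return self.values[self.zones.index(zone_id)]


def read_external_series(path, calendar: StudyCalendar,
                         resolution: str = "monthly",
                         name: str | None = None,
                         units: str = "") -> ExternalSeries:
    """Read a ``zone_id,bin,value`` table (bins 1-based) into a matrix."""
    df = pd.read_csv(path)
    required = {"zone_id", "bin", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"series file missing columns "
                         f"{sorted(required - set(df.columns))}")
    n_bins = calendar.n_bins(resolution)
    bins = df["bin"].astype(int)
    if ((bins < 1) | (bins > n_bins)).any():
        raise ValueError(f"bin index outside 1..{n_bins} for {resolution}")
    zones = sorted(df["zone_id"].unique())
    zi = {z: i for i, z in enumerate(zones)}
    values = np.full((len(zones), n_bins), np.nan)
    for z, b, v in zip(df["zone_id"], bins, df["value"]):
        values[zi[z], b - 1] = v
    missing = np.isnan(values)
    return ExternalSeries(name=name or Path(path).stem, zones=zones,
                          values=values, missing=missing,
                          resolution=resolution, units=units)


def write_external_series(series: ExternalSeries, path) -> Path:
    path = Path(path)
    rows = []
    for i, z in enumerate(series.zones):
        for b in range(series.values.shape[1]):
            if not series.missing[i, b]:
                rows.append((z, b + 1, series.values[i, b]))
    pd.DataFrame(rows, columns=["zone_id", "bin", "value"]).to_csv(
        path, index=False)
    return path
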