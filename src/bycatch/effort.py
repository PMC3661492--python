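"""Trawl-effort and observer data: schema, delimited-file I/O, linking, filtering.

The canonical in-memory container is a pandas DataFrame with one row per tow
(columns in :data:`EFFORT_COLUMNS`).  Observer records live in a second frame
(:data:`OBSERVER_COLUMNS`) and are joined onto the effort frame by
:func:`link_observer_records`; the ``captures`` column is NaN for unobserved
tows — a capture count is *undefined*, not zero, when no observer was aboard.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "EFFORT_COLUMNS",
    "OBSERVER_COLUMNS",
    "MACKEREL_CODES",
    "StudyArea",
    "LoadReport",
    "AmbiguousLinkError",
    "read_effort_table",
    "read_observer_table",
    "write_effort_table",
    "link_observer_records",
    "filter_large_vessel_mackerel_fleet",
    "assign_fishing_year",
    "fishing_year_index",
    "assign_subarea",
    "in_study_area",
    "haversine_km",
]

#: canonical effort schema; bottom_depth and trip_id are optional
EFFORT_COLUMNS = [
    "tow_id", "vessel_id", "vessel_length", "start_time", "end_time",
    "start_lat", "start_lon", "end_lat", "end_lon", "target_species",
    "catch_weight", "groundline_depth", "headline_height", "trawl_speed",
]
OPTIONAL_EFFORT_COLUMNS = ["bottom_depth", "trip_id", "observed", "captures"]
OBSERVER_COLUMNS = [
    "vessel_id", "start_time", "end_time", "start_lat", "start_lon",
    "target_species", "captures",
]
_TIME_COLS = ("start_time", "end_time")

#: jack mackerel (Trachurus spp.) and blue mackerel (Scomber australasicus)
MACKEREL_CODES = frozenset({"JMA", "EMA"})

EARTH_RADIUS_KM = 6371.0


class AmbiguousLinkError(ValueError):
    """Two observer records resolved to the same effort tow."""


@dataclass
class StudyArea:
    """Rectangular approximation of the west-coast North Island study region.

    The eastern boundary is the meridian 173 deg 2.8 min E; the southern, the
    Cook Strait line at 41 deg S; the western edge stands in for the EEZ
    boundary.  Sub-areas split at 39 deg 18 min S.
    """

    east_bound_lon: float = 173.0 + 2.8 / 60.0
    south_bound_lat: float = -41.0
    west_bound_lon: float = 171.0
    north_bound_lat: float = -34.0
    subarea_split_lat: float = -39.3

    def __post_init__(self) -> None:
        if not self.south_bound_lat < self.subarea_split_lat < self.north_bound_lat:
            raise ValueError("sub-area split latitude must lie strictly inside the area")


@dataclass
class LoadReport:
    """Row accounting for a table load or link step."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)
    n_matched: int = 0
    n_unmatched: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _drop(report: LoadReport, mask: pd.Series, reason: str) -> pd.Series:
    n = int(mask.sum())
    if n:
        report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + n
        report.n_dropped += n
    return ~mask


def read_effort_table(path, dialect: dict | None = None, sep: str = ","):
    """Read fisher-reported effort records from a delimited text file.

    Parameters
    ----------
    path : str or file-like
    dialect : dict, optional
        Mapping of canonical column name -> column name in the file.
    sep : str
        Field delimiter.

    Returns
    -------
    (DataFrame, LoadReport)
        Rows violating record invariants (unparseable times/numbers, end not
        after start, latitude out of range, non-positive gear depths) are
        dropped and tallied in the report, never silently.

    Raises
    ------
    FileNotFoundError, ValueError (missing mandatory column)
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in EFFORT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"effort table is missing mandatory column(s): {missing}")

    report = LoadReport(n_read=len(raw))
    df = raw.copy()
    for c in _TIME_COLS:
        df[c] = pd.to_datetime(df[c], errors="coerce")
    num_cols = ["vessel_length", "start_lat", "start_lon", "end_lat", "end_lon",
                "catch_weight", "groundline_depth", "headline_height", "trawl_speed"]
    for c in num_cols + [c for c in ("bottom_depth", "captures") if c in df.columns]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if "observed" in df.columns:
        df["observed"] = df["observed"].astype(str).str.lower().isin(["true", "1", "yes"])
    else:
        df["observed"] = False
    if "captures" not in df.columns:
        df["captures"] = np.nan

    keep = pd.Series(True, index=df.index)
    keep &= _drop(report, df[list(_TIME_COLS) + num_cols].isna().any(axis=1),
                  "unparseable_mandatory_field")
    keep &= _drop(report, keep & ~(df["end_time"] > df["start_time"]),
                  "end_not_after_start")
    lat_bad = (df[["start_lat", "end_lat"]].abs() > 90).any(axis=1)
    keep &= _drop(report, keep & lat_bad, "latitude_out_of_range")
    gear_bad = (df["groundline_depth"] <= 0) | (df["headline_height"] <= 0)
    keep &= _drop(report, keep & gear_bad, "nonpositive_gear_dimension")

    out = df.loc[keep].reset_index(drop=True)
    report.n_kept = len(out)
    return out, report


def read_observer_table(path, dialect: dict | None = None, sep: str = ","):
    """Read observer records (one per observed tow). Returns (DataFrame, LoadReport)."""
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in OBSERVER_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"observer table is missing mandatory column(s): {missing}")
    report = LoadReport(n_read=len(raw))
    df = raw.copy()
    for c in _TIME_COLS:
        df[c] = pd.to_datetime(df[c], errors="coerce")
    for c in ("start_lat", "start_lon", "captures"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    keep = pd.Series(True, index=df.index)
    keep &= _drop(report, df[["start_time", "end_time", "start_lat",
                              "start_lon", "captures"]].isna().any(axis=1),
                  "unparseable_mandatory_field")
    keep &= _drop(report, keep & ~(df["end_time"] > df["start_time"]),
                  "end_not_after_start")
    keep &= _drop(report, keep & (df["captures"] < 0), "negative_captures")
    out = df.loc[keep].reset_index(drop=True)
    out["captures"] = out["captures"].astype(int)
    report.n_kept = len(out)
    return out, report


def write_effort_table(df: pd.DataFrame, path) -> None:
    """Write an effort frame back to canonical CSV (ISO timestamps)."""
    out = df.copy()
    for c in _TIME_COLS:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between decimal-degree positions."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def link_observer_records(effort: pd.DataFrame, obs: pd.DataFrame,
                          time_tol_min: float = 60.0, dist_tol_km: float = 10.0):
    """Match observer records to effort tows; set ``observed`` and ``captures``.

    A match requires the same vessel and target species, start times within
    ``time_tol_min`` and start positions within ``dist_tol_km`` (great-circle).
    When several tows qualify for one observer record, the nearest in time is
    taken.  Two observer records resolving to the same tow raise
    :class:`AmbiguousLinkError`.

    Returns
    -------
    (linked effort DataFrame, unmatched observer DataFrame, LoadReport)
    """
    if effort.empty or obs.empty:
        raise ValueError("both effort and observer collections must be non-empty")
    if time_tol_min <= 0 or dist_tol_km <= 0:
        raise ValueError("tolerances must be positive")

    eff = effort.reset_index(drop=True).copy()
    eff["observed"] = eff.get("observed", False)
    if "captures" not in eff.columns:
        eff["captures"] = np.nan

    claimed: dict[int, int] = {}  # effort row -> observer row
    unmatched_idx = []
    eff_t = pd.to_datetime(eff["start_time"]).to_numpy()
    for oi, orec in obs.reset_index(drop=True).iterrows():
        cand = (eff["vessel_id"].astype(str).eq(str(orec["vessel_id"]))
                & eff["target_species"].astype(str).eq(str(orec["target_species"])))
        if cand.any():
            dt_min = np.abs((eff_t - np.datetime64(pd.Timestamp(orec["start_time"])))
                            / np.timedelta64(1, "m"))
            dist = haversine_km(eff["start_lat"].to_numpy(), eff["start_lon"].to_numpy(),
                                float(orec["start_lat"]), float(orec["start_lon"]))
            cand &= pd.Series(dt_min <= time_tol_min) & pd.Series(dist <= dist_tol_km)
        if not cand.any():
            unmatched_idx.append(oi)
            continue
        best = int(pd.Series(dt_min, index=eff.index)[cand].idxmin())
        if best in claimed:
            raise AmbiguousLinkError(
                f"observer records {claimed[best]} and {oi} both match effort tow "
                f"{eff.at[best, 'tow_id']}"
            )
        claimed[best] = oi
        eff.at[best, "observed"] = True
        eff.at[best, "captures"] = float(obs.reset_index(drop=True).at[oi, "captures"])

    report = LoadReport(n_read=len(obs), n_matched=len(claimed),
                        n_unmatched=len(unmatched_idx))
    return eff, obs.reset_index(drop=True).loc[unmatched_idx], report


def _derive_trips(df: pd.DataFrame, gap_days: float = 7.0) -> pd.Series:
    """Trip labels: explicit trip_id if present, else maximal runs of a vessel's
    tows with inter-tow gaps below ``gap_days``."""
    if "trip_id" in df.columns and df["trip_id"].notna().all():
        return df["trip_id"].astype(str)
    if df["start_time"].isna().any():
        raise ValueError(
            "cannot derive trips without start times; supply an explicit trip_id column"
        )
    trips = pd.Series("", index=df.index, dtype=object)
    for vessel, grp in df.groupby("vessel_id", sort=False):
        g = grp.sort_values("start_time")
        gaps = g["start_time"].diff() > pd.Timedelta(days=gap_days)
        trips.loc[g.index] = [f"{vessel}:{n}" for n in gaps.cumsum()]
    return trips


def filter_large_vessel_mackerel_fleet(tows: pd.DataFrame, min_length: float = 90.0,
                                       mackerel_codes=MACKEREL_CODES,
                                       trip_gap_days: float = 7.0) -> pd.DataFrame:
    """Restrict to the large-vessel mackerel fleet.

    Keeps every tow of every *trip* made by a vessel longer than ``min_length``
    metres that targeted a mackerel species on at least one tow of the trip;
    trips are kept or dropped atomically.
    """
    df = tows.copy()
    trips = _derive_trips(df, gap_days=trip_gap_days)
    is_mack = df["target_species"].astype(str).isin(set(mackerel_codes))
    trip_has_mack = is_mack.groupby(trips).transform("any")
    keep = (df["vessel_length"] > min_length) & trip_has_mack
    return df.loc[keep].reset_index(drop=True)


def assign_fishing_year(t):
    """New Zealand fishing-year label (1 October Y to 30 September Y+1 -> "Y-YY")."""
    ts = pd.to_datetime(t)
    if isinstance(ts, pd.Timestamp):
        y = ts.year - (1 if ts.month < 10 else 0)
        return f"{y}-{(y + 1) % 100:02d}"
    ser = pd.Series(pd.DatetimeIndex(ts))
    y = ser.dt.year - (ser.dt.month < 10).astype(int)
    return (y.astype(str) + "-" + ((y + 1) % 100).map("{:02d}".format)).to_numpy()


def fishing_year_index(t):
    """Integer fishing year (the calendar year containing its 1 October start)."""
    ts = pd.to_datetime(t)
    if isinstance(ts, pd.Timestamp):
        return ts.year - (1 if ts.month < 10 else 0)
    ser = pd.Series(pd.DatetimeIndex(ts))
    return (ser.dt.year - (ser.dt.month < 10).astype(int)).to_numpy()


def assign_subarea(lat, area: StudyArea | None = None):
    """North/south sub-area split at 39 deg 18 min S (boundary itself -> south)."""
    split = (area or StudyArea()).subarea_split_lat
    arr = np.asarray(lat, dtype=float)
    out = np.where(arr > split, "north", "south")
    return out.item() if out.ndim == 0 else out


def in_study_area(lat, lon, area: StudyArea | None = None):
    """True where a start position falls inside the rectangular study region."""
    a = area or StudyArea()
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    out = ((lat >= a.south_bound_lat) & (lat <= a.north_bound_lat)
           & (lon >= a.west_bound_lon) & (lon <= a.east_bound_lon))
    return bool(out) if out.ndim == 0 else out
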