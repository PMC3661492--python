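"""Per-tow covariate derivation and design-matrix assembly.

Covariates follow the fishery's capture-risk analysis: gear geometry (headline
depth = groundline depth minus headline height), tow timing (duration, night
hours, light condition from civil twilight and lunar illumination), position
(sub-area, bottom depth), and catch.  ``derive_covariates`` adds the derived
columns to an effort frame; ``build_design_matrix`` turns a list of
:class:`CovariateSpec` into the numeric matrix the models consume, with
log/log-offset transforms and treatment-coded factors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import astro
from .effort import assign_subarea, assign_fishing_year, fishing_year_index, StudyArea

__all__ = [
    "LIGHT_LEVELS",
    "MOONLIT_THRESHOLD",
    "SHALLOW_DEPTH_M",
    "CovariateSpec",
    "DesignMatrix",
    "DepthGrid",
    "InvalidGearError",
    "derive_headline_depth",
    "classify_depth_factor",
    "classify_light_condition",
    "night_hours",
    "day_hours",
    "lookup_bottom_depth",
    "derive_covariates",
    "build_design_matrix",
    "default_model_specs",
    "candidate_specs",
]

#: light-condition factor levels; "dark" is the model reference level
LIGHT_LEVELS = ("light", "dark", "black")
#: a night counts as moonlit when strictly more than 17% of the disc is lit
MOONLIT_THRESHOLD = 0.17
#: bottom-depth factor split: under 210 m is "shallow"
SHALLOW_DEPTH_M = 210.0


class InvalidGearError(ValueError):
    """Gear geometry that cannot yield a positive headline depth."""


def derive_headline_depth(groundline_depth, headline_height):
    """Depth of the net's headline: groundline depth minus headline height (m).

    Scalar inputs raise :class:`InvalidGearError` on a non-positive result;
    array inputs return NaN there (callers exclude and log those rows).
    """
    g = np.asarray(groundline_depth, dtype=float)
    h = np.asarray(headline_height, dtype=float)
    out = g - h
    if out.ndim == 0:
        if not out > 0:
            raise InvalidGearError(
                f"headline height {h} does not sit above the groundline depth {g}"
            )
        return float(out)
    return np.where(out > 0, out, np.nan)


def classify_depth_factor(bottom_depth):
    """'shallow' for water strictly less than 210 m deep, else 'deep'."""
    d = np.asarray(bottom_depth, dtype=float)
    out = np.where(d < SHALLOW_DEPTH_M, "shallow", "deep")
    return out.item() if out.ndim == 0 else out


def _night_bounds(dates, lat, lon, utc_offset):
    """(dusk of date d, dawn of date d+1) for each local calendar date."""
    d = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[D]")))
    _, dusk = astro.civil_twilight_times(d, lat, lon, utc_offset)
    dawn_next, _ = astro.civil_twilight_times(d + pd.Timedelta(days=1), lat, lon, utc_offset)
    return dusk, dawn_next


def classify_light_condition(haul_time, lat, lon, utc_offset=astro.NZ_UTC_OFFSET):
    """Three-level light factor for the net-haul instant.

    * light — hauled between civil dawn and dusk, or between dusk and local
      midnight on a moonlit night;
    * dark  — between dusk and midnight on a dark night, or between midnight
      and dawn on a moonlit night;
    * black — between midnight and dawn on a dark night.

    Moonlit means strictly more than 17% of the lunar disc illuminated at the
    haul time; midnight is 00:00 local civil time.
    """
    scalar = np.isscalar(haul_time) or isinstance(haul_time, (str, pd.Timestamp))
    t = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(haul_time)))
    lat = np.broadcast_to(np.asarray(lat, dtype=float), t.shape)
    lon = np.broadcast_to(np.asarray(lon, dtype=float), t.shape)
    date = t.normalize()
    dawn, dusk = astro.civil_twilight_times(date, lat, lon, utc_offset)
    t64 = t.to_numpy(dtype="datetime64[s]")
    moonlit = astro.moon_illuminated_fraction(t64, utc_offset) > MOONLIT_THRESHOLD

    daylight = (t64 >= dawn) & (t64 <= dusk)
    evening = t64 > dusk          # dusk -> following midnight
    # before dawn: the midnight -> dawn leg of the previous evening's night
    out = np.where(
        daylight, "light",
        np.where(evening,
                 np.where(moonlit, "light", "dark"),
                 np.where(moonlit, "dark", "black")),
    )
    return out.item() if scalar else out


def night_hours(start, end, lat, lon, utc_offset=astro.NZ_UTC_OFFSET):
    """Hours of the tow falling between civil dusk and the next civil dawn.

    Sums over every night the tow touches (tows under 48 h).
    """
    scalar = np.isscalar(start) or isinstance(start, (str, pd.Timestamp))
    s = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(start))).to_numpy("datetime64[s]")
    e = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(end))).to_numpy("datetime64[s]")
    if np.any(e <= s):
        raise ValueError("end must be after start")
    if np.any((e - s) > np.timedelta64(48, "h")):
        raise ValueError("tows longer than 48 h are not supported")
    lat = np.broadcast_to(np.asarray(lat, dtype=float), s.shape)
    lon = np.broadcast_to(np.asarray(lon, dtype=float), s.shape)

    total = np.zeros(s.shape, dtype=float)
    base = s.astype("datetime64[D]")
    for k in (-1, 0, 1, 2):  # nights whose dusk falls on start date + k
        dusk, dawn = _night_bounds(base + np.timedelta64(k, "D"), lat, lon, utc_offset)
        lo = np.maximum(s, dusk)
        hi = np.minimum(e, dawn)
        total += np.maximum((hi - lo) / np.timedelta64(1, "h"), 0.0)
    return float(total[0]) if scalar else total


def day_hours(start, end, lat, lon, utc_offset=astro.NZ_UTC_OFFSET):
    """Complement of :func:`night_hours` within the tow duration."""
    s = pd.to_datetime(start)
    e = pd.to_datetime(end)
    dur = (np.atleast_1d(e.to_numpy() if hasattr(e, "to_numpy") else np.datetime64(e))
           - np.atleast_1d(s.to_numpy() if hasattr(s, "to_numpy") else np.datetime64(s))
           ) / np.timedelta64(1, "h")
    nh = night_hours(start, end, lat, lon, utc_offset)
    out = dur - np.atleast_1d(nh)
    return float(out[0]) if np.isscalar(nh) else out


@dataclass
class DepthGrid:
    """Regular lat/lon bathymetry raster (plain-text ESRI ASCII grid layout).

    ``values`` is (nrows, ncols) with row 0 the northernmost; depths positive
    metres below the surface.
    """

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    @classmethod
    def from_ascii(cls, path) -> "DepthGrid":
        header = {}
        with open(path) as fh:
            lines = fh.read().split("\n")
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        vals = np.loadtxt(lines[i:], dtype=float)
        vals = vals.reshape(int(header["nrows"]), int(header["ncols"]))
        return cls(values=vals, xllcorner=header["xllcorner"],
                   yllcorner=header["yllcorner"], cellsize=header["cellsize"],
                   nodata=header.get("nodata_value", -9999.0))

    def at(self, lat, lon):
        """Nearest-cell depth; NaN outside the grid extent or at nodata cells."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        nrows, ncols = self.values.shape
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        row_s = np.floor((lat - self.yllcorner) / self.cellsize).astype(int)
        row = nrows - 1 - row_s
        ok = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        out = np.full(np.broadcast(lat, lon).shape, np.nan)
        oc, orw = np.clip(col, 0, ncols - 1), np.clip(row, 0, nrows - 1)
        vals = self.values[orw, oc]
        out = np.where(ok & (vals != self.nodata), vals, np.nan)
        return out.item() if out.ndim == 0 else out


def lookup_bottom_depth(tows: pd.DataFrame, grid: DepthGrid):
    """Minimum of the nearest-cell depths at the start and end positions (m)."""
    d0 = grid.at(tows["start_lat"].to_numpy(), tows["start_lon"].to_numpy())
    d1 = grid.at(tows["end_lat"].to_numpy(), tows["end_lon"].to_numpy())
    return np.fmin(d0, d1)  # fmin: one missing end falls back to the other


@dataclass
class CovariateSpec:
    """One model term: a derived column plus its transform or factor coding."""

    name: str
    source: str
    transform: str = "identity"          # identity | log | log_offset
    offset: float = 0.0                  # used only with log_offset
    levels: tuple = ()                   # factor levels, reference first
    label: str | None = None

    def __post_init__(self):
        if self.transform not in ("identity", "log", "log_offset", "factor"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "log_offset" and self.offset <= 0:
            raise ValueError("log_offset requires a positive offset")
        if self.levels and self.transform != "factor":
            raise ValueError("factor levels given for a non-factor covariate")

    @property
    def is_factor(self) -> bool:
        return self.transform == "factor"

    def column_names(self) -> list[str]:
        if self.is_factor:
            return [f"{self.name}[{lv}]" for lv in self.levels[1:]]
        return [self.name]


@dataclass
class DesignMatrix:
    """Model-ready covariates for a set of tows.

    ``X`` rows align with ``frame`` rows (the retained tows).  ``y`` is the
    capture-event indicator and ``counts`` the event size; both are NaN-free
    only on observed rows.  ``year_index`` codes fishing years 0..T-1 in
    ``year_levels`` order.
    """

    X: pd.DataFrame
    frame: pd.DataFrame
    year_index: np.ndarray
    year_levels: list
    observed: np.ndarray
    y: np.ndarray                        # event indicator (NaN if unobserved)
    counts: np.ndarray                   # captures (NaN if unobserved)
    specs: list = field(default_factory=list)
    n_excluded: int = 0

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def observed_subset(self) -> "DesignMatrix":
        m = self.observed.astype(bool)
        return DesignMatrix(
            X=self.X.loc[m].reset_index(drop=True),
            frame=self.frame.loc[m].reset_index(drop=True),
            year_index=self.year_index[m], year_levels=self.year_levels,
            observed=self.observed[m], y=self.y[m], counts=self.counts[m],
            specs=self.specs, n_excluded=self.n_excluded,
        )


def derive_covariates(tows: pd.DataFrame, grid: DepthGrid | None = None,
                      area: StudyArea | None = None,
                      utc_offset: float = astro.NZ_UTC_OFFSET) -> pd.DataFrame:
    """Attach all derived covariate columns to an effort frame.

    Adds: tow_duration_h, headline_depth, light_condition, subarea,
    fishing_year / fishing_year_label, night_hours, moon_fraction, month,
    season, and (when a grid or bottom_depth column is available) bottom_depth
    and depth_factor.
    """
    df = tows.copy()
    start = pd.to_datetime(df["start_time"])
    end = pd.to_datetime(df["end_time"])
    df["tow_duration_h"] = (end - start).dt.total_seconds() / 3600.0
    df["headline_depth"] = derive_headline_depth(
        df["groundline_depth"].to_numpy(), df["headline_height"].to_numpy())
    lat = df["start_lat"].to_numpy()
    lon = df["start_lon"].to_numpy()
    df["light_condition"] = classify_light_condition(end, lat, lon, utc_offset)
    df["night_hours"] = night_hours(start, end, lat, lon, utc_offset)
    df["moon_fraction"] = astro.moon_illuminated_fraction(
        end.to_numpy(dtype="datetime64[s]"), utc_offset)
    df["subarea"] = assign_subarea(lat, area)
    df["fishing_year"] = fishing_year_index(start)
    df["fishing_year_label"] = assign_fishing_year(start)
    df["month"] = start.dt.month
    df["season"] = ((start.dt.month - 1) // 3 + 1)  # calendar quarters
    if grid is not None:
        df["bottom_depth"] = lookup_bottom_depth(df, grid)
    if "bottom_depth" in df.columns:
        df["depth_factor"] = np.where(df["bottom_depth"].notna(),
                                      classify_depth_factor(df["bottom_depth"].fillna(1.0)),
                                      None)
    return df


def default_model_specs() -> list[CovariateSpec]:
    """The four covariates retained by the capture-event model."""
    return [
        CovariateSpec("headline_depth", "headline_depth"),
        CovariateSpec("log_tow_duration", "tow_duration_h", transform="log"),
        CovariateSpec("light_condition", "light_condition", transform="factor",
                      levels=("dark", "light", "black")),
        CovariateSpec("subarea", "subarea", transform="factor",
                      levels=("north", "south")),
    ]


def candidate_specs(include_depth: bool = False) -> list[CovariateSpec]:
    """The stepwise-selection candidate pool.

    Continuous tow descriptors enter both raw and log-transformed (offsets of
    one tonne / one hour added to catch weight and night hours before the log);
    bottom-depth terms require a depth source and are off by default.
    """
    specs = [
        CovariateSpec("trawl_speed", "trawl_speed"),
        CovariateSpec("tow_duration", "tow_duration_h"),
        CovariateSpec("log_tow_duration", "tow_duration_h", transform="log"),
        CovariateSpec("fishing_depth", "groundline_depth"),
        CovariateSpec("log_fishing_depth", "groundline_depth", transform="log"),
        CovariateSpec("headline_height", "headline_height"),
        CovariateSpec("headline_depth", "headline_depth"),
        CovariateSpec("catch_weight", "catch_weight"),
        CovariateSpec("log_catch_weight", "catch_weight", transform="log_offset",
                      offset=1.0),
        CovariateSpec("subarea", "subarea", transform="factor",
                      levels=("north", "south")),
        CovariateSpec("light_condition", "light_condition", transform="factor",
                      levels=("dark", "light", "black")),
        CovariateSpec("moon_illumination", "moon_fraction"),
        CovariateSpec("night_hours", "night_hours"),
        CovariateSpec("log_night_hours", "night_hours", transform="log_offset",
                      offset=1.0),
        CovariateSpec("season", "season", transform="factor", levels=(1, 2, 3, 4)),
    ]
    if include_depth:
        specs += [
            CovariateSpec("bottom_depth", "bottom_depth"),
            CovariateSpec("log_bottom_depth", "bottom_depth", transform="log"),
            CovariateSpec("depth_factor", "depth_factor", transform="factor",
                          levels=("deep", "shallow")),
        ]
    return specs


def _spec_columns(df: pd.DataFrame, spec: CovariateSpec) -> pd.DataFrame:
    src = df[spec.source]
    if spec.is_factor:
        out = {}
        for lv in spec.levels[1:]:
            out[f"{spec.name}[{lv}]"] = (src == lv).astype(float)
        bad = ~src.isin(list(spec.levels))
        cols = pd.DataFrame(out, index=df.index)
        cols[bad] = np.nan
        return cols
    x = pd.to_numeric(src, errors="coerce").astype(float)
    if spec.transform == "log":
        x = np.log(x.where(x > 0))
    elif spec.transform == "log_offset":
        x = np.log(x.where(x >= 0) + spec.offset)
    return x.rename(spec.name).to_frame()


def build_design_matrix(tows: pd.DataFrame, specs: list[CovariateSpec] | None = None
                        ) -> DesignMatrix:
    """Assemble the capture-event design matrix from a covariate-annotated frame.

    Rows with any underivable covariate are excluded (and counted); factor
    columns are treatment-coded against each spec's reference level.
    """
    specs = default_model_specs() if specs is None else specs
    df = tows.reset_index(drop=True)
    blocks = [_spec_columns(df, s) for s in specs]
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)
    ok = ~X.isna().any(axis=1)
    if not ok.any():
        raise ValueError("no rows with a complete covariate set; empty design")
    X = X.loc[ok].reset_index(drop=True)
    kept = df.loc[ok].reset_index(drop=True)

    years = sorted(kept["fishing_year"].unique())
    year_map = {y: i for i, y in enumerate(years)}
    year_index = kept["fishing_year"].map(year_map).to_numpy()
    observed = kept["observed"].to_numpy(dtype=bool) if "observed" in kept else \
        np.zeros(len(kept), dtype=bool)
    counts = pd.to_numeric(kept.get("captures"), errors="coerce").to_numpy(dtype=float)
    y = np.where(observed, (counts > 0).astype(float), np.nan)
    counts = np.where(observed, counts, np.nan)
    return DesignMatrix(X=X, frame=kept, year_index=year_index, year_levels=years,
                        observed=observed, y=y, counts=counts, specs=list(specs),
                        n_excluded=int((~ok).sum()))
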