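"""Gridded monthly seawater temperature and δ18Ow fields.

Ingests CF-style netCDF or long-format CSV encodings of monthly climatology
fields, reduces them (depth averaging over the upper water column,
multi-year trailing climatology), extracts area-weighted site series with
derived δ18Oc*/δ18Op* seasonal envelopes, and summarizes forward-modelled
δ18Op* isoscapes as mean ± 2σ over a region.

Grids are carried as :class:`ClimateGrid`, a thin wrapper over an
``xarray.Dataset`` with ``temperature`` and ``d18Ow`` variables on
``(month, lat, lon)``. Land cells are NaN (an explicit missing marker,
never zero). Loaders normalize orientation to ascending latitude and
longitudes in [−180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr

from . import isotopes

__all__ = [
    "ClimateGrid",
    "SiteSpec",
    "MonthlyEnvelope",
    "GridLoadError",
    "load_grid",
    "save_grid",
    "depth_average",
    "climatology_mean",
    "extract_site_series",
    "isoscape",
    "plot_isoscape",
    "SEYMOUR_ISLAND",
    "SOUTHERN_CHILE",
]


class GridLoadError(ValueError):
    """A grid file failed validation (missing variable, bad shape, months absent)."""


MONTHS = np.arange(1, 13)


@dataclass
class SiteSpec:
    """A named lat/lon box used for site extraction and regional summaries.

    The default boxes below are editable placeholders for the Seymour
    Island and southern Chile extraction regions; set them from the
    archived region definitions when working with real model output.
    """

    name: str
    lat_bounds: tuple[float, float]
    lon_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lat_bounds[0] > self.lat_bounds[1]:
            self.lat_bounds = (self.lat_bounds[1], self.lat_bounds[0])
        if self.lon_bounds[0] > self.lon_bounds[1]:
            self.lon_bounds = (self.lon_bounds[1], self.lon_bounds[0])

    @classmethod
    def from_dict(cls, d: dict) -> "SiteSpec":
        return cls(d["name"], tuple(d["lat_bounds"]), tuple(d["lon_bounds"]))


# Placeholder extraction boxes (editable config; see class docstring).
SEYMOUR_ISLAND = SiteSpec("Seymour Island", (-66.5, -62.0), (-60.0, -53.0))
SOUTHERN_CHILE = SiteSpec("southern Chile", (-56.0, -50.0), (-76.0, -68.0))


@dataclass
class ClimateGrid:
    """Monthly gridded seawater temperature (°C) and δ18Ow (‰ VSMOW)."""

    data: xr.Dataset
    co2_case: str = "3x"
    depth_averaged_to: float = 25.0

    def __post_init__(self) -> None:
        ds = self.data
        for name in ("temperature", "d18Ow"):
            if name not in ds:
                raise GridLoadError(f"missing variable {name!r}")
        if ds["temperature"].shape != ds["d18Ow"].shape:
            raise GridLoadError("temperature and d18Ow shapes differ")
        for dim in ("month", "lat", "lon"):
            if dim not in ds.dims:
                raise GridLoadError(f"missing dimension {dim!r}")
        if sorted(np.asarray(ds["month"]).tolist()) != MONTHS.tolist():
            raise GridLoadError("months must be complete 1-12")
        # normalize orientation
        ds = ds.sortby("month")
        lon = ((np.asarray(ds["lon"]) + 180.0) % 360.0) - 180.0
        ds = ds.assign_coords(lon=lon).sortby("lon").sortby("lat")
        self.data = ds

    @property
    def temperature(self) -> xr.DataArray:
        return self.data["temperature"]

    @property
    def d18Ow(self) -> xr.DataArray:
        return self.data["d18Ow"]

    def subset(self, site: SiteSpec) -> xr.Dataset:
        sub = self.data.sel(
            lat=slice(*site.lat_bounds), lon=slice(*site.lon_bounds)
        )
        if sub.sizes.get("lat", 0) == 0 or sub.sizes.get("lon", 0) == 0:
            raise ValueError(f"site {site.name!r} does not intersect the grid")
        return sub

    def equals(self, other: "ClimateGrid", atol: float = 1e-9) -> bool:
        a, b = self.data, other.data
        return (
            bool(np.allclose(a["temperature"], b["temperature"], atol=atol, equal_nan=True))
            and bool(np.allclose(a["d18Ow"], b["d18Ow"], atol=atol, equal_nan=True))
            and np.allclose(a["lat"], b["lat"])
            and np.allclose(a["lon"], b["lon"])
        )


@dataclass
class MonthlyEnvelope:
    """Per-site 12-month series of T, δ18Ow and forward-predicted δ18Oc*/δ18Op*.

    ``d18Oc_star`` is ‰ VPDB (aragonite thermometer inverse), ``d18Op_star``
    is ‰ VSMOW (phosphate thermometer inverse). Min/max over months define
    the seasonal envelope used for habitat and bivalve comparisons.
    """

    site: SiteSpec
    temperature: np.ndarray
    d18Ow: np.ndarray
    d18Oc_star: np.ndarray = field(init=False)
    d18Op_star: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        w = np.asarray(self.d18Ow, dtype=float)
        if t.shape != (12,) or w.shape != (12,):
            raise ValueError("monthly series must have length 12")
        self.temperature = t
        self.d18Ow = w
        self.d18Oc_star = isotopes.predict_d18Oc(t, w)
        self.d18Op_star = isotopes.predict_d18Op(t, w)

    def range_of(self, series: str) -> tuple[float, float]:
        v = getattr(self, series)
        return float(np.min(v)), float(np.max(v))

    @property
    def warmest_month(self) -> int:
        return int(MONTHS[np.argmax(self.temperature)])

    @property
    def coldest_month(self) -> int:
        return int(MONTHS[np.argmin(self.temperature)])

    def summary(self) -> dict:
        out = {"site": self.site.name,
               "warmest_month": self.warmest_month,
               "coldest_month": self.coldest_month}
        for s in ("temperature", "d18Ow", "d18Oc_star", "d18Op_star"):
            lo, hi = self.range_of(s)
            out[f"{s}_min"], out[f"{s}_max"] = lo, hi
        return out


# ---------------------------------------------------------------------------
# I/O

def save_grid(grid: ClimateGrid, path) -> None:
    """Write a grid as CF-style netCDF (.nc) or long-format CSV (.csv)."""
    path = Path(path)
    if path.suffix == ".csv":
        df = grid.data.to_dataframe().reset_index()
        df["co2_case"] = grid.co2_case
        df["depth_averaged_to"] = grid.depth_averaged_to
        df.to_csv(path, index=False)
    else:
        ds = grid.data.copy()
        ds.attrs.update(
            co2_case=grid.co2_case, depth_averaged_to=grid.depth_averaged_to
        )
        ds["temperature"].attrs.setdefault("units", "degC")
        ds["d18Ow"].attrs.setdefault("units", "permil VSMOW")
        ds.to_netcdf(path, engine="scipy")


def load_grid(path, co2_case: str | None = None) -> ClimateGrid:
    """Load a :class:`ClimateGrid` from netCDF or long-format CSV.

    CSV files need columns (month, lat, lon, temperature, d18Ow); an
    optional ``depth`` column is depth-averaged on load.
    """
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        for col in ("month", "lat", "lon", "temperature", "d18Ow"):
            if col not in df.columns:
                raise GridLoadError(f"missing variable {col!r}")
        case = co2_case or (str(df["co2_case"].iloc[0]) if "co2_case" in df else "3x")
        depth_to = float(df["depth_averaged_to"].iloc[0]) if "depth_averaged_to" in df else 25.0
        ds = (
            df.set_index(["month", "lat", "lon"])[["temperature", "d18Ow"]]
            .to_xarray()
        )
        return ClimateGrid(ds, co2_case=case, depth_averaged_to=depth_to)
    ds = xr.open_dataset(path, engine="scipy").load()
    units = str(ds["temperature"].attrs.get("units", "")) if "temperature" in ds else ""
    if units and "K" in units and "deg" not in units.lower():
        raise GridLoadError("temperature units must be degrees Celsius")
    case = co2_case or str(ds.attrs.get("co2_case", "3x"))
    depth_to = float(ds.attrs.get("depth_averaged_to", 25.0))
    return ClimateGrid(ds, co2_case=case, depth_averaged_to=depth_to)


# ---------------------------------------------------------------------------
# Reductions

def depth_average(
    values: np.ndarray,
    depth_top: np.ndarray,
    depth_bottom: np.ndarray,
    max_depth: float = 25.0,
    axis: int = 0,
) -> np.ndarray:
    """Thickness-weighted mean over depth layers down to ``max_depth`` meters.

    Layers whose tops lie above ``max_depth`` contribute; a partial bottom
    layer is clipped at ``max_depth``. Depths are meters below surface,
    positive downward.
    """
    tops = np.asarray(depth_top, dtype=float)
    bottoms = np.asarray(depth_bottom, dtype=float)
    if np.any(bottoms <= tops):
        raise ValueError("layer bottoms must lie below tops")
    eff_bottom = np.minimum(bottoms, max_depth)
    thickness = np.clip(eff_bottom - tops, 0.0, None)
    if not np.any(thickness > 0):
        raise ValueError(f"no depth levels above {max_depth} m")
    v = np.asarray(values, dtype=float)
    shape = [1] * v.ndim
    shape[axis] = len(thickness)
    w = thickness.reshape(shape)
    return np.sum(v * w, axis=axis) / np.sum(thickness)


def climatology_mean(multi_year: xr.Dataset, last_n_years: int = 100) -> xr.Dataset:
    """Per-month mean over the trailing ``last_n_years`` of a (year, month, ...) dataset."""
    if "year" not in multi_year.dims:
        raise ValueError("dataset must have a 'year' dimension")
    n_avail = multi_year.sizes["year"]
    if last_n_years > n_avail:
        raise ValueError(
            f"window of {last_n_years} years exceeds the {n_avail} available"
        )
    years = np.sort(np.asarray(multi_year["year"]))[-last_n_years:]
    return multi_year.sel(year=years).mean("year")


def _area_weights(sub: xr.Dataset, mask: xr.DataArray, weighted: bool = True) -> xr.DataArray:
    if weighted:
        w = np.cos(np.deg2rad(sub["lat"]))
    else:
        w = xr.ones_like(sub["lat"], dtype=float)
    return w.broadcast_like(mask).where(mask)


def extract_site_series(
    grid: ClimateGrid, site: SiteSpec, area_weighted: bool = True
) -> MonthlyEnvelope:
    """Area-weighted (cos-latitude) monthly mean series over ocean cells in a site box.

    Derived δ18Oc*/δ18Op* series and their seasonal extrema come with the
    returned :class:`MonthlyEnvelope`.
    """
    sub = grid.subset(site)
    ocean = sub["temperature"].notnull().all("month") & sub["d18Ow"].notnull().all("month")
    if not bool(ocean.any()):
        raise ValueError(f"site {site.name!r} contains no ocean cells")
    w = _area_weights(sub, ocean)
    t = sub["temperature"].weighted(w.fillna(0.0)).mean(("lat", "lon"))
    d = sub["d18Ow"].weighted(w.fillna(0.0)).mean(("lat", "lon"))
    return MonthlyEnvelope(site, np.asarray(t), np.asarray(d))


def isoscape(
    grid: ClimateGrid,
    region: SiteSpec,
    month_aggregation: Literal["annual_mean", "per_month"] = "annual_mean",
    area_weighted: bool = True,
    sd_ddof: int = 1,
) -> tuple[xr.DataArray, dict]:
    """Cell-wise forward-predicted δ18Op* map over a region, with mean ± 2σ summary.

    δ18Op* is the phosphate-thermometer inverse applied to each (T, δ18Ow)
    cell. The summary (mean, sd, mean±2σ) pools non-missing ocean cells in
    the region, area-weighted by cos(latitude); ``sd_ddof=1`` selects the
    sample-SD convention (reliability-corrected for weights).
    """
    sub = grid.subset(region)
    field_map = xr.DataArray(
        isotopes.predict_d18Op(sub["temperature"].values, sub["d18Ow"].values),
        coords=sub["temperature"].coords,
        name="d18Op_star",
    )
    if month_aggregation == "annual_mean":
        field_map = field_map.mean("month")
    elif month_aggregation != "per_month":
        raise ValueError(f"unknown month_aggregation {month_aggregation!r}")

    mask = field_map.notnull()
    if not bool(mask.any()):
        raise ValueError(f"region {region.name!r} has no ocean cells")
    w = _area_weights(sub, mask, area_weighted).broadcast_like(field_map).where(mask)
    wn = (w / w.sum()).fillna(0.0)
    x = field_map.fillna(0.0)
    mean = float((wn * x).sum())
    var = float((wn * (x - mean) ** 2).sum())
    if sd_ddof == 1:
        denom = 1.0 - float((wn**2).sum())
        var = var / denom if denom > 0 else np.nan
    sd = float(np.sqrt(var))
    summary = {
        "region": region.name,
        "co2_case": grid.co2_case,
        "n_cells": int(mask.sum()),
        "mean": mean,
        "sd": sd,
        "mean_minus_2sd": mean - 2 * sd,
        "mean_plus_2sd": mean + 2 * sd,
    }
    return field_map, summary


def plot_isoscape(field_map: xr.DataArray, path, title: str | None = None) -> None:
    """Render a δ18Op* map (annual mean if a month dimension remains) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = field_map.mean("month") if "month" in field_map.dims else field_map
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(data["lon"], data["lat"], data.values, shading="auto")
    fig.colorbar(mesh, ax=ax, label="δ18Op* (‰ VSMOW)")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
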