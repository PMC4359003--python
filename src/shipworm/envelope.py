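"""Mechanistic climate-envelope model for shipworm reproduction/metamorphosis.

The envelope is defined by published lower physiological tolerance limits of
*Teredo navalis*: larval metamorphosis requires temperature >= 12 degC while
adult reproduction requires only >= 11 degC; both require salinity >= 8 PSU
and dissolved oxygen >= 4 mg O2 l^-1.  Monthly mean conditions in two water
layers — a "surface" layer (upper 9 m, the larval settlement habitat) and a
"bottom" layer (lowest 2 m above the seabed, potential adult source
populations) — are classified cell-by-cell as favourable when all three
thresholds are met simultaneously (inclusive comparisons).  Where the water
column is <= 9 m deep the two layers may overlap.

Classified cell-months are aggregated into frequency-of-occurrence maps:

* overall      — % of all cell-months over a period of years;
* by month     — % of years in which a given calendar month is favourable;
* period-month — the by-month frequency evaluated separately over a list of
  (quasi-decadal) year ranges, to expose trends such as a lengthening of the
  favourable season under surface warming.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthetic import (
    Bathymetry,
    ConfigurationError,
    FormatError,
    GridSpec,
    HydroFieldSet,
)

__all__ = [
    "EnvelopeThresholds",
    "LayerModel",
    "SURFACE",
    "BOTTOM",
    "LayerFields",
    "MonthlyLayerState",
    "FavourabilityMask",
    "FrequencyMap",
    "extract_layer",
    "monthly_bin",
    "classify",
    "frequency_overall",
    "frequency_by_month",
    "frequency_period_month",
    "mask_to_table",
    "export_map",
    "read_esri_ascii",
    "read_geotiff",
]


@dataclass(frozen=True)
class EnvelopeThresholds:
    """Lower tolerance limits (inclusive) for favourable conditions."""

    temp_min_metamorphosis: float = 12.0  # degC, larval metamorphosis + reproduction
    temp_min_reproduction: float = 11.0  # degC, adult reproduction only
    sal_min: float = 8.0  # PSU
    oxy_min: float = 4.0  # mg O2 / l

    def __post_init__(self) -> None:
        vals = (
            self.temp_min_metamorphosis,
            self.temp_min_reproduction,
            self.sal_min,
            self.oxy_min,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ConfigurationError("all thresholds must be finite")
        if self.temp_min_metamorphosis < self.temp_min_reproduction:
            raise ConfigurationError(
                "metamorphosis temperature threshold cannot be below the "
                "reproduction threshold"
            )


@dataclass(frozen=True)
class LayerModel:
    """Which water layer is classified, and with which temperature column.

    The surface model uses the stricter metamorphosis+reproduction thresholds;
    the bottom model uses the reproduction-only column.
    """

    name: str  # "surface" | "bottom"
    surface_depth_limit: float = 9.0  # m
    bottom_thickness: float = 2.0  # m

    def __post_init__(self) -> None:
        if self.name not in {"surface", "bottom"}:
            raise ConfigurationError("layer name must be 'surface' or 'bottom'")

    def temp_min(self, thresholds: EnvelopeThresholds) -> float:
        if self.name == "surface":
            return thresholds.temp_min_metamorphosis
        return thresholds.temp_min_reproduction


SURFACE = LayerModel("surface")
BOTTOM = LayerModel("bottom")


@dataclass
class LayerFields:
    """Per-time, per-cell layer means of the three variables [time, lat, lon]."""

    grid: GridSpec
    times: np.ndarray
    layer: LayerModel
    temperature: np.ndarray
    salinity: np.ndarray
    oxygen: np.ndarray


@dataclass
class MonthlyLayerState:
    """Monthly-mean layer conditions; ``months`` is a list of (year, month)."""

    grid: GridSpec
    months: list[tuple[int, int]]
    layer: LayerModel
    temperature: np.ndarray  # [month, lat, lon]
    salinity: np.ndarray
    oxygen: np.ndarray


@dataclass
class FavourabilityMask:
    """Boolean favourability per cell-month, with a defined-data mask."""

    grid: GridSpec
    months: list[tuple[int, int]]
    layer: LayerModel
    favourable: np.ndarray  # bool [month, lat, lon]
    defined: np.ndarray  # bool [month, lat, lon]


@dataclass
class FrequencyMap:
    """Percentage of classified time units favourable, per cell (NaN on land)."""

    grid: GridSpec
    percent_favourable: np.ndarray  # [lat, lon], 0..100 or NaN
    aggregation: str  # "overall" | "by_month" | "period_month"
    layer: LayerModel
    period: tuple[int, int]
    month: int | None = None


# ---------------------------------------------------------------------------
# Layer extraction
# ---------------------------------------------------------------------------


def _layer_weights(
    grid: GridSpec, bathy: Bathymetry, layer: LayerModel
) -> np.ndarray:
    """Thickness overlap (m) of each depth bin with the layer, [depth, lat, lon].

    Surface layer: [0, min(surface_depth_limit, local depth)].
    Bottom layer:  [max(local depth - bottom_thickness, 0), local depth].
    """
    depth = bathy.depth  # [lat, lon]
    if layer.name == "surface":
        lo = np.zeros_like(depth)
        hi = np.minimum(layer.surface_depth_limit, depth)
    else:
        lo = np.maximum(depth - layer.bottom_thickness, 0.0)
        hi = depth
    edges_lo = grid.depth_edges[:-1][:, None, None]
    edges_hi = grid.depth_edges[1:][:, None, None]
    w = np.minimum(edges_hi, hi[None]) - np.maximum(edges_lo, lo[None])
    w = np.clip(w, 0.0, None)
    w[:, bathy.land_mask] = 0.0
    return w


def extract_layer(
    fields: HydroFieldSet, bathy: Bathymetry, layer: LayerModel
) -> LayerFields:
    """Thickness-weighted layer mean of T, S, O2 for every time step and cell."""
    grid = fields.grid
    w = _layer_weights(grid, bathy, layer)  # [z, y, x]
    wsum = w.sum(axis=0)  # [y, x]
    sea = bathy.sea_mask
    if np.any((wsum <= 0) & sea):
        raise RuntimeError(
            "layer does not intersect the water column at some sea cell; "
            "depth axis cannot resolve the layer"
        )

    def wmean(arr: np.ndarray) -> np.ndarray:
        prod = np.where(w[None] > 0, arr * w[None], 0.0)
        out = prod.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = out / wsum[None]
        out[:, ~sea] = np.nan
        return out

    return LayerFields(
        grid,
        fields.times,
        layer,
        wmean(fields.temperature),
        wmean(fields.salinity),
        wmean(fields.oxygen),
    )


# ---------------------------------------------------------------------------
# Monthly binning and classification
# ---------------------------------------------------------------------------


def monthly_bin(layer_fields: LayerFields) -> MonthlyLayerState:
    """Arithmetic mean of all time steps falling in each calendar (year, month)."""
    idx = pd.DatetimeIndex(layer_fields.times.astype("datetime64[ns]"))
    periods = idx.to_period("M")
    uniq = periods.unique().sort_values()
    months = [(p.year, p.month) for p in uniq]
    shape = (len(months), layer_fields.grid.n_lat, layer_fields.grid.n_lon)
    out = {}
    for name in ("temperature", "salinity", "oxygen"):
        arr = getattr(layer_fields, name)
        res = np.empty(shape)
        for k, p in enumerate(uniq):
            res[k] = arr[periods == p].mean(axis=0)
        out[name] = res
    return MonthlyLayerState(layer_fields.grid, months, layer_fields.layer, **out)


def classify(
    state: MonthlyLayerState,
    thresholds: EnvelopeThresholds,
    layer: LayerModel | None = None,
    ignore_oxygen: bool = False,
) -> FavourabilityMask:
    """Favourable <=> T >= T_min AND S >= sal_min AND O2 >= oxy_min (inclusive).

    ``ignore_oxygen`` drops the oxygen criterion, which is useful for testing
    whether oxygen is ever the limiting factor.
    """
    layer = layer if layer is not None else state.layer
    t_min = layer.temp_min(thresholds)
    defined = (
        np.isfinite(state.temperature)
        & np.isfinite(state.salinity)
        & np.isfinite(state.oxygen)
    )
    fav = (state.temperature >= t_min) & (state.salinity >= thresholds.sal_min)
    if not ignore_oxygen:
        fav = fav & (state.oxygen >= thresholds.oxy_min)
    fav = fav & defined
    return FavourabilityMask(state.grid, state.months, layer, fav, defined)


# ---------------------------------------------------------------------------
# Frequency aggregations
# ---------------------------------------------------------------------------


def _period_index(mask: FavourabilityMask, period: tuple[int, int]) -> np.ndarray:
    y0, y1 = int(period[0]), int(period[1])
    if y1 < y0:
        raise ConfigurationError("period must satisfy last year >= first year")
    sel = np.array([y0 <= y <= y1 for (y, _m) in mask.months])
    if not sel.any():
        raise ConfigurationError(f"no classified months fall in period {period}")
    return sel


def _percent(fav: np.ndarray, defined: np.ndarray) -> np.ndarray:
    n_def = defined.sum(axis=0).astype(float)
    n_fav = (fav & defined).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * n_fav / n_def
    pct[n_def == 0] = np.nan
    return pct


def frequency_overall(mask: FavourabilityMask, period: tuple[int, int]) -> FrequencyMap:
    """Percent of all defined cell-months favourable within the year range."""
    sel = _period_index(mask, period)
    pct = _percent(mask.favourable[sel], mask.defined[sel])
    return FrequencyMap(mask.grid, pct, "overall", mask.layer, (int(period[0]), int(period[1])))


def frequency_by_month(
    mask: FavourabilityMask, period: tuple[int, int], month: int
) -> FrequencyMap:
    """Percent of years (within the range) in which ``month`` is favourable."""
    if not 1 <= int(month) <= 12:
        raise ConfigurationError("month must be 1..12")
    sel = _period_index(mask, period) & np.array(
        [m == int(month) for (_y, m) in mask.months]
    )
    if not sel.any():
        raise ConfigurationError(f"month {month} has no data in period {period}")
    pct = _percent(mask.favourable[sel], mask.defined[sel])
    return FrequencyMap(
        mask.grid, pct, "by_month", mask.layer, (int(period[0]), int(period[1])), int(month)
    )


def frequency_period_month(
    mask: FavourabilityMask, periods: Sequence[tuple[int, int]], month: int
) -> list[FrequencyMap]:
    """By-month frequency evaluated over each of several disjoint year ranges."""
    if not periods:
        raise ConfigurationError("periods must be non-empty")
    years_seen: set[int] = set()
    for y0, y1 in periods:
        span = set(range(int(y0), int(y1) + 1))
        if span & years_seen:
            raise ConfigurationError("periods must be disjoint")
        years_seen |= span
    maps = [frequency_by_month(mask, p, month) for p in periods]
    for m in maps:
        m.aggregation = "period_month"
    return maps


def mask_to_table(mask: FavourabilityMask) -> pd.DataFrame:
    """Long-format (cell, year, month, layer, favourable) table of sea cell-months."""
    rows = []
    ny, nx = mask.grid.n_lat, mask.grid.n_lon
    for k, (year, month) in enumerate(mask.months):
        defined = mask.defined[k]
        iy, ix = np.nonzero(defined)
        rows.append(
            pd.DataFrame(
                {
                    "cell": mask.grid.flat_index(iy, ix),
                    "year": year,
                    "month": month,
                    "layer": mask.layer.name,
                    "favourable": mask.favourable[k][iy, ix],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Raster export
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def _grid_transform(grid: GridSpec) -> tuple[float, float, float, float]:
    dlon = float(np.diff(grid.lon_edges).mean())
    dlat = float(np.diff(grid.lat_edges).mean())
    return float(grid.lon_edges[0]), float(grid.lat_edges[-1]), dlon, dlat


def export_map(fmap: FrequencyMap, path, format: str = "esri_ascii") -> None:
    """Write a frequency map as a georeferenced raster.

    ``esri_ascii`` (Arc/Info ASCII grid) requires square cells — the format
    carries a single CELLSIZE; use ``geotiff`` for anisotropic grids.  Missing
    cells (land) are encoded as the nodata value (-9999).
    """
    grid = fmap.grid
    lon0, lat1, dlon, dlat = _grid_transform(grid)
    data = np.flipud(fmap.percent_favourable)  # row 0 = northernmost
    data = np.where(np.isfinite(data), data, _NODATA)
    if format == "esri_ascii":
        if abs(dlon - dlat) > 1e-9 * max(dlon, dlat):
            raise FormatError(
                "ESRI ASCII requires square cells (single CELLSIZE); "
                "use format='geotiff'"
            )
        header = (
            f"NCOLS {grid.n_lon}\n"
            f"NROWS {grid.n_lat}\n"
            f"XLLCORNER {grid.lon_edges[0]:.10g}\n"
            f"YLLCORNER {grid.lat_edges[0]:.10g}\n"
            f"CELLSIZE {dlon:.10g}\n"
            f"NODATA_VALUE {_NODATA:.10g}\n"
        )
        body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in data)
        with open(path, "w") as fh:
            fh.write(header + body + "\n")
    elif format == "geotiff":
        tifffile.imwrite(
            str(path),
            data.astype(np.float32),
            extratags=[
                (33550, "d", 3, (dlon, dlat, 0.0)),  # ModelPixelScale
                (33922, "d", 6, (0.0, 0.0, 0.0, lon0, lat1, 0.0)),  # ModelTiepoint
                (42113, "s", None, str(_NODATA)),  # GDAL nodata
            ],
        )
    else:
        raise FormatError(f"unknown raster format {format!r}")


def read_esri_ascii(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array south-up [lat, lon], header)."""
    header: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].upper() in {
                "NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE", "NODATA_VALUE",
            }:
                header[parts[0].upper()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows)
    nodata = header.get("NODATA_VALUE", _NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    return np.flipud(arr), header


def read_geotiff(path) -> tuple[np.ndarray, dict]:
    """Read a GeoTIFF written by :func:`export_map`; array is south-up."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = page.asarray().astype(float)
        tags = {}
        if 33550 in page.tags:
            tags["pixel_scale"] = tuple(page.tags[33550].value)
        if 33922 in page.tags:
            tags["tiepoint"] = tuple(page.tags[33922].value)
        if 42113 in page.tags:
            nodata = float(page.tags[42113].value)
            arr = np.where(arr == nodata, np.nan, arr)
            tags["nodata"] = nodata
    return np.flipud(arr), tags
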