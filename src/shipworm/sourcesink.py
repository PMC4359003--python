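"""Forward dispersal maps and backward source maps from a connectivity matrix.

A forward map answers "where do larvae released in this area end up?": the
mean, over the area's release cells, of their dispersal-probability rows.  A
backward map answers "where do larvae arriving in this area come from?": for
every release cell, the summed probability of ending anywhere in the target
area, normalised by its maximum to a relative source strength in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dispersal import ConnectivityMatrix
from .synthetic import Bathymetry, ConfigurationError, EARTH_RADIUS_M, GridSpec

__all__ = [
    "AreaDefinition",
    "DispersalMap",
    "SpreadSummary",
    "forward_map",
    "backward_map",
    "summarize_spread",
]


@dataclass(frozen=True)
class AreaDefinition:
    """A named set of sea grid cells (flat indices)."""

    name: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.unique(np.asarray(self.cells, dtype=int))
        object.__setattr__(self, "cells", cells)
        if cells.size == 0:
            raise ConfigurationError(f"area {self.name!r} is empty")

    @staticmethod
    def from_polygon(
        name: str,
        grid: GridSpec,
        bathy: Bathymetry,
        polygon: Sequence[tuple[float, float]],
    ) -> "AreaDefinition":
        """Resolve an area from a lon-lat polygon by cell-centroid containment."""
        from shapely.geometry import Point, Polygon

        poly = Polygon(polygon)
        lons, lats = np.meshgrid(grid.lon_centers, grid.lat_centers)
        inside = np.array(
            [poly.covers(Point(x, y)) for x, y in zip(lons.ravel(), lats.ravel())]
        ).reshape(lons.shape)
        inside &= bathy.sea_mask
        if not inside.any():
            raise ConfigurationError(f"polygon for {name!r} contains no sea cell")
        return AreaDefinition(name, grid.flat_index(*np.nonzero(inside)))

    def validate_sea(self, grid: GridSpec, bathy: Bathymetry) -> None:
        iy, ix = grid.unflatten(self.cells)
        if np.any(bathy.land_mask[iy, ix]):
            raise ConfigurationError(f"area {self.name!r} includes land cells")

    def centroid(self, grid: GridSpec) -> tuple[float, float]:
        iy, ix = grid.unflatten(self.cells)
        return float(grid.lon_centers[ix].mean()), float(grid.lat_centers[iy].mean())


@dataclass
class DispersalMap:
    """Per-cell relative dispersal probability for one area and direction.

    Forward maps hold raw mean probabilities; backward maps hold max-normalised
    relative source strengths with the unnormalised sums in ``raw_values``.
    """

    grid: GridSpec
    values: np.ndarray  # [lat, lon]
    direction: str  # "forward" | "backward"
    area: AreaDefinition
    raw_values: np.ndarray | None = None


def forward_map(P: ConnectivityMatrix, area: AreaDefinition) -> DispersalMap:
    """Mean dispersal-probability row over the area's release cells."""
    released = set(P.released_cells.tolist())
    missing = [c for c in area.cells if c not in released]
    if len(missing) == len(area.cells):
        raise ConfigurationError(
            f"area {area.name!r} shares no cells with the release set"
        )
    rows = np.asarray(P.P[area.cells].mean(axis=0)).ravel()
    grid = P.grid
    return DispersalMap(grid, rows.reshape(grid.n_lat, grid.n_lon), "forward", area)


def backward_map(P: ConnectivityMatrix, area: AreaDefinition) -> DispersalMap:
    """Relative strength of each release cell as a source of larvae to the area."""
    grid = P.grid
    bad = area.cells[(area.cells < 0) | (area.cells >= grid.n_cells)]
    if bad.size:
        raise ConfigurationError(f"area {area.name!r} has cells outside the grid")
    raw = np.asarray(P.P[:, area.cells].sum(axis=1)).ravel()
    peak = raw.max()
    values = raw / peak if peak > 0 else raw
    return DispersalMap(
        grid,
        values.reshape(grid.n_lat, grid.n_lon),
        "backward",
        area,
        raw_values=raw.reshape(grid.n_lat, grid.n_lon),
    )


@dataclass
class SpreadSummary:
    """Descriptive statistics of a dispersal map relative to its area."""

    philopatry_fraction: float  # probability mass inside the area / total
    east_fraction: float  # mass in cells east of the area centroid / total
    west_fraction: float
    max_beyond_distance: float  # largest value farther than distance_km away
    n_cells_beyond_threshold: int  # cells outside the area exceeding threshold
    threshold: float
    distance_km: float


def _distance_km(grid: GridSpec, lon0: float, lat0: float) -> np.ndarray:
    """Great-circle (haversine) distance of every cell centre from a point."""
    lons, lats = np.meshgrid(grid.lon_centers, grid.lat_centers)
    p1, p2 = np.deg2rad(lat0), np.deg2rad(lats)
    dphi = p2 - p1
    dlam = np.deg2rad(lons - lon0)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)) / 1000.0


def summarize_spread(
    dmap: DispersalMap, threshold: float = 0.005, distance_km: float = 50.0
) -> SpreadSummary:
    """Philopatry and directional spread of the probability mass in a map."""
    grid = dmap.grid
    values = np.where(np.isfinite(dmap.values), dmap.values, 0.0)
    total = values.sum()
    in_area = np.zeros(grid.n_cells, dtype=bool)
    in_area[dmap.area.cells] = True
    in_area = in_area.reshape(grid.n_lat, grid.n_lon)

    lon_c, lat_c = dmap.area.centroid(grid)
    lons = np.broadcast_to(grid.lon_centers, (grid.n_lat, grid.n_lon))
    east = values[(lons > lon_c)].sum()
    west = values[(lons < lon_c)].sum()

    dist = _distance_km(grid, lon_c, lat_c)
    far = dist > distance_km
    max_far = float(values[far].max()) if far.any() else 0.0

    beyond = (~in_area) & (values > threshold)
    if total > 0:
        phil = float(values[in_area].sum() / total)
        east_f, west_f = float(east / total), float(west / total)
    else:
        phil = east_f = west_f = 0.0
    return SpreadSummary(
        phil, east_f, west_f, max_far, int(beyond.sum()), threshold, distance_km
    )
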