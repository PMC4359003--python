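"""Synthetic Baltic-like hydrography, circulation, and gridded-field I/O.

The Baltic Sea system (Skagerrak–Kattegat–Baltic proper) is characterised by a
stable horizontal surface-salinity gradient from fully marine water (~32 PSU)
at its North Sea entrance down to nearly fresh water (~3 PSU) at its far end,
a strong seasonal surface-temperature cycle, near-permanent vertical
stratification with saltier (and often hypoxic) water below the halocline, and
a largely wind-driven surface circulation with basin-scale gyres and coastal
boundary currents.

This module generates parametric fields with exactly that structure on a
regular latitude/longitude/depth grid, so that the climate-envelope
classification and the Lagrangian dispersal machinery downstream can be
exercised and tested end-to-end without access to any ocean-model hindcast.
The generators are deliberately kinematic: velocities come from a
streamfunction (hence divergence-free with no normal flow into land), and the
scalar fields are closed-form functions of position and time.  The scenario
seed perturbs only the synthetic bathymetry and (elsewhere) particle-release
lattices; the scalar fields are exactly reproducible from their parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ConfigurationError",
    "FormatError",
    "GridSpec",
    "Bathymetry",
    "SyntheticScenario",
    "HydroFieldSet",
    "VelocityFieldSet",
    "make_grid",
    "default_grid",
    "synth_bathymetry",
    "synth_hydro",
    "synth_velocity",
    "streamfunction",
    "face_transports",
    "discrete_divergence",
    "write_fields",
    "read_fields",
    "EARTH_RADIUS_M",
]

EARTH_RADIUS_M = 6371.0e3

#: Salinity excess (PSU) of sub-halocline water over the local surface value.
DEEP_SALINITY_EXCESS = 4.0
#: Temperature offset (degC) of sub-halocline water relative to the annual
#: surface mean; deep water carries no seasonal cycle and no warming trend.
DEEP_TEMP_OFFSET = -4.0
#: Length of the model year in days for the seasonal cycle.
DAYS_PER_YEAR = 365.2425


class ConfigurationError(ValueError):
    """Invalid grid, scenario, or protocol configuration."""


class FormatError(ValueError):
    """A gridded file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# Grid and bathymetry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular latitude/longitude/depth grid.

    Edges are strictly monotone; ``depth_edges`` starts at the surface (0 m)
    and is positive downward.  Horizontal indices are 0-based ``[lat, lon]``
    row-major; ``flat_index = ilat * n_lon + ilon`` is the cell labelling used
    by the connectivity matrix.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    depth_edges: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lat_edges", "lon_edges", "depth_edges"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1 or arr.size < 2:
                raise ConfigurationError(f"{name} must be 1-D with >= 2 entries")
            if not np.all(np.diff(arr) > 0):
                raise ConfigurationError(f"{name} must be strictly increasing")
        if self.depth_edges[0] != 0.0:
            raise ConfigurationError("depth_edges must start at the surface (0 m)")

    # -- sizes ------------------------------------------------------------
    @property
    def n_lat(self) -> int:
        return self.lat_edges.size - 1

    @property
    def n_lon(self) -> int:
        return self.lon_edges.size - 1

    @property
    def n_depth(self) -> int:
        return self.depth_edges.size - 1

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    # -- centres ----------------------------------------------------------
    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) in decimal degrees."""
        return (
            float(self.lon_edges[0]),
            float(self.lon_edges[-1]),
            float(self.lat_edges[0]),
            float(self.lat_edges[-1]),
        )

    @property
    def cell_area(self) -> np.ndarray:
        """Horizontal cell areas (m^2), spherical earth, shape (n_lat, n_lon)."""
        lat_r = np.deg2rad(self.lat_edges)
        band = EARTH_RADIUS_M**2 * (np.sin(lat_r[1:]) - np.sin(lat_r[:-1]))
        dlon_r = np.deg2rad(np.diff(self.lon_edges))
        return np.outer(band, dlon_r)

    # -- position <-> index ------------------------------------------------
    def flat_index(self, ilat: np.ndarray, ilon: np.ndarray) -> np.ndarray:
        return np.asarray(ilat) * self.n_lon + np.asarray(ilon)

    def unflatten(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = np.asarray(flat)
        return flat // self.n_lon, flat % self.n_lon

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Flat cell index containing each (lon, lat); -1 outside the domain."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        ilon = np.searchsorted(self.lon_edges, lon, side="right") - 1
        ilat = np.searchsorted(self.lat_edges, lat, side="right") - 1
        # points exactly on the outer edge belong to the last cell
        ilon = np.where((lon == self.lon_edges[-1]), self.n_lon - 1, ilon)
        ilat = np.where((lat == self.lat_edges[-1]), self.n_lat - 1, ilat)
        inside = (ilon >= 0) & (ilon < self.n_lon) & (ilat >= 0) & (ilat < self.n_lat)
        out = np.where(inside, self.flat_index(ilat, ilon), -1)
        return out


@dataclass(frozen=True)
class Bathymetry:
    """Water depth per horizontal cell (m, positive down; <= 0 means land)."""

    depth: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        if self.depth.ndim != 2:
            raise ConfigurationError("bathymetry depth must be 2-D [lat, lon]")

    @property
    def land_mask(self) -> np.ndarray:
        return self.depth <= 0.0

    @property
    def sea_mask(self) -> np.ndarray:
        return ~self.land_mask


def make_grid(
    n_lat: int,
    n_lon: int,
    depth_edges: Sequence[float],
    bbox: tuple[float, float, float, float],
) -> GridSpec:
    """Build a regular grid of ``n_lat x n_lon`` cells inside ``bbox``.

    ``bbox`` is (lon_min, lon_max, lat_min, lat_max) in decimal degrees.
    """
    if n_lat < 2 or n_lon < 2:
        raise ConfigurationError("grid needs at least 2 cells along each axis")
    lon_min, lon_max, lat_min, lat_max = map(float, bbox)
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ConfigurationError("bbox must satisfy lon_max > lon_min, lat_max > lat_min")
    return GridSpec(
        lat_edges=np.linspace(lat_min, lat_max, n_lat + 1),
        lon_edges=np.linspace(lon_min, lon_max, n_lon + 1),
        depth_edges=np.asarray(depth_edges, dtype=float),
    )


def default_grid(n_lat: int = 20, n_lon: int = 36) -> GridSpec:
    """Demo-scale Baltic-like grid: 10-22 degE, 54-60 degN, 6 depth bins to 150 m."""
    return make_grid(
        n_lat,
        n_lon,
        depth_edges=[0.0, 9.0, 12.0, 25.0, 60.0, 100.0, 150.0],
        bbox=(10.0, 22.0, 54.0, 60.0),
    )


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the synthetic Baltic-like conditions.

    Defaults encode the canonical description of the system: a ~32 -> ~3 PSU
    west-to-east surface salinity gradient, a seasonal surface-temperature
    cycle peaking in late July, a halocline near 60 m with hypoxic saltier
    water below it, and a basin-scale gyre circulation.
    """

    salinity_west: float = 32.0  # PSU at the marine (western) end
    salinity_east: float = 3.0  # PSU at the fresh (eastern) end
    sst_mean: float = 9.0  # degC annual-mean surface temperature
    sst_amplitude: float = 8.0  # degC seasonal half-range
    sst_peak_day: float = 210.0  # day-of-year of the warm peak (late July)
    warming_trend: float = 0.0  # degC per decade, surface layer only
    halocline_depth: float = 60.0  # m
    bottom_oxygen: float = 3.0  # mg O2 / l below the halocline (hypoxic)
    surface_oxygen: float = 9.0  # mg O2 / l above the halocline
    gyre_strength: float = 1.0e4  # streamfunction amplitude, m^2 s^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.salinity_west > self.salinity_east:
            raise ConfigurationError("salinity_west must exceed salinity_east")
        for name in ("salinity_west", "salinity_east", "bottom_oxygen", "surface_oxygen"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Field containers
# ---------------------------------------------------------------------------


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype="datetime64[s]")
    if times.ndim != 1 or times.size == 0:
        raise ConfigurationError("times must be a non-empty 1-D array")
    if times.size > 1 and not np.all(np.diff(times).astype(float) > 0):
        raise ConfigurationError("times must be strictly increasing")
    return times


@dataclass
class HydroFieldSet:
    """Temperature / salinity / oxygen on [time, depth, lat, lon].

    Land cells and depth bins below the local seabed hold NaN.
    """

    grid: GridSpec
    times: np.ndarray
    temperature: np.ndarray  # degC
    salinity: np.ndarray  # PSU
    oxygen: np.ndarray  # mg O2 / l

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        shape = (self.times.size, self.grid.n_depth, self.grid.n_lat, self.grid.n_lon)
        for name in ("temperature", "salinity", "oxygen"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ConfigurationError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.salinity) < 0 or np.nanmin(self.oxygen) < 0:
                raise ConfigurationError("salinity and oxygen must be non-negative")


@dataclass
class VelocityFieldSet:
    """Horizontal velocity (m/s, eastward/northward) on [time, depth, lat, lon].

    Land cells hold 0 (no flow); the generator guarantees no normal flow across
    land faces and zero discrete divergence of the underlying face transports.
    """

    grid: GridSpec
    times: np.ndarray
    u_east: np.ndarray
    v_north: np.ndarray

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        shape = (self.times.size, self.grid.n_depth, self.grid.n_lat, self.grid.n_lon)
        for name in ("u_east", "v_north"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ConfigurationError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)


# ---------------------------------------------------------------------------
# Bathymetry generator
# ---------------------------------------------------------------------------


def synth_bathymetry(
    grid: GridSpec,
    scenario: SyntheticScenario,
    flat_depth: float | None = None,
) -> Bathymetry:
    """Synthesise a basin bathymetry.

    Default shape: a land fringe along the domain boundary, a shallow (< 25 m)
    southern shelf, and a central basin deeper than 100 m, with small seeded
    roughness.  ``flat_depth`` instead returns an all-sea constant-depth
    bathymetry (useful as a degenerate test case).
    """
    ny, nx = grid.n_lat, grid.n_lon
    max_depth = float(grid.depth_edges[-1])
    if flat_depth is not None:
        if flat_depth <= 0 or flat_depth > max_depth:
            raise ConfigurationError("flat_depth must lie in (0, max(depth_edges)]")
        return Bathymetry(np.full((ny, nx), float(flat_depth)))

    yy, xx = np.meshgrid(
        (np.arange(ny) + 0.5) / ny, (np.arange(nx) + 0.5) / nx, indexing="ij"
    )
    # bowl reaching ~110% of a 140 m basin at the centre, tapering to the coast
    depth = 1.15 * min(140.0, max_depth) * np.sin(np.pi * xx) * np.sin(np.pi * yy)
    # shallow southern shelf
    shelf = yy < 0.25
    depth[shelf] = np.minimum(depth[shelf], 18.0)
    # seeded roughness (deterministic for a given scenario seed)
    rng = np.random.default_rng(scenario.seed)
    depth = depth + rng.normal(0.0, 1.5, size=depth.shape)
    depth = np.clip(depth, 2.0, max_depth)
    # land fringe: outermost ring of cells
    depth[0, :] = 0.0
    depth[-1, :] = 0.0
    depth[:, 0] = 0.0
    depth[:, -1] = 0.0
    return Bathymetry(depth)


# ---------------------------------------------------------------------------
# Hydrographic generator
# ---------------------------------------------------------------------------


def _sea_column_fraction(grid: GridSpec, bathy: Bathymetry) -> np.ndarray:
    """Along-basin coordinate in [0, 1] anchored at the westernmost and
    easternmost sea columns (so the boundary salinities are attained exactly)."""
    sea_cols = np.flatnonzero(bathy.sea_mask.any(axis=0))
    if sea_cols.size == 0:
        raise ConfigurationError("bathymetry contains no sea cells")
    lo, hi = grid.lon_centers[sea_cols[0]], grid.lon_centers[sea_cols[-1]]
    if hi == lo:
        return np.zeros(grid.n_lon)
    return np.clip((grid.lon_centers - lo) / (hi - lo), 0.0, 1.0)


def _wet_bin_mask(grid: GridSpec, bathy: Bathymetry) -> np.ndarray:
    """[depth, lat, lon] True where the depth bin intersects the water column."""
    bin_top = grid.depth_edges[:-1][:, None, None]
    return (bin_top < bathy.depth[None, :, :]) & bathy.sea_mask[None, :, :]


def synth_hydro(
    grid: GridSpec,
    bathy: Bathymetry,
    scenario: SyntheticScenario,
    years: Sequence[int],
    time_step: np.timedelta64 | str = np.timedelta64(1, "D"),
) -> HydroFieldSet:
    """Generate the scalar fields for whole calendar ``years``.

    Surface (above-halocline) structure:

    * salinity: linear in longitude from ``salinity_west`` to ``salinity_east``
      between the westernmost and easternmost sea columns;
    * temperature: ``sst_mean + sst_amplitude * cos(2 pi (doy - peak)/365.2425)``
      plus ``warming_trend`` (degC/decade) linear in time from the first year;
    * oxygen: ``surface_oxygen``.

    Below ``halocline_depth`` (by bin centre): salinity is the surface value
    plus ``DEEP_SALINITY_EXCESS``, temperature is ``sst_mean + DEEP_TEMP_OFFSET``
    (aseasonal, untrended), oxygen is ``bottom_oxygen``.
    """
    years = sorted(int(y) for y in years)
    if not years:
        raise ConfigurationError("years must be non-empty")
    step = pd.Timedelta(time_step)
    if step > pd.Timedelta(days=31):
        raise ConfigurationError(
            "time_step exceeds one month; monthly binning would be undefined"
        )
    t0 = pd.Timestamp(f"{years[0]}-01-01")
    t_end = pd.Timestamp(f"{years[-1]}-12-31T23:59:59")
    times = pd.date_range(t0, t_end, freq=step)
    times64 = times.values.astype("datetime64[s]")

    doy = times.day_of_year.values.astype(float)
    elapsed_years = (times - t0).days.values / DAYS_PER_YEAR
    sst = (
        scenario.sst_mean
        + scenario.sst_amplitude
        * np.cos(2.0 * np.pi * (doy - scenario.sst_peak_day) / DAYS_PER_YEAR)
        + scenario.warming_trend * elapsed_years / 10.0
    )

    fx = _sea_column_fraction(grid, bathy)
    s_surf = scenario.salinity_west + (scenario.salinity_east - scenario.salinity_west) * fx
    s_surf2d = np.broadcast_to(s_surf, (grid.n_lat, grid.n_lon))

    deep = grid.depth_centers >= scenario.halocline_depth  # [depth]
    nt, nz, ny, nx = times64.size, grid.n_depth, grid.n_lat, grid.n_lon

    temperature = np.empty((nt, nz, ny, nx))
    temperature[:] = sst[:, None, None, None]
    temperature[:, deep, :, :] = scenario.sst_mean + DEEP_TEMP_OFFSET

    salinity = np.empty((nt, nz, ny, nx))
    salinity[:] = s_surf2d[None, None, :, :]
    salinity[:, deep, :, :] += DEEP_SALINITY_EXCESS

    oxygen = np.full((nt, nz, ny, nx), scenario.surface_oxygen)
    oxygen[:, deep, :, :] = scenario.bottom_oxygen

    dry = ~_wet_bin_mask(grid, bathy)
    for arr in (temperature, salinity, oxygen):
        arr[:, dry] = np.nan

    return HydroFieldSet(grid, times64, temperature, salinity, oxygen)


# ---------------------------------------------------------------------------
# Velocity generator
# ---------------------------------------------------------------------------


def streamfunction(
    grid: GridSpec,
    bathy: Bathymetry,
    scenario: SyntheticScenario,
    mode: str = "gyre",
    omega: float | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Node-registered streamfunction psi (m^2/s), shape (n_lat+1, n_lon+1).

    Modes:

    * ``"gyre"``   — single basin-scale gyre, amplitude ``scenario.gyre_strength``;
    * ``"double_gyre"`` — two counter-rotating gyres split along the basin axis;
    * ``"solid_body"``  — psi = omega r^2 / 2 about ``center`` (lon, lat) in the
      centre-based equirectangular projection; analytic circular orbits;
    * ``"zero"``   — no flow.

    Nodes touching any land cell are zeroed, which enforces zero normal flow
    across every land face (psi is constant along land boundaries).
    """
    ny, nx = grid.n_lat, grid.n_lon
    yn, xn = np.meshgrid(
        np.linspace(0.0, 1.0, ny + 1), np.linspace(0.0, 1.0, nx + 1), indexing="ij"
    )
    if mode == "zero":
        psi = np.zeros((ny + 1, nx + 1))
    elif mode == "gyre":
        psi = scenario.gyre_strength * np.sin(np.pi * xn) * np.sin(np.pi * yn)
    elif mode == "double_gyre":
        psi = scenario.gyre_strength * np.sin(2.0 * np.pi * xn) * np.sin(np.pi * yn)
    elif mode == "solid_body":
        if omega is None:
            raise ConfigurationError("solid_body mode requires omega (rad/s)")
        lon_c, lat_c = center if center is not None else (
            float(np.mean(grid.lon_edges)),
            float(np.mean(grid.lat_edges)),
        )
        lam = np.deg2rad(grid.lon_edges[None, :] - lon_c)
        phi = np.deg2rad(grid.lat_edges[:, None] - lat_c)
        x = EARTH_RADIUS_M * np.cos(np.deg2rad(lat_c)) * lam
        y = EARTH_RADIUS_M * phi
        psi = 0.5 * omega * (x**2 + y**2)
    else:
        raise ConfigurationError(f"unknown streamfunction mode {mode!r}")

    land = bathy.land_mask
    if land.any():
        touch = np.zeros((ny + 1, nx + 1), dtype=bool)
        touch[:-1, :-1] |= land
        touch[:-1, 1:] |= land
        touch[1:, :-1] |= land
        touch[1:, 1:] |= land
        psi = np.where(touch, 0.0, psi)
    return psi


def face_transports(grid: GridSpec, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transports (m^3/s per unit depth) across east and north faces.

    ``t_east[j, i]`` is the transport out of cell (j, i) through its eastern
    face; ``t_north[j, i]`` through its northern face.  Because both are pure
    differences of node streamfunction values, the discrete divergence
    ``t_east - t_west + t_north - t_south`` telescopes to exactly zero.
    """
    # east face of cell (j,i): nodes (j, i+1) -> (j+1, i+1)
    t_east = psi[:-1, 1:] - psi[1:, 1:]
    # north face of cell (j,i): nodes (j+1, i) -> (j+1, i+1)
    t_north = psi[1:, 1:] - psi[1:, :-1]
    return t_east, t_north


def discrete_divergence(grid: GridSpec, psi: np.ndarray) -> np.ndarray:
    """Net outflow per cell of the streamfunction-derived face transports."""
    t_east, t_north = face_transports(grid, psi)
    t_west = psi[:-1, :-1] - psi[1:, :-1]
    t_south = psi[:-1, 1:] - psi[:-1, :-1]
    return t_east - t_west + t_north - t_south


def _face_lengths(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Physical lengths (m) of east faces (meridional) and north faces (zonal)."""
    dlat_m = EARTH_RADIUS_M * np.deg2rad(np.diff(grid.lat_edges))  # per row
    dlon_m = (
        EARTH_RADIUS_M
        * np.cos(np.deg2rad(grid.lat_edges[1:]))[:, None]
        * np.deg2rad(np.diff(grid.lon_edges))[None, :]
    )  # at northern edge of each row
    east_len = np.broadcast_to(dlat_m[:, None], (grid.n_lat, grid.n_lon))
    north_len = dlon_m
    return east_len, north_len


def synth_velocity(
    grid: GridSpec,
    bathy: Bathymetry,
    scenario: SyntheticScenario,
    times: np.ndarray,
    mode: str = "gyre",
    omega: float | None = None,
    center: tuple[float, float] | None = None,
    drift: tuple[float, float] = (0.0, 0.0),
) -> VelocityFieldSet:
    """Steady streamfunction-derived velocity replicated over ``times``.

    Cell-centred velocities are the mean of the two opposing face velocities
    (transport / face length); land cells are set to 0.  ``drift`` adds a
    uniform (u, v) in m/s on sea cells; with land present a pure drift is not
    divergence-free and relies on the integrator's beaching guard.
    """
    times = _check_times(np.asarray(times))
    psi = streamfunction(grid, bathy, scenario, mode=mode, omega=omega, center=center)
    t_east, t_north = face_transports(grid, psi)
    east_len, north_len = _face_lengths(grid)
    u_east_face = t_east / east_len
    v_north_face = t_north / north_len

    u_west_face = (psi[:-1, :-1] - psi[1:, :-1]) / east_len
    v_south_face = (psi[:-1, 1:] - psi[:-1, :-1]) / north_len

    u_c = 0.5 * (u_east_face + u_west_face) + drift[0]
    v_c = 0.5 * (v_north_face + v_south_face) + drift[1]
    u_c = np.where(bathy.sea_mask, u_c, 0.0)
    v_c = np.where(bathy.sea_mask, v_c, 0.0)

    nt, nz = times.size, grid.n_depth
    u = np.broadcast_to(u_c, (nt, nz) + u_c.shape).copy()
    v = np.broadcast_to(v_c, (nt, nz) + v_c.shape).copy()
    return VelocityFieldSet(grid, times, u, v)


# ---------------------------------------------------------------------------
# NetCDF I/O
# ---------------------------------------------------------------------------

_HYDRO_VARS = {"temperature": "degC", "salinity": "PSU", "oxygen": "mg l-1"}
_VEL_VARS = {"u": "m s-1", "v": "m s-1"}
_SALINITY_DIALECTS = {"PSU", "psu", "1e-3"}


def _grid_to_attrs(grid: GridSpec) -> dict:
    return {
        "lat_edges": grid.lat_edges,
        "lon_edges": grid.lon_edges,
        "depth_edges": grid.depth_edges,
    }


def _grid_from_attrs(ds: xr.Dataset) -> GridSpec:
    try:
        return GridSpec(
            lat_edges=np.asarray(ds.attrs["lat_edges"], dtype=float),
            lon_edges=np.asarray(ds.attrs["lon_edges"], dtype=float),
            depth_edges=np.asarray(ds.attrs["depth_edges"], dtype=float),
        )
    except KeyError as exc:
        raise FormatError(f"missing grid attribute {exc.args[0]!r}") from exc


def write_fields(
    fields: HydroFieldSet | VelocityFieldSet,
    path,
    bathymetry: Bathymetry | None = None,
) -> None:
    """Write a field set to NetCDF (CF-style time/depth/lat/lon order)."""
    grid = fields.grid
    coords = {
        "time": fields.times.astype("datetime64[ns]"),
        "depth": ("depth", grid.depth_centers, {"units": "m", "positive": "down"}),
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }
    dims = ("time", "depth", "lat", "lon")
    data = {}
    if isinstance(fields, HydroFieldSet):
        data["temperature"] = (dims, fields.temperature, {"units": "degC"})
        data["salinity"] = (dims, fields.salinity, {"units": "PSU"})
        data["oxygen"] = (dims, fields.oxygen, {"units": "mg l-1"})
    else:
        data["u"] = (dims, fields.u_east, {"units": "m s-1"})
        data["v"] = (dims, fields.v_north, {"units": "m s-1"})
    if bathymetry is not None:
        data["bathymetry"] = (("lat", "lon"), bathymetry.depth, {"units": "m"})
    ds = xr.Dataset(data, coords=coords, attrs=_grid_to_attrs(grid))
    ds.to_netcdf(path, engine="scipy")


def read_fields(path) -> HydroFieldSet | VelocityFieldSet:
    """Read a NetCDF file written by :func:`write_fields` (or compatible).

    The file type is detected from its variables (temperature/salinity/oxygen
    vs u/v).  Variable units are validated; salinity in ``g/kg`` is accepted
    with a warning and treated as PSU (the two scales differ by < 0.5% in this
    salinity range).
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = _grid_from_attrs(ds)
    times = ds["time"].values.astype("datetime64[s]")
    names = set(ds.data_vars)
    if {"u", "v"} <= names:
        for name in ("u", "v"):
            units = ds[name].attrs.get("units", "")
            if units not in {"m s-1", "m/s"}:
                raise FormatError(f"variable {name!r} has unexpected units {units!r}")
        return VelocityFieldSet(grid, times, ds["u"].values, ds["v"].values)
    missing = [n for n in _HYDRO_VARS if n not in names]
    if missing and names & set(_HYDRO_VARS):
        raise FormatError(f"missing variable {missing[0]!r}")
    if missing:
        raise FormatError("file contains neither hydrographic nor velocity variables")
    sal_units = ds["salinity"].attrs.get("units", "PSU")
    if sal_units == "g/kg":
        warnings.warn(
            "salinity units 'g/kg' treated as PSU", UserWarning, stacklevel=2
        )
    elif sal_units not in _SALINITY_DIALECTS:
        raise FormatError(f"variable 'salinity' has unexpected units {sal_units!r}")
    t_units = ds["temperature"].attrs.get("units", "degC")
    if t_units not in {"degC", "degree_Celsius", "Celsius"}:
        raise FormatError(f"variable 'temperature' has unexpected units {t_units!r}")
    return HydroFieldSet(
        grid, times, ds["temperature"].values, ds["salinity"].values, ds["oxygen"].values
    )


def read_bathymetry(path) -> Bathymetry:
    """Read the bathymetry variable from a NetCDF field file."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if "bathymetry" not in ds.data_vars:
        raise FormatError("missing variable 'bathymetry'")
    return Bathymetry(ds["bathymetry"].values)
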