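"""Lagrangian simulation of passive larval dispersal and cell connectivity.

Shipworm larvae are pelagic for weeks and are modelled here as passive
particles drifting in the surface layer (0-12 m).  The release protocol
mirrors a full multi-year campaign: 98 particles per grid cell, released at 6
time points per year (first of each month, May-October) over 8 years — 4704
trajectories per cell — each tracked for 30 days through velocity fields
updated every 3 hours.

Trajectories are integrated with fourth-order Runge-Kutta on velocities
interpolated bilinearly in space (from cell-centred fields) and linearly in
time, with a fixed substep (default 30 min).  Particles cannot cross land
(no-normal-flow fields plus a projection guard that reverts a step ending on
land); leaving the model domain terminates a trajectory.  The dispersal
probability P[j, i] is the proportion of trajectories released in cell j that
end, after exactly the trajectory duration, in receiving cell i (receiving
cells are restricted to water depth <= 100 m); trajectories lost to deeper
water or out of the domain appear as a row-sum deficit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .synthetic import (
    Bathymetry,
    ConfigurationError,
    EARTH_RADIUS_M,
    GridSpec,
    VelocityFieldSet,
)

__all__ = [
    "ReleaseProtocol",
    "ReleaseSet",
    "Trajectory",
    "TrajectoryEnsemble",
    "ConnectivityMatrix",
    "make_releases",
    "integrate",
    "integrate_batch",
    "connectivity",
    "run_dispersal",
    "STATUS_OK",
    "STATUS_LEFT_DOMAIN",
]

STATUS_OK = 0
STATUS_LEFT_DOMAIN = 1

#: Receiving cells must be at most this deep (m).
RECEIVING_DEPTH_MAX = 100.0


@dataclass(frozen=True)
class ReleaseProtocol:
    """Release and tracking protocol for one dispersal campaign.

    Defaults reproduce the full campaign bookkeeping: 98 x 6 x 8 = 4704
    trajectories per cell.  ``seed`` drives the (single, global) jitter of the
    within-cell release lattice and the optional stochastic start positions.
    """

    particles_per_cell: int = 98
    releases_per_year: int = 6
    release_months: tuple[int, ...] = (5, 6, 7, 8, 9, 10)  # May-October
    years: tuple[int, ...] = tuple(range(1995, 2003))  # 8 years
    depth_min: float = 0.0  # m
    depth_max: float = 12.0  # m
    duration_days: float = 30.0
    velocity_update_hours: float = 3.0
    substep_minutes: float = 30.0
    stochastic_starts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particles_per_cell < 1 or self.releases_per_year < 1 or not self.years:
            raise ConfigurationError("protocol counts must be positive")
        if len(self.release_months) != self.releases_per_year:
            raise ConfigurationError(
                "releases_per_year must match the number of release months "
                "(one release on the first day of each)"
            )
        if not set(self.release_months) <= set(range(1, 13)):
            raise ConfigurationError("release_months must be calendar months 1..12")
        if self.duration_days <= 0 or self.substep_minutes <= 0:
            raise ConfigurationError("duration and substep must be positive")
        if not 0 <= self.depth_min < self.depth_max:
            raise ConfigurationError("need 0 <= depth_min < depth_max")

    @property
    def trajectories_per_cell(self) -> int:
        return self.particles_per_cell * self.releases_per_year * len(self.years)

    @property
    def release_times(self) -> np.ndarray:
        times = [
            np.datetime64(f"{y}-{m:02d}-01", "s")
            for y in self.years
            for m in self.release_months
        ]
        return np.sort(np.array(times))


@dataclass
class ReleaseSet:
    """Flat arrays of individual particle releases."""

    grid: GridSpec
    cell: np.ndarray  # flat cell index per particle
    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    time: np.ndarray  # datetime64[s] per particle

    def __len__(self) -> int:
        return self.cell.size


@dataclass
class Trajectory:
    """A single particle path; ``end_cell`` is None if the particle left the domain."""

    release_cell: int
    release_time: np.datetime64
    positions: np.ndarray  # [n_steps+1, 3] lon, lat, depth
    end_cell: int | None
    status: int


@dataclass
class TrajectoryEnsemble:
    """End-point bookkeeping for a batch of trajectories."""

    grid: GridSpec
    release_cell: np.ndarray
    release_time: np.ndarray
    end_lon: np.ndarray
    end_lat: np.ndarray
    end_cell: np.ndarray  # flat index, -1 if left domain
    status: np.ndarray

    def __len__(self) -> int:
        return self.release_cell.size

    @staticmethod
    def concatenate(parts: Sequence["TrajectoryEnsemble"]) -> "TrajectoryEnsemble":
        if not parts:
            raise ConfigurationError("nothing to concatenate")
        g = parts[0].grid
        cat = lambda name: np.concatenate([getattr(p, name) for p in parts])
        return TrajectoryEnsemble(
            g,
            cat("release_cell"),
            cat("release_time"),
            cat("end_lon"),
            cat("end_lat"),
            cat("end_cell"),
            cat("status"),
        )


# ---------------------------------------------------------------------------
# Releases
# ---------------------------------------------------------------------------


def _lattice_shape(n: int) -> tuple[int, int]:
    """Near-square factorisation n = rows x cols with rows <= cols (98 -> 7 x 14)."""
    best = (1, n)
    for r in range(1, int(np.sqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)
    return best


def make_releases(
    grid: GridSpec,
    bathy: Bathymetry,
    protocol: ReleaseProtocol,
    cells: Sequence[int] | None = None,
) -> ReleaseSet:
    """Start positions for every particle of the campaign.

    Within each cell, particles sit on a fixed near-square lattice (7 x 14 for
    98), offset by a single seeded jitter common to all cells and events, and
    are spread uniformly across the release depth range.  With
    ``protocol.stochastic_starts`` the lattice is replaced by uniform random
    positions (independent per cell and event).
    """
    if cells is None:
        cells = grid.flat_index(*np.nonzero(bathy.sea_mask))
    cells = np.asarray(cells, dtype=int)
    iy, ix = grid.unflatten(cells)
    if np.any(bathy.land_mask[iy, ix]):
        bad = cells[bathy.land_mask[iy, ix]][0]
        raise ConfigurationError(f"release cell {bad} is on land")

    p = protocol.particles_per_cell
    rng = np.random.default_rng(protocol.seed)
    nr, nc = _lattice_shape(p)
    jitter = rng.uniform(-0.2, 0.2, size=2)  # fraction of lattice spacing
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    fy = np.clip((rr.ravel() + 0.5 + jitter[0]) / nr, 1e-3, 1 - 1e-3)
    fx = np.clip((cc.ravel() + 0.5 + jitter[1]) / nc, 1e-3, 1 - 1e-3)
    fz = (np.arange(p) + 0.5) / p

    times = protocol.release_times
    n_total = cells.size * times.size * p
    out_cell = np.empty(n_total, dtype=int)
    out_lon = np.empty(n_total)
    out_lat = np.empty(n_total)
    out_depth = np.empty(n_total)
    out_time = np.empty(n_total, dtype="datetime64[s]")

    lon0 = grid.lon_edges[ix]
    dlon = grid.lon_edges[ix + 1] - lon0
    lat0 = grid.lat_edges[iy]
    dlat = grid.lat_edges[iy + 1] - lat0

    k = 0
    for t in times:
        if protocol.stochastic_starts:
            u = rng.uniform(size=(cells.size, p))
            v = rng.uniform(size=(cells.size, p))
        else:
            u = np.broadcast_to(fx, (cells.size, p))
            v = np.broadcast_to(fy, (cells.size, p))
        sl = slice(k, k + cells.size * p)
        out_lon[sl] = (lon0[:, None] + u * dlon[:, None]).ravel()
        out_lat[sl] = (lat0[:, None] + v * dlat[:, None]).ravel()
        out_depth[sl] = np.broadcast_to(
            protocol.depth_min + fz * (protocol.depth_max - protocol.depth_min),
            (cells.size, p),
        ).ravel()
        out_cell[sl] = np.repeat(cells, p)
        out_time[sl] = t
        k += cells.size * p

    return ReleaseSet(grid, out_cell, out_lon, out_lat, out_depth, out_time)


# ---------------------------------------------------------------------------
# Velocity sampling
# ---------------------------------------------------------------------------


class _LayerVelocity:
    """Depth-averaged (over the tracked layer) velocity sampler."""

    def __init__(
        self, velocity: VelocityFieldSet, protocol: ReleaseProtocol
    ) -> None:
        grid = velocity.grid
        edges = grid.depth_edges
        w = np.clip(
            np.minimum(edges[1:], protocol.depth_max)
            - np.maximum(edges[:-1], protocol.depth_min),
            0.0,
            None,
        )
        if w.sum() <= 0:
            raise ConfigurationError(
                "velocity grid has no depth bins in the tracked layer"
            )
        w = w / w.sum()
        self.grid = grid
        self.u = np.tensordot(velocity.u_east, w, axes=([1], [0]))  # [t, y, x]
        self.v = np.tensordot(velocity.v_north, w, axes=([1], [0]))
        self.t = velocity.times.astype("datetime64[s]").astype(np.int64).astype(float)
        self.dlon = float(np.diff(grid.lon_edges).mean())
        self.dlat = float(np.diff(grid.lat_edges).mean())

    def covers(self, t0: float, t1: float) -> bool:
        if self.t.size == 1:
            return True  # steady field
        return self.t[0] <= t0 and t1 <= self.t[-1]

    def fields_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Time-interpolated (u, v) 2-D fields at epoch-seconds ``t``."""
        tt = self.t
        if tt.size == 1 or t <= tt[0]:
            return self.u[0], self.v[0]
        if t >= tt[-1]:
            return self.u[-1], self.v[-1]
        k = int(np.searchsorted(tt, t, side="right") - 1)
        a = (t - tt[k]) / (tt[k + 1] - tt[k])
        return (
            (1.0 - a) * self.u[k] + a * self.u[k + 1],
            (1.0 - a) * self.v[k] + a * self.v[k + 1],
        )

    def sample(
        self, u2: np.ndarray, v2: np.ndarray, lon: np.ndarray, lat: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear interpolation of cell-centred fields at particle positions."""
        g = self.grid
        gx = np.clip((lon - g.lon_centers[0]) / self.dlon, 0.0, g.n_lon - 1.0)
        gy = np.clip((lat - g.lat_centers[0]) / self.dlat, 0.0, g.n_lat - 1.0)
        ix0 = np.minimum(gx.astype(int), g.n_lon - 2)
        iy0 = np.minimum(gy.astype(int), g.n_lat - 2)
        wx = gx - ix0
        wy = gy - iy0
        u = (
            u2[iy0, ix0] * (1 - wx) * (1 - wy)
            + u2[iy0, ix0 + 1] * wx * (1 - wy)
            + u2[iy0 + 1, ix0] * (1 - wx) * wy
            + u2[iy0 + 1, ix0 + 1] * wx * wy
        )
        v = (
            v2[iy0, ix0] * (1 - wx) * (1 - wy)
            + v2[iy0, ix0 + 1] * wx * (1 - wy)
            + v2[iy0 + 1, ix0] * (1 - wx) * wy
            + v2[iy0 + 1, ix0 + 1] * wx * wy
        )
        return u, v


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _deg_per_sec(
    u: np.ndarray, v: np.ndarray, lat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convert m/s velocities to degrees/s at the given latitudes."""
    rad = np.pi / 180.0
    dlon = u / (EARTH_RADIUS_M * np.cos(lat * rad)) / rad
    dlat = v / EARTH_RADIUS_M / rad
    return dlon, dlat


def integrate_batch(
    lon: np.ndarray,
    lat: np.ndarray,
    release_time: np.datetime64,
    velocity: VelocityFieldSet,
    bathy: Bathymetry,
    protocol: ReleaseProtocol,
    record: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Advance a batch of particles for the protocol duration.

    Returns (end_lon, end_lat, status, positions) where positions is
    [n_particles, n_steps+1, 2] if ``record`` else None.
    """
    sampler = _LayerVelocity(velocity, protocol)
    grid = velocity.grid
    t0 = float(np.datetime64(release_time, "s").astype(np.int64))
    duration = protocol.duration_days * 86400.0
    if not sampler.covers(t0, t0 + duration):
        raise ConfigurationError(
            "velocity record does not cover the trajectory window"
        )

    lon = np.array(lon, dtype=float, copy=True)
    lat = np.array(lat, dtype=float, copy=True)
    status = np.zeros(lon.shape, dtype=int)
    dt = protocol.substep_minutes * 60.0
    n_steps = int(np.ceil(duration / dt - 1e-9))
    lon_min, lon_max, lat_min, lat_max = grid.bbox

    traj = None
    if record:
        traj = np.empty((lon.size, n_steps + 1, 2))
        traj[:, 0, 0] = lon
        traj[:, 0, 1] = lat

    land = bathy.land_mask
    t = t0
    for step in range(n_steps):
        h = min(dt, t0 + duration - t)
        active = status == STATUS_OK
        if active.any():
            ua, va = sampler.fields_at(t)
            ub, vb = sampler.fields_at(t + 0.5 * h)
            uc, vc = sampler.fields_at(t + h)
            x = lon[active]
            y = lat[active]

            def rhs(fields, px, py):
                uu, vv = sampler.sample(fields[0], fields[1], px, py)
                return _deg_per_sec(uu, vv, py)

            k1x, k1y = rhs((ua, va), x, y)
            k2x, k2y = rhs((ub, vb), x + 0.5 * h * k1x, y + 0.5 * h * k1y)
            k3x, k3y = rhs((ub, vb), x + 0.5 * h * k2x, y + 0.5 * h * k2y)
            k4x, k4y = rhs((uc, vc), x + h * k3x, y + h * k3y)
            nx = x + h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            ny = y + h / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)

            out = (nx < lon_min) | (nx > lon_max) | (ny < lat_min) | (ny > lat_max)
            # beaching guard: a step that lands on a land cell is reverted
            cell = grid.locate(nx, ny)
            beached = np.zeros(nx.shape, dtype=bool)
            inside = cell >= 0
            if inside.any():
                ciy, cix = grid.unflatten(cell[inside])
                beached[inside] = land[ciy, cix]
            keep = ~out & ~beached
            x_new = np.where(keep, nx, x)
            y_new = np.where(keep, ny, y)
            lon[active] = x_new
            lat[active] = y_new
            idx = np.flatnonzero(active)
            status[idx[out]] = STATUS_LEFT_DOMAIN
        if record:
            traj[:, step + 1, 0] = lon
            traj[:, step + 1, 1] = lat
        t += h
    return lon, lat, status, traj


def integrate(
    start: tuple[float, float, float, np.datetime64],
    velocity: VelocityFieldSet,
    bathy: Bathymetry,
    protocol: ReleaseProtocol,
) -> Trajectory:
    """Integrate one particle; ``start`` is (lon, lat, depth, release_time)."""
    lon0, lat0, _depth, rtime = start
    rtime = np.datetime64(rtime, "s")
    grid = velocity.grid
    cell0 = int(grid.locate(lon0, lat0)[0])
    if cell0 < 0:
        raise ConfigurationError("start position outside the grid")
    iy, ix = grid.unflatten(np.array([cell0]))
    if bathy.land_mask[iy[0], ix[0]]:
        raise ConfigurationError("start position is on land")
    elon, elat, status, traj = integrate_batch(
        np.array([lon0]), np.array([lat0]), rtime, velocity, bathy, protocol, record=True
    )
    positions = np.column_stack(
        [traj[0], np.full(traj.shape[1], float(start[2]))]
    )
    end_cell: int | None
    if status[0] == STATUS_OK:
        end_cell = int(grid.locate(elon, elat)[0])
    else:
        end_cell = None
    return Trajectory(cell0, rtime, positions, end_cell, int(status[0]))


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Sparse dispersal probabilities P[j, i] over flat grid-cell indices.

    Rows/columns span all grid cells; only released rows are populated.
    ``n_released``, ``lost_deep`` and ``lost_domain`` are per-cell counts; for
    every released row ``P.sum(row) + (lost_deep + lost_domain)/n_released``
    equals 1 exactly.
    """

    grid: GridSpec
    P: sp.csr_matrix
    n_released: np.ndarray
    lost_deep: np.ndarray
    lost_domain: np.ndarray
    protocol: ReleaseProtocol | None = None
    n_received: np.ndarray | None = None  # per-row count of settled trajectories

    @property
    def released_cells(self) -> np.ndarray:
        return np.flatnonzero(self.n_released > 0)

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.P.sum(axis=1)).ravel()

    def loss_fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return (self.lost_deep + self.lost_domain) / self.n_released

    def count_closure(self) -> bool:
        """Exact conservation: settled + deep losses + domain exits account
        for every released trajectory (integer identity, no rounding)."""
        if self.n_received is None:
            return bool(np.all(self.row_sums() + np.nan_to_num(self.loss_fraction()) <= 1.0))
        return bool(
            np.array_equal(
                self.n_received + self.lost_deep + self.lost_domain, self.n_released
            )
        )

    def to_coo_frame(self):
        import pandas as pd

        coo = self.P.tocoo()
        return pd.DataFrame(
            {"release_cell": coo.row, "receiving_cell": coo.col, "probability": coo.data}
        )


def connectivity(
    ensemble: TrajectoryEnsemble | Sequence[Trajectory],
    grid: GridSpec,
    bathy: Bathymetry,
    protocol: ReleaseProtocol | None = None,
    receiving_depth_max: float = RECEIVING_DEPTH_MAX,
) -> ConnectivityMatrix:
    """Build P[j, i] = (# trajectories j -> i with depth_i <= 100 m) / (# released from j)."""
    if not isinstance(ensemble, TrajectoryEnsemble):
        trajs = list(ensemble)
        if not trajs:
            raise ConfigurationError("empty trajectory set")
        ensemble = TrajectoryEnsemble(
            grid,
            np.array([t.release_cell for t in trajs]),
            np.array([t.release_time for t in trajs], dtype="datetime64[s]"),
            np.array([t.positions[-1, 0] for t in trajs]),
            np.array([t.positions[-1, 1] for t in trajs]),
            np.array([-1 if t.end_cell is None else t.end_cell for t in trajs]),
            np.array([t.status for t in trajs]),
        )
    if len(ensemble) == 0:
        raise ConfigurationError("empty trajectory set")

    n_cells = grid.n_cells
    n_released = np.bincount(ensemble.release_cell, minlength=n_cells)

    ended = ensemble.status == STATUS_OK
    end_cell = ensemble.end_cell
    iy, ix = grid.unflatten(np.where(ended, end_cell, 0))
    deep = bathy.depth[iy, ix] > receiving_depth_max
    received = ended & ~deep

    lost_domain = np.bincount(
        ensemble.release_cell[~ended], minlength=n_cells
    )
    lost_deep = np.bincount(
        ensemble.release_cell[ended & deep], minlength=n_cells
    )

    rows = ensemble.release_cell[received]
    cols = end_cell[received]
    n_received = np.bincount(rows, minlength=n_cells)
    P = sp.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_cells, n_cells)
    ).tocsr()
    # exact per-row division so that e.g. 3 of 10 trajectories gives exactly 0.3
    row_of_entry = np.repeat(np.arange(n_cells), np.diff(P.indptr))
    P.data = P.data / n_released[row_of_entry]
    return ConnectivityMatrix(
        grid, P, n_released, lost_deep, lost_domain, protocol, n_received
    )


# ---------------------------------------------------------------------------
# Campaign orchestration
# ---------------------------------------------------------------------------


def run_dispersal(
    grid: GridSpec,
    bathy: Bathymetry,
    velocity: VelocityFieldSet,
    protocol: ReleaseProtocol,
    cells: Sequence[int] | None = None,
    outdir: str | Path | None = None,
) -> tuple[ConnectivityMatrix, TrajectoryEnsemble]:
    """Run the full release campaign and assemble the connectivity matrix.

    Releases sharing a release time are integrated together.  With ``outdir``
    set, writes the sparse matrix (MatrixMarket + coordinate-triplet CSV) and
    a JSON summary with loss accounting.
    """
    releases = make_releases(grid, bathy, protocol, cells)
    parts: list[TrajectoryEnsemble] = []
    for t in np.unique(releases.time):
        sel = releases.time == t
        elon, elat, status, _ = integrate_batch(
            releases.lon[sel], releases.lat[sel], t, velocity, bathy, protocol
        )
        end_cell = np.where(status == STATUS_OK, grid.locate(elon, elat), -1)
        parts.append(
            TrajectoryEnsemble(
                grid,
                releases.cell[sel],
                np.full(int(sel.sum()), t, dtype="datetime64[s]"),
                elon,
                elat,
                end_cell,
                status,
            )
        )
    ensemble = TrajectoryEnsemble.concatenate(parts)
    matrix = connectivity(ensemble, grid, bathy, protocol)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "connectivity.mtx"), matrix.P)
        matrix.to_coo_frame().to_csv(outdir / "connectivity.csv", index=False)
        released = matrix.released_cells
        summary = {
            "n_release_cells": int(released.size),
            "n_trajectories": int(len(ensemble)),
            "trajectories_per_cell": int(protocol.trajectories_per_cell),
            "mean_loss_fraction": float(np.mean(matrix.loss_fraction()[released]))
            if released.size
            else 0.0,
            "lost_deep": int(matrix.lost_deep.sum()),
            "lost_domain": int(matrix.lost_domain.sum()),
        }
        (outdir / "dispersal_summary.json").write_text(json.dumps(summary, indent=2))
    return matrix, ensemble
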