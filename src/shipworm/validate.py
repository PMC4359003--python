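"""Correspondence of frequency maps with presence/absence observations.

Established shipworm populations are expected only where the frequency of
favourable conditions exceeds ~60% of classified time units.  This module
samples a frequency map at observation coordinates and tabulates a confusion
table at that threshold: the correspondence rule holds when no infested record
falls below the threshold.  This is a correspondence check, not a fitted
classifier — the confusion counts permit skill scores downstream but none are
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .envelope import FrequencyMap
from .synthetic import ConfigurationError

__all__ = [
    "load_records",
    "sample_map",
    "correspondence",
    "ValidationReport",
]

STATUS_VALUES = {"infested", "non_infested"}


def load_records(path: str | Path) -> pd.DataFrame:
    """Read occurrence records (CSV with lon, lat, status[, source, period])."""
    df = pd.read_csv(path)
    missing = {"lon", "lat", "status"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"records file lacks columns {sorted(missing)}")
    bad = set(df["status"].unique()) - STATUS_VALUES
    if bad:
        raise ConfigurationError(f"unknown status values {sorted(bad)}")
    return df


def sample_map(
    fmap: FrequencyMap, records: pd.DataFrame, method: str = "nearest"
) -> pd.DataFrame:
    """Frequency of the map cell containing each record.

    Adds ``frequency`` and ``usable`` columns; records outside the grid or on
    land/nodata cells are flagged unusable.  ``method="bilinear"``
    interpolates between cell centres instead of taking the containing cell.
    """
    grid = fmap.grid
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    freq = np.full(lon.size, np.nan)
    if method == "nearest":
        cell = grid.locate(lon, lat)
        inside = cell >= 0
        iy, ix = grid.unflatten(np.where(inside, cell, 0))
        vals = fmap.percent_favourable[iy, ix]
        freq = np.where(inside, vals, np.nan)
    elif method == "bilinear":
        vals = fmap.percent_favourable
        dlon = float(np.diff(grid.lon_edges).mean())
        dlat = float(np.diff(grid.lat_edges).mean())
        gx = np.clip((lon - grid.lon_centers[0]) / dlon, 0.0, grid.n_lon - 1.0)
        gy = np.clip((lat - grid.lat_centers[0]) / dlat, 0.0, grid.n_lat - 1.0)
        inside = grid.locate(lon, lat) >= 0
        ix0 = np.minimum(gx.astype(int), grid.n_lon - 2)
        iy0 = np.minimum(gy.astype(int), grid.n_lat - 2)
        wx, wy = gx - ix0, gy - iy0
        freq = (
            vals[iy0, ix0] * (1 - wx) * (1 - wy)
            + vals[iy0, ix0 + 1] * wx * (1 - wy)
            + vals[iy0 + 1, ix0] * (1 - wx) * wy
            + vals[iy0 + 1, ix0 + 1] * wx * wy
        )
        freq = np.where(inside, freq, np.nan)
    else:
        raise ConfigurationError(f"unknown sampling method {method!r}")

    out = records.copy()
    out["frequency"] = freq
    out["usable"] = np.isfinite(freq)
    if not out["usable"].any():
        raise ConfigurationError("no usable records: all on land or outside the grid")
    return out


@dataclass
class ValidationReport:
    """Confusion table of sampled frequencies against the threshold rule."""

    threshold: float
    n_usable: int
    infested_above: int  # infested records at frequency >= threshold
    infested_below: int
    non_infested_above: int
    non_infested_below: int
    min_frequency_infested: float
    rule_holds: bool  # no infested record below threshold

    def to_text(self) -> str:
        lines = [
            f"threshold: {self.threshold:.1f}%",
            f"usable records: {self.n_usable}",
            f"infested  >= thr: {self.infested_above}   < thr: {self.infested_below}",
            f"clear     >= thr: {self.non_infested_above}   < thr: {self.non_infested_below}",
            f"min frequency among infested: {self.min_frequency_infested:.1f}%",
            f"correspondence rule holds: {self.rule_holds}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def correspondence(
    sampled: pd.DataFrame, threshold: float = 60.0
) -> ValidationReport:
    """Evaluate the '>threshold% favourable' correspondence rule.

    ``sampled`` is the output of :func:`sample_map`.  The rule holds when zero
    infested records fall below the threshold.
    """
    usable = sampled[sampled["usable"]]
    if usable.empty:
        raise ConfigurationError("need at least one usable record")
    infested = usable[usable["status"] == "infested"]
    clear = usable[usable["status"] == "non_infested"]
    i_above = int((infested["frequency"] >= threshold).sum())
    i_below = int((infested["frequency"] < threshold).sum())
    n_above = int((clear["frequency"] >= threshold).sum())
    n_below = int((clear["frequency"] < threshold).sum())
    min_inf = float(infested["frequency"].min()) if len(infested) else float("nan")
    return ValidationReport(
        threshold=float(threshold),
        n_usable=int(len(usable)),
        infested_above=i_above,
        infested_below=i_below,
        non_infested_above=n_above,
        non_infested_below=n_below,
        min_frequency_infested=min_inf,
        rule_holds=(i_below == 0),
    )
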