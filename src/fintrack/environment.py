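"""Environmental layers and trajectory annotation.

Static covariates (bathymetry, seabed slope, distance to coast) live on a
fine grid (~300 m); dynamic sea-surface covariates (temperature, salinity,
height, current velocity) live on a coarse grid (~7 km) with an hourly time
axis.  Annotation samples the containing fine-grid cell for static layers
and the containing coarse-grid cell at the nearest hourly layer (ties
toward the earlier hour) for dynamic layers, and appends the fractional
hour of day.

Grid convention: cell-centre registered, row 0 is the northernmost row
(``y`` coordinate descending), all coordinates in projected metres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: Covariates attached to every located record, in reporting order.
COVARIATES = (
    "bathymetry",
    "slope",
    "distance_to_coast",
    "sst",
    "salinity",
    "ssh",
    "velocity",
    "hour_of_day",
)

STATIC_LAYERS = ("bathymetry", "slope", "distance_to_coast")
DYNAMIC_LAYERS = ("sst", "salinity", "ssh", "velocity")


class OutOfBoundsError(ValueError):
    """A probe point or time falls outside a layer's coverage."""

    def __init__(self, layer: str, detail: str):
        self.layer = layer
        super().__init__(f"probe outside coverage of layer {layer!r}: {detail}")


@dataclass
class EnvWorld:
    """Static rasters plus hourly dynamic raster stacks.

    Parameters
    ----------
    static:
        Dataset with variables ``bathymetry`` (m, positive down), ``slope``
        (degrees) and ``distance_to_coast`` (m) on dims ``(y, x)``.
    dynamic:
        Dataset with variables ``sst`` (degC), ``salinity`` (PSU), ``ssh``
        (m) and ``velocity`` (m/s) on dims ``(time, y, x)``; the time axis
        is hourly and strictly increasing.
    """

    static: xr.Dataset
    dynamic: xr.Dataset

    def __post_init__(self) -> None:
        t = self.dynamic["time"].values
        if len(t) > 1:
            dt = np.diff(t).astype("timedelta64[s]").astype(float)
            if not np.all(dt > 0):
                raise ValueError("dynamic time axis must be strictly increasing")
            if not np.allclose(dt, 3600.0):
                raise ValueError("dynamic time axis must be hourly")
        if "slope" in self.static:
            s = self.static["slope"].values
            if np.nanmin(s) < -1e-9 or np.nanmax(s) > 90 + 1e-9:
                raise ValueError("slope must lie in [0, 90] degrees")

    # -- georeferencing helpers -------------------------------------------
    @staticmethod
    def _cell_index(coord: np.ndarray, values: np.ndarray, layer: str) -> np.ndarray:
        """Index of the containing cell on a centre-registered axis."""
        step = coord[1] - coord[0] if len(coord) > 1 else 1.0
        idx = np.rint((values - coord[0]) / step).astype(np.int64)
        bad = (idx < 0) | (idx >= len(coord))
        if np.any(bad):
            v = np.atleast_1d(values)[np.atleast_1d(bad)][0]
            raise OutOfBoundsError(layer, f"coordinate {v:.1f} m")
        return idx

    def time_index(self, times: np.ndarray) -> np.ndarray:
        """Nearest hourly layer, ties toward the earlier hour."""
        axis = self.dynamic["time"].values
        offs = (np.asarray(times, dtype="datetime64[ns]") - axis[0]) / np.timedelta64(1, "s")
        frac = offs / 3600.0
        idx = np.floor(frac).astype(np.int64)
        rem = frac - idx
        idx = np.where(rem > 0.5, idx + 1, idx)  # exactly :30:00 stays earlier
        bad = (idx < 0) | (idx >= len(axis))
        if np.any(bad):
            t = np.atleast_1d(times)[np.atleast_1d(bad)][0]
            raise OutOfBoundsError("dynamic", f"time {t}")
        return idx

    def to_netcdf(self, static_path, dynamic_path) -> None:
        self.static.to_netcdf(static_path, engine="scipy")
        dyn = self.dynamic.copy()
        dyn["time"].encoding.update(units="seconds since 1970-01-01", dtype="float64")
        dyn.to_netcdf(dynamic_path, engine="scipy")

    @classmethod
    def from_netcdf(cls, static_path, dynamic_path) -> "EnvWorld":
        return cls(
            static=xr.load_dataset(static_path, engine="scipy"),
            dynamic=xr.load_dataset(dynamic_path, engine="scipy"),
        )


def compute_slope(bathymetry: xr.DataArray) -> xr.DataArray:
    """Seabed slope (degrees) from a bathymetry raster.

    Uses the Horn 3x3 finite-difference stencil on the elevation surface;
    edge cells fall back to one-sided differences via edge replication.
    """
    if bathymetry.sizes["y"] < 3 or bathymetry.sizes["x"] < 3:
        raise ValueError("slope needs at least a 3x3 raster")
    z = bathymetry.values.astype(float)
    x = bathymetry["x"].values
    y = bathymetry["y"].values
    dx = abs(x[1] - x[0])
    dy = abs(y[1] - y[0])
    zp = np.pad(z, 1, mode="edge")
    # Horn weights: (c + 2f + i) - (a + 2d + g) over 8*dx, rows analogous.
    dzdx = (
        (zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8 * dx)
    dzdy = (
        (zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])
    ) / (8 * dy)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return xr.DataArray(slope, coords=bathymetry.coords, dims=bathymetry.dims, name="slope")


def compute_distance_to_coast(land_mask: xr.DataArray) -> xr.DataArray:
    """Euclidean distance (m) from each sea cell centre to the nearest
    land cell centre; land cells are 0."""
    from scipy import ndimage

    mask = land_mask.values.astype(bool)
    if not mask.any():
        raise ValueError("land mask contains no land cells")
    if mask.all():
        raise ValueError("land mask contains no sea cells")
    x = land_mask["x"].values
    y = land_mask["y"].values
    dx = abs(x[1] - x[0]) if len(x) > 1 else 1.0
    dy = abs(y[1] - y[0]) if len(y) > 1 else 1.0
    dist = ndimage.distance_transform_edt(~mask, sampling=(dy, dx))
    return xr.DataArray(
        dist, coords=land_mask.coords, dims=land_mask.dims, name="distance_to_coast"
    )


def sample_environment(
    world: EnvWorld,
    x: np.ndarray | float,
    y: np.ndarray | float,
    time: np.ndarray | pd.Timestamp,
) -> pd.DataFrame:
    """Annotate point probes with the eight candidate covariates.

    Static layers are sampled at the containing fine-grid cell, dynamic
    layers at the containing coarse-grid cell and the nearest hourly
    layer; ``hour_of_day`` is the fractional UTC hour of the timestamp.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    t = pd.to_datetime(np.atleast_1d(time))
    if not (len(x) == len(y) == len(t)):
        raise ValueError("x, y and time must have equal length")

    out = {}
    sx = world.static["x"].values
    sy = world.static["y"].values
    ix = EnvWorld._cell_index(sx, x, "static")
    iy = EnvWorld._cell_index(sy, y, "static")
    for name in STATIC_LAYERS:
        out[name] = world.static[name].values[iy, ix]

    cx = world.dynamic["x"].values
    cy = world.dynamic["y"].values
    jx = EnvWorld._cell_index(cx, x, "dynamic")
    jy = EnvWorld._cell_index(cy, y, "dynamic")
    jt = world.time_index(t.values)
    for name in DYNAMIC_LAYERS:
        out[name] = world.dynamic[name].values[jt, jy, jx]

    out["hour_of_day"] = t.hour + t.minute / 60.0 + (t.second + t.microsecond / 1e6) / 3600.0
    return pd.DataFrame(out)


def annotate(world: EnvWorld, records: pd.DataFrame) -> pd.DataFrame:
    """Append the covariate columns to a table with ``x``, ``y``, ``time``.

    Pure: covariate columns already present are recomputed identically.
    """
    cov = sample_environment(world, records["x"].values, records["y"].values,
                             records["time"].values)
    out = records.drop(columns=[c for c in COVARIATES if c in records], errors="ignore")
    out = out.reset_index(drop=True)
    return pd.concat([out, cov], axis=1)


# Variable sets used when bathymetry is collinear with the other static
# layers: set A keeps bathymetry, set B the (distance-to-coast, slope,
# temperature) trio.  ssh and hour_of_day are polynomial units downstream.
SET_A = ("bathymetry", "salinity", "ssh", "velocity", "hour_of_day")
SET_B = ("distance_to_coast", "slope", "sst", "salinity", "ssh", "velocity", "hour_of_day")


@dataclass
class CollinearityResult:
    """Outcome of the pairwise-correlation screen."""

    corr: pd.DataFrame
    split: bool
    variable_sets: list[tuple[str, ...]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def collinearity_screen(
    annotated: pd.DataFrame, threshold: float = 0.5
) -> CollinearityResult:
    """Pairwise Pearson correlations among the candidate covariates.

    When bathymetry correlates with distance to coast, slope or SST beyond
    ``threshold`` in absolute value, the candidate set is split into a
    bathymetry set and a (distance-to-coast, slope, SST) set so that the
    strongly correlated predictors never enter the same model set.
    """
    cols = [c for c in COVARIATES if c in annotated.columns]
    if len(annotated) < 10:
        raise ValueError("collinearity screen needs at least 10 rows")
    sub = annotated[cols].astype(float)
    dropped = [c for c in cols if sub[c].nunique() <= 1]
    for c in dropped:
        warnings.warn(f"covariate {c!r} is constant; dropped from the screen")
    keep = [c for c in cols if c not in dropped]
    corr = sub[keep].corr(method="pearson")

    partners = [c for c in ("distance_to_coast", "slope", "sst") if c in keep]
    split = False
    if "bathymetry" in keep and partners:
        split = bool((corr.loc["bathymetry", partners].abs() >= threshold).any())
    if split:
        sets = [
            tuple(v for v in SET_A if v in keep),
            tuple(v for v in SET_B if v in keep),
        ]
    else:
        sets = [tuple(v for v in keep if v != "hour_of_day") + (("hour_of_day",) if "hour_of_day" in keep else ())]
    return CollinearityResult(corr=corr, split=split, variable_sets=sets, dropped=dropped)
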