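"""Synthetic biologging data with known, planted structure.

The generator emulates the data a fine-scale tagging study produces for a
coastal small cetacean: smooth environmental fields (a fine static grid
and a coarse hourly dynamic grid), a latent 1-min movement path driven by
a two-state (travelling/foraging) correlated random walk, irregular GPS
fixes obtained by thinning 3-min acquisition attempts, and a 1 Hz
time-depth trace alternating surface intervals with trapezoidal dives
whose bottom phase carries a sinusoidal wiggle.

Covariate effects are planted multiplicatively on the log10 scale of each
movement parameter (speed, dive duration, dive depth, dive wiggliness,
post-dive duration) via standardized local covariate values, and on the
behaviour-state switching logit, so that downstream regression can be
tested against known signs and magnitudes.  Residual noise on the
movement parameters is AR(1) at the analysis step with per-individual
variance multipliers, matching the error structure the inference stage
assumes.

Every output is a deterministic function of the config (seed included);
named substreams keep the environmental, path, GPS and depth randomness
independent of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from fintrack.environment import EnvWorld, compute_distance_to_coast, compute_slope

# substream codes (mixed into the RNG seed sequence)
_ENV, _TRACK, _GPS, _DEPTH = 101, 202, 303, 404

#: M2 lunar semidiurnal tidal period, hours.
TIDAL_PERIOD_H = 12.42

#: Default planted effects: movement slows and dives get wigglier/longer in
#: saline water, speed and wiggliness increase with water depth, and the
#: propensity to switch into foraging rises with salinity.  Coefficients
#: are per standard deviation of the covariate, on the log10 scale of the
#: movement parameter (the foraging entry acts on the switching logit).
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "speed": {"salinity": -0.06, "bathymetry": 0.04},
    "dive_duration": {"salinity": 0.05, "bathymetry": 0.08},
    "dive_wiggliness": {"salinity": 0.10, "bathymetry": 0.15},
    "foraging": {"salinity": 0.8},
}


class InvalidConfigError(ValueError):
    """Simulation config fails a structural requirement."""


@dataclass
class SimConfig:
    """Study conditions for one simulated deployment set.

    Defaults correspond to a six-animal coastal deployment: ~4-6
    successful GPS fixes per hour thinned from 3-min attempts, 25 m
    positional noise, 2% positional spikes, dive cycles spanning 10-250 s
    and 2-45 m (bounded by local water depth), and AR(1) residual noise
    on the movement parameters with per-individual variance multipliers.
    """

    seed: int = 0
    n_individuals: int = 6
    duration_h: float = 100.0
    #: projected extent of the study square, metres
    extent_m: float = 42_000.0
    static_res_m: float = 300.0
    dynamic_res_m: float = 7_000.0
    start_time: str = "2015-06-01T00:00:00"
    #: width of the land strip along the northern edge
    land_strip_m: float = 3_000.0
    max_sea_depth_m: float = 45.0
    #: mean successful GPS fixes per hour (attempts come every 3 min)
    fix_rate: float = 5.0
    gps_noise_sd_m: float = 25.0
    outlier_rate: float = 0.02
    #: covariate name -> coefficient, per movement parameter (log10 scale)
    effect_spec: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    )
    #: residual sd of movement parameters on the log10 scale
    noise_sd: float = 0.12
    #: AR(1) residual correlation at the 15-min analysis step
    rho_true: float = 0.3
    #: per-individual residual sd multipliers (first fixed to 1)
    var_mult: tuple[float, ...] = (1.0, 1.2, 0.8, 1.5, 0.9, 1.1)
    #: depth sensor noise, metres (0 gives noise-free traces)
    depth_noise_sd_m: float = 0.05
    #: hard ceiling on simulated dive depth, metres
    max_dive_depth_m: float = 150.0

    def __post_init__(self) -> None:
        if self.static_res_m <= 0 or self.dynamic_res_m <= 0:
            raise InvalidConfigError("grid resolutions must be positive")
        if self.fix_rate <= 0:
            raise InvalidConfigError("fix_rate must be > 0")
        if not (0.0 <= self.outlier_rate <= 0.1):
            raise InvalidConfigError("outlier_rate must lie in [0, 0.1]")
        if not (-1.0 < self.rho_true < 1.0):
            raise InvalidConfigError("rho_true must lie in (-1, 1)")
        if any(v <= 0 for v in self.var_mult):
            raise InvalidConfigError("var_mult entries must be > 0")
        if abs(self.var_mult[0] - 1.0) > 1e-12:
            raise InvalidConfigError("first var_mult is fixed to 1")
        if self.n_individuals < 1:
            raise InvalidConfigError("need at least one individual")
        if self.duration_h < 0:
            raise InvalidConfigError("duration_h must be >= 0")

    def delta(self, individual: int) -> float:
        """Residual-sd multiplier for one individual (cycled if needed)."""
        return float(self.var_mult[individual % len(self.var_mult)])

    def rng(self, stream: int, individual: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, individual])


# ---------------------------------------------------------------------------
# environmental world
# ---------------------------------------------------------------------------

def generate_env_world(config: SimConfig) -> EnvWorld:
    """Smooth static and tidal dynamic fields over the study square.

    Bathymetry deepens away from a land strip on the northern edge with
    smooth mesoscale bumps; slope and distance to coast are derived from
    it.  Salinity carries a fixed west-to-east gradient (30 to 35 PSU)
    plus a small tidal wobble, SST a north-south gradient plus a diel
    cycle, SSH a pure M2 (12.42 h) sinusoid with a spatial phase lag, and
    current velocity the rectified tidal stream.
    """
    e = config.extent_m
    n_fine = int(round(e / config.static_res_m))
    n_coarse = int(round(e / config.dynamic_res_m))
    if n_fine < 4 or n_coarse < 4:
        raise InvalidConfigError(
            f"extent/resolution gives {n_fine}x{n_fine} fine and "
            f"{n_coarse}x{n_coarse} coarse cells; need at least 4x4"
        )
    rng = config.rng(_ENV)

    # --- static grid (row 0 = northernmost) ---
    res = config.static_res_m
    xs = res / 2 + res * np.arange(n_fine)
    ys = e - res / 2 - res * np.arange(n_fine)  # descending
    yy = ys[:, None] * np.ones((1, n_fine))
    coast_y = e - config.land_strip_m  # southern edge of the land strip
    frac = np.clip((coast_y - yy) / coast_y, 0.0, None)  # 0 at coast line
    land = yy > coast_y
    bumps = gaussian_filter(rng.standard_normal((n_fine, n_fine)), sigma=8.0)
    bumps *= 4.0 / max(bumps.std(), 1e-12)
    bath = 2.0 + (config.max_sea_depth_m - 2.0) * frac + bumps * np.minimum(1.0, 4 * frac)
    bath = np.clip(bath, 1.0, None)
    bath[land] = -2.0  # land elevation, positive-down convention

    static = xr.Dataset(
        {"bathymetry": (("y", "x"), bath)},
        coords={"x": xs, "y": ys},
    )
    static["slope"] = compute_slope(static["bathymetry"])
    static["slope"] = static["slope"].clip(0.0, 90.0)
    land_da = xr.DataArray(land, coords=static.coords, dims=("y", "x"))
    static["distance_to_coast"] = compute_distance_to_coast(land_da)

    # --- dynamic grid ---
    cres = config.dynamic_res_m
    cxs = cres / 2 + cres * np.arange(n_coarse)
    cys = e - cres / 2 - cres * np.arange(n_coarse)
    n_hours = int(math.ceil(config.duration_h)) + 2
    t0 = np.datetime64(config.start_time, "ns")
    times = t0 + (np.arange(n_hours) * 3600 * 1_000_000_000).astype("timedelta64[ns]")
    th = np.arange(n_hours, dtype=float)  # hours since start

    xn = (cxs - cxs[0]) / max(cxs[-1] - cxs[0], 1.0)  # 0..1 west->east
    yn = (cys - cys[-1]) / max(cys[0] - cys[-1], 1.0)  # 0..1 south->north
    XN = np.broadcast_to(xn[None, :], (n_coarse, n_coarse))
    YN = np.broadcast_to(yn[:, None], (n_coarse, n_coarse))
    tidal = 2 * np.pi * th / TIDAL_PERIOD_H

    sal_static = 30.0 + 5.0 * XN + 0.05 * gaussian_filter(
        rng.standard_normal((n_coarse, n_coarse)), 1.0
    )
    salinity = sal_static[None] + 0.3 * np.sin(tidal)[:, None, None]

    start_hour = (t0 - t0.astype("datetime64[D]").astype("datetime64[ns]")) / np.timedelta64(1, "h")
    hod = (float(start_hour) + th) % 24.0
    sst_static = 16.0 - 2.0 * YN + 0.1 * gaussian_filter(
        rng.standard_normal((n_coarse, n_coarse)), 1.0
    )
    sst = sst_static[None] + 0.8 * np.sin(2 * np.pi * (hod - 15.0) / 24.0)[:, None, None]

    phase = 0.5 * np.pi * XN
    amp = 0.8 + 0.1 * XN
    ssh = amp[None] * np.sin(tidal[:, None, None] + phase[None])
    velocity = 0.15 + 0.85 * np.abs(
        np.cos(tidal[:, None, None] + phase[None])
    ) * (0.6 + 0.4 * YN)[None]

    dynamic = xr.Dataset(
        {
            "sst": (("time", "y", "x"), sst),
            "salinity": (("time", "y", "x"), salinity),
            "ssh": (("time", "y", "x"), ssh),
            "velocity": (("time", "y", "x"), velocity),
        },
        coords={"time": times, "y": cys, "x": cxs},
    )
    return EnvWorld(static=static, dynamic=dynamic)


def field_stats(world: EnvWorld) -> dict[str, tuple[float, float]]:
    """(mean, sd) per covariate, used to standardize planted effects.

    Static layers are summarized over sea cells only; hour of day over a
    uniform 0-24 h cycle.
    """
    out: dict[str, tuple[float, float]] = {}
    sea = world.static["bathymetry"].values > 0
    for name in ("bathymetry", "slope", "distance_to_coast"):
        v = world.static[name].values[sea]
        out[name] = (float(v.mean()), float(max(v.std(), 1e-9)))
    for name in ("sst", "salinity", "ssh", "velocity"):
        v = world.dynamic[name].values
        out[name] = (float(v.mean()), float(max(v.std(), 1e-9)))
    out["hour_of_day"] = (12.0, 24.0 / math.sqrt(12.0))
    return out


# ---------------------------------------------------------------------------
# latent movement path
# ---------------------------------------------------------------------------

# state-conditional movement parameters at the 1-min step
_SPEED_BASE = {0: 1.25, 1: 0.45}  # m/s, 0 = travelling, 1 = foraging
_TURN_SD = {0: 15.0, 1: 60.0}  # degrees
_P_SWITCH = {0: 0.045, 1: 0.055}  # per-minute baseline switch probability
_MIN_DWELL_MIN = 15
_SPEED_CAP = 2.6  # m/s, below the 2.8 m/s observed ceiling


def _ar1_series(n: int, rho_step: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal sd ``sd``."""
    if n == 0:
        return np.empty(0)
    innov = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = innov[0] * sd
    c = sd * math.sqrt(max(1.0 - rho_step**2, 0.0))
    for i in range(1, n):
        out[i] = rho_step * out[i - 1] + c * innov[i]
    return out


def simulate_track(world: EnvWorld, config: SimConfig, individual: int) -> pd.DataFrame:
    """Latent 1-min path for one individual.

    Returns a frame with ``time, x, y, state, speed`` plus cached local
    covariate context used by the downstream samplers: ``depth_m`` (local
    water depth) and log10-scale modifier columns ``mod_speed``,
    ``mod_dive_duration``, ``mod_dive_depth``, ``mod_dive_wiggliness``,
    ``mod_post_dive_duration`` combining planted effects and AR(1)
    residual noise.  The walk reflects off the domain boundary and the
    coast; dwell time in a behaviour state is at least 15 min.
    """
    if individual >= config.n_individuals:
        raise InvalidConfigError("individual index out of range")
    n_min = int(round(config.duration_h * 60))
    cols = [
        "time", "x", "y", "state", "speed", "depth_m",
        "mod_speed", "mod_dive_duration", "mod_dive_depth",
        "mod_dive_wiggliness", "mod_post_dive_duration",
    ]
    if n_min == 0:
        return pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "time" else float)
                             for c in cols})
    rng = config.rng(_TRACK, individual)
    stats = field_stats(world)

    sb = world.static["bathymetry"].values
    sx = world.static["x"].values
    sy = world.static["y"].values
    sx0, sdx = float(sx[0]), float(sx[1] - sx[0])
    sy0, sdy = float(sy[0]), float(sy[0] - sy[1])
    dyn = {k: world.dynamic[k].values for k in ("salinity", "sst", "ssh", "velocity")}
    cx = world.dynamic["x"].values
    cy = world.dynamic["y"].values
    cx0, cdx = float(cx[0]), float(cx[1] - cx[0])
    cy0, cdy = float(cy[0]), float(cy[0] - cy[1])

    t0 = np.datetime64(config.start_time, "ns")
    times = t0 + (np.arange(n_min) * 60 * 1_000_000_000).astype("timedelta64[ns]")
    tidx = world.time_index(times)
    hod0 = float((t0 - t0.astype("datetime64[D]").astype("datetime64[ns]"))
                 / np.timedelta64(1, "h"))

    # covariates with planted effects anywhere in the spec
    responses = ("speed", "dive_duration", "dive_depth", "dive_wiggliness",
                 "post_dive_duration")
    needed = sorted({c for eff in config.effect_spec.values() for c in eff})
    betas = {r: config.effect_spec.get(r, {}) for r in responses}
    forage_beta = config.effect_spec.get("foraging", {})

    # AR(1) residual streams per movement parameter, at the 1-min step.
    # rho_true is defined at the 15-min analysis step.
    rho_min = math.copysign(abs(config.rho_true) ** (1.0 / 15.0), config.rho_true)
    sd_i = config.noise_sd * config.delta(individual)
    eps = {r: _ar1_series(n_min, rho_min, sd_i, rng) for r in responses}

    margin = min(4 * config.static_res_m, config.extent_m / 10)
    lo = margin
    hi_x = config.extent_m - margin
    coast_y = config.extent_m - config.land_strip_m
    hi_y = coast_y - margin

    x = float(rng.uniform(lo + 2000, hi_x - 2000))
    y = float(rng.uniform(lo + 2000, hi_y - 2000))
    heading = float(rng.uniform(0, 2 * np.pi))
    state = 0
    dwell = _MIN_DWELL_MIN

    X = np.empty(n_min)
    Y = np.empty(n_min)
    S = np.empty(n_min, dtype=np.int8)
    V = np.empty(n_min)
    D = np.empty(n_min)
    M = {r: np.empty(n_min) for r in responses}

    turn_sd = {k: math.radians(v) for k, v in _TURN_SD.items()}
    expit = lambda z: 1.0 / (1.0 + math.exp(-z))
    logit = {k: math.log(p / (1 - p)) for k, p in _P_SWITCH.items()}

    for i in range(n_min):
        ix = min(max(int(round((x - sx0) / sdx)), 0), sb.shape[1] - 1)
        iy = min(max(int(round((sy0 - y) / sdy)), 0), sb.shape[0] - 1)
        jx = min(max(int(round((x - cx0) / cdx)), 0), dyn["salinity"].shape[2] - 1)
        jy = min(max(int(round((cy0 - y) / cdy)), 0), dyn["salinity"].shape[1] - 1)
        jt = int(tidx[i])

        z = {}
        for name in needed:
            if name == "bathymetry":
                raw = float(sb[iy, ix])
            elif name in ("slope", "distance_to_coast"):
                raw = float(world.static[name].values[iy, ix])
            elif name == "hour_of_day":
                raw = (hod0 + i / 60.0) % 24.0
            else:
                raw = float(dyn[name][jt, jy, jx])
            mu, sd = stats[name]
            z[name] = (raw - mu) / sd

        # behaviour switching (minimum dwell enforced)
        if dwell >= _MIN_DWELL_MIN:
            shift = sum(b * z.get(c, 0.0) for c, b in forage_beta.items())
            p = expit(logit[state] + (shift if state == 0 else -shift))
            if rng.random() < p:
                state = 1 - state
                dwell = 0
        dwell += 1

        for r in responses:
            M[r][i] = sum(b * z.get(c, 0.0) for c, b in betas[r].items()) + eps[r][i]

        speed = _SPEED_BASE[state] * 10.0 ** M["speed"][i]
        speed = min(max(speed, 0.05), _SPEED_CAP)
        heading += rng.normal(0.0, turn_sd[state])
        nx = x + speed * 60.0 * math.cos(heading)
        ny = y + speed * 60.0 * math.sin(heading)
        if nx < lo:
            nx = 2 * lo - nx
            heading = math.pi - heading
        elif nx > hi_x:
            nx = 2 * hi_x - nx
            heading = math.pi - heading
        if ny < lo:
            ny = 2 * lo - ny
            heading = -heading
        elif ny > hi_y:
            ny = 2 * hi_y - ny
            heading = -heading
        x, y = nx, ny

        X[i], Y[i], S[i], V[i] = x, y, state, speed
        D[i] = max(float(sb[iy, ix]), 0.0)

    out = pd.DataFrame({"time": times, "x": X, "y": Y, "state": S, "speed": V,
                        "depth_m": D})
    for r in responses:
        out[f"mod_{r}"] = M[r]
    return out


# ---------------------------------------------------------------------------
# GPS fixes
# ---------------------------------------------------------------------------

def simulate_gps_fixes(
    path: pd.DataFrame, config: SimConfig, individual: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Thin 3-min acquisition attempts into noisy fixes with spikes.

    Attempts occur every third path minute; each succeeds independently
    with probability ``fix_rate / 20`` (20 attempts per hour).  Successful
    fixes get isotropic Gaussian positional noise; a fraction
    ``outlier_rate`` of the interior fixes is replaced by a single-fix
    spike 1-5 km off the path (inflated when needed so the implied speed
    from the previous fix exceeds 15 km/h and the next fix "returns").
    The ledger records each spiked fix.
    """
    if len(path) == 0:
        raise ValueError("cannot sample fixes from an empty path")
    rng = config.rng(_GPS, individual)
    att = path.iloc[::3]
    p = min(1.0, config.fix_rate / 20.0)
    keep = rng.random(len(att)) < p
    fixes = att.loc[keep, ["time", "x", "y"]].reset_index(drop=True)
    n = len(fixes)
    if n:
        fixes[["x", "y"]] += rng.normal(0.0, config.gps_noise_sd_m, size=(n, 2))
    fixes.insert(0, "id", individual)

    spike_rows: list[dict] = []
    if n >= 3 and config.outlier_rate > 0:
        flags = rng.random(n) < config.outlier_rate
        flags[0] = flags[-1] = False
        prev = -2
        xs = fixes["x"].to_numpy()
        ys = fixes["y"].to_numpy()
        ts = fixes["time"].to_numpy()
        for i in np.flatnonzero(flags):
            if i - prev < 2:
                continue  # never spike adjacent fixes: the next fix must return
            prev = i
            dt_h = float((ts[i] - ts[i - 1]) / np.timedelta64(1, "h"))
            d_prev = math.hypot(xs[i] - xs[i - 1], ys[i] - ys[i - 1])
            d_ret = math.hypot(xs[i + 1] - xs[i - 1], ys[i + 1] - ys[i - 1])
            need = max(15_000.0 * dt_h * 1.1, 2.2 * d_ret) + d_prev
            mag = max(float(rng.uniform(1_000.0, 5_000.0)), need)
            ang = float(rng.uniform(0, 2 * np.pi))
            xs[i] += mag * math.cos(ang)
            ys[i] += mag * math.sin(ang)
            spike_rows.append({"id": individual, "fix_index": int(i),
                               "time": ts[i], "magnitude_m": mag})
        fixes["x"] = xs
        fixes["y"] = ys
    ledger = pd.DataFrame(spike_rows, columns=["id", "fix_index", "time", "magnitude_m"])
    return fixes, ledger


# ---------------------------------------------------------------------------
# depth series
# ---------------------------------------------------------------------------

def _scan_true_dives(depth: np.ndarray, t0_s: float,
                     threshold: float = 2.0, min_duration: float = 10.0,
                     bottom_fraction: float = 0.8) -> list[dict]:
    """Generator-side truth for one dive block of 1 Hz samples.

    Walks maximal contiguous runs above the threshold (sensor noise can
    split a shallow dive into several runs) and keeps those spanning at
    least ``min_duration`` seconds, mirroring the segmentation rule.
    """
    out = []
    above = depth > threshold
    i = 0
    n = len(depth)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if j - i >= min_duration:
            seg = depth[i:j + 1]
            mx = float(seg.max())
            inb = seg >= bottom_fraction * mx
            pair = inb[:-1] & inb[1:]
            wig = float(np.abs(np.diff(seg))[pair].sum())
            out.append({"start_s": t0_s + i, "end_s": t0_s + j,
                        "max_depth": mx, "bottom_distance": wig})
        i = j + 1
    return out


def simulate_depth_series(
    path: pd.DataFrame, config: SimConfig, individual: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """1 Hz depth trace alternating surface intervals and dives.

    Dives are trapezoids (constant-rate descent and ascent) with a
    sinusoidal bottom wiggle; depth is capped by the local water depth
    along the path and by ``max_dive_depth_m``.  Wiggle amplitude, dive
    duration, depth and the following surface interval are modulated by
    the planted log10-scale modifiers cached on the path.  The ledger
    lists, per generated dive, the true start/end (by the 2 m crossing on
    the emitted samples), maximum depth and bottom vertical distance;
    generated dives whose emitted samples do not satisfy the 2 m / 10 s
    rule are omitted from the ledger.
    """
    if len(path) == 0:
        raise ValueError("cannot generate a depth series from an empty path")
    rng = config.rng(_DEPTH, individual)
    t0 = path["time"].iloc[0].to_datetime64()
    total_s = int((path["time"].iloc[-1].to_datetime64() - t0)
                  / np.timedelta64(1, "s")) + 60
    depth_m = path["depth_m"].to_numpy()
    mods = {r: path[f"mod_{r}"].to_numpy()
            for r in ("dive_duration", "dive_depth", "dive_wiggliness",
                      "post_dive_duration")}
    state = path["state"].to_numpy()
    n_path = len(path)

    blocks: list[np.ndarray] = []
    ledger_rows: list[dict] = []
    t = 0  # seconds since t0

    def surface(dur: int) -> np.ndarray:
        return np.clip(np.abs(rng.normal(0.12, 0.08, dur)), 0.0, 0.45)

    # initial surface interval
    d0 = int(rng.integers(5, 30))
    blocks.append(surface(d0))
    t += d0

    while t < total_s:
        i = min(t // 60, n_path - 1)
        foraging = state[i] == 1
        local = max(float(depth_m[i]), 0.0)
        ceil_d = min(config.max_dive_depth_m, max(local - 1.0, 0.5))

        md = float(np.exp(rng.normal(math.log(9.0), 0.55)))
        md *= 10.0 ** mods["dive_depth"][i]
        md = min(max(md, 2.5), ceil_d) if ceil_d >= 2.5 else ceil_d
        rate_dn = max(float(rng.normal(1.3, 0.2)), 0.8)
        rate_up = max(float(rng.normal(1.2, 0.2)), 0.8)
        leg_dn = max(int(round(md / rate_dn)), 2)
        leg_up = max(int(round(md / rate_up)), 2)
        bottom = 6.0 + float(rng.gamma(2.0, 9.0)) * (1.5 if foraging else 0.7)
        bottom *= 10.0 ** mods["dive_duration"][i]
        bottom = int(min(max(bottom, 4.0), 250.0 - leg_dn - leg_up))
        if leg_dn + leg_up + bottom < 12:
            bottom = 12 - leg_dn - leg_up

        amp = 1.5 * (1.8 if foraging else 0.7) * 10.0 ** mods["dive_wiggliness"][i]
        amp = min(max(amp, 0.25), 0.45 * md)
        period = float(rng.uniform(6.0, 12.0))
        phase = float(rng.uniform(0, 2 * np.pi))
        tt = np.arange(bottom)
        bot = md - amp * (0.5 + 0.5 * np.sin(2 * np.pi * tt / period + phase))
        down = np.linspace(0.3, md, leg_dn, endpoint=False)
        up = np.linspace(md, 0.3, leg_up + 1)[1:]
        dive = np.concatenate([down, bot, up])
        if config.depth_noise_sd_m > 0:
            dive = dive + rng.normal(0.0, config.depth_noise_sd_m, len(dive))
        dive = np.clip(dive, -0.4, None)
        if t + len(dive) > total_s:
            break  # never truncate a dive mid-record; pad with surface below

        for rec in _scan_true_dives(dive, float(t)):
            rec["id"] = individual
            rec["start_time"] = t0 + np.timedelta64(int(round(rec.pop("start_s"))), "s")
            rec["end_time"] = t0 + np.timedelta64(int(round(rec.pop("end_s"))), "s")
            ledger_rows.append(rec)
        blocks.append(dive)
        t += len(dive)

        sd = 2 + int(rng.exponential(28.0 * 10.0 ** mods["post_dive_duration"][i]))
        sd = min(sd, 300)
        blocks.append(surface(sd))
        t += sd

    depth = np.concatenate(blocks)
    if len(depth) < total_s:
        depth = np.concatenate([depth, surface(total_s - len(depth))])
    depth = depth[:total_s]
    times = t0 + (np.arange(len(depth)) * 1_000_000_000).astype("timedelta64[ns]")
    series = pd.DataFrame({"id": individual, "time": times, "depth": depth})
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["id", "start_time", "end_time", "max_depth", "bottom_distance"],
    )
    return series, ledger


def simulate_study(config: SimConfig, drop_depth_for: int | None = None) -> dict:
    """Full deployment set: world, paths, fixes and depth traces.

    ``drop_depth_for`` emulates a failed depth logger on one individual
    (its depth series and dive ledger are omitted).
    """
    world = generate_env_world(config)
    out = {"world": world, "paths": {}, "fixes": [], "fix_ledgers": [],
           "depth": [], "dive_ledgers": []}
    for ind in range(config.n_individuals):
        path = simulate_track(world, config, ind)
        out["paths"][ind] = path
        fixes, fl = simulate_gps_fixes(path, config, ind)
        out["fixes"].append(fixes)
        out["fix_ledgers"].append(fl)
        if ind != drop_depth_for:
            series, dl = simulate_depth_series(path, config, ind)
            out["depth"].append(series)
            out["dive_ledgers"].append(dl)
    nonempty = [f for f in out["fix_ledgers"] if len(f)] or out["fix_ledgers"][:1]
    out["fixes"] = pd.concat(out["fixes"], ignore_index=True)
    out["fix_ledgers"] = pd.concat(nonempty, ignore_index=True)
    out["depth"] = (pd.concat(out["depth"], ignore_index=True)
                    if out["depth"] else pd.DataFrame(columns=["id", "time", "depth"]))
    out["dive_ledgers"] = (pd.concat(out["dive_ledgers"], ignore_index=True)
                           if out["dive_ledgers"] else pd.DataFrame())
    return out
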