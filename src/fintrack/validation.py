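"""Simulation studies validating each stage against planted truth.

Each function runs a self-contained study on synthetic data and returns
the measured quantity: oracle agreement for dive segmentation, recovery
of ledgered positional spikes, gap compliance of the regularizer,
equivalence of the GLS fit with its closed-form degenerate case,
recovery of the AR(1)/variance-structure parameters, the arithmetic of
Akaike weighting and model averaging, confidence-interval calibration,
end-to-end sign recovery of planted environmental effects, and
model-set selection.  Problem sizes are chosen so a full battery runs in
minutes on one core; every study is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from fintrack import dives as dv
from fintrack import tracks as tr
from fintrack.environment import SET_A, SET_B, annotate
from fintrack.gls import ModelSpec, build_design, compute_aicc, fit_gls
from fintrack.inference import (
    FittedModel,
    akaike_weights,
    compare_model_sets,
    enumerate_and_fit,
    model_average,
)
from fintrack.pipeline import RunConfig, run_pipeline
from fintrack.synthetic import SimConfig, generate_env_world, simulate_gps_fixes, simulate_track


# ---------------------------------------------------------------------------
# dive segmentation vs a brute-force reference scan
# ---------------------------------------------------------------------------

def reference_dive_scan(depth: np.ndarray, threshold: float = 2.0,
                        min_duration: float = 10.0) -> list[tuple[int, int]]:
    """Deliberately naive sample-by-sample dive scan (the oracle).

    Walks the 1 Hz series tracking runs of samples deeper than the
    threshold and keeps a run when last-minus-first spans at least
    ``min_duration`` seconds.  Kept independent of the vectorized
    segmentation on purpose.
    """
    out = []
    start = None
    for i, d in enumerate(depth):
        if d > threshold:
            if start is None:
                start = i
        else:
            if start is not None and (i - 1) - start >= min_duration:
                out.append((start, i - 1))
            start = None
    if start is not None and (len(depth) - 1) - start >= min_duration:
        out.append((start, len(depth) - 1))
    return out


def random_depth_trace(rng: np.random.Generator, n: int = 600) -> np.ndarray:
    """Mixed trace: smooth dives, surface noise, and a rough random walk."""
    kind = rng.integers(3)
    if kind == 0:  # reflected random walk around the 2 m threshold
        steps = rng.normal(0.0, 0.6, n)
        return np.abs(np.cumsum(steps) % 8.0)
    if kind == 1:  # surface noise with occasional brief excursions
        d = np.abs(rng.normal(0.2, 0.15, n))
        for _ in range(rng.integers(1, 5)):
            i = int(rng.integers(0, n - 12))
            w = int(rng.integers(3, 12))
            d[i:i + w] += rng.uniform(2.0, 6.0)
        return d
    d = np.abs(rng.normal(0.2, 0.1, n))  # smooth trapezoidal dives
    i = 0
    while i < n - 40:
        gap = int(rng.integers(5, 40))
        i += gap
        md = rng.uniform(1.0, 30.0)
        leg = max(int(md / 1.2), 1)
        bottom = int(rng.integers(2, 60))
        prof = np.concatenate([
            np.linspace(0.2, md, leg, endpoint=False),
            np.full(bottom, md) + rng.normal(0, 0.3, bottom),
            np.linspace(md, 0.2, leg),
        ])
        j = min(n, i + len(prof))
        d[i:j] = prof[:j - i]
        i = j
    return d


def dive_segmentation_agreement(n_traces: int = 1000, seed: int = 0) -> int:
    """Number of traces where segmentation disagrees with the oracle."""
    rng = np.random.default_rng([seed, 11])
    t0 = pd.Timestamp("2020-01-01")
    mismatches = 0
    for _ in range(n_traces):
        depth = random_depth_trace(rng)
        series = pd.DataFrame({
            "id": 0,
            "time": t0 + pd.to_timedelta(np.arange(len(depth)), "s"),
            "depth": depth,
        })
        got = list(zip(dv.segment_dives(series)["start_idx"],
                       dv.segment_dives(series)["end_idx"]))
        want = reference_dive_scan(depth)
        if got != want:
            mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# outlier screen recovery
# ---------------------------------------------------------------------------

def outlier_screen_recovery(
    n_tracks: int = 50, seed: int = 0, duration_h: float = 50.0,
    outlier_rate: float = 0.02,
) -> tuple[float, float]:
    """(sensitivity, false-removal rate) of the speed/return screen
    against the simulator's spike ledger."""
    base = SimConfig(seed=seed, n_individuals=1, duration_h=duration_h,
                     outlier_rate=outlier_rate)
    world = generate_env_world(base)
    spikes = hits = clean = false = 0
    for i in range(n_tracks):
        cfg = dataclasses.replace(base, seed=seed + 1000 + i)
        path = simulate_track(world, cfg, 0)
        fixes, ledger = simulate_gps_fixes(path, cfg, 0)
        _, removed = tr.screen_outliers(fixes)
        spike_times = set(pd.to_datetime(ledger["time"])) if len(ledger) else set()
        removed_times = set(pd.to_datetime(removed["time"])) if len(removed) else set()
        spikes += len(spike_times)
        hits += len(spike_times & removed_times)
        clean += len(fixes) - len(spike_times)
        false += len(removed_times - spike_times)
    sensitivity = hits / spikes if spikes else 1.0
    false_rate = false / clean if clean else 0.0
    return sensitivity, false_rate


# ---------------------------------------------------------------------------
# regularization gap compliance
# ---------------------------------------------------------------------------

def regularization_gap_violations(
    seed: int = 0, n_tracks: int = 5, duration_h: float = 50.0,
) -> int:
    """Count within-segment gaps outside the tolerance band over all
    regularization modes (15/30/60 min with proportional tolerance)."""
    base = SimConfig(seed=seed, n_individuals=1, duration_h=duration_h)
    world = generate_env_world(base)
    violations = 0
    for i in range(n_tracks):
        cfg = dataclasses.replace(base, seed=seed + 2000 + i)
        path = simulate_track(world, cfg, 0)
        fixes, _ = simulate_gps_fixes(path, cfg, 0)
        for interval, tol in ((15.0, 2.0), (30.0, 4.0), (60.0, 8.0)):
            traj = tr.regularize(fixes, interval, tol)
            if len(traj) < 2:
                continue
            t = traj["time"].to_numpy("datetime64[ns]").astype("int64") / 60e9
            same = traj["segment_id"].to_numpy()[1:] == traj["segment_id"].to_numpy()[:-1]
            gaps = np.diff(t)[same]
            violations += int(np.sum((gaps < interval - tol - 1e-9)
                                     | (gaps > interval + tol + 1e-9)))
    return violations


# ---------------------------------------------------------------------------
# GLS: degenerate-case equivalence and parameter recovery
# ---------------------------------------------------------------------------

def gls_degenerate_max_rel_err(n_designs: int = 20, seed: int = 0,
                               n: int = 200) -> float:
    """Worst relative error of (beta, sigma, loglik, AICc) against the
    closed-form ordinary-regression solution with rho = 0 and unit
    variance weights imposed."""
    rng = np.random.default_rng([seed, 31])
    worst = 0.0
    t0 = pd.Timestamp("2020-01-01")
    for _ in range(n_designs):
        p = int(rng.integers(1, 6))
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = 1.0 + X @ beta + rng.normal(0, 0.5, n)
        tab = pd.DataFrame(X, columns=[f"v{j}" for j in range(p)])
        tab["id"] = 0
        tab["time"] = t0 + pd.to_timedelta(np.arange(n), "min")
        tab["turning_angle"] = y  # identity transform path
        design = build_design(tab, ModelSpec("turning_angle",
                                             tuple(f"v{j}" for j in range(p))))
        fit = fit_gls(design, estimate_rho=False, estimate_delta=False)

        # closed-form normal-equations oracle on the same design matrix
        Xd = design.X
        bo = np.linalg.solve(Xd.T @ Xd, Xd.T @ design.y)
        rss = float(np.sum((design.y - Xd @ bo) ** 2))
        sigma_o = math.sqrt(rss / n)
        ll_o = -0.5 * n * (math.log(2 * math.pi * sigma_o**2) + 1.0)
        k = Xd.shape[1] + 1
        aicc_o = compute_aicc(ll_o, k, n)
        worst = max(
            worst,
            float(np.max(np.abs(fit.beta - bo) / np.maximum(np.abs(bo), 1e-12))),
            abs(fit.sigma - sigma_o) / sigma_o,
            abs(fit.loglik - ll_o) / abs(ll_o),
            abs(fit.aicc - aicc_o) / abs(aicc_o),
        )
    return worst


def _simulate_gls_dataset(rng, n_per_group=500, rho=0.6,
                          deltas=(1.0, 1.5, 2.0, 0.5), sigma=0.3,
                          beta=(0.5, 1.0, -0.7)):
    rows = []
    t0 = pd.Timestamp("2020-01-01")
    for g, d in enumerate(deltas):
        x1 = rng.normal(size=n_per_group)
        x2 = rng.normal(size=n_per_group)
        e = np.empty(n_per_group)
        e[0] = rng.normal()
        c = math.sqrt(1 - rho**2)
        for i in range(1, n_per_group):
            e[i] = rho * e[i - 1] + c * rng.normal()
        y = beta[0] + beta[1] * x1 + beta[2] * x2 + sigma * d * e
        rows.append(pd.DataFrame({
            "id": g, "time": t0 + pd.to_timedelta(np.arange(n_per_group), "min"),
            "turning_angle": y, "v1": x1, "v2": x2,
        }))
    return pd.concat(rows, ignore_index=True)


def gls_recovery_study(n_reps: int = 100, seed: int = 0,
                       rho: float = 0.6,
                       deltas=(1.0, 1.5, 2.0, 0.5)) -> dict:
    """Recovery of rho and the variance multipliers across replicates.

    Returns the median absolute error of rho-hat and the fraction of
    replicates with every delta-hat within 10% of truth.
    """
    rng = np.random.default_rng([seed, 41])
    rho_err = []
    delta_ok = 0
    deltas = np.asarray(deltas)
    for _ in range(n_reps):
        tab = _simulate_gls_dataset(rng, rho=rho, deltas=deltas)
        design = build_design(tab, ModelSpec("turning_angle", ("v1", "v2")))
        fit = fit_gls(design)
        rho_err.append(abs(fit.rho - rho))
        if np.all(np.abs(fit.delta - deltas) / deltas <= 0.10):
            delta_ok += 1
    return {
        "median_rho_abs_err": float(np.median(rho_err)),
        "frac_delta_within_10pct": delta_ok / n_reps,
    }


# ---------------------------------------------------------------------------
# averaging arithmetic
# ---------------------------------------------------------------------------

def averaging_arithmetic_max_err(seed: int = 0) -> float:
    """Worst discrepancy between the averaging pipeline and direct
    arithmetic (weight normalization, w+(j), conditional means,
    unconditional SEs) on a small two-variable enumeration."""
    rng = np.random.default_rng([seed, 51])
    t0 = pd.Timestamp("2020-01-01")
    n = 120
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    y = 0.3 + 0.4 * x1 + rng.normal(0, 0.5, n)
    tab = pd.DataFrame({"id": 0, "time": t0 + pd.to_timedelta(np.arange(n), "min"),
                        "turning_angle": y, "v1": x1, "v2": x2})
    _, models = enumerate_and_fit(tab, ("v1", "v2"), "turning_angle",
                                  estimate_rho=False, estimate_delta=False)
    w = akaike_weights(models)
    res = model_average(models, w)

    err = abs(float(w.sum()) - 1.0)
    # independent arithmetic
    aicc = np.array([m.aicc for m in models])
    w_direct = np.exp(-(aicc - aicc.min()) / 2)
    w_direct /= w_direct.sum()
    err = max(err, float(np.max(np.abs(w - w_direct))))
    for unit in ("v1", "v2"):
        has = np.array([unit in m.terms for m in models])
        w_plus = float(w_direct[has].sum())
        got_wp = float(res.table.loc[res.table["term"] == unit, "w_plus"].iloc[0])
        err = max(err, abs(w_plus - got_wp))
        wn = w_direct[has] / w_direct[has].sum()
        raw = [m.coef_raw().set_index("column") for m, h in zip(models, has) if h]
        b = np.array([r.loc[unit, "beta"] for r in raw])
        s = np.array([r.loc[unit, "se"] for r in raw])
        bbar = float(wn @ b)
        se_u = float(wn @ np.sqrt(s**2 + (b - bbar) ** 2))
        row = res.table.loc[res.table["column"] == unit].iloc[0]
        err = max(err, abs(bbar - row["beta"]), abs(se_u - row["se"]))
    return err


# ---------------------------------------------------------------------------
# CI calibration at the regression layer
# ---------------------------------------------------------------------------

def _covariate_pool(seed: int = 0, duration_h: float = 100.0,
                    n_individuals: int = 6,
                    rows_per_individual: int = 60) -> pd.DataFrame:
    """Annotated step-scale covariates from one simulated deployment at
    the generator's default duration, thinned to ``rows_per_individual``
    rows spread evenly over each individual's track (so the rows sample
    the whole deployment, not just its first hours)."""
    cfg = SimConfig(seed=seed, n_individuals=n_individuals, duration_h=duration_h)
    world = generate_env_world(cfg)
    rows = []
    for ind in range(n_individuals):
        path = simulate_track(world, cfg, ind)
        sub = path.iloc[::15][["time", "x", "y"]]  # 15-min step spacing
        stride = max(len(sub) // rows_per_individual, 1)
        sub = sub.iloc[::stride].head(rows_per_individual).copy()
        sub.insert(0, "id", ind)
        rows.append(sub)
    return annotate(world, pd.concat(rows, ignore_index=True))


def ci_calibration_study(
    n_reps: int = 200, seed: int = 0, beta_sal: float | None = None,
    rows_per_individual: int = 60, rho: float = 0.3, sigma: float = 0.12,
    variable_set=("bathymetry", "salinity", "ssh"),
) -> float:
    """Coverage of the averaged 95% CI for a planted salinity effect.

    The covariates come from a simulated deployment at the generator's
    defaults; each replicate draws fresh AR(1) errors with the
    per-individual variance multipliers, rebuilds the response, runs the
    all-subsets averaging, and checks whether the salinity CI covers the
    planted coefficient (raw scale, log10 response units per PSU).  The
    default planted effect matches the generator's default salinity
    coefficient (-0.06 per covariate sd).
    """
    pool = _covariate_pool(seed)
    pool = pool.groupby("id", group_keys=False).head(
        rows_per_individual).reset_index(drop=True)
    if beta_sal is None:
        beta_sal = -0.06 / float(pool["salinity"].std())
    rng = np.random.default_rng([seed, 61])
    deltas = SimConfig().var_mult
    covered = 0
    for _ in range(n_reps):
        y = _planted_response(pool, {"salinity": beta_sal}, rng, rho, sigma, deltas)
        tab = pool.copy()
        tab["speed"] = 10.0 ** y
        _, models = enumerate_and_fit(tab, variable_set, "speed")
        res = model_average(models, akaike_weights(models))
        row = res.table.loc[res.table["column"] == "salinity"].iloc[0]
        if row["ci_low"] <= beta_sal <= row["ci_high"]:
            covered += 1
    return covered / n_reps


def _planted_response(pool, betas: dict, rng, rho, sigma, deltas):
    y = np.full(len(pool), -0.2)
    for cov, b in betas.items():
        y = y + b * pool[cov].to_numpy(float)
    c = math.sqrt(1 - rho**2)
    for ind, sub in pool.groupby("id"):
        idx = sub.index.to_numpy()
        e = np.empty(len(idx))
        e[0] = rng.normal()
        for i in range(1, len(idx)):
            e[i] = rho * e[i - 1] + c * rng.normal()
        y[idx] = y[idx] + sigma * deltas[int(ind) % len(deltas)] * e
    return y


def null_false_positive_study(
    n_seeds: int = 50, seed: int = 0, rows_per_individual: int = 60,
    rho: float = 0.3, sigma: float = 0.12,
    variable_set=("bathymetry", "salinity", "ssh"),
) -> dict:
    """Per-covariate rate of the "CI excludes 0" flag under the all-null
    generator (no planted effects)."""
    pool = _covariate_pool(seed).groupby("id", group_keys=False).head(
        rows_per_individual).reset_index(drop=True)
    rng = np.random.default_rng([seed, 71])
    deltas = SimConfig().var_mult
    flags: dict[str, int] = {}
    for _ in range(n_seeds):
        y = _planted_response(pool, {}, rng, rho, sigma, deltas)
        tab = pool.copy()
        tab["speed"] = 10.0 ** y
        _, models = enumerate_and_fit(tab, variable_set, "speed")
        res = model_average(models, akaike_weights(models))
        for _, row in res.table.iterrows():
            if row["term"] == "(Intercept)":
                continue
            flags.setdefault(row["column"], 0)
            flags[row["column"]] += int(bool(row["effect"]))
    return {k: v / n_seeds for k, v in flags.items()}


# ---------------------------------------------------------------------------
# end-to-end studies through the pipeline
# ---------------------------------------------------------------------------

def sign_recovery_study(
    n_seeds: int = 20, seed: int = 0, duration_h: float = 100.0,
    n_individuals: int = 6,
) -> float:
    """Fraction of seeds where the full pipeline recovers the planted
    qualitative pattern: speed decreases and dive wiggliness increases
    with salinity, each with a 95% CI excluding zero."""
    ok = 0
    for i in range(n_seeds):
        sim = SimConfig(seed=seed + 3000 + i, n_individuals=n_individuals,
                        duration_h=duration_h)
        cfg = RunConfig(sim=sim, responses=("speed", "dive_wiggliness"),
                        model_sets="A")
        report = run_pipeline(cfg)
        good = True
        for resp, sign in (("speed", -1), ("dive_wiggliness", +1)):
            entry = report.results.get(resp)
            if entry is None or "A" not in entry:
                good = False
                break
            row = entry["A"].table
            row = row.loc[row["column"] == "salinity"]
            if len(row) != 1:
                good = False
                break
            r = row.iloc[0]
            if not (np.sign(r["beta"]) == sign and r["effect"]):
                good = False
                break
        ok += int(good)
    return ok / n_seeds


def model_set_selection_study(n_seeds: int = 20, seed: int = 0,
                              rows_per_individual: int = 60,
                              beta_bath: float | None = None) -> float:
    """Fraction of seeds where a bathymetry-driven planted response makes
    the comparison pick the bathymetry model set over the
    distance/slope/SST set."""
    pool = _covariate_pool(seed).groupby("id", group_keys=False).head(
        rows_per_individual).reset_index(drop=True)
    if beta_bath is None:
        beta_bath = 0.10 / float(pool["bathymetry"].std())
    rng = np.random.default_rng([seed, 81])
    deltas = SimConfig().var_mult
    wins = 0
    for _ in range(n_seeds):
        y = _planted_response(pool, {"bathymetry": beta_bath}, rng, 0.3, 0.12, deltas)
        tab = pool.copy()
        tab["speed"] = 10.0 ** y
        _, models_a = enumerate_and_fit(tab, SET_A, "speed")
        res_a = model_average(models_a, akaike_weights(models_a))
        _, models_b = enumerate_and_fit(tab, SET_B, "speed")
        res_b = model_average(models_b, akaike_weights(models_b))
        choice = compare_model_sets(res_a, res_b)
        wins += int(choice.selected == "A")
    return wins / n_seeds
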