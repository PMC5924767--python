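"""End-to-end orchestration: simulate/ingest -> clean -> regularize ->
dive-process -> annotate -> fit -> report.

A single :class:`RunConfig` (one seed) drives the whole chain; the
resulting :class:`RunReport` carries per-stage record counts mirroring
the bookkeeping a tagging study reports (ingested, outliers removed,
post-tagging discard, retained after regularization, dives segmented and
condensed) plus the model-averaged coefficient tables per movement
parameter.  Identical config and seed reproduce the report bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fintrack import dives as dv
from fintrack import tracks as tr
from fintrack.environment import annotate, collinearity_screen
from fintrack.gls import RESPONSES
from fintrack.inference import (
    AveragedResult,
    ModelSetChoice,
    akaike_weights,
    compare_model_sets,
    enumerate_and_fit,
    model_average,
)
from fintrack.synthetic import SimConfig, simulate_study

logger = logging.getLogger(__name__)

#: condensed-table column -> response name used in the models
_DIVE_RESPONSES = {
    "duration": "dive_duration",
    "max_depth": "dive_depth",
    "wiggliness": "dive_wiggliness",
    "post_dive_duration": "post_dive_duration",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    simulate: bool = True
    #: CSV paths used when ``simulate`` is False
    fixes_path: str | None = None
    depth_path: str | None = None
    # track processing
    interval_min: float = 15.0
    tol_min: float = 2.0
    speed_threshold: float = tr.SPEED_THRESHOLD_MS
    return_ratio: float = 0.5
    discard_h: float = 24.0
    # dive processing
    depth_threshold: float = 2.0
    min_dive_duration: float = 10.0
    bottom_fraction: float = 0.8
    window_s: float = 60.0
    # inference
    responses: tuple[str, ...] = RESPONSES
    #: "auto" fits every set the collinearity screen emits; "A" keeps
    #: only the first (bathymetry) set
    model_sets: str = "auto"
    collinearity_threshold: float = 0.5
    estimate_rho: bool = True
    estimate_delta: bool = True
    gls_starts: str = "auto"
    drop_depth_for: int | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig(**data.pop("sim", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **data)


@dataclass
class RunReport:
    """Stage bookkeeping plus the averaged inference tables."""

    seed: int
    counts: dict
    results: dict  # response -> {"A": AveragedResult, ["B", "choice"]}
    corr: pd.DataFrame | None
    split: bool
    config: RunConfig
    version: str = ""

    def digest(self) -> str:
        """Deterministic hash of counts and coefficient tables."""
        h = hashlib.sha256()
        h.update(json.dumps(self.counts, sort_keys=True, default=str).encode())
        for resp in sorted(self.results):
            for key in sorted(self.results[resp]):
                val = self.results[resp][key]
                if isinstance(val, AveragedResult):
                    h.update(val.table.round(10).to_csv(index=False).encode())
                elif isinstance(val, ModelSetChoice):
                    h.update(f"{val.selected}:{val.delta_aicc:.10f}".encode())
        return h.hexdigest()

    def summary_table(self) -> pd.DataFrame:
        """Long-format coefficient report across responses and sets."""
        rows = []
        for resp, entry in self.results.items():
            for set_name in ("A", "B"):
                if set_name not in entry:
                    continue
                res = entry[set_name]
                t = res.table.copy()
                t.insert(0, "response", resp)
                t.insert(1, "model_set", set_name)
                t["r2_mean"] = res.r2_mean
                t["r2_min"] = res.r2_min
                t["r2_max"] = res.r2_max
                rows.append(t)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest(config: RunConfig) -> dict:
    if config.simulate:
        return simulate_study(config.sim, drop_depth_for=config.drop_depth_for)
    if not config.fixes_path:
        raise ValueError("no input: set simulate=True or provide fixes_path")
    fixes = pd.read_csv(config.fixes_path, parse_dates=["time"])
    if len(fixes) == 0:
        raise ValueError("fix table is empty")
    depth = (pd.read_csv(config.depth_path, parse_dates=["time"])
             if config.depth_path else pd.DataFrame(columns=["id", "time", "depth"]))
    from fintrack.synthetic import generate_env_world
    world = generate_env_world(config.sim)
    return {"world": world, "fixes": fixes, "depth": depth,
            "fix_ledgers": pd.DataFrame(), "dive_ledgers": pd.DataFrame()}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order and return the report.

    Any stage error aborts with the stage name; tables produced before
    the failure are written to ``out_dir`` when one is configured.
    """
    data = _ingest(config)
    world = data["world"]
    fixes = data["fixes"]
    depth = data["depth"]
    counts: dict = {"fixes_ingested": int(len(fixes)),
                    "depth_samples": int(len(depth))}
    outputs: dict[str, pd.DataFrame] = {}

    # --- tracks ---
    kept_all, removed_all, steps_all = [], [], []
    try:
        for ind, sub in fixes.groupby("id"):
            sub = sub.sort_values("time").reset_index(drop=True)
            tag_time = sub["time"].iloc[0]
            kept, removed = tr.screen_outliers(
                sub, config.speed_threshold, config.return_ratio)
            kept = tr.discard_post_tagging(kept, tag_time, config.discard_h)
            traj = tr.regularize(kept, config.interval_min, config.tol_min)
            steps = tr.step_metrics(traj)
            kept_all.append(traj)
            removed_all.append(removed)
            steps_all.append(steps)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("tracks", str(exc)) from exc
    traj = pd.concat(kept_all, ignore_index=True) if kept_all else pd.DataFrame()
    removed = pd.concat(removed_all, ignore_index=True) if removed_all else pd.DataFrame()
    steps = pd.concat(steps_all, ignore_index=True) if steps_all else pd.DataFrame()
    counts["outliers_removed"] = int(len(removed))
    counts["fixes_regularized"] = int(len(traj))
    counts["steps"] = int(len(steps))
    outputs["trajectory"] = traj
    outputs["removed_outliers"] = removed
    outputs["steps"] = steps

    # --- dives ---
    dive_rows, condensed_rows = [], []
    try:
        for ind, sub in depth.groupby("id"):
            sub = sub.sort_values("time").reset_index(drop=True)
            if len(sub) == 0:
                continue
            tag_time = sub["time"].iloc[0]
            sub = tr.discard_post_tagging(sub, tag_time, config.discard_h)
            if len(sub) == 0:
                continue
            try:
                _, sub = dv.check_zero_offset(sub)
            except dv.ZeroOffsetError as exc:
                logger.warning("zero-offset check skipped for id %s: %s", ind, exc)
            bounds = dv.segment_dives(sub, config.depth_threshold,
                                      config.min_dive_duration)
            metrics = dv.dive_metrics(bounds, sub, config.bottom_fraction)
            dive_rows.append(metrics)
            tsub = traj[traj["id"] == ind] if len(traj) else traj
            condensed_rows.append(dv.condense_to_fixes(metrics, tsub, config.window_s))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("dives", str(exc)) from exc
    dive_table = pd.concat(dive_rows, ignore_index=True) if dive_rows else pd.DataFrame()
    condensed = (pd.concat(condensed_rows, ignore_index=True)
                 if condensed_rows else pd.DataFrame())
    counts["dives_segmented"] = int(len(dive_table))
    counts["dives_condensed"] = int(len(condensed))
    outputs["dives"] = dive_table
    outputs["condensed"] = condensed

    # --- annotation ---
    try:
        steps_ann = annotate(world, steps) if len(steps) else steps
        cond_ann = annotate(world, condensed) if len(condensed) else condensed
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotate", str(exc)) from exc
    outputs["steps_annotated"] = steps_ann
    outputs["condensed_annotated"] = cond_ann

    # --- inference ---
    results: dict = {}
    corr = None
    split = False
    try:
        if len(steps_ann) >= 10:
            screen = collinearity_screen(steps_ann, config.collinearity_threshold)
            corr, split = screen.corr, screen.split
            sets = screen.variable_sets
            if config.model_sets == "A":
                sets = sets[:1]
        else:
            sets = []
        for resp in config.responses:
            table = _response_table(resp, steps_ann, cond_ann)
            if table is None or len(table) < 30:
                logger.warning("response %s skipped: too few rows", resp)
                continue
            entry: dict = {}
            for set_name, vset in zip(("A", "B"), sets):
                design, models = enumerate_and_fit(
                    table, vset, resp,
                    estimate_rho=config.estimate_rho,
                    estimate_delta=config.estimate_delta,
                    starts=config.gls_starts,
                )
                w = akaike_weights(models)
                entry[set_name] = model_average(models, w, response=resp,
                                               label=set_name)
                entry[f"models_{set_name}"] = models
                entry[f"design_{set_name}"] = design
            if "A" in entry and "B" in entry:
                entry["choice"] = compare_model_sets(entry["A"], entry["B"])
            if entry:
                results[resp] = entry
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("inference", str(exc)) from exc

    report = RunReport(
        seed=config.sim.seed, counts=counts, results=results,
        corr=corr, split=split, config=config,
    )
    from fintrack import __version__
    report.version = __version__
    if config.out_dir:
        _write_outputs(Path(config.out_dir), outputs, report, data)
    return report


def _response_table(resp: str, steps_ann: pd.DataFrame,
                    cond_ann: pd.DataFrame) -> pd.DataFrame | None:
    """Rows for one response, with non-positive log10 responses dropped."""
    if resp in ("speed", "turning_angle"):
        table = steps_ann
        col = resp
    else:
        if len(cond_ann) == 0:
            return None
        inv = {v: k for k, v in _DIVE_RESPONSES.items()}
        table = cond_ann.rename(columns={inv[resp]: resp})
        col = resp
    if col not in table.columns:
        return None
    table = table.dropna(subset=[col])
    if resp != "turning_angle":
        n0 = len(table)
        table = table[table[col] > 0]
        if len(table) < n0:
            logger.info("%s: dropped %d non-positive response rows",
                        resp, n0 - len(table))
    return table.reset_index(drop=True)


def _write_outputs(out: Path, outputs: dict, report: RunReport, data: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    header = f"# seed={report.seed} version={report.version}\n"
    for name, frame in outputs.items():
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
    summary = report.summary_table()
    with open(out / "model_averages.csv", "w") as fh:
        fh.write(header)
        summary.to_csv(fh, index=False)
    with open(out / "counts.json", "w") as fh:
        json.dump({"seed": report.seed, **report.counts}, fh, indent=2)


def make_fixtures(seed: int = 0) -> dict:
    """Miniature deterministic dataset for tests and demos.

    Two individuals, six hours, coarse 10x10 static and 4x4 dynamic
    grids, a high fix rate, at least one injected positional spike and
    one sub-10-s vertical excursion.  Regenerable byte-identically from
    the seed.
    """
    config = SimConfig(
        seed=seed, n_individuals=2, duration_h=6.0,
        extent_m=30_000.0, static_res_m=3_000.0, dynamic_res_m=7_500.0,
        fix_rate=12.0, outlier_rate=0.05, land_strip_m=4_500.0,
    )
    data = simulate_study(config)
    data["config"] = config

    # guarantee at least one ledgered spike
    if len(data["fix_ledgers"]) == 0:
        fixes = data["fixes"]
        sub = fixes[fixes["id"] == 0]
        i = sub.index[len(sub) // 2]
        prev_t = fixes.loc[i - 1, "time"]
        dt_h = (fixes.loc[i, "time"] - prev_t).total_seconds() / 3600.0
        mag = max(2_000.0, 16_000.0 * dt_h + 500.0)
        fixes.loc[i, "x"] += mag
        data["fix_ledgers"] = pd.DataFrame(
            [{"id": 0, "fix_index": int(i - sub.index[0]),
              "time": fixes.loc[i, "time"], "magnitude_m": mag}]
        )

    # inject a sub-10-s vertical excursion into a surface stretch
    depth = data["depth"]
    d0 = depth[depth["id"] == 0].reset_index()
    surf = d0["depth"].rolling(9, center=True).max() < 0.5
    pos = surf[surf].index
    if len(pos):
        c = int(pos[len(pos) // 2])
        rows = d0.loc[c - 2:c + 2, "index"]
        depth.loc[rows, "depth"] = 3.0
    return data
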