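"""GPS track cleaning, regularization and horizontal movement metrics.

The cleaning chain follows standard biologging practice for snapshot-GPS
deployments on small cetaceans: remove positional outliers identified by
an unlikely speed (> 15 km/h) followed by a return toward the previous
position, discard everything recorded within 24 h of tagging, then thin
the irregular fix series to a near-constant interval (15 min with a
+-2 min tolerance by default; 30 and 60 min variants for sensitivity
checks).  Movement speed is Euclidean displacement over elapsed time
between consecutive retained fixes; the turning angle is the absolute
heading change across three consecutive fixes, 0 (straight) to 180
degrees (reversal).  No statistic is ever computed across a gap that
violates the tolerance band: such gaps break the trajectory into
segments.

Fix tables are pandas frames with columns ``id, time, x, y`` (projected
metres, UTC timestamps).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default outlier speed threshold: 15 km/h in m/s.
SPEED_THRESHOLD_MS = 15_000.0 / 3600.0


def _dist(x: np.ndarray, y: np.ndarray, i: int, j: int) -> float:
    return float(np.hypot(x[j] - x[i], y[j] - y[i]))


def screen_outliers(
    fixes: pd.DataFrame,
    speed_threshold: float = SPEED_THRESHOLD_MS,
    return_ratio: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove single-fix positional spikes.

    A fix ``i`` is removed iff the speed from its predecessor exceeds
    ``speed_threshold`` (m/s) *and* the track then returns toward where
    it came from: ``dist(i-1, i+1) < return_ratio * dist(i-1, i)``.  The
    rule is applied iteratively (earliest offending fix first, then
    recompute) until no fix qualifies, so consecutive spikes and spikes
    revealed by earlier removals are handled.

    Returns ``(kept, removed)``; their union is the input.
    """
    fixes = fixes.sort_values("time", kind="stable").reset_index(drop=True)
    if len(fixes) < 3:
        logger.warning("outlier screen skipped: fewer than 3 fixes")
        return fixes, fixes.iloc[0:0]

    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    t = fixes["time"].to_numpy("datetime64[ns]").astype("int64") / 1e9
    alive = np.ones(len(fixes), dtype=bool)
    removed_order: list[int] = []

    while True:
        idx = np.flatnonzero(alive)
        if len(idx) < 3:
            break
        xi, yi, ti = x[idx], y[idx], t[idx]
        d_prev = np.hypot(np.diff(xi), np.diff(yi))
        dt = np.diff(ti)
        speed = np.divide(d_prev, dt, out=np.full_like(d_prev, np.inf), where=dt > 0)
        # candidate positions 1..n-2 in the alive sequence
        d_skip = np.hypot(xi[2:] - xi[:-2], yi[2:] - yi[:-2])
        bad = (speed[:-1] > speed_threshold) & (d_skip < return_ratio * d_prev[:-1])
        hits = np.flatnonzero(bad)
        if len(hits) == 0:
            break
        victim = idx[hits[0] + 1]  # earliest offending fix this pass
        alive[victim] = False
        removed_order.append(victim)

    kept = fixes.loc[alive].reset_index(drop=True)
    removed = fixes.loc[removed_order].reset_index(drop=True)
    return kept, removed


def discard_post_tagging(
    records: pd.DataFrame, tagging_time, window_h: float = 24.0,
    time_col: str = "time",
) -> pd.DataFrame:
    """Drop records within ``window_h`` hours after tagging.

    Applies identically to GPS fixes and depth samples (pass the frame's
    time column).  Retains records with ``time >= tagging_time + window``.
    """
    cutoff = pd.Timestamp(tagging_time) + pd.Timedelta(hours=window_h)
    out = records[records[time_col] >= cutoff].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("post-tagging discard removed every record")
    return out


def regularize(
    fixes: pd.DataFrame, interval_min: float = 15.0, tol_min: float = 2.0
) -> pd.DataFrame:
    """Thin fixes to a near-constant interval by greedy forward selection.

    Starting from the first fix, the next retained fix is the one whose
    gap from the last retained fix is closest to ``interval_min`` among
    gaps inside ``[interval - tol, interval + tol]`` (earlier fix wins a
    tie).  When no fix falls in the band, a new segment starts at the
    first fix with a gap beyond the band.  The returned frame carries a
    ``segment_id`` column; every within-segment gap respects the band.
    """
    fixes = fixes.sort_values("time", kind="stable").reset_index(drop=True)
    n = len(fixes)
    if n == 0:
        out = fixes.copy()
        out["segment_id"] = pd.Series(dtype="int64")
        return out
    t = fixes["time"].to_numpy("datetime64[ns]").astype("int64") / 60e9  # minutes
    lo, hi = interval_min - tol_min, interval_min + tol_min

    retained = [0]
    segments = [0]
    seg = 0
    anchor = 0
    while True:
        gaps = t[anchor + 1:] - t[anchor]
        in_band = np.flatnonzero((gaps >= lo) & (gaps <= hi))
        if len(in_band):
            rel = in_band[np.argmin(np.abs(gaps[in_band] - interval_min), )]
            nxt = anchor + 1 + int(rel)
        else:
            beyond = np.flatnonzero(gaps > hi)
            if len(beyond) == 0:
                break
            nxt = anchor + 1 + int(beyond[0])
            seg += 1
        retained.append(nxt)
        segments.append(seg)
        anchor = nxt
        if anchor == n - 1:
            break

    out = fixes.iloc[retained].reset_index(drop=True)
    out["segment_id"] = segments
    _assert_gap_band(out, interval_min, tol_min)
    return out


def _assert_gap_band(traj: pd.DataFrame, interval_min: float, tol_min: float) -> None:
    """Runtime check: all within-segment gaps inside the tolerance band."""
    if len(traj) < 2:
        return
    t = traj["time"].to_numpy("datetime64[ns]").astype("int64") / 60e9
    same = traj["segment_id"].to_numpy()[1:] == traj["segment_id"].to_numpy()[:-1]
    gaps = np.diff(t)[same]
    if len(gaps) and (
        gaps.min() < interval_min - tol_min - 1e-9
        or gaps.max() > interval_min + tol_min + 1e-9
    ):
        raise AssertionError("regularized gaps violate the tolerance band")


def step_metrics(traj: pd.DataFrame) -> pd.DataFrame:
    """Speed and turning angle along a regularized trajectory.

    One row per within-segment step end fix: ``speed`` (m/s) is the
    Euclidean distance from the previous fix divided by the elapsed
    seconds; ``turning_angle`` (degrees, 0-180) is the absolute heading
    change at that fix, defined when the next fix is in the same segment
    and both adjacent displacements are non-zero (otherwise NaN, logged).
    Rows carry the end fix's id, time and position for annotation.
    """
    rows = []
    for seg_id, seg in traj.groupby("segment_id", sort=True):
        if len(seg) < 2:
            continue
        x = seg["x"].to_numpy(float)
        y = seg["y"].to_numpy(float)
        t = seg["time"].to_numpy("datetime64[ns]").astype("int64") / 1e9
        dx, dy = np.diff(x), np.diff(y)
        d = np.hypot(dx, dy)
        speed = d / np.diff(t)
        heading = np.arctan2(dy, dx)
        # angle at interior fix i (between displacement into and out of i)
        turn = np.abs(np.degrees(np.arctan2(
            np.sin(heading[1:] - heading[:-1]), np.cos(heading[1:] - heading[:-1])
        )))
        turn = np.where((d[:-1] > 0) & (d[1:] > 0), turn, np.nan)
        if np.any((d[:-1] == 0) | (d[1:] == 0)):
            logger.info("zero-length displacement: turning angle undefined at "
                        "%d step(s)", int(np.sum((d[:-1] == 0) | (d[1:] == 0))))
        frame = seg.iloc[1:][["id", "time", "x", "y"]].copy()
        frame["segment_id"] = seg_id
        frame["speed"] = speed
        frame["turning_angle"] = np.append(turn, np.nan)
        rows.append(frame)
    if not rows:
        return pd.DataFrame(columns=["id", "time", "x", "y", "segment_id",
                                     "speed", "turning_angle"])
    return pd.concat(rows, ignore_index=True)
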