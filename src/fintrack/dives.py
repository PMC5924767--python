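"""Time-depth-recorder processing: dive segmentation and metrics.

A dive is any vertical excursion exceeding 2 m depth and lasting at least
10 s.  From each dive four metrics are extracted: duration (s), maximum
depth (m), wiggliness — the cumulative absolute vertical distance (m)
covered during the bottom phase, a proxy for prey chasing — and the
post-dive surface duration (s).  The bottom phase is defined as samples
at or below ``bottom_fraction`` (default 0.8) of the dive's maximum
depth.  Dives are optionally condensed onto regularized GPS fixes (dive
start within +-30 s of the fix timestamp) so that dive behaviour can be
related to environmental conditions at a located position.

Depth tables are pandas frames with columns ``id, time, depth`` (metres,
positive down, 1 Hz cadence).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ZeroOffsetError(ValueError):
    """Surface intervals cannot be found, so drift cannot be estimated."""


def check_zero_offset(
    series: pd.DataFrame,
    max_drift_m_per_day: float = 0.1,
    min_span_h: float = 1.0,
    surface_cut_m: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """Estimate pressure-transducer drift and correct it when material.

    Drift is the Theil-Sen slope of a robust line through per-hour
    surface-depth minima.  When the estimated drift exceeds
    ``max_drift_m_per_day`` in magnitude the fitted offset is subtracted;
    otherwise the series is returned unchanged.

    Returns ``(drift_m_per_day, series)``.
    """
    t = series["time"].to_numpy("datetime64[ns]").astype("int64") / 1e9
    if len(series) == 0 or (t[-1] - t[0]) < min_span_h * 3600.0:
        raise ZeroOffsetError(f"need at least {min_span_h} h of data")
    hours = np.floor((t - t[0]) / 3600.0).astype(int)
    depth = series["depth"].to_numpy(float)
    frame = pd.DataFrame({"hour": hours, "depth": depth})
    minima = frame.groupby("hour")["depth"].min()
    surface = minima[minima < surface_cut_m]
    if len(surface) < 2:
        raise ZeroOffsetError("no surface intervals found; cannot estimate drift")
    th = surface.index.to_numpy(float) + 0.5  # hour-bin midpoints
    res = stats.theilslopes(surface.to_numpy(), th)
    drift = res.slope * 24.0
    if abs(drift) <= max_drift_m_per_day:
        return float(drift), series
    logger.warning("zero-offset drift %.3f m/day exceeds %.3f; correcting",
                   drift, max_drift_m_per_day)
    offset = res.intercept + res.slope * ((t - t[0]) / 3600.0)
    corrected = series.copy()
    corrected["depth"] = depth - offset
    return float(drift), corrected


def segment_dives(
    series: pd.DataFrame, depth_threshold: float = 2.0, min_duration: float = 10.0
) -> pd.DataFrame:
    """Find dives: maximal runs of samples deeper than ``depth_threshold``
    spanning at least ``min_duration`` seconds (last minus first sample).

    Returns one row per kept dive with integer positions ``start_idx`` /
    ``end_idx`` into the (time-sorted) series and the boundary times.
    """
    cols = ["id", "start_idx", "end_idx", "start_time", "end_time"]
    if len(series) == 0:
        return pd.DataFrame(columns=cols)
    series = series.sort_values("time", kind="stable").reset_index(drop=True)
    depth = series["depth"].to_numpy(float)
    above = depth > depth_threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above) - 1]
    t = series["time"].to_numpy("datetime64[ns]")
    dur = (t[ends] - t[starts]) / np.timedelta64(1, "s")
    keep = dur >= min_duration
    out = pd.DataFrame({
        "id": series["id"].iloc[starts[keep]].to_numpy(),
        "start_idx": starts[keep],
        "end_idx": ends[keep],
        "start_time": t[starts[keep]],
        "end_time": t[ends[keep]],
    })
    return out


def dive_metrics(
    boundaries: pd.DataFrame, series: pd.DataFrame, bottom_fraction: float = 0.8
) -> pd.DataFrame:
    """The four dive metrics for each segmented dive.

    duration (s) = last minus first sample time; max_depth (m) = deepest
    sample; wiggliness (m) = sum of absolute depth changes over pairs of
    consecutive samples that both lie in the bottom phase (depth >=
    ``bottom_fraction`` x max_depth); post_dive_duration (s) = gap to the
    next dive's start (NaN for the last dive of an individual).
    """
    series = series.sort_values("time", kind="stable").reset_index(drop=True)
    depth = series["depth"].to_numpy(float)
    t = series["time"].to_numpy("datetime64[ns]")
    n = len(series)
    rows = []
    for rec in boundaries.itertuples(index=False):
        i, j = int(rec.start_idx), int(rec.end_idx)
        if not (0 <= i <= j < n) or t[i] != np.datetime64(rec.start_time):
            raise ValueError("dive boundaries are inconsistent with the series")
        seg = depth[i:j + 1]
        mx = float(seg.max())
        inb = seg >= bottom_fraction * mx
        pair = inb[:-1] & inb[1:]
        wig = float(np.abs(np.diff(seg))[pair].sum()) if len(seg) > 1 else 0.0
        rows.append({
            "id": rec.id,
            "start_time": rec.start_time,
            "end_time": rec.end_time,
            "duration": float((t[j] - t[i]) / np.timedelta64(1, "s")),
            "max_depth": mx,
            "wiggliness": wig,
        })
    out = pd.DataFrame(rows, columns=["id", "start_time", "end_time", "duration",
                                      "max_depth", "wiggliness"])
    if len(out):
        nxt = out["start_time"].shift(-1)
        pdd = (nxt - out["end_time"]).dt.total_seconds()
        same = out["id"].shift(-1) == out["id"]
        out["post_dive_duration"] = pdd.where(same)
    else:
        out["post_dive_duration"] = pd.Series(dtype=float)
    return out


def condense_to_fixes(
    dives: pd.DataFrame, trajectory: pd.DataFrame, window_s: float = 60.0
) -> pd.DataFrame:
    """Attach dives to regularized GPS fixes.

    A dive matches a fix when its start time lies within
    ``[fix - window/2, fix + window/2]``.  Each dive is assigned to its
    nearest fix only; when several dives match one fix the dive whose
    start is closest to the fix timestamp wins.  Output rows carry the
    fix position and the dive metrics.
    """
    out_cols = ["id", "time", "x", "y", "segment_id", "start_time", "duration",
                "max_depth", "wiggliness", "post_dive_duration"]
    if len(dives) == 0 or len(trajectory) == 0:
        return pd.DataFrame(columns=out_cols)
    half = pd.Timedelta(seconds=window_s / 2)
    pieces = []
    for ind, dsub in dives.groupby("id"):
        tsub = trajectory[trajectory["id"] == ind]
        if len(tsub) == 0:
            continue
        d = dsub.sort_values("start_time").reset_index(drop=True)
        f = tsub.sort_values("time").reset_index(drop=True)
        merged = pd.merge_asof(
            d, f[["time", "x", "y", "segment_id"]],
            left_on="start_time", right_on="time", direction="nearest",
        )
        delta = (merged["start_time"] - merged["time"]).abs()
        merged = merged[delta <= half].copy()
        merged["abs_offset"] = (merged["start_time"] - merged["time"]).abs()
        merged = (merged.sort_values(["time", "abs_offset"], kind="stable")
                        .drop_duplicates(subset="time", keep="first"))
        pieces.append(merged[out_cols])
    if not pieces:
        return pd.DataFrame(columns=out_cols)
    return pd.concat(pieces, ignore_index=True).sort_values(
        ["id", "time"]).reset_index(drop=True)
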