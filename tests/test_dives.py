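"""Dive segmentation, metrics and condensing onto fixes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fintrack import dives as dv
from fintrack.validation import reference_dive_scan
from tests.conftest import depth_frame, fix_frame


class TestZeroOffset:
    def test_clean_series_unchanged(self):
        depth = np.tile(np.r_[np.zeros(60), np.full(60, 8.0)], 40)
        series = depth_frame(depth)
        drift, out = dv.check_zero_offset(series)
        assert drift == pytest.approx(0.0, abs=1e-9)
        assert out is series

    def test_planted_drift_detected_and_corrected(self):
        n = 2 * 86400  # two days
        base = np.tile(np.r_[np.zeros(60), np.full(60, 8.0)], n // 120)[:n]
        t_days = np.arange(n) / 86400.0
        series = depth_frame(base + 1.0 * t_days)
        drift, out = dv.check_zero_offset(series)
        assert 0.9 <= drift <= 1.1
        hours = np.arange(n) // 3600
        minima = pd.Series(out["depth"].to_numpy()).groupby(hours).min()
        assert abs(minima.median()) < 0.05

    def test_short_series_raises(self):
        series = depth_frame(np.zeros(1800))  # 30 min
        with pytest.raises(dv.ZeroOffsetError):
            dv.check_zero_offset(series)

    def test_no_surface_raises(self):
        depth = np.full(7200, 20.0)
        with pytest.raises(dv.ZeroOffsetError):
            dv.check_zero_offset(depth_frame(depth))


class TestSegmentDives:
    def test_short_excursion_dropped(self):
        series = depth_frame([0, 0, 3, 5, 3, 0])
        assert len(dv.segment_dives(series)) == 0

    def test_eleven_second_run_kept(self):
        # 12 consecutive samples above threshold: duration 11 s >= 10 s
        series = depth_frame([0] + [4.0] * 12 + [0])
        out = dv.segment_dives(series)
        assert len(out) == 1
        dur = (out["end_time"] - out["start_time"]).dt.total_seconds().iloc[0]
        assert dur == 11.0

    def test_empty_series(self):
        assert len(dv.segment_dives(depth_frame([]))) == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_reference_scan(self, s):
        depth = np.abs(np.random.default_rng(s).normal(1.5, 1.5, 400).cumsum() % 10)
        series = depth_frame(depth)
        got = list(zip(dv.segment_dives(series)["start_idx"],
                       dv.segment_dives(series)["end_idx"]))
        assert got == reference_dive_scan(depth)

    def test_partition_properties(self, fixture_data):
        sub = fixture_data["depth"]
        sub = sub[sub["id"] == 0].reset_index(drop=True)
        out = dv.segment_dives(sub)
        starts = out["start_idx"].to_numpy()
        ends = out["end_idx"].to_numpy()
        assert (ends >= starts).all()
        assert (starts[1:] > ends[:-1]).all()  # disjoint and ordered
        # every above-threshold sample outside a kept dive is in a <10 s run
        depth = sub["depth"].to_numpy()
        covered = np.zeros(len(depth), bool)
        for i, j in zip(starts, ends):
            covered[i:j + 1] = True
        for i, j in reference_dive_scan(depth, min_duration=0):
            if not covered[i:j + 1].any():
                assert j - i < 10


class TestDiveMetrics:
    def run(self, depths, **kw):
        series = depth_frame(depths)
        bounds = dv.segment_dives(series)
        return dv.dive_metrics(bounds, series, **kw)

    def test_v_dive_has_zero_wiggliness(self):
        # only the apex sample reaches the 80% bottom band
        down = np.arange(3.0, 16.0, 2.0)
        prof = np.r_[0, down, 20.0, down[::-1], 0]
        out = self.run(prof)
        assert len(out) == 1
        assert out["wiggliness"].iloc[0] == pytest.approx(0.0)

    def test_alternating_bottom_sums_absolute_changes(self):
        prof = [0, 0] + [10, 12, 10, 12, 10] * 3 + [0, 0]
        out = self.run(prof)
        # bottom phase (>= 0.8 * 12 = 9.6 m) spans all 15 samples:
        # fourteen |delta| terms of 0 or 2 summing to 24
        assert out["wiggliness"].iloc[0] == pytest.approx(24.0)

    def test_bottom_phase_excludes_shallow_samples(self):
        prof = [0.0, 10, 12, 10, 12, 10, 0.0]
        series = depth_frame(prof)
        bounds = pd.DataFrame({"id": [0], "start_idx": [1], "end_idx": [5],
                               "start_time": [series["time"][1]],
                               "end_time": [series["time"][5]]})
        out = dv.dive_metrics(bounds, series)
        assert out["wiggliness"].iloc[0] == pytest.approx(8.0)
        assert out["max_depth"].iloc[0] == 12.0
        assert out["duration"].iloc[0] == 4.0

    def test_wiggliness_monotone_in_bottom_fraction(self, rng):
        depth = np.abs(rng.normal(3, 3, 2000).cumsum() % 40)
        series = depth_frame(depth)
        bounds = dv.segment_dives(series)
        prev = None
        for frac in (0.5, 0.65, 0.8, 0.95):
            total = dv.dive_metrics(bounds, series, bottom_fraction=frac)[
                "wiggliness"].sum()
            if prev is not None:
                assert total <= prev + 1e-9
            prev = total

    def test_post_dive_duration_chain(self):
        prof = [0] * 2 + [5.0] * 15 + [0] * 30 + [5.0] * 15 + [0] * 2
        out = self.run(prof)
        assert len(out) == 2
        assert out["post_dive_duration"].iloc[0] == pytest.approx(31.0)
        assert np.isnan(out["post_dive_duration"].iloc[1])

    def test_inconsistent_boundaries_raise(self):
        series = depth_frame([0, 5, 5, 0])
        bounds = pd.DataFrame({"id": [0], "start_idx": [1], "end_idx": [2],
                               "start_time": [pd.Timestamp("1999-01-01")],
                               "end_time": [series["time"][2]]})
        with pytest.raises(ValueError, match="inconsistent"):
            dv.dive_metrics(bounds, series)


class TestCondense:
    def make_dives(self, offsets_s, t0="2020-01-01"):
        t0 = pd.Timestamp(t0)
        return pd.DataFrame({
            "id": 0,
            "start_time": [t0 + pd.Timedelta(seconds=s) for s in offsets_s],
            "duration": 20.0, "max_depth": 5.0, "wiggliness": 1.0,
            "post_dive_duration": 30.0,
        })

    def make_traj(self, offsets_s, t0="2020-01-01"):
        traj = fix_frame(offsets_s, np.arange(len(offsets_s)),
                         np.zeros(len(offsets_s)), t0=t0)
        traj["segment_id"] = 0
        return traj

    def test_within_half_window_matched(self):
        out = dv.condense_to_fixes(self.make_dives([900 - 29]), self.make_traj([900]))
        assert len(out) == 1

    def test_outside_half_window_unmatched(self):
        out = dv.condense_to_fixes(self.make_dives([900 - 31]), self.make_traj([900]))
        assert len(out) == 0

    def test_nearest_dive_wins_per_fix(self):
        out = dv.condense_to_fixes(self.make_dives([880, 905]), self.make_traj([900]))
        assert len(out) == 1
        assert out["start_time"].iloc[0].second == 5  # the 905 s dive

    def test_matches_brute_force_double_loop(self, fixture_data):
        from fintrack import tracks as tr

        fixes = fixture_data["fixes"]
        depth = fixture_data["depth"]
        traj = pd.concat([
            tr.regularize(sub.reset_index(drop=True))
            for _, sub in fixes.groupby("id")
        ], ignore_index=True)
        dives = pd.concat([
            dv.dive_metrics(dv.segment_dives(sub.reset_index(drop=True)),
                            sub.reset_index(drop=True))
            for _, sub in depth.groupby("id")
        ], ignore_index=True)
        got = dv.condense_to_fixes(dives, traj)

        # oracle: all (dive, fix) pairs, nearest fix per dive, best dive per fix
        count = 0
        for ind in traj["id"].unique():
            dsub = dives[dives["id"] == ind]
            fsub = traj[traj["id"] == ind]
            best_per_fix = {}
            for _, drow in dsub.iterrows():
                offs = (fsub["time"] - drow["start_time"]).dt.total_seconds().abs()
                if not len(offs) or offs.min() > 30:
                    continue
                fi = offs.idxmin()
                if fi not in best_per_fix or offs[fi] < best_per_fix[fi]:
                    best_per_fix[fi] = offs[fi]
            count += len(best_per_fix)
        assert len(got) == count


def test_duration_conservation(fixture_data):
    """Dive + surface + dropped-run durations tile the record span."""
    sub = fixture_data["depth"]
    sub = sub[sub["id"] == 1].reset_index(drop=True)
    out = dv.segment_dives(sub)
    span = (sub["time"].iloc[-1] - sub["time"].iloc[0]).total_seconds()
    dive_s = (out["end_time"] - out["start_time"]).dt.total_seconds().sum()
    depth = sub["depth"].to_numpy()
    covered = np.zeros(len(depth), bool)
    for i, j in zip(out["start_idx"], out["end_idx"]):
        covered[i:j + 1] = True
    other = np.sum(~covered)  # surface samples plus dropped short runs
    assert abs(dive_s + other - span) <= 1 + len(out)
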