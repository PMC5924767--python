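"""Generator structure: fields, paths, fixes, depth traces, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fintrack import dives as dv
from fintrack.synthetic import (
    SimConfig,
    TIDAL_PERIOD_H,
    generate_env_world,
    simulate_depth_series,
    simulate_gps_fixes,
    simulate_study,
    simulate_track,
)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"static_res_m": -1}, {"fix_rate": 0}, {"outlier_rate": 0.2},
        {"rho_true": 1.0}, {"var_mult": (1.0, -2.0)}, {"var_mult": (2.0, 1.0)},
    ])
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="4x4"):
            generate_env_world(SimConfig(extent_m=10_000.0))


class TestEnvWorldGeneration:
    def test_ssh_is_m2_periodic(self):
        # 50 tidal cycles = 621.0 h lands exactly on the hourly axis
        cfg = SimConfig(seed=2, duration_h=620.0)
        world = generate_env_world(cfg)
        lag = int(round(50 * TIDAL_PERIOD_H))
        ssh = world.dynamic["ssh"].values
        assert np.allclose(ssh[0], ssh[lag], atol=1e-9)

    def test_salinity_gradient_monotone_eastward(self):
        world = generate_env_world(SimConfig(seed=3, duration_h=24.0))
        col_means = world.dynamic["salinity"].values.mean(axis=(0, 1))
        assert (np.diff(col_means) >= 0).all()
        assert 29.0 < col_means[0] < col_means[-1] < 36.0

    def test_derived_layers_present_and_finite(self, small_world):
        world, _ = small_world
        for name in ("bathymetry", "slope", "distance_to_coast"):
            assert np.isfinite(world.static[name].values).all()
        for name in ("sst", "salinity", "ssh", "velocity"):
            assert np.isfinite(world.dynamic[name].values).all()
        assert world.static["slope"].values.min() >= 0.0
        # land strip carries zero distance-to-coast, sea positive
        land = world.static["bathymetry"].values <= 0
        assert (world.static["distance_to_coast"].values[land] == 0).all()
        assert (world.static["distance_to_coast"].values[~land] > 0).all()


class TestTrack:
    def test_zero_duration_gives_empty_path(self, small_world):
        world, cfg = small_world
        path = simulate_track(world, dataclasses.replace(cfg, duration_h=0.0), 0)
        assert len(path) == 0

    def test_path_inside_grid_and_speed_capped(self, small_world):
        world, cfg = small_world
        path = simulate_track(world, cfg, 0)
        assert path["x"].between(0, cfg.extent_m).all()
        assert path["y"].between(0, cfg.extent_m - cfg.land_strip_m).all()
        step = np.hypot(path["x"].diff(), path["y"].diff()).dropna()
        assert (step / 60.0).max() <= 2.8
        assert path["time"].is_monotonic_increasing
        assert not path.drop(columns="time").isna().any().any()

    def test_foraging_slower_and_more_tortuous(self, small_world):
        world, cfg = small_world
        paths = [simulate_track(world, dataclasses.replace(cfg, seed=s), 0)
                 for s in range(4)]
        path = pd.concat(paths, ignore_index=True)
        sp = path.groupby("state")["speed"].mean()
        assert sp[1] < sp[0]

    def test_null_effects_leave_state_unconditioned(self, small_world):
        world, cfg = small_world
        null = dataclasses.replace(cfg, effect_spec={})
        slopes = []
        for s in range(10):
            path = simulate_track(world, dataclasses.replace(null, seed=100 + s), 0)
            from fintrack.environment import sample_environment
            covs = sample_environment(world, path["x"].values, path["y"].values,
                                      path["time"].values)
            res = stats.linregress(covs["salinity"], path["state"].astype(float))
            slopes.append(res.slope)
        t = stats.ttest_1samp(slopes, 0.0)
        assert t.pvalue > 0.01  # no detectable state-salinity coupling

    def test_planted_salinity_effect_slows_speed(self, small_world):
        world, cfg = small_world
        from fintrack.environment import sample_environment
        lo_all, hi_all = [], []
        for s in range(20):
            path = simulate_track(world, dataclasses.replace(cfg, seed=200 + s), 0)
            covs = sample_environment(world, path["x"].values, path["y"].values,
                                      path["time"].values)
            sal = covs["salinity"]
            q1, q3 = sal.quantile([0.25, 0.75])
            lo_all.append(path["speed"][(sal <= q1).to_numpy()].mean())
            hi_all.append(path["speed"][(sal >= q3).to_numpy()].mean())
        assert np.nanmean(hi_all) < np.nanmean(lo_all)


class TestGPSFixes:
    def test_zero_outlier_rate_empty_ledger(self, small_world):
        world, cfg = small_world
        path = simulate_track(world, cfg, 0)
        _, ledger = simulate_gps_fixes(
            path, dataclasses.replace(cfg, outlier_rate=0.0), 0)
        assert len(ledger) == 0

    def test_fix_count_in_poisson_band(self):
        cfg = SimConfig(seed=9, n_individuals=1, duration_h=100.0, fix_rate=4.0,
                        outlier_rate=0.0)
        world = generate_env_world(cfg)
        path = simulate_track(world, cfg, 0)
        fixes, _ = simulate_gps_fixes(path, cfg, 0)
        # binomial thinning of 2000 attempts at p = 0.2: 99% band
        n, p = 2000, 0.2
        sd = np.sqrt(n * p * (1 - p))
        assert n * p - 2.58 * sd <= len(fixes) <= n * p + 2.58 * sd

    def test_spikes_exceed_speed_threshold(self, small_world):
        world, cfg = small_world
        spiky = dataclasses.replace(cfg, outlier_rate=0.1, seed=11)
        path = simulate_track(world, spiky, 0)
        fixes, ledger = simulate_gps_fixes(path, spiky, 0)
        assert len(ledger) >= 1
        for _, row in ledger.iterrows():
            i = int(row["fix_index"])
            d = np.hypot(fixes["x"][i] - fixes["x"][i - 1],
                         fixes["y"][i] - fixes["y"][i - 1])
            dt = (fixes["time"][i] - fixes["time"][i - 1]).total_seconds()
            assert d / dt > 15_000 / 3600


class TestDepthSeries:
    def test_dive_ceiling_below_threshold_gives_no_dives(self, small_world):
        world, cfg = small_world
        shallow = dataclasses.replace(cfg, max_dive_depth_m=1.9)
        path = simulate_track(world, shallow, 0)
        series, ledger = simulate_depth_series(path, shallow, 0)
        assert len(dv.segment_dives(series)) == 0
        assert len(ledger) == 0

    def test_ledger_agrees_with_segmentation(self, small_world):
        world, cfg = small_world
        path = simulate_track(world, cfg, 0)
        series, ledger = simulate_depth_series(path, cfg, 0)
        seg = dv.segment_dives(series)
        assert len(seg) == len(ledger)
        assert (seg["start_time"].to_numpy()
                == ledger["start_time"].to_numpy()).all()

    def test_max_depth_bounded_by_bathymetry(self, small_world):
        world, cfg = small_world
        path = simulate_track(world, cfg, 0)
        _, ledger = simulate_depth_series(path, cfg, 0)
        assert ledger["max_depth"].max() <= path["depth_m"].max() + 0.2

    def test_one_hz_cadence_and_sane_range(self, small_world):
        world, cfg = small_world
        path = simulate_track(world, cfg, 0)
        series, _ = simulate_depth_series(path, cfg, 0)
        dt = series["time"].diff().dropna().dt.total_seconds()
        assert (dt == 1.0).all()
        assert series["depth"].min() >= -0.5


def test_full_study_is_deterministic():
    cfg = SimConfig(seed=17, n_individuals=2, duration_h=4.0)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    pd.testing.assert_frame_equal(a["fixes"], b["fixes"])
    pd.testing.assert_frame_equal(a["depth"], b["depth"])
    pd.testing.assert_frame_equal(a["dive_ledgers"], b["dive_ledgers"])
    assert a["world"].static.identical(b["world"].static)
    assert a["world"].dynamic.identical(b["world"].dynamic)
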