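import numpy as np
import pandas as pd
import pytest

from batforage import preprocessing, synthetic
from conftest import _dummy_track, make_series


def _track_from_xy(x, y, interval=120.0, colony_id="colony1"):
    n = len(x)
    times = pd.DatetimeIndex(
        pd.Timestamp("2022-03-01 23:00", tz="UTC")
        + pd.to_timedelta(np.arange(n) * interval, "s")
    )
    return _dummy_track(times, np.asarray(x, float), np.asarray(y, float),
                        colony_id=colony_id)


class TestRemoveOutliers:
    def test_speed_spike_removed(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        # middle fix implies 20 m/s both ways at a 120 s interval
        tr = _track_from_xy([rx, rx + 2400, rx], [ry, ry, ry])
        clean, log = preprocessing.remove_outliers(tr, land)
        assert len(clean) == 2
        assert list(log["reason"]) == ["speed"]

    def test_clean_track_unchanged(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        tr = _track_from_xy([rx, rx + 1000, rx + 2000], [ry, ry, ry])
        clean, log = preprocessing.remove_outliers(tr, land)
        assert len(clean) == 3 and log.empty

    def test_far_over_water_fix_removed(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        xs = [rx, rx + 100, rx + 200, rx + 300]
        ys = [ry, ry, ry + 65_000, ry]  # 65 km north: open water, > 60 km range
        tr = _track_from_xy(xs, ys, interval=3600.0)  # slow enough to pass speed
        clean, log = preprocessing.remove_outliers(tr, land)
        assert len(clean) == 3
        assert list(log["reason"]) == ["water_range"]

    def test_idempotent(self, small_dataset, landscape_cfg):
        land, _ = landscape_cfg
        tr = small_dataset.tracks[0]
        once, _ = preprocessing.remove_outliers(tr, land)
        twice, log2 = preprocessing.remove_outliers(once, land)
        assert log2.empty
        pd.testing.assert_frame_equal(once.fixes, twice.fixes)

    def test_all_removed_raises(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        tr = _track_from_xy([rx, rx + 100], [ry + 70_000, ry + 70_000])
        with pytest.raises(preprocessing.EmptyTrackError):
            preprocessing.remove_outliers(tr, land)

    def test_injected_spikes_all_caught_no_clean_lost(self, landscape_cfg):
        """Precision and recall 1 on the synthetic corruption fixture."""
        land, cfg = landscape_cfg
        scen = synthetic.default_scenarios(1, 1)[:1]
        ds = synthetic.simulate_dataset(
            scen, seed=11, landscape=land, config=cfg,
            corruptions=synthetic.CorruptionSpec(n_speed_spikes=4),
        )
        tr = ds.tracks[0]
        clean, log = preprocessing.remove_outliers(tr, land)
        corrupted = set(
            pd.to_datetime(
                ds.corruption_logs[(tr.individual_id, tr.night_date)]["timestamp"]
            )
        )
        removed = set(pd.to_datetime(log["timestamp"]))
        assert removed == corrupted


class TestDownsample:
    def test_exact_divisor_keeps_every_fourth(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        n = 41
        tr = _track_from_xy(rx + 10.0 * np.arange(n), np.full(n, ry), interval=30.0)
        out = preprocessing.downsample(tr, 120.0)
        assert len(out) == 11
        np.testing.assert_allclose(out.fixes["x"], rx + 10.0 * np.arange(0, 41, 4))

    def test_already_at_target_identity(self, small_dataset):
        tr = small_dataset.tracks[0]
        out = preprocessing.downsample(tr, 120.0)
        assert len(out) == len(tr)

    def test_native_coarser_than_target_warns(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        tr = _track_from_xy([rx, rx + 10, rx + 20], [ry] * 3, interval=300.0)
        with pytest.warns(UserWarning, match="exceeds target"):
            out = preprocessing.downsample(tr, 120.0)
        assert len(out) == 3

    def test_jittered_fixes_land_near_grid(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        rng = np.random.default_rng(5)
        t = np.cumsum(rng.uniform(25, 35, 120))
        times = pd.Timestamp("2022-03-01 23:00", tz="UTC") + pd.to_timedelta(t, "s")
        tr = _dummy_track(pd.DatetimeIndex(times),
                          rx + np.arange(120.0), np.full(120, ry))
        out = preprocessing.downsample(tr, 120.0)
        ts = out.fixes["timestamp"].astype("int64").to_numpy() / 1e9
        grid_offsets = (ts - ts[0]) % 120.0
        offsets = np.minimum(grid_offsets, 120.0 - grid_offsets)
        assert np.all(offsets <= 60.0)
        assert len(out) <= int((t[-1] - t[0]) // 120) + 1


class TestRegularize:
    def test_gap_inserts_missing_slots(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        times = pd.DatetimeIndex(
            pd.Timestamp("2022-03-01 23:00", tz="UTC")
            + pd.to_timedelta([0, 120, 240, 600, 720], "s")  # 6-min gap
        )
        tr = _dummy_track(times, rx + np.arange(5.0) * 100, np.full(5, ry))
        s = preprocessing.regularize(tr, 120.0)
        assert s.n_slots == 7
        assert (~s.observed).sum() == 2

    def test_collinear_track_zero_angles(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        tr = _track_from_xy(rx + 500.0 * np.arange(6), np.full(6, ry))
        s = preprocessing.regularize(tr, 120.0)
        np.testing.assert_allclose(s.angle[2:], 0.0, atol=1e-12)

    def test_square_path_left_turn_convention(self):
        s = make_series([0, 1000, 1000, 0], [0, 0, 1000, 1000])
        np.testing.assert_allclose(s.angle[2:], np.pi / 2)

    def test_too_few_fixes_raises(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        tr = _track_from_xy([rx, rx + 10], [ry, ry])
        with pytest.raises(preprocessing.InsufficientDataError):
            preprocessing.regularize(tr, 120.0)

    def test_gap_free_track_has_no_missing_slots(self, small_dataset):
        tr = preprocessing.downsample(small_dataset.tracks[0], 120.0)
        s = preprocessing.regularize(tr, 120.0)
        assert (~s.observed).sum() == 0


class TestClassifyNight:
    def test_simulated_full_night_complete(self, small_dataset, landscape_cfg):
        land, _ = landscape_cfg
        tr = small_dataset.tracks[0]
        roost = land.roosts[tr.colony_id]
        assert preprocessing.classify_night(tr, roost) == "complete"

    def test_truncated_night_incomplete(self, small_dataset, landscape_cfg):
        land, _ = landscape_cfg
        tr = small_dataset.tracks[0]
        half = tr.replace_fixes(tr.fixes.iloc[: len(tr) // 2])
        roost = land.roosts[tr.colony_id]
        assert preprocessing.classify_night(half, roost) == "incomplete"

    def test_never_leaving_roost_incomplete(self, landscape_cfg):
        land, _ = landscape_cfg
        rx, ry = land.roosts["colony1"]
        tr = _track_from_xy(rx + 50.0 * np.arange(4), np.full(4, ry))
        assert preprocessing.classify_night(tr, (rx, ry)) == "incomplete"


def test_clean_synthetic_data_passes_untouched(small_dataset, landscape_cfg):
    """With corruptions disabled the whole cleaning stage is a no-op."""
    land, _ = landscape_cfg
    for tr in small_dataset.tracks[:3]:
        assert np.nanmax(tr.fixes["ground_speed"]) < 15.0
        clean, log = preprocessing.remove_outliers(tr, land)
        assert log.empty and len(clean) == len(tr)
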