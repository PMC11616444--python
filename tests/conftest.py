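import numpy as np
import pandas as pd
import pytest

from batforage import hmm, preprocessing, synthetic


@pytest.fixture(scope="session")
def landscape_cfg():
    return synthetic.make_landscape(seed=1)


@pytest.fixture(scope="session")
def small_dataset(landscape_cfg):
    """Two dry-season colonies, 2 bats × 2 nights each (8 bat-nights)."""
    land, cfg = landscape_cfg
    scenarios = synthetic.default_scenarios(2, 2)[:2]
    return synthetic.simulate_dataset(scenarios, seed=7, landscape=land, config=cfg)


@pytest.fixture(scope="session")
def small_series(small_dataset):
    return [preprocessing.regularize(t, 120.0) for t in small_dataset.tracks]


@pytest.fixture(scope="session")
def truth_sequences(small_dataset):
    return [
        synthetic.truth_state_sequence(
            small_dataset.states[(t.individual_id, t.night_date)]
        )
        for t in small_dataset.tracks
    ]


@pytest.fixture(scope="session")
def pooled_hmm(small_series):
    return hmm.fit(small_series, n_states=2, n_restarts=2, seed=0)


@pytest.fixture
def square_landscape():
    """A featureless all-land 60×60 km landscape for geometric tests."""
    from shapely.geometry import MultiPolygon, box

    from batforage.data_io import Landscape

    big = box(-30_000, -30_000, 30_000, 30_000)
    return Landscape(
        land_polygons=MultiPolygon([big]),
        home_island_polygon=big,
        roosts={"c": (0.0, 0.0)},
        bounding_box=big.bounds,
    )


def make_series(x, y, interval=120.0):
    """Build a StepSeries from explicit planar coordinates (no gaps)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    times = pd.DatetimeIndex(
        pd.Timestamp("2022-03-01 23:00", tz="UTC")
        + pd.to_timedelta(np.arange(n) * interval, "s")
    )
    step = np.full(n, np.nan)
    angle = np.full(n, np.nan)
    step[1:] = np.hypot(np.diff(x), np.diff(y))
    if n >= 3:
        from batforage.geometry import turning_angles

        angle[2:] = turning_angles(x, y)
    track = _dummy_track(times, x, y)
    return preprocessing.StepSeries(
        track=track, interval=interval, times=times, x=x, y=y, step=step, angle=angle
    )


def _dummy_track(times, x, y, colony_id="c", individual_id="bat0"):
    from batforage.data_io import GpsTrack, recompute_speeds

    fixes = recompute_speeds(
        pd.DataFrame({"timestamp": times, "lon": 0.0, "lat": 0.0, "x": x, "y": y})
    )
    return GpsTrack(
        individual_id=individual_id,
        colony_id=colony_id,
        season="dry",
        tracking_period="t1",
        night_date=pd.Timestamp("2022-03-01"),
        fixes=fixes,
        sampling_interval=120.0,
    )
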