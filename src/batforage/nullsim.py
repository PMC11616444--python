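"""Landscape-constrained null-track simulation.

Null tracks answer "where *could* the bats have foraged, given how they
move?": trajectories are sampled from a fitted movement kernel with no
knowledge of resources, subject only to physical constraints — a bat
cannot settle into foraging over open water, stays inside the study
bounding box, and is biased back toward the roost in the second half of
the night so the trip remains a central-place excursion.  Comparing
foraging-location spread between these null cohorts and observed tracks
quantifies how much more of the available landscape the colony *could*
have used.

The exact constrained-simulation procedure is a reconstruction: each
choice (rejection rule, return-bias onset, bounding-box handling) sits
behind a config field so alternatives can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GpsTrack, Landscape, StudyConfig
from .geometry import wrap_angle
from .hmm import (
    COMMUTING,
    FORAGING,
    MovementKernel,
    StateSequence,
    sample_wrapped_cauchy,
)
from .metrics import ForagingLocation, extract_foraging_locations
from .preprocessing import StepSeries, regularize

logger = logging.getLogger(__name__)


@dataclass
class NullConstraints:
    """Tunable constraints of the null simulation."""

    return_onset_fraction: float = 0.5  # from this fraction of the night on,
    # commuting headings are re-centred on the bearing to the roost
    return_home_radius_m: float = 2000.0  # during the return phase, a bat
    # farther than this from the roost keeps commuting (no new foraging
    # bouts), so the trip closes like a central-place excursion
    max_heading_attempts: int = 100
    max_night_resamples: int = 20
    bbox_pad_m: float = 5000.0


@dataclass
class NullTrackSpec:
    """Template for one null night: timing from an observed night, movement
    from a pooled colony × season kernel."""

    start_time: pd.Timestamp
    n_slots: int
    interval_s: float
    roost: tuple[float, float]
    colony_id: str
    season: str
    kernel: MovementKernel
    constraints: NullConstraints = field(default_factory=NullConstraints)


class ConstraintDeadlock(RuntimeError):
    pass


def _try_simulate(spec: NullTrackSpec, landscape: Landscape, rng):
    k = spec.kernel
    cons = spec.constraints
    x0, y0, x1, y1 = landscape.bounding_box
    pad = cons.bbox_pad_m
    bx0, by0, bx1, by1 = x0 - pad, y0 - pad, x1 + pad, y1 + pad

    n = spec.n_slots
    xs = np.empty(n)
    ys = np.empty(n)
    states = np.empty(n, dtype=int)
    xs[0], ys[0] = spec.roost
    states[0] = int(rng.choice(k.n_states, p=k.delta))
    heading = rng.uniform(-np.pi, np.pi)
    return_slot = int(cons.return_onset_fraction * n)

    for t in range(1, n):
        prev = states[t - 1]
        s = int(rng.choice(k.n_states, p=k.tmat[prev]))
        # constraint (a): no settling into foraging over water
        if s == FORAGING and not landscape.is_on_land(xs[t - 1], ys[t - 1]):
            s = COMMUTING
        # return phase: keep commuting until back near the roost
        if (
            s == FORAGING
            and t >= return_slot
            and np.hypot(xs[t - 1] - spec.roost[0], ys[t - 1] - spec.roost[1])
            > cons.return_home_radius_m
        ):
            s = COMMUTING
        states[t] = s

        step = rng.gamma(k.gamma_shape[s], k.gamma_scale[s])
        if s == COMMUTING and t >= return_slot:
            centre = np.arctan2(spec.roost[1] - ys[t - 1], spec.roost[0] - xs[t - 1])
            base = lambda: centre + float(
                sample_wrapped_cauchy(0.0, k.wc_rho[s], 1, rng)[0]
            )
        else:
            base = lambda: heading + float(
                sample_wrapped_cauchy(k.wc_mu[s], k.wc_rho[s], 1, rng)[0]
            )
        for _attempt in range(cons.max_heading_attempts):
            h = base()
            px = xs[t - 1] + step * np.cos(h)
            py = ys[t - 1] + step * np.sin(h)
            if bx0 <= px <= bx1 and by0 <= py <= by1:
                break
        else:
            # reflect back toward the box centre as a last resort
            h = np.arctan2((by0 + by1) / 2 - ys[t - 1], (bx0 + bx1) / 2 - xs[t - 1])
            px = xs[t - 1] + step * np.cos(h)
            py = ys[t - 1] + step * np.sin(h)
            if not (bx0 <= px <= bx1 and by0 <= py <= by1):
                raise ConstraintDeadlock(f"slot {t}: no admissible heading")
        heading = wrap_angle(h)
        xs[t], ys[t] = px, py
    return xs, ys, states


def simulate_null_track(
    spec: NullTrackSpec,
    landscape: Landscape,
    seed,
    config: StudyConfig | None = None,
) -> tuple[GpsTrack, StateSequence]:
    """Sample one constrained null night; deterministic for a given seed.

    On a constraint deadlock (no admissible move after the configured
    number of attempts) the whole night is resampled from the next
    substream, with a log record.
    """
    config = config or StudyConfig()
    base_seed = np.atleast_1d(np.asarray(seed, dtype=np.int64)).tolist()
    for resample in range(spec.constraints.max_night_resamples):
        rng = np.random.default_rng(base_seed + [resample])
        try:
            xs, ys, states = _try_simulate(spec, landscape, rng)
            break
        except ConstraintDeadlock as exc:
            logger.info("null night resampled (%d): %s", resample, exc)
    else:
        raise ConstraintDeadlock("night resampling budget exhausted")

    times = pd.Timestamp(spec.start_time) + pd.to_timedelta(
        np.arange(spec.n_slots) * spec.interval_s, "s"
    )
    proj = config.projector
    lon, lat = proj.inverse(xs, ys)
    fixes = pd.DataFrame({"timestamp": times, "lon": lon, "lat": lat, "x": xs, "y": ys})
    track = GpsTrack(
        individual_id="null",
        colony_id=spec.colony_id,
        season=spec.season,
        tracking_period="null",
        night_date=pd.Timestamp(spec.start_time).tz_localize(None).normalize(),
        fixes=fixes,
        sampling_interval=spec.interval_s,
    )
    seq = StateSequence(
        states=states,
        posteriors=np.eye(spec.kernel.n_states)[states],
        imputed=np.zeros(spec.n_slots, dtype=bool),
    )
    return track, seq


def template_from_series(
    series: StepSeries, kernel: MovementKernel, roost: tuple[float, float],
    constraints: NullConstraints | None = None,
) -> NullTrackSpec:
    """Build a null-night template from an observed regularized night."""
    t = series.track
    return NullTrackSpec(
        start_time=series.times[0],
        n_slots=series.n_slots,
        interval_s=series.interval,
        roost=roost,
        colony_id=t.colony_id,
        season=t.season,
        kernel=kernel,
        constraints=constraints or NullConstraints(),
    )


def simulate_null_cohort(
    templates: list[NullTrackSpec],
    landscape: Landscape,
    n_per_template: int,
    seed: int,
    config: StudyConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Simulate a cohort of null nights and extract their foraging locations.

    Foraging locations are pulled through the *same* extraction code path
    as observed tracks (regularize → bout rule), then locations over
    water are dropped; the drop rate is returned alongside the table.
    """
    from .metrics import locations_to_frame

    locations: list[ForagingLocation] = []
    n_total = 0
    n_water = 0
    for ti, spec in enumerate(templates):
        for r in range(n_per_template):
            track, seq = simulate_null_track(
                spec, landscape, seed=[int(seed), ti, r], config=config
            )
            series = regularize(track, spec.interval_s)
            locs = extract_foraging_locations(
                series, seq, landscape, provenance="simulated"
            )
            n_total += len(locs)
            for loc in locs:
                if landscape.is_on_land(loc.x, loc.y):
                    locations.append(loc)
                else:
                    n_water += 1
    drop_rate = n_water / n_total if n_total else 0.0
    logger.info(
        "null cohort: %d locations, %.1f%% dropped over water",
        n_total,
        100 * drop_rate,
    )
    return locations_to_frame(locations), drop_rate
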