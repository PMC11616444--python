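"""Synthetic landscapes and bat-night GPS tracks.

The generator emulates the statistical structure the analysis pipeline
assumes for island-roosting *Phyllostomus hastatus*: nightly trips from a
roost on a home island, a fast straight outbound commute to a
colony-specific mainland foraging area 15–25 km away, alternating
foraging bouts and short relocations there, and a straight inbound
commute — plus optional data corruptions (fix dropout, speed-spike
outliers, stray over-water fixes) so the cleaning steps can be exercised
with known ground truth.

Commutes are biased correlated random walks toward an individual- and
night-specific target; the bias weight (default 0.8) reproduces the high
straightness indices of real commutes without prescribing exact paths.
Ground-truth states use the segmentation convention: state 1 = foraging,
state 2 = commuting.

All randomness flows from a single integer seed through per-night
substreams indexed by (colony, individual, night), so any night can be
regenerated independently and a full dataset is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon

from .data_io import GpsTrack, Landscape, StudyConfig, recompute_speeds
from .geometry import (
    bearing_south_cw,
    circular_mean,
    displacement_from_bearing,
    wrap_angle,
)
from .hmm import FORAGING, COMMUTING, MovementKernel, sample_wrapped_cauchy


class GenerationError(RuntimeError):
    pass


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# landscape


@dataclass
class GeometrySpec:
    """Parameters of the synthetic island/mainland geometry (km)."""

    center_lonlat: tuple[float, float] = (-82.25, 9.38)
    island_radius_km: float = 4.0
    mainland_inner_km: float = 15.0
    mainland_outer_km: float = 70.0
    mainland_bearing_range: tuple[float, float] = (-0.8, 2.4)  # south-zero cw, rad
    coast_noise: float = 0.12
    min_water_gap_km: float = 10.0


def _noisy_radius(base_km: float, theta: np.ndarray, rng, noise: float) -> np.ndarray:
    """Smooth Fourier perturbation of a radius, for irregular coastlines."""
    r = np.ones_like(theta)
    for k in range(2, 6):
        amp = noise * rng.uniform(0.2, 1.0) / k
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return base_km * r


def make_landscape(
    seed: int,
    geometry_spec: GeometrySpec | None = None,
    colony_ids: tuple[str, ...] = ("colony1", "colony2", "colony3"),
    config: StudyConfig | None = None,
) -> tuple[Landscape, StudyConfig]:
    """Build a deterministic island + mainland landscape.

    The home island is an irregular blob around the projected centre; the
    mainland is an annular sector of bearings/ranges where foraging
    targets can land, separated from the island by at least the
    configured water gap.  Roosts for ``colony_ids`` are placed near the
    island centre.  Returns the landscape together with a matching
    :class:`StudyConfig` (roosts in lon/lat).
    """
    spec = geometry_spec or GeometrySpec()
    config = config or StudyConfig()
    rng = np.random.default_rng([int(seed), 7919])
    proj = config.projector
    cx, cy = (float(v) for v in proj.forward(*spec.center_lonlat))

    theta = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    r_island = _noisy_radius(spec.island_radius_km, theta, rng, spec.coast_noise)
    island = Polygon(
        np.column_stack(
            [cx + 1000 * r_island * np.cos(theta), cy + 1000 * r_island * np.sin(theta)]
        )
    ).buffer(0)

    parts = [island]
    if spec.mainland_outer_km > spec.mainland_inner_km > 0:
        if spec.mainland_inner_km < r_island.max():
            raise SpecError("mainland inner edge overlaps the home island")
        gap = spec.mainland_inner_km - r_island.max()
        if gap < spec.min_water_gap_km * (1 - spec.coast_noise) - 1e-9:
            raise SpecError(
                f"water gap {gap:.1f} km below configured minimum "
                f"{spec.min_water_gap_km} km"
            )
        b0, b1 = spec.mainland_bearing_range
        bearings = np.linspace(b0, b1, 120)
        r_in = _noisy_radius(spec.mainland_inner_km, bearings, rng, spec.coast_noise / 2)
        r_out = np.full_like(bearings, spec.mainland_outer_km)
        inner = np.column_stack(displacement_from_bearing(1000 * r_in, bearings))
        outer = np.column_stack(displacement_from_bearing(1000 * r_out, bearings[::-1]))
        ring = np.vstack([inner, outer]) + [cx, cy]
        parts.append(Polygon(ring).buffer(0))

    land = MultiPolygon([p if isinstance(p, Polygon) else max(p.geoms, key=lambda g: g.area) for p in parts])

    roosts_xy = {}
    for k, cid in enumerate(colony_ids):
        ang = 2 * np.pi * k / max(len(colony_ids), 1)
        rx = cx + 600 * np.cos(ang)
        ry = cy + 600 * np.sin(ang)
        roosts_xy[cid] = (rx, ry)
    lonlat = {
        cid: tuple(float(v) for v in proj.inverse(x, y))
        for cid, (x, y) in roosts_xy.items()
    }
    config.roosts_lonlat = lonlat

    landscape = Landscape(
        land_polygons=land,
        home_island_polygon=island,
        roosts=roosts_xy,
        bounding_box=land.bounds,
    )
    return landscape, config


# ---------------------------------------------------------------------------
# scenarios and kernels


@dataclass
class ColonyScenario:
    """Study conditions for one colony × season."""

    colony_id: str
    season: str  # "dry" | "wet"
    n_individuals: int = 5
    nights_per_individual: int = 4
    mean_commute_distance: float = 20.0  # km
    commute_angle_mean: float = 0.8  # rad, south-zero clockwise
    commute_angle_sd: float = 0.1  # rad, night-to-night
    individual_angle_sd: float = 0.15  # rad, between individuals
    individual_distance_sd: float = 1.5  # km, between individuals
    night_distance_sd: float = 1.0  # km, night-to-night
    p_on_island_foraging: float = 0.3
    tracking_period: str = "sim"

    def __post_init__(self) -> None:
        if self.mean_commute_distance <= 0:
            raise ValueError("mean_commute_distance must be positive")
        if min(self.commute_angle_sd, self.individual_angle_sd,
               self.individual_distance_sd, self.night_distance_sd) < 0:
            raise ValueError("scenario SDs must be non-negative")
        if not 0.0 <= self.p_on_island_foraging <= 1.0:
            raise ValueError("p_on_island_foraging must be in [0,1]")


@dataclass
class CorruptionSpec:
    """Optional data defects injected after the clean track is built."""

    dropout_prob: float = 0.0
    n_speed_spikes: int = 0
    n_water_fixes: int = 0


def default_kernel(interval_s: float = 120.0) -> MovementKernel:
    """Two-state movement kernel at the analysis interval.

    Foraging: mean step ~85 m per 2 min (slow, tortuous, ρ = 0.25);
    commuting: mean ~1200 m per 2 min (~10 m/s, near-straight, ρ = 0.92).
    """
    scale = interval_s / 120.0
    return MovementKernel(
        gamma_shape=np.array([1.2, 40.0]),
        gamma_scale=np.array([70.0 * scale, 30.0 * scale]),
        wc_mu=np.zeros(2),
        wc_rho=np.array([0.25, 0.92]),
        tmat=np.array([[0.93, 0.07], [0.10, 0.90]]),
    )


def default_scenarios(
    n_individuals: int = 5, nights_per_individual: int = 4, seasons=("dry",)
) -> list[ColonyScenario]:
    """Three colonies with distinct commute bearings and 16–24 km ranges;
    wet-season variants have shorter/noisier trips (doubled angle SDs)."""
    base = {
        "colony1": dict(dry=(23.5, 1.54), wet=(18.3, 0.92)),
        "colony2": dict(dry=(23.2, 1.43), wet=(21.6, 0.98)),
        "colony3": dict(dry=(16.0, 0.09), wet=(16.0, 0.30)),
    }
    out = []
    for cid, seasons_map in base.items():
        for season in seasons:
            dist, ang = seasons_map[season]
            widen = 2.0 if season == "wet" else 1.0
            out.append(
                ColonyScenario(
                    colony_id=cid,
                    season=season,
                    n_individuals=n_individuals,
                    nights_per_individual=nights_per_individual,
                    mean_commute_distance=dist,
                    commute_angle_mean=ang,
                    commute_angle_sd=0.08 * widen,
                    individual_angle_sd=0.12 * widen,
                    individual_distance_sd=1.2 * widen,
                    night_distance_sd=0.8 * widen,
                    p_on_island_foraging=0.3,
                )
            )
    return out


# ---------------------------------------------------------------------------
# night simulation

_MAX_SPEED_CAP = 1700.0  # m per 2-min slot (~14.2 m/s); keeps clean tracks
# below the 15 m/s filter so preprocessing is a no-op without corruptions


@dataclass
class NightSim:
    """One simulated bat-night with its generative ground truth."""

    track: GpsTrack
    states: np.ndarray  # 1 = foraging, 2 = commuting, per fix
    anchor_xy: tuple[float, float]  # first off-island foraging location
    true_bearing: float
    true_distance_km: float
    corruption_log: pd.DataFrame


def _blend_heading(prev: float, target: float, w: float) -> float:
    """Circular convex combination of previous heading and target bearing."""
    return np.arctan2(
        w * np.sin(target) + (1 - w) * np.sin(prev),
        w * np.cos(target) + (1 - w) * np.cos(prev),
    )


def _walk_to(
    pos, goal, kernel, rng, bias: float, arrive_m: float, max_steps: int
):
    """Biased correlated walk (commuting kernel) until within arrive_m of goal."""
    xs, ys = [], []
    x, y = pos
    heading = np.arctan2(goal[1] - y, goal[0] - x)
    for _ in range(max_steps):
        if np.hypot(goal[0] - x, goal[1] - y) <= arrive_m:
            break
        to_goal = np.arctan2(goal[1] - y, goal[0] - x)
        heading = _blend_heading(heading, to_goal, bias)
        heading += float(
            sample_wrapped_cauchy(kernel.wc_mu[COMMUTING], kernel.wc_rho[COMMUTING], 1, rng)[0]
        )
        step = min(
            rng.gamma(kernel.gamma_shape[COMMUTING], kernel.gamma_scale[COMMUTING]),
            _MAX_SPEED_CAP,
        )
        remaining = np.hypot(goal[0] - x, goal[1] - y)
        step = min(step, remaining + arrive_m / 2)
        x += step * np.cos(heading)
        y += step * np.sin(heading)
        xs.append(x)
        ys.append(y)
    return np.array(xs), np.array(ys)


def _forage_steps(pos, center, kernel, rng, n: int, patch_radius_m: float):
    """Slow tortuous movement around a patch centre; stays near the patch."""
    xs, ys = [], []
    x, y = pos
    heading = rng.uniform(-np.pi, np.pi)
    for _ in range(n):
        if np.hypot(x - center[0], y - center[1]) > patch_radius_m:
            heading = np.arctan2(center[1] - y, center[0] - x)
        heading += float(
            sample_wrapped_cauchy(kernel.wc_mu[FORAGING], kernel.wc_rho[FORAGING], 1, rng)[0]
        )
        step = min(
            rng.gamma(kernel.gamma_shape[FORAGING], kernel.gamma_scale[FORAGING]),
            _MAX_SPEED_CAP,
        )
        x += step * np.cos(heading)
        y += step * np.sin(heading)
        xs.append(x)
        ys.append(y)
    return np.array(xs), np.array(ys)


def _find_land_target(roost, bearing, dist_km, landscape, off_island: bool):
    """Nearest on-land point along the bearing ray around the nominal range."""
    for scale in np.concatenate([[1.0], np.linspace(0.85, 1.6, 16)]):
        dx, dy = displacement_from_bearing(dist_km * scale * 1000.0, bearing)
        x, y = roost[0] + dx, roost[1] + dy
        if landscape.is_on_land(x, y) and (
            not off_island or not landscape.is_on_home_island(x, y)
        ):
            return x, y
    raise GenerationError(
        f"no land target along bearing {bearing:.2f} rad at ~{dist_km:.1f} km"
    )


def simulate_night(
    scenario: ColonyScenario,
    kernel: MovementKernel,
    individual_effects: dict,
    seed,
    landscape: Landscape,
    config: StudyConfig | None = None,
    night_date: pd.Timestamp | None = None,
    n_slots: int = 360,
    interval_s: float = 120.0,
    corruptions: CorruptionSpec | None = None,
    commute_bias: float = 0.8,
) -> NightSim:
    """Simulate one bat-night.

    ``individual_effects`` carries the individual's systematic deviations:
    ``{"individual_id", "angle_offset" (rad), "distance_offset" (km)}``.
    ``seed`` may be an int or a seed sequence (list of ints).
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    roost = landscape.roosts[scenario.colony_id]

    bearing = wrap_angle(
        scenario.commute_angle_mean
        + individual_effects.get("angle_offset", 0.0)
        + rng.normal(0.0, scenario.commute_angle_sd)
    )
    dist_km = max(
        scenario.mean_commute_distance
        + individual_effects.get("distance_offset", 0.0)
        + rng.normal(0.0, scenario.night_distance_sd),
        5.0,
    )
    target = _find_land_target(roost, bearing, dist_km, landscape, off_island=True)

    # rough slot budget check before committing to the trip
    mean_commute_step = kernel.mean_step[COMMUTING] * commute_bias
    est_commute = int(np.ceil(dist_km * 1000.0 / mean_commute_step))
    if n_slots - 2 * int(est_commute * 1.3) - 12 < 20:
        raise GenerationError("night too short for the requested commute distance")

    xs = [roost[0]]
    ys = [roost[1]]
    states = [FORAGING]

    def extend(x_arr, y_arr, state):
        xs.extend(x_arr)
        ys.extend(y_arr)
        states.extend([state] * len(x_arr))

    # settle at roost: cave-bound jitter, not free foraging movement
    jit = rng.normal(0.0, 40.0, size=(3, 2))
    extend(roost[0] + jit[:, 0], roost[1] + jit[:, 1], FORAGING)

    # outbound commute
    cx_, cy_ = _walk_to(
        (xs[-1], ys[-1]), target, kernel, rng, commute_bias, 600.0, 4 * est_commute
    )
    extend(cx_, cy_, COMMUTING)

    # split the remaining night between off-island foraging at the target
    # and (after the return) on-island foraging, so that the realized
    # on-island share of foraging time tracks p_on_island_foraging; the
    # roost-sitting slots (state = foraging, on island) are part of that
    # share, which is why the on-island bout is sized from realized counts
    inbound_est = int(1.1 * est_commute) + 2
    avail = n_slots - len(xs) - inbound_est - 6
    if avail < 10:
        raise GenerationError("commute consumed the whole night")
    p_on = scenario.p_on_island_foraging
    n_on = max(0, int(round(p_on * (avail + 8) - 8)))
    n_off = max(avail - n_on, 5)

    # foraging at the target patch: bouts + short relocations
    anchor_xy = None
    remaining = n_off
    while remaining > 0:
        bout = int(min(remaining, 3 + rng.geometric(0.15)))
        fx, fy = _forage_steps((xs[-1], ys[-1]), target, kernel, rng, bout, 2500.0)
        if anchor_xy is None and len(fx):
            anchor_xy = (float(fx[0]), float(fy[0]))
        extend(fx, fy, FORAGING)
        remaining -= bout
        if remaining > 3 and rng.uniform() < 0.6:
            reloc = int(rng.integers(1, 4))
            ang = rng.uniform(-np.pi, np.pi)
            sub = (
                target[0] + 1500 * np.cos(ang),
                target[1] + 1500 * np.sin(ang),
            )
            rx_, ry_ = _walk_to((xs[-1], ys[-1]), sub, kernel, rng, 0.6, 400.0, reloc)
            extend(rx_, ry_, COMMUTING)
            remaining -= len(rx_)
    if anchor_xy is None:
        anchor_xy = target

    # inbound commute
    cx_, cy_ = _walk_to(
        (xs[-1], ys[-1]), roost, kernel, rng, commute_bias, 300.0, 4 * est_commute
    )
    extend(cx_, cy_, COMMUTING)

    # on-island foraging near the roost before day roosting
    n_on = min(n_on, n_slots - len(xs) - 6)
    if n_on > 0:
        for _ in range(20):
            ang = rng.uniform(-np.pi, np.pi)
            r = rng.uniform(1000.0, 2500.0)
            px, py = roost[0] + r * np.cos(ang), roost[1] + r * np.sin(ang)
            if landscape.is_on_home_island(px, py):
                break
        else:
            px, py = roost
        cx_, cy_ = _walk_to((xs[-1], ys[-1]), (px, py), kernel, rng, commute_bias,
                            300.0, 6)
        extend(cx_, cy_, COMMUTING)
        fx, fy = _forage_steps((xs[-1], ys[-1]), (px, py), kernel, rng, n_on, 1200.0)
        extend(fx, fy, FORAGING)
        cx_, cy_ = _walk_to((xs[-1], ys[-1]), roost, kernel, rng, commute_bias,
                            200.0, 8)
        extend(cx_, cy_, COMMUTING)

    # pad at roost to the full night, then truncate to n_slots
    n_pad = max(n_slots - len(xs), 0)
    if n_pad:
        jit = rng.normal(0.0, 40.0, size=(n_pad, 2))
        extend(roost[0] + jit[:, 0], roost[1] + jit[:, 1], FORAGING)
    xs_arr = np.array(xs[:n_slots])
    ys_arr = np.array(ys[:n_slots])
    states_arr = np.array(states[:n_slots]) + 1  # 1 = foraging, 2 = commuting

    # timestamps: window opens at night_start local time
    if night_date is None:
        night_date = pd.Timestamp("2022-03-01")
    start_utc = pd.Timestamp(night_date).tz_localize("UTC") + timedelta(
        hours=config.night_start_hour - config.utc_offset_hours
    )
    times = start_utc + pd.to_timedelta(np.arange(n_slots) * interval_s, "s")

    proj = config.projector
    lon, lat = proj.inverse(xs_arr, ys_arr)
    fixes = pd.DataFrame(
        {"timestamp": times, "lon": lon, "lat": lat, "x": xs_arr, "y": ys_arr}
    )

    # corruptions
    corruptions = corruptions or CorruptionSpec()
    logs = []
    keep = np.ones(n_slots, dtype=bool)
    interior = np.arange(5, n_slots - 5)
    if corruptions.n_speed_spikes > 0:
        idx = rng.choice(interior, size=corruptions.n_speed_spikes, replace=False)
        for i in idx:
            ang = rng.uniform(-np.pi, np.pi)
            d = rng.uniform(8000.0, 15000.0)
            fixes.loc[i, "x"] += d * np.cos(ang)
            fixes.loc[i, "y"] += d * np.sin(ang)
            lo, la = proj.inverse(fixes.loc[i, "x"], fixes.loc[i, "y"])
            fixes.loc[i, ["lon", "lat"]] = [float(lo), float(la)]
            logs.append((times[i], "speed_spike"))
    if corruptions.n_water_fixes > 0:
        idx = rng.choice(interior, size=corruptions.n_water_fixes, replace=False)
        for i in idx:
            d = rng.uniform(65000.0, 80000.0)
            dx, dy = displacement_from_bearing(d, np.pi)  # due north: open water
            fixes.loc[i, "x"] = roost[0] + dx
            fixes.loc[i, "y"] = roost[1] + dy
            lo, la = proj.inverse(fixes.loc[i, "x"], fixes.loc[i, "y"])
            fixes.loc[i, ["lon", "lat"]] = [float(lo), float(la)]
            logs.append((times[i], "water_fix"))
    if corruptions.dropout_prob > 0:
        drop = rng.uniform(size=n_slots) < corruptions.dropout_prob
        drop[0] = drop[-1] = False
        keep &= ~drop
        for t in times[drop]:
            logs.append((t, "dropout"))

    fixes = recompute_speeds(fixes.loc[keep].reset_index(drop=True))
    track = GpsTrack(
        individual_id=individual_effects.get("individual_id", "sim"),
        colony_id=scenario.colony_id,
        season=scenario.season,
        tracking_period=scenario.tracking_period,
        night_date=pd.Timestamp(night_date),
        fixes=fixes,
        sampling_interval=interval_s,
    )
    # truth is the drawn target (anchors scatter within-bout around it)
    tdx = target[0] - roost[0]
    tdy = target[1] - roost[1]
    return NightSim(
        track=track,
        states=states_arr[keep],
        anchor_xy=anchor_xy,
        true_bearing=float(bearing_south_cw(tdx, tdy)),
        true_distance_km=float(np.hypot(tdx, tdy) / 1000.0),
        corruption_log=pd.DataFrame(logs, columns=["timestamp", "kind"]),
    )


@dataclass
class SyntheticDataset:
    tracks: list[GpsTrack]
    states: dict  # (individual_id, night_date) -> ground-truth state array
    corruption_logs: dict  # same key -> DataFrame of injected defects
    truth: pd.DataFrame  # per-night anchors and true bearings/distances
    individual_truth: pd.DataFrame  # per-individual true means
    landscape: Landscape
    config: StudyConfig

    @property
    def metadata(self) -> pd.DataFrame:
        rows = {
            (t.individual_id, t.colony_id, t.season, t.tracking_period)
            for t in self.tracks
        }
        return pd.DataFrame(
            sorted(rows),
            columns=["individual_id", "colony_id", "season", "tracking_period"],
        )


def simulate_dataset(
    scenarios: list[ColonyScenario],
    kernel: MovementKernel | None = None,
    seed: int = 0,
    landscape: Landscape | None = None,
    config: StudyConfig | None = None,
    n_slots: int = 360,
    interval_s: float = 120.0,
    corruptions: CorruptionSpec | None = None,
) -> SyntheticDataset:
    """Simulate a full multi-colony dataset with its ground-truth table."""
    kernel = kernel or default_kernel(interval_s)
    if landscape is None:
        landscape, config = make_landscape(
            seed, colony_ids=tuple(dict.fromkeys(s.colony_id for s in scenarios))
        )
    config = config or StudyConfig()

    tracks, states, truth_rows, ind_rows = [], {}, [], []
    corruption_logs = {}
    for ci, scn in enumerate(scenarios):
        for ii in range(scn.n_individuals):
            ind_id = f"{scn.colony_id}-{scn.season}-b{ii:02d}"
            ind_rng = np.random.default_rng([int(seed), ci, ii, 104729])
            eff = {
                "individual_id": ind_id,
                "angle_offset": float(ind_rng.normal(0.0, scn.individual_angle_sd)),
                "distance_offset": float(ind_rng.normal(0.0, scn.individual_distance_sd)),
            }
            ind_rows.append(
                {
                    "individual_id": ind_id,
                    "colony_id": scn.colony_id,
                    "season": scn.season,
                    "true_angle_mean": wrap_angle(
                        scn.commute_angle_mean + eff["angle_offset"]
                    ),
                    "true_distance_mean": scn.mean_commute_distance
                    + eff["distance_offset"],
                }
            )
            for ni in range(scn.nights_per_individual):
                night_date = pd.Timestamp("2022-03-01") + timedelta(days=ni)
                sim = simulate_night(
                    scn,
                    kernel,
                    eff,
                    seed=[int(seed), ci, ii, ni],
                    landscape=landscape,
                    config=config,
                    night_date=night_date,
                    n_slots=n_slots,
                    interval_s=interval_s,
                    corruptions=corruptions,
                )
                tracks.append(sim.track)
                states[(ind_id, sim.track.night_date)] = sim.states
                corruption_logs[(ind_id, sim.track.night_date)] = sim.corruption_log
                truth_rows.append(
                    {
                        "individual_id": ind_id,
                        "colony_id": scn.colony_id,
                        "season": scn.season,
                        "night_date": sim.track.night_date,
                        "anchor_x": sim.anchor_xy[0],
                        "anchor_y": sim.anchor_xy[1],
                        "true_bearing": sim.true_bearing,
                        "true_distance_km": sim.true_distance_km,
                    }
                )
    return SyntheticDataset(
        tracks=tracks,
        states=states,
        corruption_logs=corruption_logs,
        truth=pd.DataFrame(truth_rows),
        individual_truth=pd.DataFrame(ind_rows),
        landscape=landscape,
        config=config,
    )


def write_movebank_csv(tracks: list[GpsTrack], path) -> None:
    """Write tracks in the Movebank CSV dialect (WGS84 coordinates only)."""
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": t.fixes["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S"),
                    "location-long": t.fixes["lon"],
                    "location-lat": t.fixes["lat"],
                    "individual-local-identifier": t.individual_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def truth_state_sequence(states_1based: np.ndarray):
    """Wrap a ground-truth 1/2 state array as a decoded StateSequence."""
    from .hmm import StateSequence

    s = np.asarray(states_1based, dtype=int) - 1
    return StateSequence(
        states=s,
        posteriors=np.eye(2)[s],
        imputed=np.zeros(len(s), dtype=bool),
    )


def colony_mean_bearings(truth: pd.DataFrame) -> pd.Series:
    """Circular mean of true per-night bearings per colony (truth-table view)."""
    return truth.groupby("colony_id")["true_bearing"].apply(circular_mean)
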