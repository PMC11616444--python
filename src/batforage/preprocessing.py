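"""Track cleaning and regularization.

Implements the standard telemetry hygiene steps for nightly central-place
trips: a sequential speed filter (fixes implying > 15 m/s from the last
retained fix are discarded — implausibly fast for a large phyllostomid),
removal of far over-water fixes, downsampling to a common interval, and
regularization onto a fixed time grid with explicit missing slots so the
step/turn series can feed a hidden Markov model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GpsTrack, Landscape, recompute_speeds
from .geometry import wrap_angle

DEFAULT_MAX_SPEED = 15.0  # m/s
DEFAULT_MAX_RANGE_KM = 60.0
DEFAULT_ROOST_RADIUS_M = 500.0


class EmptyTrackError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class StepSeries:
    """Step lengths and turning angles on an arithmetic time grid.

    All arrays share length ``n_slots``.  ``x``/``y`` are NaN at missing
    slots.  ``step[t]`` is the displacement (m) from slot ``t−1`` to slot
    ``t`` (NaN unless both ends are present); ``angle[t]`` is the heading
    change at slot ``t−1`` (counterclockwise positive, (−π, π]; NaN unless
    slots ``t−2, t−1, t`` are all present).
    """

    track: GpsTrack
    interval: float
    times: pd.DatetimeIndex
    x: np.ndarray
    y: np.ndarray
    step: np.ndarray
    angle: np.ndarray

    @property
    def n_slots(self) -> int:
        return len(self.times)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of slots with a location."""
        return ~np.isnan(self.x)


def remove_outliers(
    track: GpsTrack,
    landscape: Landscape,
    max_speed: float = DEFAULT_MAX_SPEED,
    max_range_km: float = DEFAULT_MAX_RANGE_KM,
) -> tuple[GpsTrack, pd.DataFrame]:
    """Drop speed-spike and far over-water fixes.

    The speed filter is sequential: each fix is tested against the last
    *retained* fix, so one bad position does not condemn its neighbours.
    Over-water fixes farther than ``max_range_km`` from the roost are
    removed regardless of speed.  Returns the cleaned track and a removal
    log with one row per dropped fix (``timestamp``, ``reason``).
    """
    fixes = track.fixes
    roost = landscape.roosts[track.colony_id]
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9

    dist_roost = np.hypot(x - roost[0], y - roost[1]) / 1000.0
    on_land = landscape.is_on_land(x, y)
    water_range = (~on_land) & (dist_roost > max_range_km)

    keep = np.zeros(len(fixes), dtype=bool)
    reasons: list[tuple[int, str]] = []
    last = -1
    for i in range(len(fixes)):
        if water_range[i]:
            reasons.append((i, "water_range"))
            continue
        if last >= 0:
            speed = np.hypot(x[i] - x[last], y[i] - y[last]) / (t[i] - t[last])
            if speed > max_speed:
                reasons.append((i, "speed"))
                continue
        keep[i] = True
        last = i

    if not keep.any():
        raise EmptyTrackError(
            f"all fixes removed from {track.individual_id} {track.night_date}"
        )
    log = pd.DataFrame(
        {
            "timestamp": fixes["timestamp"].iloc[[i for i, _ in reasons]].to_numpy(),
            "reason": [r for _, r in reasons],
            "individual_id": track.individual_id,
        }
    )
    return track.replace_fixes(fixes.loc[keep]), log


def downsample(track: GpsTrack, target_interval: float = 120.0) -> GpsTrack:
    """Thin a track to ``target_interval`` seconds.

    Keeps the fix nearest each grid time (grid anchored at the first fix)
    within half an interval; a fix is never used for two grid slots.
    If the native interval already exceeds the target the track is
    returned unchanged with a warning.
    """
    fixes = track.fixes
    if len(fixes) < 2:
        return track
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    native = np.median(np.diff(t))
    if native > target_interval:
        warnings.warn(
            f"native interval {native:.0f}s exceeds target "
            f"{target_interval:.0f}s; track passed through",
            stacklevel=2,
        )
        out = track.replace_fixes(fixes)
        out.sampling_interval = native
        return out

    t0 = t[0]
    grid = t0 + target_interval * np.arange(int((t[-1] - t0) // target_interval) + 1)
    keep_idx: list[int] = []
    used = -1
    for g in grid:
        i = int(np.argmin(np.abs(t - g)))
        if abs(t[i] - g) <= target_interval / 2.0 and i > used:
            keep_idx.append(i)
            used = i
    out = track.replace_fixes(fixes.iloc[keep_idx])
    out.sampling_interval = target_interval
    return out


def regularize(track: GpsTrack, interval: float) -> StepSeries:
    """Snap fixes to a fixed grid, inserting missing slots for gaps."""
    fixes = track.fixes
    if len(fixes) < 3:
        raise InsufficientDataError("need at least 3 fixes to form a step series")
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    t0 = t[0]
    n_slots = int(round((t[-1] - t0) / interval)) + 1
    x = np.full(n_slots, np.nan)
    y = np.full(n_slots, np.nan)
    slot = np.round((t - t0) / interval).astype(int)
    for i, s in enumerate(slot):
        if 0 <= s < n_slots and np.isnan(x[s]):
            x[s] = fixes["x"].iloc[i]
            y[s] = fixes["y"].iloc[i]
    if np.count_nonzero(~np.isnan(x)) < 3:
        raise InsufficientDataError("fewer than 3 non-missing grid locations")

    step = np.full(n_slots, np.nan)
    angle = np.full(n_slots, np.nan)
    present = ~np.isnan(x)
    for s in range(1, n_slots):
        if present[s] and present[s - 1]:
            step[s] = np.hypot(x[s] - x[s - 1], y[s] - y[s - 1])
    for s in range(2, n_slots):
        if present[s] and present[s - 1] and present[s - 2]:
            h1 = np.arctan2(y[s - 1] - y[s - 2], x[s - 1] - x[s - 2])
            h2 = np.arctan2(y[s] - y[s - 1], x[s] - x[s - 1])
            angle[s] = wrap_angle(h2 - h1)

    times = pd.DatetimeIndex(
        fixes["timestamp"].iloc[0] + pd.to_timedelta(np.arange(n_slots) * interval, "s")
    )
    return StepSeries(
        track=track, interval=interval, times=times, x=x, y=y, step=step, angle=angle
    )


def classify_night(
    track: GpsTrack,
    roost: tuple[float, float],
    roost_radius_m: float = DEFAULT_ROOST_RADIUS_M,
) -> str:
    """Label a night ``complete`` iff it starts and ends at the roost
    and actually left it (so both commutes are recorded)."""
    x = track.fixes["x"].to_numpy()
    y = track.fixes["y"].to_numpy()
    d = np.hypot(x - roost[0], y - roost[1])
    starts_home = d[0] <= roost_radius_m
    ends_home = d[-1] <= roost_radius_m
    left = d.max() > roost_radius_m
    return "complete" if (starts_home and ends_home and left) else "incomplete"


def preprocess_tracks(
    tracks: list[GpsTrack],
    landscape: Landscape,
    interval: float = 120.0,
    max_speed: float = DEFAULT_MAX_SPEED,
    max_range_km: float = DEFAULT_MAX_RANGE_KM,
) -> tuple[list[GpsTrack], list[StepSeries], pd.DataFrame]:
    """Convenience pipeline: outlier removal → downsample → regularize."""
    clean, series, logs = [], [], []
    for tr in tracks:
        try:
            tr2, log = remove_outliers(tr, landscape, max_speed, max_range_km)
            tr2 = downsample(tr2, interval)
            series.append(regularize(tr2, interval))
            clean.append(tr2)
            logs.append(log)
        except (EmptyTrackError, InsufficientDataError) as exc:
            warnings.warn(f"skipping track: {exc}", stacklevel=2)
    logs = [l for l in logs if not l.empty]
    log_df = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["timestamp", "reason", "individual_id"])
    )
    return clean, series, log_df
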