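"""Foraging metrics derived from decoded tracks.

Covers commute straightness, foraging-bout anchor extraction, roost-relative
distance/bearing (south-zero clockwise convention; compass degrees =
rad·180/π + 180), on/off-island time budgets with binomial GLMs, and the
back-of-envelope balsa-tree requirement of a nectar-feeding colony.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data_io import GpsTrack, Landscape
from .geometry import bearing_south_cw, bearing_to_compass_degrees
from .hmm import FORAGING, COMMUTING, StateSequence
from .preprocessing import DEFAULT_ROOST_RADIUS_M, StepSeries


@dataclass
class CommuteSegment:
    track: GpsTrack
    direction: str  # "outbound" | "inbound"
    x: np.ndarray
    y: np.ndarray
    straightness_index: float


@dataclass
class ForagingLocation:
    """Anchor point of one foraging bout, relative to the roost."""

    individual_id: str
    colony_id: str
    season: str
    provenance: str  # "observed" | "simulated"
    x: float
    y: float
    distance_to_roost: float  # km
    angle_to_roost: float  # rad, south-zero clockwise, (−π, π]
    on_home_island: bool

    @property
    def compass_degrees(self) -> float:
        return float(bearing_to_compass_degrees(self.angle_to_roost))


def straightness_index(x, y) -> float:
    """Net displacement over cumulative path length; 1 = perfectly straight."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return float("nan")
    path = float(np.hypot(np.diff(x), np.diff(y)).sum())
    if path == 0.0:
        return float("nan")
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return min(net / path, 1.0)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def extract_commutes(
    series: StepSeries,
    states: StateSequence,
    roost: tuple[float, float],
    roost_radius_m: float = DEFAULT_ROOST_RADIUS_M,
) -> list[CommuteSegment]:
    """Outbound and inbound commute segments of one night.

    The outbound commute is the first maximal commuting-state run that
    carries the bat beyond the roost radius; the inbound commute is the
    last such run that returns it.  Runs that never leave the roost
    radius (short relocations at the roost) are ignored.
    """
    st = states.states
    d_roost = np.hypot(series.x - roost[0], series.y - roost[1])
    commuting = st == COMMUTING
    segs = []
    runs = [
        (a, b)
        for a, b in _runs(commuting)
        if np.count_nonzero(np.isfinite(d_roost[a:b])) >= 2
        and np.nanmax(np.where(np.isfinite(d_roost[a:b]), d_roost[a:b], -np.inf))
        > roost_radius_m
    ]
    if not runs:
        return []
    for (a, b), direction in ((runs[0], "outbound"), (runs[-1], "inbound")):
        x, y = series.x[a:b], series.y[a:b]
        segs.append(
            CommuteSegment(
                track=series.track,
                direction=direction,
                x=x,
                y=y,
                straightness_index=straightness_index(x, y),
            )
        )
    if len(runs) == 1:
        segs = segs[:1]
    return segs


def angle_distance_to_roost(x: float, y: float, roost: tuple[float, float]):
    """(distance km, bearing rad) from roost to a point, south-zero clockwise."""
    dx = x - roost[0]
    dy = y - roost[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("point coincides with the roost; bearing undefined")
    return float(np.hypot(dx, dy) / 1000.0), float(bearing_south_cw(dx, dy))


def extract_foraging_locations(
    series: StepSeries,
    states: StateSequence,
    landscape: Landscape,
    provenance: str = "observed",
) -> list[ForagingLocation]:
    """One anchor per foraging bout of length > 1.

    A bout is a maximal run of foraging-state slots with observed
    locations; singleton bouts are discarded and the bout's first
    location becomes the anchor.
    """
    track = series.track
    roost = landscape.roosts[track.colony_id]
    foraging = (states.states == FORAGING) & series.observed
    out = []
    for a, b in _runs(foraging):
        if b - a <= 1:
            continue
        x, y = float(series.x[a]), float(series.y[a])
        try:
            dist, ang = angle_distance_to_roost(x, y, roost)
        except ValueError:
            continue
        out.append(
            ForagingLocation(
                individual_id=track.individual_id,
                colony_id=track.colony_id,
                season=track.season,
                provenance=provenance,
                x=x,
                y=y,
                distance_to_roost=dist,
                angle_to_roost=ang,
                on_home_island=landscape.is_on_home_island(x, y),
            )
        )
    return out


def locations_to_frame(locations: list[ForagingLocation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": l.individual_id,
                "colony_id": l.colony_id,
                "season": l.season,
                "provenance": l.provenance,
                "x": l.x,
                "y": l.y,
                "distance_km": l.distance_to_roost,
                "angle_rad": l.angle_to_roost,
                "compass_deg": l.compass_degrees,
                "on_home_island": l.on_home_island,
            }
            for l in locations
        ]
    )


def foraging_time_proportions(
    series_list: list[StepSeries],
    states_list: list[StateSequence],
    landscape: Landscape,
) -> pd.DataFrame:
    """Per-night fraction of foraging time on vs off the home island.

    Nights with zero observed foraging slots are excluded (logged via a
    warning).  ``p_on + p_off == 1`` for every retained night.
    """
    rows = []
    for series, states in zip(series_list, states_list):
        foraging = (states.states == FORAGING) & series.observed
        n = int(foraging.sum())
        if n == 0:
            warnings.warn(
                f"night {series.track.individual_id} {series.track.night_date}: "
                "no foraging slots; excluded",
                stacklevel=2,
            )
            continue
        on = int(
            np.count_nonzero(
                landscape.is_on_home_island(series.x[foraging], series.y[foraging])
            )
        )
        t = series.track
        rows.append(
            {
                "individual_id": t.individual_id,
                "colony_id": t.colony_id,
                "season": t.season,
                "tracking_period": t.tracking_period,
                "night_date": t.night_date,
                "on_count": on,
                "off_count": n - on,
                "p_on": on / n,
                "p_off": (n - on) / n,
            }
        )
    return pd.DataFrame(rows)


def fit_binomial_glm(data: pd.DataFrame, formula: str):
    """Binomial (logit) GLM on per-night aggregated counts.

    ``formula`` uses the patsy dialect with the two-column response, e.g.
    ``"on_count + off_count ~ tracking_period + C(location)"``.  Counts are
    aggregated per night rather than expanded to per-slot Bernoulli rows —
    the likelihood is identical.  Returns the fitted statsmodels results
    object (coefficients, standard errors, Wald z p-values).
    """
    for term in formula.split("~")[1].replace("C(", "").replace(")", "").split("+"):
        name = term.strip()
        if name and name in data.columns and data[name].nunique() < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels")
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        result = smf.glm(formula, data=data, family=sm.families.Binomial()).fit()
    if np.any(np.abs(result.params) > 15):
        warnings.warn(
            "very large coefficient magnitude: possible complete separation",
            stacklevel=2,
        )
    return result


def balsa_tree_requirement(
    colony_size: int, bats_per_tree_min: int, bats_per_tree_max: int
) -> tuple[int, int]:
    """Number of flowering balsa trees needed to feed a colony for a night.

    With each tree supporting between ``bats_per_tree_min`` and
    ``bats_per_tree_max`` bats per night, a colony of ``colony_size``
    needs at least ``ceil(size/max)`` and at most ``floor(size/min)``
    trees.
    """
    if min(colony_size, bats_per_tree_min, bats_per_tree_max) <= 0:
        raise ValueError("all arguments must be positive")
    if bats_per_tree_min > bats_per_tree_max:
        raise ValueError("bats_per_tree_min must not exceed bats_per_tree_max")
    return (
        math.ceil(colony_size / bats_per_tree_max),
        math.floor(colony_size / bats_per_tree_min),
    )
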