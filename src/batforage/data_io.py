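"""Reading tracking data, landscape geometry, and study configuration.

GPS input follows the Movebank CSV dialect (``timestamp``,
``location-long``, ``location-lat``, ``individual-local-identifier``);
a column map in the configuration accepts other dialects.  Tracks are
split into *bat-nights*: one record per individual per nightly activity
window (default 18:00–06:00 local time, half-open), with coordinates
projected into a local metric CRS so step lengths and speeds are in
metres.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon, shape, mapping
from shapely.ops import unary_union

from .geometry import TransverseMercator

logger = logging.getLogger(__name__)

MOVEBANK_COLUMNS = {
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "individual_id": "individual-local-identifier",
}


class FormatError(ValueError):
    """Input file does not match the expected dialect."""


class MetadataError(KeyError):
    """An individual in the data is missing from the study metadata."""


@dataclass
class StudyConfig:
    """Study-level configuration: CRS, night window, roosts, column map."""

    utm_zone: int = 17
    night_start_hour: int = 18
    night_end_hour: int = 6
    utc_offset_hours: float = -5.0  # Panamá (EST, no DST)
    roosts_lonlat: dict[str, tuple[float, float]] = field(default_factory=dict)
    column_map: dict[str, str] = field(default_factory=lambda: dict(MOVEBANK_COLUMNS))

    @property
    def projector(self) -> TransverseMercator:
        return TransverseMercator.for_utm_zone(self.utm_zone)

    def roosts_xy(self) -> dict[str, tuple[float, float]]:
        proj = self.projector
        out = {}
        for cid, (lon, lat) in self.roosts_lonlat.items():
            x, y = proj.forward(lon, lat)
            out[cid] = (float(x), float(y))
        return out

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        roosts = {k: tuple(v) for k, v in raw.get("roosts_lonlat", {}).items()}
        kwargs = {k: raw[k] for k in ("utm_zone", "night_start_hour",
                                      "night_end_hour", "utc_offset_hours")
                  if k in raw}
        cmap = dict(MOVEBANK_COLUMNS)
        cmap.update(raw.get("column_map", {}))
        return cls(roosts_lonlat=roosts, column_map=cmap, **kwargs)


@dataclass
class GpsTrack:
    """One bat-night of GPS fixes.

    ``fixes`` is a DataFrame with columns ``timestamp`` (UTC),
    ``lon``, ``lat``, ``x``, ``y`` (projected metres) and
    ``ground_speed`` (m/s between consecutive fixes; first fix NaN),
    sorted by strictly increasing timestamp.
    """

    individual_id: str
    colony_id: str
    season: str
    tracking_period: str
    night_date: pd.Timestamp
    fixes: pd.DataFrame
    sampling_interval: float | None = None

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("fix timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy()

    def replace_fixes(self, fixes: pd.DataFrame) -> "GpsTrack":
        return GpsTrack(
            individual_id=self.individual_id,
            colony_id=self.colony_id,
            season=self.season,
            tracking_period=self.tracking_period,
            night_date=self.night_date,
            fixes=recompute_speeds(fixes.reset_index(drop=True)),
            sampling_interval=self.sampling_interval,
        )


@dataclass
class Landscape:
    """Land polygons, home island, and roost positions in projected metres."""

    land_polygons: MultiPolygon
    home_island_polygon: Polygon
    roosts: dict[str, tuple[float, float]]
    bounding_box: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for cid, (x, y) in self.roosts.items():
            if not self.home_island_polygon.covers(Point(x, y)):
                raise ValueError(f"roost {cid!r} is not on the home island")
        if not self.land_polygons.covers(self.home_island_polygon.representative_point()):
            raise ValueError("home island must be part of the land polygons")

    def is_on_land(self, x, y):
        """Point-in-polygon test against all land; boundary counts as land."""
        res = shapely.intersects_xy(self.land_polygons, x, y)
        return bool(res) if np.ndim(x) == 0 else res

    def is_on_home_island(self, x, y):
        res = shapely.intersects_xy(self.home_island_polygon, x, y)
        return bool(res) if np.ndim(x) == 0 else res


def recompute_speeds(fixes: pd.DataFrame) -> pd.DataFrame:
    """Ground speed between consecutive fixes (m/s); first fix NaN."""
    fixes = fixes.copy()
    dt = fixes["timestamp"].diff().dt.total_seconds().to_numpy()
    dist = np.hypot(fixes["x"].diff(), fixes["y"].diff())
    with np.errstate(invalid="ignore", divide="ignore"):
        fixes["ground_speed"] = dist / dt
    return fixes


def _night_date(ts_local: pd.Series, start_hour: int, end_hour: int):
    """Map local timestamps to the date their night window opened.

    Returns (night_date, in_window) arrays; fixes outside the half-open
    [start, end) window get in_window = False.
    """
    hour = ts_local.dt.hour + ts_local.dt.minute / 60 + ts_local.dt.second / 3600
    evening = hour >= start_hour
    morning = hour < end_hour
    in_window = evening | morning
    date = ts_local.dt.normalize()
    night_date = date.where(evening, date - timedelta(days=1))
    return night_date, in_window


def read_tracks(
    path,
    metadata: pd.DataFrame,
    config: StudyConfig | None = None,
) -> list[GpsTrack]:
    """Read a Movebank-dialect CSV and split it into bat-night tracks.

    ``metadata`` must contain one row per individual with columns
    ``individual_id``, ``colony_id``, ``season``, ``tracking_period``.
    Fixes outside the nightly window are dropped with a logged count.
    """
    config = config or StudyConfig()
    cmap = config.column_map
    df = pd.read_csv(path)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    df = df.rename(columns={v: k for k, v in cmap.items()})
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="mixed")
    df = df.sort_values(["individual_id", "timestamp"], kind="stable")
    df = df.drop_duplicates(subset=["individual_id", "timestamp"])

    meta = metadata.set_index("individual_id")
    unknown = set(df["individual_id"].astype(str)) - set(meta.index.astype(str))
    if unknown:
        raise MetadataError(f"individuals absent from metadata: {sorted(unknown)}")

    proj = config.projector
    df["x"], df["y"] = proj.forward(df["lon"].to_numpy(), df["lat"].to_numpy())

    local = df["timestamp"] + timedelta(hours=config.utc_offset_hours)
    night_date, in_window = _night_date(
        local, config.night_start_hour, config.night_end_hour
    )
    n_dropped = int((~in_window).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} fixes outside the "
            f"[{config.night_start_hour}:00, {config.night_end_hour}:00) window",
            stacklevel=2,
        )
        logger.info("read_tracks: dropped %d out-of-window fixes", n_dropped)
    df = df.loc[in_window].assign(night_date=night_date[in_window])

    tracks = []
    for (ind, night), grp in df.groupby(["individual_id", "night_date"], sort=True):
        row = meta.loc[ind]
        fixes = grp[["timestamp", "lon", "lat", "x", "y"]].reset_index(drop=True)
        tracks.append(
            GpsTrack(
                individual_id=str(ind),
                colony_id=str(row["colony_id"]),
                season=str(row["season"]),
                tracking_period=str(row["tracking_period"]),
                night_date=night,
                fixes=recompute_speeds(fixes),
            )
        )
    return tracks


def write_tracks_csv(tracks: list[GpsTrack], path) -> None:
    """Write cleaned tracks back to CSV with projected columns added."""
    frames = []
    for t in tracks:
        f = t.fixes.copy()
        f["individual-local-identifier"] = t.individual_id
        f["colony_id"] = t.colony_id
        f["season"] = t.season
        f["tracking_period"] = t.tracking_period
        f["night_date"] = t.night_date.date()
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"lon": "location-long", "lat": "location-lat"})
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# landscape I/O


def load_landscape(geojson_path, config: StudyConfig) -> Landscape:
    """Load a WGS84 GeoJSON coastline file and project it.

    The feature carrying ``"home_island": true`` in its properties is the
    roost island; all polygon features together form the land.
    """
    with open(geojson_path) as fh:
        gj = json.load(fh)
    proj = config.projector

    def _project_geom(geom):
        return shapely.transform(
            shape(geom),
            lambda coords: np.column_stack(proj.forward(coords[:, 0], coords[:, 1])),
        )

    land_parts, home = [], None
    for feat in gj["features"]:
        geom = _project_geom(feat["geometry"])
        land_parts.append(geom)
        if feat.get("properties", {}).get("home_island"):
            home = geom
    if home is None:
        raise FormatError("no feature with property home_island=true")
    land = unary_union(land_parts)
    if isinstance(land, Polygon):
        land = MultiPolygon([land])
    return Landscape(
        land_polygons=land,
        home_island_polygon=home,
        roosts=config.roosts_xy(),
        bounding_box=land.bounds,
    )


def save_landscape_geojson(landscape: Landscape, config: StudyConfig, path) -> None:
    """Write a projected Landscape back to WGS84 GeoJSON."""
    proj = config.projector

    def _unproject(geom):
        return shapely.transform(
            geom,
            lambda coords: np.column_stack(proj.inverse(coords[:, 0], coords[:, 1])),
        )

    features = []
    home = landscape.home_island_polygon
    for poly in landscape.land_polygons.geoms:
        is_home = poly.equals(home) or poly.contains(home.representative_point())
        features.append(
            {
                "type": "Feature",
                "properties": {"home_island": bool(is_home)},
                "geometry": mapping(_unproject(poly)),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
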