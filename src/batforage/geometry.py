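"""Planar projection and circular-geometry primitives.

All distance computations in the pipeline happen in a local metric
transverse-Mercator (UTM-style) projection of WGS84 coordinates; the
forward/inverse maps here follow the Krüger series expansion (4th order
in the third flattening), which is accurate to well under a millimetre
inside a UTM zone.

Bearing convention used throughout the package: angles to/from the roost
are measured with 0 rad = due south and positive clockwise (south → west
→ north → east), wrapped to (−π, π].  The corresponding compass bearing
in degrees is ``rad · 180/π + 180``.  Turning angles, by contrast, use
the usual mathematical convention: counterclockwise positive, in (−π, π].
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E = np.sqrt(_F * (2.0 - _F))
_N = _F / (2.0 - _F)

# rectifying radius
_A_RECT = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0)

_ALPHA = np.array([
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 5.0 * _N**3 / 16.0 + 41.0 * _N**4 / 180.0,
    13.0 * _N**2 / 48.0 - 3.0 * _N**3 / 5.0 + 557.0 * _N**4 / 1440.0,
    61.0 * _N**3 / 240.0 - 103.0 * _N**4 / 140.0,
    49561.0 * _N**4 / 161280.0,
])
_BETA = np.array([
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 37.0 * _N**3 / 96.0 - _N**4 / 360.0,
    _N**2 / 48.0 + _N**3 / 15.0 - 437.0 * _N**4 / 1440.0,
    17.0 * _N**3 / 480.0 - 37.0 * _N**4 / 840.0,
    4397.0 * _N**4 / 161280.0,
])

_K0 = 0.9996
_FALSE_EASTING = 500_000.0


class TransverseMercator:
    """Forward/inverse transverse-Mercator projection on WGS84.

    Parameters
    ----------
    central_meridian_deg:
        Longitude of the projection's central meridian.  The default
        (−81°) is the UTM zone 17N meridian appropriate for the Bocas
        del Toro archipelago.
    """

    def __init__(self, central_meridian_deg: float = -81.0) -> None:
        self.central_meridian_deg = float(central_meridian_deg)

    @classmethod
    def for_utm_zone(cls, zone: int) -> "TransverseMercator":
        if not 1 <= zone <= 60:
            raise ValueError(f"UTM zone must be in 1..60, got {zone}")
        return cls(central_meridian_deg=-183.0 + 6.0 * zone)

    def forward(self, lon, lat):
        """Project WGS84 ``lon, lat`` (degrees) to ``x, y`` in metres."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lam = np.radians(lon - self.central_meridian_deg)
        phi = np.radians(lat)
        if np.any(np.abs(lam) > np.radians(30.0)):
            import warnings

            warnings.warn(
                "coordinates far outside the projection zone; distances "
                "may be distorted",
                stacklevel=2,
            )
        sphi = np.sin(phi)
        t = np.sinh(np.arctanh(sphi) - _E * np.arctanh(_E * sphi))
        xi_p = np.arctan2(t, np.cos(lam))
        eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))
        j = np.arange(1, 5)
        xi = xi_p + np.sum(
            _ALPHA * np.sin(2 * j * xi_p[..., None]) * np.cosh(2 * j * eta_p[..., None]),
            axis=-1,
        )
        eta = eta_p + np.sum(
            _ALPHA * np.cos(2 * j * xi_p[..., None]) * np.sinh(2 * j * eta_p[..., None]),
            axis=-1,
        )
        x = _K0 * _A_RECT * eta + _FALSE_EASTING
        y = _K0 * _A_RECT * xi
        return x, y

    def inverse(self, x, y):
        """Inverse projection: ``x, y`` metres back to ``lon, lat`` degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xi = y / (_K0 * _A_RECT)
        eta = (x - _FALSE_EASTING) / (_K0 * _A_RECT)
        j = np.arange(1, 5)
        xi_p = xi - np.sum(
            _BETA * np.sin(2 * j * xi[..., None]) * np.cosh(2 * j * eta[..., None]),
            axis=-1,
        )
        eta_p = eta - np.sum(
            _BETA * np.cos(2 * j * xi[..., None]) * np.sinh(2 * j * eta[..., None]),
            axis=-1,
        )
        t = np.sin(xi_p) / np.sqrt(np.sinh(eta_p) ** 2 + np.cos(xi_p) ** 2)
        lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
        # geodetic latitude from the conformal quantity t by fixed point
        sphi = np.tanh(np.arcsinh(t))
        for _ in range(8):
            sphi = np.tanh(np.arcsinh(t) + _E * np.arctanh(_E * sphi))
        lat = np.degrees(np.arcsin(np.clip(sphi, -1.0, 1.0)))
        lon = np.degrees(lam) + self.central_meridian_deg
        return lon, lat


def geodesic_distance(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance (m) on the WGS84 mean-radius sphere (haversine).

    Used only as an independent sanity check on projected distances, never
    in the analysis itself.
    """
    r = 6371008.8
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(h))


# ---------------------------------------------------------------------------
# circular helpers


def wrap_angle(theta):
    """Wrap angle(s) to (−π, π]."""
    theta = np.asarray(theta, dtype=float)
    out = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def circular_mean(theta) -> float:
    theta = np.asarray(theta, dtype=float)
    return float(np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta))))


def mean_resultant_length(theta) -> float:
    theta = np.asarray(theta, dtype=float)
    return float(np.hypot(np.mean(np.sin(theta)), np.mean(np.cos(theta))))


def circular_sd(theta) -> float:
    """sqrt(−2 ln R̄) of a circular sample, in radians."""
    r = mean_resultant_length(theta)
    r = min(max(r, 1e-300), 1.0)
    return float(np.sqrt(-2.0 * np.log(r)))


# ---------------------------------------------------------------------------
# bearing convention (0 = due south, clockwise positive)


def bearing_south_cw(dx, dy):
    """Bearing of displacement (dx east, dy north), south-zero clockwise."""
    return wrap_angle(np.arctan2(-np.asarray(dx, float), -np.asarray(dy, float)))


def displacement_from_bearing(distance_m, bearing_rad):
    """Inverse of :func:`bearing_south_cw`: (dx, dy) for a given range/bearing."""
    b = np.asarray(bearing_rad, dtype=float)
    d = np.asarray(distance_m, dtype=float)
    return -d * np.sin(b), -d * np.cos(b)


def bearing_to_compass_degrees(bearing_rad):
    """Convert a south-zero clockwise bearing (rad) to compass degrees."""
    return np.asarray(bearing_rad, dtype=float) * 180.0 / np.pi + 180.0


def turning_angles(x, y):
    """Turning angles (counterclockwise positive, (−π, π]) along a path.

    Returns an array of length ``len(x) − 2``; entry ``i`` is the heading
    change at vertex ``i+1``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    headings = np.arctan2(np.diff(y), np.diff(x))
    return wrap_angle(np.diff(headings))
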