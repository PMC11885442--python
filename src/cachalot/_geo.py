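"""Spherical geodesy helpers shared across the pipeline.

All distances are in kilometres on a sphere of radius 6371.0 km. Two local
planar frames are provided:

* azimuthal equidistant (AEQD) — distance-true from the centre, used as the
  working frame for the state-space model at high latitudes;
* Lambert azimuthal equal-area (LAEA) — area-true, used for gridding
  time-spent-in-area and for polygon areas.

Both are simple closed-form spherical projections; no ellipsoidal model is
used anywhere in the package.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in degrees (vectorized)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle azimuth from point 1 to point 2, degrees
    clockwise from north in [0, 360)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    y = np.sin(dlmb) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlmb)
    return np.degrees(np.arctan2(y, x)) % 360.0


class LocalProjection:
    """A local spherical projection centred on (lat0, lon0), in km.

    kind="aeqd" is azimuthal equidistant; kind="laea" is Lambert azimuthal
    equal-area. Forward maps degrees -> (x, y) km; inverse maps back.
    """

    def __init__(self, lat0: float, lon0: float, kind: str = "aeqd"):
        if kind not in ("aeqd", "laea"):
            raise ValueError(f"unknown projection kind {kind!r}")
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self.kind = kind
        self._sin0 = np.sin(np.radians(lat0))
        self._cos0 = np.cos(np.radians(lat0))

    def forward(self, lat, lon):
        phi = np.radians(np.asarray(lat, dtype=float))
        dlmb = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        sinp, cosp = np.sin(phi), np.cos(phi)
        cosc = self._sin0 * sinp + self._cos0 * cosp * np.cos(dlmb)
        cosc = np.clip(cosc, -1.0, 1.0)
        if self.kind == "aeqd":
            c = np.arccos(cosc)
            sinc = np.sin(c)
            # k -> 1 as c -> 0
            k = np.where(sinc > 1e-12, np.where(sinc > 0, c / np.where(sinc > 0, sinc, 1.0), 1.0), 1.0)
        else:  # laea
            k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
        x = EARTH_RADIUS_KM * k * cosp * np.sin(dlmb)
        y = EARTH_RADIUS_KM * k * (self._cos0 * sinp - self._sin0 * cosp * np.cos(dlmb))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        small = rho < 1e-12
        rho_safe = np.where(small, 1.0, rho)
        if self.kind == "aeqd":
            c = rho
        else:
            c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        sinc, cosc = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cosc * self._sin0 + y * sinc * self._cos0 / rho_safe, -1.0, 1.0))
        lmb = np.arctan2(x * sinc, rho_safe * self._cos0 * cosc - y * self._sin0 * sinc)
        lat = np.where(small, self.lat0, np.degrees(phi))
        lon = np.where(small, self.lon0, self.lon0 + np.degrees(lmb))
        lon = (lon + 180.0) % 360.0 - 180.0
        return lat, lon
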