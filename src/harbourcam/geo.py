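"""Local planar geographic frame.

All positioning is done on a local east-north plane centred at the camera.
At the working ranges of a harbour rig (well under 1 km) the curvature error
of an equirectangular projection is far below the pixel-level calibration
error, so a planar frame is used throughout; great-circle formulas appear
only as independent checks in the test suite.

Bearings are true-north clockwise in degrees at every API boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class LocalFrame:
    """Equirectangular east-north frame centred at (lat0, lon0)."""

    lat0: float
    lon0: float

    def to_xy(self, lat, lon):
        """Geographic degrees -> (east, north) metres."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        coslat = math.cos(math.radians(self.lat0))
        x = np.radians(lon - self.lon0) * coslat * EARTH_RADIUS_M
        y = np.radians(lat - self.lat0) * EARTH_RADIUS_M
        return x, y

    def to_latlon(self, x, y):
        """(east, north) metres -> geographic degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        coslat = math.cos(math.radians(self.lat0))
        lon = self.lon0 + np.degrees(x / (coslat * EARTH_RADIUS_M))
        lat = self.lat0 + np.degrees(y / EARTH_RADIUS_M)
        return lat, lon


def polar_to_xy(range_m, bearing_deg):
    """Range/true-bearing -> (east, north)."""
    b = np.radians(np.asarray(bearing_deg, dtype=float))
    r = np.asarray(range_m, dtype=float)
    return r * np.sin(b), r * np.cos(b)


def xy_to_polar(x, y):
    """(east, north) -> (range, true bearing in [0, 360))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    b = np.degrees(np.arctan2(x, y)) % 360.0
    return r, b


def normalize_bearing(bearing_deg):
    """Wrap a bearing into [0, 360)."""
    return np.asarray(bearing_deg, dtype=float) % 360.0
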