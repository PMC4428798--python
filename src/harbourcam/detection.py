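"""Field-of-view geometry and detection-range/bearing analysis.

The sampled area of a shore camera is the water-surface polygon bounded by
the camera apex, the two edge-bearing rays, and the opposite wharf waterline.
Detection analysis works on one position per transit event — the first
detected surfacing of the individual or group — binned by range and bearing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConfigurationError, DataError
from .geo import LocalFrame, polar_to_xy
from .rig import CameraRig


@dataclass(frozen=True)
class TransitEvent:
    """One individual's or group's passage through the field of view."""

    transit_event_id: str
    camera_id: str
    first_detection_time: pd.Timestamp
    last_detection_time: pd.Timestamp
    group_size_min: int
    group_size_max: int
    group_size_best: int

    def __post_init__(self):
        if self.first_detection_time > self.last_detection_time:
            raise DataError(f"event {self.transit_event_id}: first after last detection")
        if not 1 <= self.group_size_min <= self.group_size_best <= self.group_size_max:
            raise DataError(f"event {self.transit_event_id}: invalid group-size triple")


@dataclass(frozen=True)
class FieldOfView:
    camera_id: str
    polygon_xy: Polygon  # local east-north metres, camera at origin
    polygon_latlon: list  # [(lat, lon), ...]
    area_m2: float
    bearing_min: float
    bearing_max: float

    def to_geojson(self) -> str:
        coords = [[lon, lat] for lat, lon in self.polygon_latlon]
        coords.append(coords[0])
        return json.dumps(
            {
                "type": "Feature",
                "properties": {
                    "camera_id": self.camera_id,
                    "area_m2": self.area_m2,
                    "bearing_min": self.bearing_min,
                    "bearing_max": self.bearing_max,
                },
                "geometry": {"type": "Polygon", "coordinates": [coords]},
            }
        )


def build_fov(rig: CameraRig, n_arc: int = 128) -> FieldOfView:
    """Field-of-view polygon and planar area for a rig.

    The far boundary follows the wharf waterline profile (piecewise-linear in
    bearing, sampled at ``n_arc`` bearings), not a circular arc.
    """
    b_lo = rig.bearing_at_col(0)
    b_hi = rig.bearing_at_col(rig.image_width - 1)
    bearing_min, bearing_max = min(b_lo, b_hi), max(b_lo, b_hi)
    if not bearing_max > bearing_min:
        raise ConfigurationError("degenerate (zero-width) field of view")
    bearings = np.linspace(bearing_min, bearing_max, n_arc)
    dists = np.array([rig.wharf_distance(b) for b in bearings])
    xs, ys = polar_to_xy(dists, bearings)
    ring = [(0.0, 0.0)] + list(zip(xs, ys))
    poly = Polygon(ring)
    if not poly.is_valid or poly.area <= 0:
        raise ConfigurationError("field-of-view polygon is degenerate or self-intersecting")
    frame = LocalFrame(rig.lat, rig.lon)
    latlon = [tuple(map(float, frame.to_latlon(x, y))) for x, y in ring]
    return FieldOfView(
        camera_id=rig.camera_id,
        polygon_xy=poly,
        polygon_latlon=latlon,
        area_m2=float(poly.area),
        bearing_min=float(bearing_min),
        bearing_max=float(bearing_max),
    )


def first_detections(estimates: pd.DataFrame) -> pd.DataFrame:
    """One position per transit event: the earliest-timestamped surfacing.

    ``estimates`` must carry ``transit_event_id``, ``timestamp``, ``obs_id``
    and position columns.  Ties on the timestamp break to the smallest
    ``obs_id`` so the result is order-invariant.
    """
    if estimates.empty:
        raise DataError("no position estimates supplied")
    df = estimates.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    missing = df["transit_event_id"].isna()
    if missing.any():
        raise DataError(
            f"{int(missing.sum())} estimates lack a transit_event_id"
        )
    df = df.sort_values(["transit_event_id", "timestamp", "obs_id"], kind="mergesort")
    return df.groupby("transit_event_id", as_index=False).first()


def detection_histograms(
    firsts: pd.DataFrame,
    range_bin_m: float = 10.0,
    bearing_bin_deg: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of first detections per range bin and per bearing bin.

    Bins are half-open ``[k*w, (k+1)*w)`` with edges at multiples of the bin
    width; totals are preserved (every detection falls in exactly one bin).
    Returns ``(range_hist, bearing_hist)`` frames with bin edges and counts.
    """
    if range_bin_m <= 0 or bearing_bin_deg <= 0:
        raise ValueError("bin widths must be positive")

    def _hist(values: np.ndarray, width: float) -> pd.DataFrame:
        if len(values) == 0:
            return pd.DataFrame({"bin_left": [], "bin_right": [], "count": []})
        idx = np.floor(values / width).astype(int)
        lo, hi = idx.min(), idx.max()
        ks = np.arange(lo, hi + 1)
        counts = np.bincount(idx - lo, minlength=len(ks))
        return pd.DataFrame(
            {"bin_left": ks * width, "bin_right": (ks + 1) * width, "count": counts}
        )

    r = _hist(firsts["range_m"].to_numpy(dtype=float), range_bin_m)
    b = _hist(firsts["bearing_true"].to_numpy(dtype=float), bearing_bin_deg)
    return r, b
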