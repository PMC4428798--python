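"""Camera rig description and image-space calibration.

A rig is a fixed shore camera of known geographic position and lens height
above the tidal datum, looking across a harbour channel at an opposite wharf.
Three calibration tables live on the rig:

* ``landmarks`` — surveyed features (flood lights, buildings) with known true
  bearings and pixel columns; bearing at an arbitrary column is interpolated
  between them.  Landmarks with a known physical height and measured top/base
  pixel rows additionally calibrate the vertical degrees-per-pixel scale for
  cameras that do not store focal length (video frames).
* ``wharf_profile`` — horizontal distance from the camera to the opposite
  wharf waterline as a function of bearing.  The waterline is the artificial
  horizon from which depression angles are measured.
* ``horizon_points`` — ground-control points giving the pixel row of the
  wharf waterline as a function of pixel column.

Both the camera height and the tide series must be referred to the same
tidal datum; the ``datum`` field exists so configurations state it
explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError


def _interp_linear_extrap(x: float, xp: np.ndarray, fp: np.ndarray) -> float:
    """Piecewise-linear interpolation with linear (edge-slope) extrapolation."""
    if x < xp[0]:
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        return float(fp[0] + slope * (x - xp[0]))
    if x > xp[-1]:
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        return float(fp[-1] + slope * (x - xp[-1]))
    return float(np.interp(x, xp, fp))


@dataclass(frozen=True)
class Landmark:
    """A surveyed feature visible in the image."""

    name: str
    bearing_true: float
    pixel_col: float
    pixel_row_top: Optional[float] = None
    pixel_row_base: Optional[float] = None
    physical_height: Optional[float] = None  # metres above the waterline

    def __post_init__(self):
        if not 0.0 <= self.bearing_true < 360.0:
            raise ConfigurationError(
                f"landmark {self.name!r}: bearing {self.bearing_true} outside [0, 360)"
            )
        if self.physical_height is not None:
            if self.pixel_row_top is None or self.pixel_row_base is None:
                raise ConfigurationError(
                    f"landmark {self.name!r}: physical_height set without pixel rows"
                )
            if not self.pixel_row_top < self.pixel_row_base:
                raise ConfigurationError(
                    f"landmark {self.name!r}: pixel_row_top must be above pixel_row_base"
                )

    @property
    def height_calibrated(self) -> bool:
        return self.physical_height is not None


@dataclass(frozen=True)
class CameraRig:
    camera_id: str
    lat: float
    lon: float
    height_above_datum: float
    image_width: int
    image_height: int
    landmarks: Sequence[Landmark]
    wharf_profile: Sequence[tuple]  # (bearing_deg, distance_m), sorted by bearing
    horizon_points: Sequence[tuple]  # (pixel_col, pixel_row), sorted by column
    heading_reference: float = 0.0
    focal_length_mm: Optional[float] = None
    pixel_pitch_mm: Optional[float] = None
    datum: str = "unspecified"

    # cached arrays, filled in __post_init__
    _lm_cols: np.ndarray = field(init=False, repr=False, compare=False, default=None)
    _lm_bearings: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.height_above_datum <= 0:
            raise ConfigurationError("height_above_datum must be > 0")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if len(self.landmarks) < 2:
            raise ConfigurationError("at least 2 landmarks are required for bearing interpolation")
        cols = np.array([lm.pixel_col for lm in self.landmarks], dtype=float)
        brgs = np.array([lm.bearing_true for lm in self.landmarks], dtype=float)
        order = np.argsort(cols)
        cols, brgs = cols[order], brgs[order]
        if np.any(np.diff(cols) <= 0):
            raise ConfigurationError("landmark pixel columns must be distinct")
        d = np.diff(brgs)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigurationError("landmark bearings must be strictly monotone in pixel column")
        if np.any(cols < 0) or np.any(cols >= self.image_width):
            raise ConfigurationError("landmark pixel columns outside image width")
        wp = np.asarray([(b, dm) for b, dm in self.wharf_profile], dtype=float)
        if len(wp) < 2 or np.any(np.diff(wp[:, 0]) <= 0):
            raise ConfigurationError("wharf_profile needs >=2 rows sorted by bearing")
        if np.any(wp[:, 1] <= 0):
            raise ConfigurationError("wharf_profile distances must be > 0")
        hp = np.asarray([(c, r) for c, r in self.horizon_points], dtype=float)
        if len(hp) < 2 or np.any(np.diff(hp[:, 0]) <= 0):
            raise ConfigurationError("horizon_points needs >=2 rows sorted by column")
        object.__setattr__(self, "_lm_cols", cols)
        object.__setattr__(self, "_lm_bearings", brgs)
        object.__setattr__(self, "wharf_profile", [(float(a), float(b)) for a, b in wp])
        object.__setattr__(self, "horizon_points", [(float(a), float(b)) for a, b in hp])

    # ---- bearing calibration -------------------------------------------------

    def bearing_at_col(self, pixel_col: float) -> float:
        """True bearing at a pixel column by landmark interpolation, in [0, 360)."""
        if not 0 <= pixel_col < self.image_width:
            raise ConfigurationError(f"pixel_col {pixel_col} outside image width")
        b = _interp_linear_extrap(pixel_col, self._lm_cols, self._lm_bearings)
        return b % 360.0

    def bearing_is_extrapolated(self, pixel_col: float) -> bool:
        return pixel_col < self._lm_cols[0] or pixel_col > self._lm_cols[-1]

    def col_at_bearing(self, bearing: float) -> float:
        """Inverse of :meth:`bearing_at_col` (bearings are monotone in column)."""
        xp, fp = self._lm_bearings, self._lm_cols
        if xp[0] > xp[-1]:  # decreasing bearings: flip for interpolation
            xp, fp = xp[::-1], fp[::-1]
        return _interp_linear_extrap(bearing, xp, fp)

    # ---- wharf geometry ------------------------------------------------------

    def wharf_distance(self, bearing: float) -> float:
        """Horizontal distance to the opposite wharf waterline at a bearing."""
        wp = np.asarray(self.wharf_profile, dtype=float)
        return _interp_linear_extrap(bearing, wp[:, 0], wp[:, 1])

    def horizon_row(self, pixel_col: float) -> float:
        """Pixel row of the wharf waterline (artificial horizon) at a column."""
        hp = np.asarray(self.horizon_points, dtype=float)
        return _interp_linear_extrap(pixel_col, hp[:, 0], hp[:, 1])

    # ---- vertical pixel scale ------------------------------------------------

    @property
    def has_focal_metadata(self) -> bool:
        return self.focal_length_mm is not None and self.pixel_pitch_mm is not None

    def video_row_scale(self) -> float:
        """Degrees per pixel row, from height-calibrated landmarks.

        For a landmark of height ``H`` metres with its base on the waterline at
        distance ``D``, the camera (lens ``h`` metres above the datum) sees it
        spanning ``arctan(h/D) + arctan((H - h)/D)`` degrees.  Dividing by the
        measured pixel span gives the scale; with several calibrated landmarks
        the mean of the per-landmark scales is used.
        """
        scales = []
        h = self.height_above_datum
        for lm in self.landmarks:
            if not lm.height_calibrated:
                continue
            dist = self.wharf_distance(lm.bearing_true)
            span = math.degrees(
                math.atan(h / dist) + math.atan((lm.physical_height - h) / dist)
            )
            scales.append(span / (lm.pixel_row_base - lm.pixel_row_top))
        if not scales:
            raise ConfigurationError(
                "no height-calibrated landmark; cannot derive a video pixel scale"
            )
        return float(np.mean(scales))

    # ---- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "camera_id": self.camera_id,
            "position": {"lat": self.lat, "lon": self.lon},
            "height_above_datum": self.height_above_datum,
            "datum": self.datum,
            "heading_reference": self.heading_reference,
            "image": {"width": self.image_width, "height": self.image_height},
            "optics": {
                "focal_length_mm": self.focal_length_mm,
                "pixel_pitch_mm": self.pixel_pitch_mm,
            },
            "landmarks": [
                {
                    "name": lm.name,
                    "bearing_true": lm.bearing_true,
                    "pixel_col": lm.pixel_col,
                    "pixel_row_top": lm.pixel_row_top,
                    "pixel_row_base": lm.pixel_row_base,
                    "physical_height": lm.physical_height,
                }
                for lm in self.landmarks
            ],
            "wharf_profile": [
                {"bearing": b, "distance_m": d} for b, d in self.wharf_profile
            ],
            "horizon_points": [
                {"pixel_col": c, "pixel_row": r} for c, r in self.horizon_points
            ],
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "CameraRig":
        optics = d.get("optics") or {}
        return cls(
            camera_id=d["camera_id"],
            lat=d["position"]["lat"],
            lon=d["position"]["lon"],
            height_above_datum=d["height_above_datum"],
            datum=d.get("datum", "unspecified"),
            heading_reference=d.get("heading_reference", 0.0),
            image_width=d["image"]["width"],
            image_height=d["image"]["height"],
            focal_length_mm=optics.get("focal_length_mm"),
            pixel_pitch_mm=optics.get("pixel_pitch_mm"),
            landmarks=[
                Landmark(
                    name=lm["name"],
                    bearing_true=lm["bearing_true"],
                    pixel_col=lm["pixel_col"],
                    pixel_row_top=lm.get("pixel_row_top"),
                    pixel_row_base=lm.get("pixel_row_base"),
                    physical_height=lm.get("physical_height"),
                )
                for lm in d["landmarks"]
            ],
            wharf_profile=[(w["bearing"], w["distance_m"]) for w in d["wharf_profile"]],
            horizon_points=[
                (p["pixel_col"], p["pixel_row"]) for p in d["horizon_points"]
            ],
        )

    @classmethod
    def load(cls, path) -> "CameraRig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
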