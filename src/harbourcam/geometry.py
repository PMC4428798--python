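"""Single-camera photogrammetric positioning with an artificial horizon.

A surfacing dolphin appears in the image at (col, row).  Its true bearing is
interpolated from surveyed landmarks at that column.  Its range follows from
the depression angle below the horizontal at the lens: the waterline of the
opposite wharf (at known distance D on that bearing) acts as an artificial
horizon, sitting ``arctan(h/D)`` below the horizontal for a lens ``h`` metres
above the water; the extra angle from the wharf line down to the dolphin
pixel is read off the image using the camera's vertical pixel scale.  Then

    range = h / tan(depression_total)

with ``h`` corrected for tide at the observation time.  Range and bearing are
finally converted to a geographic position on a local planar east-north
frame centred at the camera.

``project_forward`` is the exact inverse — the projector the scene simulator
uses — so position estimation can be validated by round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import ConfigurationError, PositioningError
from .geo import LocalFrame, polar_to_xy, xy_to_polar
from .rig import CameraRig
from .tide import TideSeries, effective_height


@dataclass(frozen=True)
class PositionEstimate:
    """Tide-corrected position of one surfacing."""

    obs_id: str
    camera_id: str
    range_m: float
    bearing_true: float
    lat: float
    lon: float
    effective_camera_height: float
    depression_angle: float  # degrees below horizontal, total
    bearing_extrapolated: bool = False


@dataclass(frozen=True)
class SkipRecord:
    """An observation that could not be resolved, with the reason."""

    obs_id: str
    camera_id: str
    reason: str


@dataclass(frozen=True)
class Projection:
    """Forward-projected pixel coordinates of a geographic point."""

    pixel_col: float
    pixel_row: float
    in_view: bool
    reason: str = ""


# ---- pixel-to-angle conversions ---------------------------------------------


def pixel_to_bearing(rig: CameraRig, pixel_col: float) -> float:
    """True bearing at a pixel column (piecewise-linear in landmark columns)."""
    return rig.bearing_at_col(pixel_col)


def pixel_to_degrees_still(rig: CameraRig, pixel_offset: float) -> float:
    """Pixel offset -> degrees using stored focal length and sensor pitch.

    Exact pinhole relation ``arctan(offset * pitch / focal)``; the sign of the
    offset is preserved.
    """
    if not rig.has_focal_metadata:
        raise ConfigurationError(
            "rig has no focal length / pixel pitch; use the video-style "
            "landmark-height calibration instead"
        )
    return math.degrees(
        math.atan(pixel_offset * rig.pixel_pitch_mm / rig.focal_length_mm)
    )


def pixel_to_degrees_video(rig: CameraRig, pixel_offset: float) -> float:
    """Pixel offset -> degrees via the landmark-height vertical scale.

    Video frames store no focal length, so the degrees-per-pixel scale is
    calibrated from lights of known height on the opposite wharf (mean over
    all height-calibrated landmarks), and applied linearly.
    """
    return pixel_offset * rig.video_row_scale()


def _row_offset_to_degrees(rig: CameraRig, d_row: float) -> float:
    if rig.has_focal_metadata:
        return pixel_to_degrees_still(rig, d_row)
    return pixel_to_degrees_video(rig, d_row)


def _degrees_to_row_offset(rig: CameraRig, deg: float) -> float:
    if rig.has_focal_metadata:
        return (
            math.tan(math.radians(deg)) * rig.focal_length_mm / rig.pixel_pitch_mm
        )
    return deg / rig.video_row_scale()


# ---- range from depression ---------------------------------------------------


def depression_to_range(effective_height_m: float, depression_total_deg: float) -> float:
    """Range along the water from lens height and total depression angle."""
    if depression_total_deg <= 0:
        raise PositioningError(
            f"depression angle {depression_total_deg:.4f} deg is at or above the horizon"
        )
    return effective_height_m / math.tan(math.radians(depression_total_deg))


# ---- full estimate -----------------------------------------------------------


def estimate_position(
    rig: CameraRig,
    obs,
    tide: TideSeries,
) -> PositionEstimate:
    """Estimate the geographic position for one surfacing observation.

    ``obs`` needs attributes/keys ``obs_id, timestamp, pixel_col, pixel_row``.
    Raises :class:`PositioningError` when the pixel sits at or above the
    artificial horizon (unresolvable geometry); batch drivers convert this to
    a skip record.
    """
    get = obs.get if hasattr(obs, "get") else lambda k: getattr(obs, k)
    obs_id, t = get("obs_id"), get("timestamp")
    col, row = float(get("pixel_col")), float(get("pixel_row"))
    if not (0 <= col < rig.image_width and 0 <= row < rig.image_height):
        raise PositioningError(f"obs {obs_id}: pixel ({col}, {row}) outside image bounds")

    bearing = rig.bearing_at_col(col)
    h_eff = effective_height(rig, tide, t)
    dist_wharf = rig.wharf_distance(bearing)
    theta_wharf = math.degrees(math.atan(h_eff / dist_wharf))
    d_row = row - rig.horizon_row(col)
    delta = _row_offset_to_degrees(rig, d_row)
    if delta < 0:
        raise PositioningError(f"obs {obs_id}: pixel above the artificial horizon")
    depression = theta_wharf + delta
    range_m = depression_to_range(h_eff, depression)

    frame = LocalFrame(rig.lat, rig.lon)
    x, y = polar_to_xy(range_m, bearing)
    lat, lon = frame.to_latlon(x, y)
    return PositionEstimate(
        obs_id=obs_id,
        camera_id=rig.camera_id,
        range_m=range_m,
        bearing_true=bearing,
        lat=float(lat),
        lon=float(lon),
        effective_camera_height=h_eff,
        depression_angle=depression,
        bearing_extrapolated=rig.bearing_is_extrapolated(col),
    )


def estimate_positions(
    rig: CameraRig, observations: pd.DataFrame, tide: TideSeries
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch position estimation.

    Returns ``(estimates, skips)``; every input row lands in exactly one of
    the two frames — unresolvable observations are never silently dropped.
    """
    ests, skips = [], []
    for _, obs in observations.iterrows():
        try:
            ests.append(estimate_position(rig, obs, tide).__dict__)
        except PositioningError as exc:
            skips.append(
                SkipRecord(str(obs["obs_id"]), rig.camera_id, str(exc)).__dict__
            )
    est_cols = [f.name for f in PositionEstimate.__dataclass_fields__.values()]
    skip_cols = [f.name for f in SkipRecord.__dataclass_fields__.values()]
    return (
        pd.DataFrame(ests, columns=est_cols),
        pd.DataFrame(skips, columns=skip_cols),
    )


# ---- forward model (simulator projector) ------------------------------------


def project_forward(
    rig: CameraRig, lat: float, lon: float, tide: TideSeries, t
) -> Projection:
    """Project a geographic water-surface point into pixel coordinates.

    Exact inverse of :func:`estimate_position`: projecting a point and
    estimating the position from the resulting pixels returns the point (up to
    floating-point error).  Points beyond the wharf waterline, behind the
    camera, or outside the image come back flagged out-of-view.
    """
    frame = LocalFrame(rig.lat, rig.lon)
    x, y = frame.to_xy(lat, lon)
    range_m, bearing = xy_to_polar(x, y)
    range_m, bearing = float(range_m), float(bearing)
    if range_m <= 0:
        return Projection(math.nan, math.nan, False, "zero range")

    col = rig.col_at_bearing(bearing)
    if not 0 <= col < rig.image_width:
        return Projection(col, math.nan, False, "bearing outside image")
    h_eff = effective_height(rig, tide, t)
    dist_wharf = rig.wharf_distance(bearing)
    depression = math.degrees(math.atan(h_eff / range_m))
    theta_wharf = math.degrees(math.atan(h_eff / dist_wharf))
    delta = depression - theta_wharf
    if delta < 0:
        return Projection(col, math.nan, False, "beyond the artificial horizon")
    row = rig.horizon_row(col) + _degrees_to_row_offset(rig, delta)
    if not 0 <= row < rig.image_height:
        return Projection(col, row, False, "row outside image")
    return Projection(col, row, True)
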