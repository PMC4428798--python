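"""Scoring camera position estimates against GPS ground truth.

A boat carrying a handheld GPS raises a flag at a set of stations across the
survey area; the flag instant is matched to a camera observation, the
observation is positioned photogrammetrically, and the horizontal distance to
the GPS fix is the positioning error.  The report summarises per-camera
error statistics and tests whether error grows with range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, MatchingError
from .geometry import estimate_position
from .rig import CameraRig
from .tide import TideSeries

DEFAULT_MATCH_WINDOW = pd.Timedelta(seconds=5)
EARTH_RADIUS_M = 6_371_008.8


def haversine_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in metres (the error metric; altitude ignored)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


@dataclass
class CalibrationReport:
    per_fix: pd.DataFrame  # fix_id, camera_id, range_m, error_m
    min_error_m: float
    mean_error_m: float
    max_error_m: float
    slope_m_per_m: float
    correlation: float
    p_value: float
    significant: bool
    by_camera: pd.DataFrame = field(default=None)

    def __post_init__(self):
        e = self.per_fix["error_m"]
        assert (e >= 0).all()
        assert self.min_error_m <= self.mean_error_m <= self.max_error_m

    def summary(self) -> str:
        lines = [
            f"Calibration fixes scored: {len(self.per_fix)}",
            f"Error range {self.min_error_m:.1f}-{self.max_error_m:.1f} m, "
            f"mean {self.mean_error_m:.1f} m",
            f"Error vs range: slope {self.slope_m_per_m:.4f} m/m, "
            f"r = {self.correlation:.3f}, p = {self.p_value:.3f} "
            f"({'significant' if self.significant else 'not significant'} at 0.05)",
        ]
        for _, row in self.by_camera.iterrows():
            lines.append(
                f"  {row['camera_id']}: {row['min_error_m']:.1f}-{row['max_error_m']:.1f} m, "
                f"mean {row['mean_error_m']:.1f} m (n={int(row['n'])})"
            )
        return "\n".join(lines)


def match_fixes(
    fixes: pd.DataFrame,
    observations: pd.DataFrame,
    window: pd.Timedelta = DEFAULT_MATCH_WINDOW,
) -> pd.DataFrame:
    """Pair each GPS fix with the nearest-in-time observation within a window.

    Raises :class:`MatchingError` when two observations inside the window tie,
    listing the candidates.
    """
    fixes = fixes.copy()
    obs = observations.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    obs["timestamp"] = pd.to_datetime(obs["timestamp"])
    rows = []
    for _, fx in fixes.iterrows():
        cand = obs[obs["camera_id"] == fx["camera_id"]]
        dt = (cand["timestamp"] - fx["timestamp"]).abs()
        inside = cand[dt <= window]
        if inside.empty:
            raise MatchingError(f"fix {fx['fix_id']}: no observation within {window}")
        dmin = dt[inside.index].min()
        best = inside[dt[inside.index] == dmin]
        if len(best) > 1:
            raise MatchingError(
                f"fix {fx['fix_id']}: ambiguous match, candidates "
                f"{sorted(best['obs_id'].tolist())}"
            )
        row = fx.to_dict()
        for k in ("obs_id", "pixel_col", "pixel_row"):
            row[k] = best.iloc[0][k]
        row["obs_timestamp"] = best.iloc[0]["timestamp"]
        rows.append(row)
    return pd.DataFrame(rows)


def score_calibration(
    rig_by_camera: dict,
    matched: pd.DataFrame,
    tide: TideSeries,
    alpha: float = 0.05,
) -> CalibrationReport:
    """Score matched fixes: per-fix error, per-camera summaries, error-vs-range.

    ``matched`` is the output of :func:`match_fixes` (needs gps lat/lon plus
    matched pixel coordinates).  The error-vs-range association is an OLS
    slope with a two-sided test at ``alpha``.
    """
    if len(matched) < 2:
        raise DataError("need at least 2 matched calibration fixes")
    recs = []
    for _, fx in matched.iterrows():
        rig = rig_by_camera[fx["camera_id"]]
        est = estimate_position(
            rig,
            {
                "obs_id": fx.get("obs_id", fx["fix_id"]),
                "timestamp": fx["timestamp"],
                "pixel_col": fx["pixel_col"],
                "pixel_row": fx["pixel_row"],
            },
            tide,
        )
        err = haversine_m(est.lat, est.lon, fx["lat"], fx["lon"])
        recs.append(
            {
                "fix_id": fx["fix_id"],
                "camera_id": fx["camera_id"],
                "range_m": est.range_m,
                "error_m": err,
            }
        )
    per_fix = pd.DataFrame(recs)
    by_cam = (
        per_fix.groupby("camera_id")["error_m"]
        .agg(min_error_m="min", mean_error_m="mean", max_error_m="max", n="size")
        .reset_index()
    )
    if per_fix["range_m"].nunique() > 1:
        lr = stats.linregress(per_fix["range_m"], per_fix["error_m"])
        slope, r, p = lr.slope, lr.rvalue, lr.pvalue
    else:
        slope, r, p = 0.0, 0.0, 1.0
    return CalibrationReport(
        per_fix=per_fix,
        min_error_m=float(per_fix["error_m"].min()),
        mean_error_m=float(per_fix["error_m"].mean()),
        max_error_m=float(per_fix["error_m"].max()),
        slope_m_per_m=float(slope),
        correlation=float(r),
        p_value=float(p),
        significant=bool(p < alpha),
        by_camera=by_cam,
    )
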