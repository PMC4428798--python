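"""Tide-gauge series and tide-corrected camera height.

The range model measures depression angles from the instantaneous water
surface, so the lens height that enters the geometry is the surveyed height
above the tidal datum minus the gauge reading at the observation time.  Gauge
readings are linearly interpolated in time; queries beyond the series by more
than a configurable tolerance are rejected rather than extrapolated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .rig import CameraRig

DEFAULT_EDGE_TOLERANCE = pd.Timedelta(minutes=30)


class TideSeries:
    """Strictly time-ordered water levels (metres above the tidal datum)."""

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise DataError("tide series is empty")
        frame = frame[["timestamp", "level_m"]].copy()
        frame["timestamp"] = pd.to_datetime(frame["timestamp"])
        if not frame["timestamp"].is_monotonic_increasing or frame["timestamp"].duplicated().any():
            raise DataError("tide timestamps must be strictly increasing")
        if not np.isfinite(frame["level_m"]).all():
            raise DataError("tide levels must be finite")
        self.frame = frame.reset_index(drop=True)
        self._t = frame["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        self._lvl = frame["level_m"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "TideSeries":
        return cls(pd.read_csv(Path(path)))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def level_at(self, t, edge_tolerance: pd.Timedelta = DEFAULT_EDGE_TOLERANCE):
        """Linearly interpolated water level at time(s) ``t``.

        Queries at most ``edge_tolerance`` beyond either end use the edge
        value; anything further out raises :class:`DataError`.
        """
        ts = pd.to_datetime(t)
        scalar = np.ndim(ts) == 0 and not isinstance(ts, pd.DatetimeIndex)
        tns = np.atleast_1d(np.asarray(pd.DatetimeIndex(np.atleast_1d(ts)).view(np.int64)))
        tol = edge_tolerance.value
        if (tns < self._t[0] - tol).any() or (tns > self._t[-1] + tol).any():
            raise DataError("query time outside the tide series span (beyond tolerance)")
        out = np.interp(tns, self._t, self._lvl)
        return float(out[0]) if scalar else out


def effective_height(rig: CameraRig, tide: TideSeries, t) -> float:
    """Lens height above the instantaneous water surface at time ``t``.

    ``height_above_datum`` and the gauge must share the rig's stated datum.
    """
    level = tide.level_at(t)
    h = rig.height_above_datum - level
    if np.any(np.asarray(h) <= 0):
        raise DataError(
            f"effective camera height {h} m is not positive: water level above the lens"
        )
    return h
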