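"""Convert every simulated surfacing from pixels to a geographic position.

Applies the artificial-horizon depression geometry with tide correction and
compares the estimates against the simulator's ground truth, then writes
positions (and any skip records) under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from harbourcam.calibration import haversine_m
from harbourcam.geometry import estimate_positions
from harbourcam.rig import CameraRig
from harbourcam.tide import TideSeries

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    rig = CameraRig.load(ROOT / "inputs" / "rig.yaml")
    tide = TideSeries.from_csv(ROOT / "inputs" / "tide.csv")
    obs = pd.read_csv(ROOT / "inputs" / "observations.csv", parse_dates=["timestamp"])
    truth = pd.read_csv(ROOT / "inputs" / "truth.csv")

    est, skips = estimate_positions(rig, obs, tide)
    est = est.merge(obs[["obs_id", "timestamp", "transit_event_id"]], on="obs_id")
    est.to_csv(ROOT / "positions.csv", index=False)
    skips.to_csv(ROOT / "position_skips.csv", index=False)

    merged = est.merge(truth, on="obs_id", suffixes=("", "_true"))
    err = np.array(
        [
            haversine_m(r["lat"], r["lon"], r["lat_true"], r["lon_true"])
            for _, r in merged.iterrows()
        ]
    )
    print(f"{len(est)} surfacings positioned, {len(skips)} skipped "
          f"(at/above the artificial horizon)")
    print(f"positioning error vs ground truth under ±1 px observation noise: "
          f"median {np.median(err):.1f} m, 95th percentile {np.percentile(err, 95):.1f} m")
    print(f"range span {est['range_m'].min():.1f}-{est['range_m'].max():.1f} m, "
          f"bearing span {est['bearing_true'].min():.1f}-{est['bearing_true'].max():.1f} deg")
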