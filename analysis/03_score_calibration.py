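"""Score the boat-and-flag GPS calibration run.

Matches each GPS fix to its camera observation, positions the observation
photogrammetrically, and reports the per-station error and whether error
grows with range.
"""

from pathlib import Path

import pandas as pd

from harbourcam.calibration import match_fixes, score_calibration
from harbourcam.rig import CameraRig
from harbourcam.tide import TideSeries

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    rig = CameraRig.load(ROOT / "inputs" / "rig.yaml")
    tide = TideSeries.from_csv(ROOT / "inputs" / "tide.csv")
    fixes = pd.read_csv(ROOT / "inputs" / "fixes.csv", parse_dates=["timestamp"])
    cal_obs = pd.read_csv(
        ROOT / "inputs" / "calibration_observations.csv", parse_dates=["timestamp"]
    )
    report = score_calibration({rig.camera_id: rig}, match_fixes(fixes, cal_obs), tide)
    report.per_fix.to_csv(ROOT / "calibration_errors.csv", index=False)
    (ROOT / "calibration_report.txt").write_text(report.summary() + "\n")
    print(report.summary())
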