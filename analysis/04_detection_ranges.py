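"""Field of view and detection range/bearing structure.

Builds the sampled-area polygon, takes one position per transit event (its
first detected surfacing), and histograms detections by range and bearing;
writes the polygon as GeoJSON, the histograms as CSV, and a summary figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from harbourcam.detection import build_fov, detection_histograms, first_detections
from harbourcam.rig import CameraRig

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    rig = CameraRig.load(ROOT / "inputs" / "rig.yaml")
    fov = build_fov(rig)
    (ROOT / "fov.geojson").write_text(fov.to_geojson())

    est = pd.read_csv(ROOT / "positions.csv", parse_dates=["timestamp"])
    firsts = first_detections(est)
    firsts.to_csv(ROOT / "first_detections.csv", index=False)
    rh, bh = detection_histograms(firsts, range_bin_m=10.0, bearing_bin_deg=5.0)
    rh.to_csv(ROOT / "range_histogram.csv", index=False)
    bh.to_csv(ROOT / "bearing_histogram.csv", index=False)

    peak = rh.loc[rh["count"].idxmax()]
    peak_b = bh.loc[bh["count"].idxmax()]
    print(f"field of view: {fov.area_m2:,.0f} m2 over bearings "
          f"{fov.bearing_min:.0f}-{fov.bearing_max:.0f} deg")
    print(f"{len(firsts)} transit events; first detections span "
          f"{firsts['range_m'].min():.1f}-{firsts['range_m'].max():.1f} m")
    print(f"detection peak in the {peak['bin_left']:.0f}-{peak['bin_right']:.0f} m bin "
          f"({int(peak['count'])} events); busiest bearing bin "
          f"{peak_b['bin_left']:.0f}-{peak_b['bin_right']:.0f} deg")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].bar(rh["bin_left"], rh["count"], width=10, align="edge")
    axes[0].set_xlabel("range (m)")
    axes[0].set_ylabel("transit events")
    axes[1].bar(bh["bin_left"], bh["count"], width=5, align="edge")
    axes[1].set_xlabel("bearing (deg true)")
    fig.tight_layout()
    fig.savefig(ROOT / "detection_histograms.png", dpi=120)
    print(f"figure: {ROOT / 'detection_histograms.png'}")
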