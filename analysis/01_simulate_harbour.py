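"""Generate the synthetic harbour campaign all later steps analyse.

Writes the full input set — rig calibration, tide gauge, surfacing
observations with ground truth, transit events, hourly environment/presence
table, GPS calibration fixes and the cost line items — to results/inputs/.
"""

from pathlib import Path

from harbourcam.simulate import SimulationConfig, write_inputs

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"

if __name__ == "__main__":
    cfg = SimulationConfig(seed=SEED)
    paths = write_inputs(cfg, OUT)
    print(f"simulated campaign (seed {SEED}): {cfg.block1_days + cfg.block2_days} "
          f"recording days in two blocks, camera {cfg.height_above_datum} m above datum")
    for name, p in paths.items():
        print(f"  {name}: {p.relative_to(OUT.parents[1])}")
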