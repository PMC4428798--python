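"""Camera-system vs field-personnel cost comparison.

Aggregates the line items with exact cent arithmetic and reports the
fast-playback perusal arithmetic that drives the labour difference.
"""

from pathlib import Path

from harbourcam.costs import perusal_time, read_cost_csv, summarise_costs

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    items = read_cost_csv(ROOT / "inputs" / "costs.csv")
    cmp_ = summarise_costs(items)
    cmp_.table().to_csv(ROOT / "cost_comparison.csv", index=False)
    print(cmp_.summary())
    hours, whole = perusal_time(12.0, speed_factor=1.75)
    print(f"12 h of footage at 1.75x playback: minimum {hours:.2f} h review "
          f"({whole} h in whole hours)")
    hours_total, _ = perusal_time(493.4, speed_factor=1.75, overhead_fraction=0.22)
    print(f"a 493.4 h campaign at 1.75x with 22% rewind/recheck overhead: "
          f"~{hours_total:.0f} h of analyst time")
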