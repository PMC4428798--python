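"""Detectability vs environmental conditions: the GEE workflow.

Prepares the hourly table (first observation of each hour; sparse covariate
levels dropped), screens collinearity by VIF, fits the binomial AR-1 GEE,
reduces it by backward Wald elimination, and re-checks the surviving glare
term on a midday-exclusion submodel.
"""

from pathlib import Path

import pandas as pd

from harbourcam.detectability import (
    collinearity_screen,
    glare_confound_check,
    prepare_dataset,
    reduce_model,
)

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    hourly = pd.read_csv(ROOT / "inputs" / "hourly.csv", parse_dates=["timestamp"])
    prepared, log = prepare_dataset(hourly)
    log.dropped.to_csv(ROOT / "preparation_dropped.csv", index=False)
    print(log.summary())

    screen = collinearity_screen(
        prepared, ["glare", "beaufort", "cloud", "light"], priority=["beaufort", "glare"]
    )
    screen.vif.to_csv(ROOT / "vif_report.csv", index=False)
    print(f"VIF screen retained: {', '.join(screen.retained)}"
          + (f" (dropped {', '.join(d[0] for d in screen.dropped)})" if screen.dropped else ""))

    final, trail = reduce_model(prepared, ["glare", "beaufort", "glare:beaufort"])
    trail.to_csv(ROOT / "reduction_trail.csv", index=False)
    final.table().to_csv(ROOT / "gee_coefficients.csv")
    print(final.summary())

    check = glare_confound_check(prepared, final_terms=final.terms or ["glare"])
    check.plot_data.to_csv(ROOT / "presence_glare_timeseries.csv", index=False)
    print(f"midday-exclusion submodel ({check.n_excluded} records excluded): "
          f"glare p = {check.term_pvalue:.4f} "
          f"({'remains significant' if check.significant else 'not significant'})")

    from harbourcam.simulate import SimulationConfig

    cfg = SimulationConfig()
    print(f"\nsimulator truth for reference: beta0 = {cfg.beta0}, "
          f"beta_glare = {cfg.beta_glare}, alpha = {cfg.ar1_alpha}. "
          "At a single ~500-hour survey the weak glare effect is detected only "
          "intermittently; see the 200-replicate recovery study "
          "(scripts/acceptance.py) for its sampling distribution.")
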