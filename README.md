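# harbourcam

Shore-based camera photogrammetry and detectability analysis for harbour
dolphin monitoring.

Monitoring coastal dolphins with fixed cameras instead of field observers
is cheap and safe, but only useful if single-camera images can be turned
into positions and if environmental conditions that degrade detection are
understood.  `harbourcam` implements that full analysis chain for a camera
on one side of a harbour channel looking at an opposite wharf:

- **Positioning** — a surfacing at pixel `(col, row)` gets a true bearing
  by interpolation through surveyed landmarks, and a range from the
  depression angle below the opposite wharf's waterline (an *artificial
  horizon*): with the lens `h` metres above the tide-corrected water
  surface and the wharf at distance `D(b)`,
  `range = h / tan(arctan(h/D(b)) + Δ)`, where `Δ` is the angle from the
  waterline row down to the dolphin pixel.
- **Calibration** — estimated positions scored against boat GPS fixes
  (per-station error, error-vs-range regression).
- **Detection analysis** — field-of-view polygon and area; range/bearing
  histograms of first-detection positions per transit event.
- **Detectability** — hourly presence/absence modelled by a binomial GEE
  with AR-1 working correlation (`corr(y_s, y_{s−k}) = α^k` in calendar
  hours), robust Wald tests, backward elimination, VIF collinearity
  screening, and a midday-exclusion check that a glare effect is not a
  time-of-day artefact.
- **Costs** — exact line-item aggregation for camera vs field methods and
  fast-playback perusal arithmetic.
- **Simulator** — a synthetic harbour (scene, tides, transits, covariates,
  correlated presence, GPS runs) with known ground truth, so every stage is
  testable end to end without field data.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
harbour, writing tables under `results/`:

```
python analysis/01_simulate_harbour.py
python analysis/02_estimate_positions.py
...
python analysis/06_compare_costs.py
```

Step 02 prints, for the default 42-day campaign at seed 1:

```
1084 surfacings positioned, 0 skipped (at/above the artificial horizon)
positioning error vs ground truth under ±1 px observation noise: median 1.1 m, 95th percentile 9.3 m
range span 27.1-361.2 m, bearing span 245.1-299.0 deg
```

i.e. with one-pixel observation noise a 5 m-high camera positions
surfacings to metres near the camera, degrading with range as the
depression angle flattens.  Step 03 scores the nine-station GPS calibration
run (`Error range 1.6-20.5 m, mean 6.5 m`), step 04 maps the 42,769 m²
field of view and the detection-range histogram, step 05 fits and reduces
the GEE (printing the coefficient table, the working correlation
α̂ ≈ 0.40 against a simulated truth of 0.4, and the midday-exclusion
submodel), and step 06 reports the cost comparison:

```
camera method: USD $30,485 total, 490 labour hours
field method: USD $47,580 total, 588 labour hours
largest cost difference is in labour: USD $12,015
12 h of footage at 1.75x playback: minimum 6.86 h review (7 h in whole hours)
```

The same stages are available as a CLI (`harbourcam simulate|position|
calibrate|detections|detectability|costs|run-all`); `run-all` writes a
manifest of config hash and input checksums so identical runs are
verifiable.

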