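# Methods

This note documents the models and procedures implemented in `harbourcam`,
the defaults they ship with, and what the synthetic harbour does and does
not emulate.

## Positioning model

A fixed shore camera of known geographic position sits `h₀` metres above
the tidal datum, looking across a channel at an opposite wharf.  A
surfacing dolphin appears at pixel `(col, row)`.

**Bearing.** True bearing is piecewise-linear in pixel column through
surveyed landmarks (flood lights, buildings) of known bearing; columns
outside the outermost landmarks are linearly extrapolated and flagged.
Lens distortion is not modelled: the cameras this emulates are fully zoomed
out, and residual distortion is absorbed by the calibration error budget.
Bearing interpolation cannot cross the 0°/360° wrap; rigs looking due north
must re-reference their bearings.

**Range.** The waterline of the opposite wharf is an artificial horizon.
With the wharf at distance `D(b)` on bearing `b` and the lens `h` metres
above the instantaneous water surface, the waterline sits
`θ_wharf = arctan(h / D(b))` below the horizontal.  The extra depression
from the waterline row (stored per rig as ground-control points, piecewise
linear in column) down to the dolphin pixel is converted to degrees either
exactly through the pinhole relation `arctan(Δrow · pitch / focal)` when
focal metadata exist (still frames), or through a linear degrees-per-pixel
scale calibrated from lights of known height on the far wharf (video
frames, which store no focal length).  Then

    range = h / tan(θ_wharf + Δ)

**Tide.** `h = h₀ − w(t)`, with the gauge level `w` linearly interpolated
in time.  Camera height and gauge must share one datum (the rig config
carries a `datum` string precisely so mismatches are caught by humans).
Queries beyond the gauge series by more than 30 min are errors, not
extrapolations.

**Geographic conversion.** Range/bearing become coordinates on a local
planar east-north frame centred at the camera (equirectangular).  At
working ranges below ~500 m the curvature error is micrometres — far below
the pixel-noise error of metres — so great-circle formulas appear only as
independent oracles in the tests.

**Forward model.** `project_forward` is the algebraic inverse of the
estimator and is what the simulator uses to render surfacings into pixels;
round-trip closure (< 0.1 m, < 0.5 px) is property-tested over randomized
rigs.  Observations at or above the artificial horizon are unresolvable and
become flagged skip records; batch drivers never silently drop a row.

The video pixel scale is computed once per rig (not per frame) at datum
water level; tide moves the *depression origin* (`θ_wharf`), not the scale.

## Calibration scoring

GPS fixes from a boat-and-flag run are matched to camera observations by
nearest timestamp within ±5 s (ties are errors listing candidates).  The
error metric is horizontal great-circle distance; GPS altitude is ignored.
The report gives per-camera min/mean/max and an OLS slope of error on range
with a two-sided test at α = 0.05.  Under the default rig (5 m lens height,
wharf 100–450 m, ±1 px observation noise) the nine-station mean error comes
out at metres to low tens of metres, the scale expected when a ~0.03°/px
camera resolves depression angles under 3°.

## Detection analysis

The sampled area is the polygon bounded by the camera apex, the two
edge-bearing rays, and the wharf waterline polyline (not a circular arc),
with planar area.  Detection structure is analysed on one position per
transit event — the earliest surfacing, ties broken by smallest observation
id so results are order-invariant — binned into half-open `[k·w, (k+1)·w)`
range (default 10 m) and bearing (default 5°) bins.  No detection-function
model (half-normal etc.) is fitted; the analysis is deliberately
count-based.

## Detectability model

The response is hourly presence/absence of transit events over 12-hour
recording days.  Preparation keeps the first record of each clock hour and
iteratively removes records on covariate levels with ≤ 20 observations
(iterating to a fixed point makes the filter idempotent); every dropped row
is logged with its reason, and kept + dropped = input is asserted.
Collinearity is screened by VIF (threshold 3), with a priority list so
that, of a collinear pair such as cloud cover and Beaufort, the named
covariate is retained.

The model is a marginal binomial-logit GEE with AR-1 working correlation,
`corr(y_s, y_{s−k}) = α^k`, indexed by *calendar-hour* lag within each
survey block, so missing hours and overnight breaks weaken the working
correlation rather than being ignored.  Estimation is delegated to
`statsmodels.GEE`; an independent Fisher-scoring solver in the test suite
confirms the score equations are solved.  Covariates enter as numeric
scores (after level filtering, glare is effectively binary, so factor vs
numeric coding is immaterial and numeric gives the single-df Wald test).

Standard errors: with ≥ 10 clusters the usual robust sandwich is used; with
fewer (e.g. the two survey blocks) the plain sandwich is degenerate and the
Mancl–DeRouen bias-reduced estimator is used instead.  The working
correlation's standard error is a moment approximation (sd/√m of lag-1
standardised-residual products) because statsmodels does not provide one.

Model reduction is backward elimination by Wald tests at α = 0.05,
interactions always dropped before the main effects of their components,
with the full trail recorded.  The glare term gets one extra scrutiny: a
submodel excluding a configurable midday window (default 09:00–13:00)
checks that an apparent glare effect is not a pure time-of-day artefact,
since glare-free conditions cluster in the middle of the day.

## Cost model

Line items (gear/labour/expendables per method) are summed in integer
cents, so totals are exact and order-invariant.  Overheads and on-costs are
excluded by design.  The minimum video review time is
`footage / speed_factor · (1 + overhead_fraction)` with a round-half-up
whole-hour convenience value; the default speed factor is 1.75, the fastest
playback at which trial observers missed no detections.  The bundled
default cost table describes a 42-day dual-method campaign in USD; only the
video-perusal labour hours (418 h) and the field total (588 h) are fixed by
that campaign's records — the split of the remaining 72 camera-method hours
across gear preparation, servicing and programming is a bookkeeping choice
that only needs to sum correctly.

## Synthetic harbour

Defaults: camera 5 m above datum; wharf waterline sweeping 100–450 m over a
54° bearing span; video frame 1440×1020 px with a true vertical scale of
0.030°/px (still variant 3840×2160 px, 5.8 mm focal, 1.71 µm pitch); a
diurnal tide (amplitude 0.35 m, period 24.84 h, 2 cm gauge noise); two
survey blocks (24 + 18 recording days) with a seasonal gap; a still capture
every 20 s; ±1 px observation noise and 2 m GPS jitter.

Covariate schedules: Beaufort is a bounded random walk on 1–5; cloud
(eighths) is generated from Beaufort plus noise, deliberately collinear
with it; glare is 0 in the 09:00–15:00 window and otherwise present unless
heavy cloud suppresses it, with rare sparse levels 2–3 to exercise the
level filter; haze, rain and droplets are rare.  Presence follows the
marginal model `logit P = β₀ + β_g·glare + β_b·Beaufort` (defaults 0.25,
−0.26, 0) with AR-1 serial dependence α = 0.4, generated by thresholding a
latent calendar-hour AR-1 Gaussian process whose autocorrelation is
calibrated numerically (bivariate-normal orthant equation at the mean
marginal probability) so the realized *binary* lag-1 correlation matches α.
This is an approximation to the GEE's working-model semantics: the realized
correlation drifts slightly where the marginal probability varies, which is
why recovery tolerances are stated as ±0.05/±0.1 rather than exact.  A
confound mode replaces the glare effect with a midday presence bump for
testing the time-of-day check.

Dolphin transits are straight constant-speed (1.5 m/s) chords across the
field of view — no behavioural movement model — with surfacings at roughly
normal intervals (30 ± 12 s) and group-size triples min ≤ best ≤ max drawn
around a small-group mean.  Group-size and surfacing-interval distributions
are fixtures, not estimates of real behaviour.

What passing tests show: the geometry, accounting, and estimation machinery
are correct, and the estimators recover known truth under the stated noise
model.  What they do not show: anything about real dolphin behaviour,
real glare optics, image-analyst performance, or lens distortion — none of
which the simulator attempts.

## Study sizes

The verification studies use sizes chosen a priori for statistical
adequacy: coefficient/α recovery runs 200 replicates at the survey size
n = 343 (two blocks); the model-selection study runs 200 replicates of a
larger panel (40 series × 180 h) because at n = 343 the weak true glare
effect (−0.26) has Wald power well below any sensible selection-consistency
bar — the panel size is set so the glare test has power ≈ 1, making
glare-only selection probability ≈ 0.9 after two null drops at α = 0.05.
Monte-Carlo FOV checks use 10⁵ points (area) and 5,000 points (density).

## Known limitations

- Bearing interpolation cannot cross north; single-harbour use only.
- The latent-Gaussian binary generator matches lag-1 correlation at the
  mean marginal probability, not per-pair.
- The AR-1 α standard error is approximate (see above).
- The planar frame ignores earth curvature (negligible below ~1 km) and
  the model ignores atmospheric refraction, which at 20 m+ camera heights
  and kilometre ranges would not be negligible.
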