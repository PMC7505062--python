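# Methods

## Detector model

The trigger is a per-second state machine over two ADC channels. With
instantaneous ratio `r_t = s1/s2` (polarity `dark_high`: shading the top
sensor *raises* s1, because the photoresistor divider maps darkness to high
counts) and window mean `r̄`, the indicator is `Y_t = r_t / r̄`. Parameters,
with the field defaults:

| parameter | default | meaning |
|---|---|---|
| `reset_interval_X_s` | 300 s | averaging-window reset period |
| `ratio_threshold_Y` | 1.05 | trigger threshold on `Y_t` |
| `perch_duration_Z_s` | 10 s | continuous supra-threshold time before the shutter |
| `reboot_at_s` | 7 s | wake-up pulse to the sleeping camera |
| `sample_period_s` | 1 s | sensor/sleep cycle |
| `signal_floor` | 8 counts | gate: no detection if either channel reads below it |
| `baseline_includes_perch` | false | supra-threshold samples excluded from the baseline |
| `rearm_samples` | 1 | sub-threshold samples needed to re-arm after a photo |

Choices where the published description is ambiguous (all switchable):

- **Baseline** is the arithmetic mean of instantaneous ratios accumulated
  since the window start; `Y_t := 1` while the window is empty, so the very
  first trace sample can never trigger.
- **Ordering**: `Y_t` is evaluated against the *current* window before any
  reset; the X-interval reset runs afterwards and only when `Td = 0`, so a
  reset is postponed while a perch is in progress. The fresh window is
  seeded with the current sub-threshold ratio rather than left empty —
  with an empty window the next sample would have `Y_t := 1` and a perch
  beginning there would absorb itself into its own baseline and go
  undetected. With seeding, a rectangular ratio step of relative height
  ≥ Y lasting ≥ Z s is detected exactly once for *any* onset after the
  first sample, including onsets spanning a reset boundary.
- **Excluding perch samples from the baseline** keeps a long bout from
  eroding its own detectability; setting `baseline_includes_perch=true`
  restores the contaminating behaviour for conformance experiments.
- **Timing convention**: a sample stamped `t` integrates light over
  `(t-1, t]`, so a perch starting at `p` first elevates the sample at
  `p+1`; the reboot lands at `p+7` and the shutter at `p+10`.
- Ratios are computed in double precision; the original fixed-point
  firmware details are not modelled.

A hazard worth knowing: if the ratio rises and *stays* above threshold
(e.g. a permanent occlusion), the baseline stops updating and resets stay
postponed, so `Td` grows until the signal falls again. One photo is still
all that is taken; the condition clears at the next sub-threshold sample.

## Synthetic sky, clouds, sensors

The simulator exists to exercise the detector and the validation pipeline
with known ground truth. Its functional forms are deliberately simple:

- **Clear sky**: direct irradiance is a half-sine between sunrise and
  sunset (peak 1000 arbitrary units); diffuse = 0.15 × direct + a floor of
  20 units. The floor (2 % of peak) represents twilight/night sky
  brightness; it also keeps the sunset ratio transition slow enough that
  the clear-sky trace never false-triggers (max `Y_t` ≈ 1.041 against the
  1.05 threshold) — with a perfectly black night sky the day→night ratio
  swing outruns the 300-s baseline and produces a spurious sunset trigger.
- **Clouds**: a reflected Ornstein–Uhlenbeck optical-depth `x_t ≥ 0`
  (reversion time ~10 min); direct and diffuse components are attenuated
  by `exp(-x·s)` with sensitivities 1.0 and 0.3. Clouds dim the beam more
  than the skylight — precisely the asymmetry a perch produces — so cloud
  volatility is the simulator's false-positive dial, and false-positive
  counts rise monotonically with it (verified over seed ensembles).
- **Perch schedule**: Poisson arrivals inside the daylight window
  (default lognormal bout durations, median 30 s, σ = 0.6 on log-seconds —
  most bouts clear the 10-s threshold, short visits occur); overlapping or
  window-clipping proposals are resampled; occlusion default 0.9 of the
  direct component at sensor 1 only (a leakage term can bleed direct light
  into sensor 2).
- **Sensor response**: CDS photoresistor `R(E) = r0·E^-γ` (γ = 0.8,
  `r0` = 1 MΩ — the cells' dark-resistance scale) in a divider
  (`r_fixed` = 10.5 kΩ), ADC = `1023·R/(R+r_fixed)`, Gaussian read noise
  (σ = 1 count), clamped and quantized. Mid-scale sits at ~300 irradiance
  units, putting full daylight near count 260 and deep shade near 1020, so
  a 10 % direct occlusion at midday moves the channel ratio by ≥ 5 % — the
  Y = 1.05 operating point.
- **Camera**: the trap cannot query the camera, so a reboot pulse doubles
  as a shutter press if the camera happens to be awake (awake = within
  60 s of last activity; the sleep timeout is not documented and 60 s is a
  plausible consumer-camera idle). This reproduces the duplicate-photo
  bursts that the validation protocol removes.

What the simulator does **not** model: physically calibrated radiometry,
sun-angle effects on the diffuser, condensation, wind-moved vegetation, or
species behaviour. Passing tests therefore demonstrate the *algorithmic*
properties of the trigger and pipeline (thresholds, timing, bout logic,
statistics), not field false-positive rates — those depend on real skies,
and the published field counts (17–51 per ~2 days) are represented here
only qualitatively by the cloud-volatility monotonicity.

## Validation pipeline

- **De-duplication**: among consecutive photos closer than 5 s the earlier
  one is dropped, left to right (a reboot-then-shutter burst keeps only
  the final frame).
- **Perching events**: maximal runs of present frames (10-s time-lapse) in
  which any internal absent run is shorter than 2 frames; an absent run of
  ≥ 2 frames (≥ 20 s, the bout criterion interval) closes the event. The
  duration class uses the first-to-last-present span; exactly 20 s falls
  in the ≤ 20 s class.
- **Matching**: an event is a true positive iff a dragonfly photo lies
  within its span ± 10 s (one frame interval of clock-skew tolerance).
  With no events at all, sensitivity is explicitly *undefined* rather
  than 0 or 1.

## Statistics

- **Fisher's exact test** (one-sided): hypergeometric tail by enumeration
  over all tables with the observed margins, direction an explicit
  parameter (`greater` = larger top-left cell).
- **Monte-Carlo goodness of fit**: chi-square of two counts against an
  even split; null replicates `Binomial(n, ½)`; p = `(m+1)/(B+1)` with
  `B = 10⁶` by default — never exactly zero, matching standard
  simulated-p-value practice. An exact binomial enumeration oracle backs
  the Monte-Carlo estimator in the tests.
- **Holm step-down** adjustment, capped at 1, returned in input order.
- **Power estimate**: cells × volts × mAh / (days × 24 h), in mW.

## Problem sizes and numerical choices

The packaged synthetic experiment is two days × three sites (high-density,
mid-density, empty control) at 1 Hz, ~520 k detector steps, a few seconds
of runtime; statistical ensemble tests use 20–120 seeds and 4·10⁴–10⁶
Monte-Carlo replicates. One top-level seed deterministically derives
sub-streams (clouds, schedule, per-channel noise) via `SeedSequence`, so
every pipeline output is bit-reproducible under a fixed seed. Degenerate
inputs fail loudly: empty traces, unordered timestamps, out-of-range ADC
values (with the file row named), empty Fisher margins, zero events for a
sensitivity, infeasible perch densities.
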