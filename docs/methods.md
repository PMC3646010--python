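# Methods

## Overview

`echorisk` is a forward-and-inverse analysis of the acoustic scene
around a bat attack on a tiger moth. The forward side generates the
scene (bat flight, echolocation sequence, beam directivity, propagation,
microphone response); the inverse side recovers what a field calibration
chain would estimate from the recordings (source levels, levels at the
moth); the analysis side asks the moth's question — is this attack aimed
at me? — with discriminant and ROC machinery. Because every downstream
stage can run on generated scenes, the whole chain is testable without
field data.

## Propagation model

Levels are dB peSPL re 20 µPa. Source levels are referenced to 0.1 m
from the bat's mouth. One-way transmission loss from the reference is

    TL(d) = 20 log10(d / 0.1) + α(f, T, RH) · (d − 0.1)

with α the ISO 9613-1 pure-tone atmospheric absorption coefficient
(valid over the 20–100 kHz band used here; standard pressure assumed).
The implementation was validated once against published pure-tone
tables (e.g. α(40 kHz, 20 °C, 50 % RH) = 1.32 dB/m) and those values are
frozen as test oracles. Attenuation is accrued from the reference
distance outward, consistent with the 10 cm source-level convention;
the same convention is applied on the bat→mic and bat→moth legs.

## Beam directivity

*Myotis* search/approach calls have a −6 dB full width of 80°
(half-width 40°), buzz calls 180° (half-width 90°). Only the two anchor
constraints (0 dB on axis, −6 dB at the half-width) are known, so the
falloff between them is modeled parabolic in dB,
`gain(θ) = −6 (θ/θ_half)²`, floored at −40 dB. The floor keeps
far-off-axis levels finite without affecting any geometry the analyses
visit (tethered mic within 0.25 m of the focal moth).

## Microphone model

The default sensitivity tables emulate a miniature field microphone on
a long thin cable: flat (0 dB) from 20–40 kHz, sensitivity falling
5 dB per 10 kHz up to 100 kHz, and a mild parabolic-in-angle
directionality deepening from 2 dB (20 kHz) to 4 dB (60 kHz) at the
rear — all within the ±2–4 dB "fairly omnidirectional" envelope typical
of such sensors. `mic_correction` is the sign-flipped bilinear
interpolation of these tables; the forward model applies the same
tables with the opposite sign, so inverse-after-forward is exact.

## Echolocation sequence generator

Phases are defined by pulse-interval bands induced from representative
per-phase PIs: buzz ≤ 10 ms < approach ≤ 60 ms < search (12 and 60 ms
being transitional). The generator schedules:

* **search** — PI = 1000/rate (default 10 calls/s, realistic range
  7–12), source level fixed at 110 dB, beam wandering 20–60° off the
  flight direction (a scanning bat does not aim at undetected prey);
* **approach** — begins when the bat first comes within the detection
  distance (drawn from 2.2–4.5 m); PI falls linearly 60 → 20 ms; the
  beam slerps from its direction at detection onto the target, locking
  by 60 % of the approach;
* **buzz** — engaged inside 0.4 m; PI = 1000/160 ms, beam locked.

Source level: a linear localization ramp (default 0.2 s, matching the
~200 ms intensity rise seen when attacks are aligned on their loudest
call) from the search level up to the gain-control ceiling, then
automatic gain control `SL = setpoint + TL(d)` once that law drops
below the ceiling. The engagement distance defaults to 1.5 m —
mid-approach for the detection distances above — which puts the ceiling
near 120 dB and the held level at the target at the setpoint (default
95.3 dB). Calls carry a generator-truth `gain_control` flag used only
for evaluating recovery, never by the inverse.

Multiplicative lognormal PI jitter (σ = 5 %) is truncated at the phase
band edges so generated phase labels and PI-based classification agree
exactly; with jitter disabled the schedule is strictly non-increasing
after detection.

## Scenario geometry

The field rig: focal moth tethered at (0, 0, 3) m, microphone 0.25 m
above it (axis vertical), bats flying straight at constant speed
(2–6 m/s) toward the focal moth (real threat), toward a free-flying
neighbor 0.5–2 m away (false threat), or past the site at a 1–4 m miss
distance without detecting anything (pass). One second of search flight
precedes detection; tracks are sampled at 60 frames/s. Straight
constant-speed paths are a deliberate simplification — they preserve
every acoustic property the analyses use (distances, angles, phase
timing) while keeping geometry exactly reconstructable from the stored
track by linear interpolation, which both the forward model and the
inverse use so that the calibration round trip is exact at machine
precision. Curved or evasive flight, moth motion, and multi-bat scenes
are not modeled.

## Calibration inverse

    SPL_mic   = recorded + mic_correction(f, mic off-axis angle)
    SL_moth-dir = SPL_mic + TL(d_bat→mic) + 3 dB
    SPL_moth  = SL_moth-dir − TL(d_bat→moth)

The +3 dB is a fixed compensation for the beam pointing at the moth
rather than the mic, applied exactly once (in the source-level step).
Under the idealized convention (mic-direction gain exactly 3 dB below
moth-direction gain) the chain is an exact inverse of the forward
model; under the true beam geometry the per-call bias equals
`beam_gain(mic) − beam_gain(moth) + 3`, and the pipeline reports that
bound per scenario rather than pretending the error away. In the
default tether geometry the realized bias is ≈ +1 to +4 dB, the same
order as the irreducible beam-direction uncertainty of the field
method.

Event features follow the field readout rules: for clicking events the
mean level and start-to-start interval of the two calls preceding the
click; for non-clicking events the mean of the loudest call and its two
neighbors (using whichever neighbors exist, flagged at the edges).

## Trend fits

Attack-aligned trends (intensity or angle vs time, time²) use the
within-attack centered least-squares (fixed-effects) estimator:
response and regressors demeaned per attack, then pooled OLS. This
replaces random-intercept mixed models — per-attack intercepts are
treated as fixed nuisance offsets, which recovers the shared time
coefficients exactly on noise-free data and avoids maximum-likelihood
machinery that small synthetic ensembles cannot support. R² is reported
within the centered space; a constant response gives slope 0 and R² 0.

## Decision analyses

* **Ramp thresholds** — stimuli are 10 s files of 2 ms, 40 kHz pulses
  at one of nine PIs (4–100 ms) ramping 5 dB/s from 70 to 120 dB. The
  measured threshold is the level of the pulse immediately preceding
  the first click, so measurement error is bounded by one ramp step,
  5 dB/s × PI. Phase means average the representative PIs only
  (search 80, 100; approach 20, 30, 45; buzz 4, 7 ms).
* **Discrimination model** — two Gaussians over (log₁₀ PI ms, dB at
  moth); log PI because thresholds live naturally on a logarithmic PI
  axis. Sample means/covariances per class, equal priors by default
  (the field design fixes no prior), optional ridge for near-singular
  covariances. Iso-posterior threshold curves are found per grid PI by
  a 0.25 dB scan plus Brent root search for the lowest crossing in
  [60, 130] dB, with multiple crossings flagged. The model is fit on
  calls pooled across attacks (per-attack summaries would leave ~5–9
  points per class).
* **AUR** — pairwise enumeration with ties at 0.5; the rank-statistic
  formulation U/(n₁n₂) serves as an independent oracle in tests, never
  as the implementation.
* **Pass discrimination** — forward stepwise variable selection by the
  partial F of the Wilks' Λ change (entry p < 0.05), then a linear
  discriminant on the selected variables. PPV/NPV follow the field
  convention: fraction of clicking (resp. non-clicking) interactions
  classified correctly — sensitivity and specificity in standard
  nomenclature.

## Kinematics

Quintic smoothing splines per coordinate (FITPACK). The smoothing
budget defaults to `n·σ̂²` with σ̂² a second-difference noise-variance
estimate — automatic and reproducible without hand tuning; zero
smoothing interpolates. Approach angle is the angle between the flight
velocity and the bat→target vector, reported missing below 0.05 m/s
(directions are numerically meaningless for a near-stationary point).
The wand check reports mean absolute inter-marker error and its percent
of the true separation.

## What the synthetic data does and does not show

The generator reproduces the structural features the analyses depend
on — phase-scheduled PIs, beam convergence, localization rise, gain
control, tether geometry, detection-range and speed distributions, the
5 dB/s ramps — under idealized noise (iid Gaussian on recorded levels,
lognormal PI jitter). It does not reproduce call-to-call source-level
variability of real bats, curved flight, moth evasive motion,
atmospheric refraction or clutter echoes. Passing tests therefore
demonstrate the correctness and self-consistency of the analysis chain
under the stated model, not field-level effect sizes: ensemble AUR
values, trend coefficients and PPV/NPV on synthetic scenes are cleaner
than any field dataset would give, and only their signs and orderings
(approach/buzz separate, search does not; false-threat levels fall;
real-threat levels rise then plateau) should be read as the scientific
content.

## Numerical choices and problem sizes

Ensonified volumes use 181-point Simpson quadrature over the polar
angle with per-angle Brent root finding (doubling the resolution moves
the omnidirectional closed-form case by < 0.1 %). The acceptance script
uses 20 scenarios for round trips, 100 replicates × 3 attacks for
gain-control recovery, one 5-real/9-false ensemble for AUR and trends,
1000 group pairs for the AUR oracle, and the nine-PI grid elsewhere —
sizes at which every quantity is stable to well inside its reported
precision. All randomness flows from `numpy.random.SeedSequence`
children of a single seed; identical seeds give bitwise-identical
outputs (reports exclude timestamps and output paths for this reason).
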