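# echorisk

Acoustic–kinematic analysis of echolocating-bat attacks and the
threat-discrimination problem faced by sonar-jamming tiger moths.

A tiger moth that hears an approaching *Myotis* bat must decide whether
*it* is the target (a **real threat**) or whether the bat is attacking a
neighboring moth (a **false threat**), using only two acoustic cues: the
bat's **pulse interval** (PI, the start-to-start time between
echolocation calls, which reveals the bat's attack phase — search
> 60 ms, approach 10–60 ms, terminal buzz ≤ 10 ms) and the **call
intensity arriving at the moth**. `echorisk` provides the full analysis
chain for studying that decision with synthetic field data:

* **Propagation & sensors** — spherical spreading from the 10 cm
  source-level reference, ISO 9613-1 excess atmospheric attenuation,
  phase-dependent sonar-beam directivity (−6 dB full widths 80° for
  search/approach, 180° for buzz), microphone frequency/directionality
  corrections, and ensonified-volume integrals.
* **Attack simulation** — seeded *Myotis* attack sequences with
  search/approach/buzz phase structure, a localization intensity ramp,
  and automatic gain control holding the level at the target constant
  (`SL = setpoint + TL(d)`), over straight constant-speed 3-D flight
  paths with detection at 2.2–4.5 m.
* **Calibration inverse** — from recorded microphone levels plus 3-D
  geometry back to each call's source level at 10 cm (in the moth's
  direction, via a fixed +3 dB beam-direction compensation) and the
  level at the moth; per-event intensity/PI features; attack-aligned
  trend fits.
* **Kinematics** — quintic smoothing splines over 60 frames/s tracks,
  flight vectors, approach angles, wand-calibration error checks.
* **Decision analyses** — clicking-threshold extraction from 5 dB/s
  ramped playbacks, per-phase threshold means, a two-class Gaussian
  (quadratic discriminant) model over (log₁₀ PI, intensity) with
  iso-posterior threat thresholds at p = 0.5 / 0.75, ROC area (AUR) as
  the probability a random real-threat call out-louds a random
  false-threat call, and stepwise discriminant analysis of clicking vs
  non-clicking bat passes with PPV/NPV.

## Worked example

```bash
python examples/05_threat_discrimination.py
```

builds 5 real-threat and 9 false-threat attacks, fits the discriminant
model and prints:

```
phase-wise separability of real vs false threats (level at the moth):
    search: AUR = 0.474  (n = 54 real, 92 false)
  approach: AUR = 0.884  (n = 117 real, 203 false)
      buzz: AUR = 1.000  (n = 56 real, 104 false)
...
p = 0.75 threat threshold (dB at moth): 4 ms: 97.5, 7 ms: 94.0, 12 ms: 90.9, 20 ms: 88.7, 30 ms: 88.4
```

During search, the bat's scanning beam gives real and false threats
nearly identical intensity distributions at the moth (AUR ≈ 0.5 —
useless for discrimination). Once the bat targets a moth, the beam
locks on and gain control engages: approach- and buzz-phase calls
separate the two conditions almost perfectly. The p = 0.75 curve is the
intensity, per pulse interval, above which the odds of being the actual
target exceed 3:1 — the optimal clicking threshold for a moth that
tolerates a 25% false-alarm-ish risk.

The other examples cover propagation arithmetic
(`01_sound_propagation.py`), the phase structure and gain control of a
single simulated attack (`02_attack_simulation.py`), the calibration
round trip and its beam-direction bias bound
(`03_calibration_roundtrip.py`), and ramp-playback threshold
measurement with per-phase means (`04_ramp_thresholds.py`).

A thin CLI wraps the same functions for end-to-end runs:

```bash
echorisk run --seed 3 --n-attacks 5 --out run_out   # simulate -> calibrate -> analyze
echorisk simulate --threat-type false --n-attacks 3 --seed 2 --out bundles
echorisk analyze bundles/* --out analysis
```

Scenario bundles are plain-text directories (`calls.csv`, `tracks.csv`,
`meta.json`); outputs are `received_levels.csv`, `thresholds.csv`,
`model.json`, `roc.json`, and a deterministic `report.json`.

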