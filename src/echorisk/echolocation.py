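"""Generative model of *Myotis* attack echolocation sequences.

An attack progresses through three phases read directly off the pulse
interval (PI, start-to-start time between consecutive calls):

* **search** -- low repetition rate (7-12 calls/s), beam scanning, not
  aimed at the prey;
* **approach** -- begins at prey detection; PI drops along a schedule
  (default 60 -> 20 ms) while the beam converges onto the target and the
  emitted source level first rises (localization) and then falls as
  automatic gain control holds the level arriving at the target constant;
* **terminal buzz** -- maximal repetition rate (default 160 calls/s),
  beam locked on the prey, until capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .acoustics import Environment, transmission_loss

__all__ = [
    "Call",
    "SequenceParams",
    "AttackTimeline",
    "classify_phase",
    "gain_control_source_level",
    "generate_call_sequence",
    "PHASE_BOUNDS_MS",
]

#: PI class boundaries (ms): buzz <= 10 < approach <= 60 < search.
#: Induced from the representative per-phase PIs (search 80, 100;
#: approach 20, 30, 45; buzz 4, 7) with 12 and 60 ms transitional.
PHASE_BOUNDS_MS = (10.0, 60.0)

SOURCE_LEVEL_RANGE_DB = (60.0, 130.0)


def classify_phase(pulse_interval_ms: float, bounds=PHASE_BOUNDS_MS) -> str:
    """Assign an echolocation phase from a pulse interval (ms)."""
    pi = float(pulse_interval_ms)
    if pi <= 0:
        raise ValueError("pulse interval must be positive")
    buzz_max, approach_max = bounds
    if pi <= buzz_max:
        return "buzz"
    if pi <= approach_max:
        return "approach"
    return "search"


@dataclass(frozen=True)
class Call:
    """One echolocation emission."""

    emission_time_s: float
    source_level_db: float  # on-axis, dB peSPL re 20 uPa at 10 cm
    beam_direction: np.ndarray  # unit 3-vector
    phase: str
    pulse_interval_ms: float  # start-to-start interval to the next call
    peak_frequency_khz: float = 40.0
    duration_ms: float = 2.0
    gain_control: bool = False  # generator truth: gain-control law active

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("call duration must be positive")
        lo, hi = SOURCE_LEVEL_RANGE_DB
        if not lo <= self.source_level_db <= hi:
            raise ValueError(
                f"source level {self.source_level_db} dB outside [{lo}, {hi}]"
            )
        b = np.asarray(self.beam_direction, float)
        object.__setattr__(self, "beam_direction", b / np.linalg.norm(b))


@dataclass(frozen=True)
class SequenceParams:
    """Tunable parameters of the attack-sequence generator."""

    search_rate_hz: float = 10.0  # 7-12 calls/s typical
    buzz_rate_hz: float = 160.0
    approach_pi_start_ms: float = 60.0
    approach_pi_end_ms: float = 20.0
    gain_setpoint_db: float = 95.3  # level held at the target
    search_source_level_db: float = 110.0
    gain_engage_distance_m: float = 1.5  # mid-approach engagement
    localization_duration_s: float = 0.2  # linear SL rise after detection
    buzz_trigger_distance_m: float = 0.4
    beam_lock_fraction: float = 0.6  # fraction of approach by which beam locks
    search_beam_wander_deg: tuple = (20.0, 60.0)
    pi_jitter_sigma: float = 0.05  # lognormal multiplicative PI jitter
    peak_frequency_khz: float = 40.0
    call_duration_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.search_rate_hz <= 0 or self.buzz_rate_hz <= 0:
            raise ValueError("call rates must be positive")
        if self.approach_pi_end_ms >= self.approach_pi_start_ms:
            raise ValueError("approach PI schedule must be decreasing")


@dataclass
class AttackTimeline:
    """Continuous bat/target geometry over the span of one attack.

    ``bat_position`` and ``flight_direction`` are callables of time;
    the target is a fixed point (the attacked moth).
    """

    bat_position: Callable[[float], np.ndarray]
    flight_direction: Callable[[float], np.ndarray]
    target_position: np.ndarray
    t_start: float
    t_end: float

    def distance(self, t: float) -> float:
        return float(
            np.linalg.norm(np.asarray(self.target_position) - self.bat_position(t))
        )

    def direction_to_target(self, t: float) -> np.ndarray:
        v = np.asarray(self.target_position, float) - self.bat_position(t)
        return v / np.linalg.norm(v)

    def first_time_within(self, distance_m: float, dt: float = 1e-3) -> float | None:
        """First time the bat comes within ``distance_m`` of the target."""
        ts = np.arange(self.t_start, self.t_end + dt, dt)
        for t in ts:
            if self.distance(min(t, self.t_end)) <= distance_m:
                return float(min(t, self.t_end))
        return None


def gain_control_source_level(
    distance_m: float, setpoint_db: float, frequency_khz: float, env: Environment
) -> float:
    """Source level (dB at 10 cm) holding the level at the target at the setpoint.

    The automatic-gain-control forward law: ``SL = setpoint + TL(d)``,
    so the noise-free level arriving at the target is exactly the
    setpoint at any distance.
    """
    return setpoint_db + transmission_loss(distance_m, frequency_khz, env)


def _slerp(a: np.ndarray, b: np.ndarray, u: float) -> np.ndarray:
    """Spherical interpolation between unit vectors a (u=0) and b (u=1)."""
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-9:
        return b
    return (np.sin((1 - u) * omega) * a + np.sin(u * omega) * b) / np.sin(omega)


def _random_cone_direction(axis: np.ndarray, angle_deg: float, rng) -> np.ndarray:
    """Unit vector at a given polar angle from ``axis``, random azimuth."""
    axis = axis / np.linalg.norm(axis)
    # build an orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    th = np.radians(angle_deg)
    return np.cos(th) * axis + np.sin(th) * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _clip_pi_to_phase(pi_ms: float, phase: str, bounds=PHASE_BOUNDS_MS) -> float:
    """Truncate a jittered PI to its phase's PI band.

    Phases are defined by PI bands, so jitter is truncated at the band
    edges; this keeps generated labels and PI-based classification in
    exact agreement.
    """
    buzz_max, approach_max = bounds
    eps = 1e-9
    if phase == "buzz":
        return min(pi_ms, buzz_max)
    if phase == "approach":
        return float(np.clip(pi_ms, buzz_max + eps, approach_max))
    return max(pi_ms, approach_max + eps)


def generate_call_sequence(
    params: SequenceParams,
    timeline: AttackTimeline,
    detection_distance_m: float | None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    env: Environment | None = None,
) -> list[Call]:
    """Generate the call sequence of one attack along a timeline.

    ``detection_distance_m=None`` yields a pure search-phase pass (the
    bat never detects the focal prey). Otherwise the sequence runs
    search -> approach (localization ramp, then automatic gain control)
    -> terminal buzz, ending at the timeline's end (capture).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    env = env or Environment()
    f = params.peak_frequency_khz

    if detection_distance_m is None:
        t_detect = None
    else:
        t_detect = timeline.first_time_within(detection_distance_m)
        if t_detect is None or t_detect >= timeline.t_end:
            raise ValueError(
                "timeline too short: bat never reaches detection distance "
                f"{detection_distance_m} m before t_end"
            )
        t_buzz = timeline.first_time_within(params.buzz_trigger_distance_m)
        t_engage = timeline.first_time_within(params.gain_engage_distance_m)
        if t_buzz is None or t_engage is None:
            raise ValueError("timeline too short: attack phases incomplete")
        t_loc_end = min(t_detect + params.localization_duration_s, t_engage)
        sl_ceiling = gain_control_source_level(
            params.gain_engage_distance_m, params.gain_setpoint_db, f, env
        )
        sl_ceiling = min(sl_ceiling, SOURCE_LEVEL_RANGE_DB[1])

    lo_sl, hi_sl = SOURCE_LEVEL_RANGE_DB
    calls: list[Call] = []
    t = timeline.t_start
    beam_at_detect = None
    last_beam = None
    while t < timeline.t_end:
        d = timeline.distance(t)
        # ---- phase
        if t_detect is None or t < t_detect:
            phase = "search"
        elif t < t_buzz:
            phase = "approach"
        else:
            phase = "buzz"
        # ---- scheduled pulse interval
        if phase == "search":
            pi = 1000.0 / params.search_rate_hz
        elif phase == "approach":
            frac = (t - t_detect) / max(t_buzz - t_detect, 1e-9)
            pi = params.approach_pi_start_ms + frac * (
                params.approach_pi_end_ms - params.approach_pi_start_ms
            )
        else:
            pi = 1000.0 / params.buzz_rate_hz
        if params.pi_jitter_sigma > 0:
            sig = params.pi_jitter_sigma
            pi *= rng.lognormal(mean=-0.5 * sig**2, sigma=sig)
            pi = _clip_pi_to_phase(pi, phase)
        # ---- source level
        gain_control = False
        if t_detect is None or t < t_detect:
            sl = params.search_source_level_db
        elif t < t_loc_end:
            u = (t - t_detect) / max(t_loc_end - t_detect, 1e-9)
            sl = params.search_source_level_db + u * (
                sl_ceiling - params.search_source_level_db
            )
        elif t < t_engage:
            sl = sl_ceiling
        else:
            sl = gain_control_source_level(
                max(d, 0.1), params.gain_setpoint_db, f, env
            )
            gain_control = True
        sl = float(np.clip(sl, lo_sl, hi_sl))
        # ---- beam direction
        flight = timeline.flight_direction(t)
        if phase == "search":
            wander = rng.uniform(*params.search_beam_wander_deg)
            beam = _random_cone_direction(flight, wander, rng)
            last_beam = beam
        elif phase == "approach":
            if beam_at_detect is None:
                beam_at_detect = (
                    last_beam if last_beam is not None else flight
                )
            frac = (t - t_detect) / max(t_buzz - t_detect, 1e-9)
            u = min(1.0, frac / params.beam_lock_fraction)
            beam = _slerp(beam_at_detect, timeline.direction_to_target(t), u)
        else:
            beam = timeline.direction_to_target(t)
        calls.append(
            Call(
                emission_time_s=float(t),
                source_level_db=sl,
                beam_direction=beam,
                phase=phase,
                pulse_interval_ms=float(pi),
                peak_frequency_khz=f,
                duration_ms=params.call_duration_ms,
                gain_control=gain_control,
            )
        )
        t += pi / 1000.0
    if not calls:
        raise ValueError("timeline too short: no calls generated")
    return calls
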