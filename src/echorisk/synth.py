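"""Seeded synthetic scenarios for every downstream analysis stage.

Generates complete attack scenarios (real threat: the bat converges on
the focal moth; false threat: the bat attacks a free-flying neighbor;
pass: the bat transits without detecting anything), the forward acoustic
model producing received levels at the field microphone and at the focal
moth, laboratory ramp playbacks (5 dB/s, 70-120 dB SPL, 40 kHz), and a
threshold-curve moth response model.

Geometry emulates the field rig: a focal moth tethered ~3 m up with the
miniature microphone 0.25 m above it, bats detected at 2.2-4.5 m flying
2-6 m/s. Flight paths are constant-speed straight approaches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acoustics import (
    REFERENCE_DISTANCE_M,
    BeamModel,
    Environment,
    MicrophoneModel,
    beam_gain,
    default_microphone,
    mic_sensitivity,
    transmission_loss,
)
from .echolocation import AttackTimeline, Call, SequenceParams, generate_call_sequence
from .kinematics import RawTrack
from .threat import ThresholdCurve

__all__ = [
    "ScenarioParams",
    "AttackScenario",
    "RampStimulus",
    "MothResponseModel",
    "RAMP_PULSE_INTERVALS_MS",
    "make_attack_scenario",
    "simulate_received_levels",
    "make_ramp_playback",
    "simulate_moth_response",
    "track_positions_at",
]

#: The laboratory playback pulse intervals (ms).
RAMP_PULSE_INTERVALS_MS = (4.0, 7.0, 12.0, 20.0, 30.0, 45.0, 60.0, 80.0, 100.0)

FRAME_RATE_HZ = 60.0


@dataclass(frozen=True)
class ScenarioParams:
    """Study conditions for generated attacks."""

    detection_distance_range_m: tuple = (2.2, 4.5)
    speed_range_m_s: tuple = (2.0, 6.0)
    neighbor_offset_range_m: tuple = (0.5, 2.0)
    pass_miss_distance_range_m: tuple = (1.0, 4.0)
    focal_position_m: tuple = (0.0, 0.0, 3.0)
    mic_offset_m: tuple = (0.0, 0.0, 0.25)  # mic hangs just above the moth
    search_lead_s: float = 1.0  # search flight recorded before detection
    capture_distance_m: float = 0.1
    env: Environment = field(default_factory=Environment)
    beam: BeamModel = field(default_factory=BeamModel)
    sequence: SequenceParams = field(default_factory=SequenceParams)
    noise_db: float = 0.0  # measurement noise on recorded levels


@dataclass
class AttackScenario:
    """One complete synthetic field event."""

    threat_type: str  # 'real' | 'false' | 'pass'
    bat_track: RawTrack
    focal_moth: np.ndarray
    neighbor_moth: np.ndarray | None
    mic: MicrophoneModel
    env: Environment
    beam: BeamModel
    calls: list[Call]
    seed: int | None = None
    params: ScenarioParams | None = None

    @property
    def target_position(self) -> np.ndarray:
        if self.threat_type == "real":
            return self.focal_moth
        if self.threat_type == "false":
            return self.neighbor_moth
        raise ValueError("pass scenarios have no attack target")


def _straight_timeline(start, velocity, target, t_end) -> AttackTimeline:
    start = np.asarray(start, float)
    velocity = np.asarray(velocity, float)
    direction = velocity / np.linalg.norm(velocity)
    return AttackTimeline(
        bat_position=lambda t: start + velocity * t,
        flight_direction=lambda t: direction,
        target_position=np.asarray(target, float),
        t_start=0.0,
        t_end=t_end,
    )


def _random_unit(rng, max_elevation_deg=25.0) -> np.ndarray:
    """Random mostly-horizontal direction (bats approach near-level)."""
    az = rng.uniform(0, 2 * np.pi)
    el = np.radians(rng.uniform(-max_elevation_deg, max_elevation_deg))
    return np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])


def make_attack_scenario(
    threat_type: str,
    params: ScenarioParams | None = None,
    seed: int = 0,
) -> AttackScenario:
    """Generate one seeded attack scenario.

    Real threats converge on the focal moth to within the capture
    distance; false threats converge on a neighbor placed 0.5-2 m from
    the focal moth; passes transit the area in search phase only.
    Deterministic for a fixed seed.
    """
    if threat_type not in ("real", "false", "pass"):
        raise ValueError(f"unknown threat type {threat_type!r}")
    params = params or ScenarioParams()
    rng = np.random.default_rng(seed)
    focal = np.asarray(params.focal_position_m, float)
    mic_pos = focal + np.asarray(params.mic_offset_m, float)

    speed = rng.uniform(*params.speed_range_m_s)
    detect_d = rng.uniform(*params.detection_distance_range_m)
    approach_dir = _random_unit(rng)

    neighbor = None
    if threat_type == "false":
        offset = rng.uniform(*params.neighbor_offset_range_m)
        neighbor = focal + offset * _random_unit(rng)

    if threat_type == "pass":
        # straight transit whose closest point to the focal moth exceeds
        # the miss distance; the bat never detects the moth.
        miss = rng.uniform(*params.pass_miss_distance_range_m)
        closest = focal + miss * _random_unit(rng)
        direction = _random_unit(rng)
        direction -= np.dot(direction, (closest - focal) / miss) * (closest - focal) / miss
        direction /= np.linalg.norm(direction)
        half_span = speed * (params.search_lead_s + 1.5)
        start = closest - direction * half_span
        t_end = 2.0 * half_span / speed
        timeline = _straight_timeline(start, direction * speed, focal, t_end)
        detection = None
    else:
        target = focal if threat_type == "real" else neighbor
        start_dist = detect_d + speed * params.search_lead_s
        start = target + approach_dir * start_dist
        velocity = -approach_dir * speed
        t_end = (start_dist - params.capture_distance_m) / speed
        timeline = _straight_timeline(start, velocity, target, t_end)
        detection = detect_d

    calls = generate_call_sequence(
        params.sequence, timeline, detection, rng=rng, env=params.env
    )
    times = np.arange(0.0, timeline.t_end + 1.0 / FRAME_RATE_HZ / 2, 1.0 / FRAME_RATE_HZ)
    track = RawTrack(times=times, positions=np.array([timeline.bat_position(t) for t in times]))
    mic = default_microphone(position=mic_pos, axis=(0.0, 0.0, 1.0))
    return AttackScenario(
        threat_type=threat_type,
        bat_track=track,
        focal_moth=focal,
        neighbor_moth=neighbor,
        mic=mic,
        env=params.env,
        beam=params.beam,
        calls=calls,
        seed=seed,
        params=params,
    )


def track_positions_at(track: RawTrack, times) -> np.ndarray:
    """Linear interpolation of a raw track at arbitrary times.

    Shared by the forward model and the calibration inverse so both
    sides see identical geometry for the same bundle.
    """
    t = np.asarray(times, float)
    return np.stack(
        [np.interp(t, track.times, track.positions[:, j]) for j in range(3)], axis=-1
    )


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    return float(
        np.degrees(np.arccos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)))
    )


def simulate_received_levels(
    scn: AttackScenario,
    noise_db: float | None = None,
    seed: int | None = None,
    idealized_mic_beam: bool = False,
) -> pd.DataFrame:
    """Forward acoustic model: per-call levels at the mic and focal moth.

    For each call, the level at the microphone is
    ``SL + beam_gain(beam->mic angle) - TL(d_bat_mic)`` and the level at
    the focal moth is the analogue with the beam->moth angle; the
    recorded (voltage-domain) level additionally passes through the mic
    frequency response and directionality. Optional Gaussian measurement
    noise (dB) is added to the recorded level last, seeded.

    With ``idealized_mic_beam=True`` the mic-direction beam gain is set
    to exactly 3 dB below the moth-direction gain, the convention the
    calibration inverse compensates with its fixed +3 dB term; this is
    the configuration under which the inverse is an exact round trip.

    Calls whose emission time falls outside the track span are flagged
    (``valid=False``) and carry NaN levels.
    """
    noise = scn.params.noise_db if (noise_db is None and scn.params) else (noise_db or 0.0)
    rng = np.random.default_rng(seed)
    rows = []
    t0, t1 = scn.bat_track.times[0], scn.bat_track.times[-1]
    for call in scn.calls:
        t = call.emission_time_s
        if not t0 <= t <= t1:
            rows.append(
                dict(
                    time_s=t, phase=call.phase, valid=False,
                    recorded_level_db=np.nan, spl_at_mic_db=np.nan,
                    true_spl_at_moth_db=np.nan, true_source_level_toward_moth_db=np.nan,
                    d_bat_mic_m=np.nan, d_bat_moth_m=np.nan,
                    angle_batmoth_batmic_deg=np.nan, mic_offaxis_deg=np.nan,
                    pulse_interval_ms=call.pulse_interval_ms,
                    freq_khz=call.peak_frequency_khz, gain_control=call.gain_control,
                )
            )
            continue
        bat = track_positions_at(scn.bat_track, t)
        to_moth = scn.focal_moth - bat
        to_mic = scn.mic.position - bat
        d_moth = max(np.linalg.norm(to_moth), REFERENCE_DISTANCE_M)
        d_mic = max(np.linalg.norm(to_mic), REFERENCE_DISTANCE_M)
        g_moth = beam_gain(_angle_deg(call.beam_direction, to_moth), call.phase, scn.beam)
        if idealized_mic_beam:
            g_mic = g_moth - 3.0
        else:
            g_mic = beam_gain(_angle_deg(call.beam_direction, to_mic), call.phase, scn.beam)
        spl_mic = call.source_level_db + g_mic - transmission_loss(
            d_mic, call.peak_frequency_khz, scn.env
        )
        spl_moth = call.source_level_db + g_moth - transmission_loss(
            d_moth, call.peak_frequency_khz, scn.env
        )
        mic_offaxis = _angle_deg(scn.mic.axis, -to_mic)  # mic looks toward the bat side
        recorded = spl_mic + mic_sensitivity(
            call.peak_frequency_khz, mic_offaxis, scn.mic
        )
        if noise > 0:
            recorded += rng.normal(0.0, noise)
        rows.append(
            dict(
                time_s=t,
                phase=call.phase,
                valid=True,
                recorded_level_db=recorded,
                spl_at_mic_db=spl_mic,
                true_spl_at_moth_db=spl_moth,
                true_source_level_toward_moth_db=call.source_level_db + g_moth,
                d_bat_mic_m=d_mic,
                d_bat_moth_m=d_moth,
                angle_batmoth_batmic_deg=_angle_deg(to_moth, to_mic),
                mic_offaxis_deg=mic_offaxis,
                pulse_interval_ms=call.pulse_interval_ms,
                freq_khz=call.peak_frequency_khz,
                gain_control=call.gain_control,
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Laboratory ramp playbacks


@dataclass(frozen=True)
class RampStimulus:
    """A 10 s ramped pulse train: 2 ms pulses at 40 kHz, 5 dB/s ramp.

    Pulse k starts at ``k * PI`` and carries level ``70 + 5 t_k`` dB SPL;
    the ramp spans exactly 70-120 dB over the 10 s file.
    """

    pulse_interval_ms: float
    pulse_times_s: np.ndarray
    pulse_levels_db: np.ndarray
    duration_s: float = 10.0
    frequency_khz: float = 40.0
    pulse_duration_ms: float = 2.0
    rise_fall_ms: float = 0.5


def make_ramp_playback(pulse_interval_ms: float) -> RampStimulus:
    """Build the ramped playback for one of the nine supported PIs."""
    if float(pulse_interval_ms) not in RAMP_PULSE_INTERVALS_MS:
        raise ValueError(
            f"unsupported pulse interval {pulse_interval_ms} ms; "
            f"valid values: {RAMP_PULSE_INTERVALS_MS}"
        )
    times = np.arange(0.0, 10.0, pulse_interval_ms / 1000.0)
    levels = 70.0 + 5.0 * times
    return RampStimulus(
        pulse_interval_ms=float(pulse_interval_ms),
        pulse_times_s=times,
        pulse_levels_db=levels,
    )


@dataclass(frozen=True)
class MothResponseModel:
    """Clicking decision rule of a simulated moth.

    The moth clicks at the first pulse whose level meets its threshold
    for the ongoing pulse interval; optional per-trial Gaussian threshold
    noise and a fixed response latency.
    """

    threshold_curve: ThresholdCurve
    latency_ms: float = 0.0
    noise_sigma_db: float = 0.0

    def threshold(self, pi_ms: float) -> float:
        return self.threshold_curve(pi_ms)


def simulate_moth_response(
    stimulus_or_scenario,
    moth: MothResponseModel,
    seed: int | None = None,
    levels_at_moth: np.ndarray | None = None,
) -> float | None:
    """Time of the moth's first click, or None if it never clicks.

    For a :class:`RampStimulus` the threshold at the stimulus PI is
    compared against each pulse's level. For an :class:`AttackScenario`
    the per-call level at the focal moth (noise-free forward model by
    default, or ``levels_at_moth`` if given) is compared against the
    threshold at each call's pulse interval.
    """
    rng = np.random.default_rng(seed)

    def drawn(base: float) -> float:
        return base + (rng.normal(0.0, moth.noise_sigma_db) if moth.noise_sigma_db > 0 else 0.0)

    if isinstance(stimulus_or_scenario, RampStimulus):
        stim = stimulus_or_scenario
        thr = drawn(moth.threshold(stim.pulse_interval_ms))
        hits = stim.pulse_levels_db >= thr
        if not hits.any():
            return None
        return float(stim.pulse_times_s[hits][0] + moth.latency_ms / 1000.0)

    scn: AttackScenario = stimulus_or_scenario
    if levels_at_moth is None:
        levels_at_moth = simulate_received_levels(scn, noise_db=0.0)[
            "true_spl_at_moth_db"
        ].to_numpy()
    thr_noise = rng.normal(0.0, moth.noise_sigma_db) if moth.noise_sigma_db > 0 else 0.0
    for call, level in zip(scn.calls, levels_at_moth):
        if not np.isfinite(level):
            continue
        if level >= moth.threshold(call.pulse_interval_ms) + thr_noise:
            return float(call.emission_time_s + moth.latency_ms / 1000.0)
    return None
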