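"""Physical sound propagation and sensor models.

Everything downstream of a bat's larynx and upstream of a microphone's
voltage output lives here: spherical spreading, excess atmospheric
attenuation (ISO 9613-1 pure-tone form), the piecewise sonar-beam
directivity of *Myotis* calls, microphone frequency/directionality
corrections, and the volume of air ensonified above a given SPL.

Conventions
-----------
* All levels are dB peSPL re 20 uPa.
* Source levels are referenced to ``REFERENCE_DISTANCE_M`` (10 cm) from
  the bat's mouth.
* Atmospheric attenuation is accrued from the reference distance
  outward, ``alpha * (d - 0.1)``, consistent with the 10 cm source-level
  convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

__all__ = [
    "REFERENCE_DISTANCE_M",
    "Environment",
    "MicrophoneModel",
    "BeamModel",
    "default_microphone",
    "spreading_loss",
    "atmos_atten_coeff",
    "transmission_loss",
    "beam_gain",
    "mic_correction",
    "ensonified_volume",
]

#: Reference distance for source levels (meters).
REFERENCE_DISTANCE_M = 0.1

#: Ultrasonic band supported by the attenuation model and mic tables (kHz).
FREQ_BAND_KHZ = (20.0, 100.0)


@dataclass(frozen=True)
class Environment:
    """Ambient conditions governing atmospheric absorption.

    Parameters
    ----------
    temperature_C : float
        Air temperature in degrees Celsius, within [-10, 50].
    relative_humidity_pct : float
        Relative humidity in percent, within [0, 100].
    """

    temperature_C: float = 20.0
    relative_humidity_pct: float = 50.0

    def __post_init__(self) -> None:
        if not -10.0 <= self.temperature_C <= 50.0:
            raise ValueError(
                f"temperature_C={self.temperature_C} outside supported [-10, 50]"
            )
        if not 0.0 <= self.relative_humidity_pct <= 100.0:
            raise ValueError(
                f"relative_humidity_pct={self.relative_humidity_pct} outside [0, 100]"
            )


def spreading_loss(distance_m: float, reference_m: float = REFERENCE_DISTANCE_M) -> float:
    """Spherical-spreading loss in dB between two distances.

    Returns ``20 log10(distance / reference)``; additive over chained
    distances, zero at the reference.
    """
    d = np.asarray(distance_m, dtype=float)
    r = np.asarray(reference_m, dtype=float)
    if np.any(d <= 0) or np.any(r <= 0):
        raise ValueError("distances must be positive")
    out = 20.0 * np.log10(d / r)
    return float(out) if out.ndim == 0 else out


def atmos_atten_coeff(frequency_khz: float, env: Environment) -> float:
    """Pure-tone atmospheric absorption coefficient in dB/m (ISO 9613-1).

    Valid for the ultrasonic band used by the bats in this system
    (20-100 kHz). Standard atmospheric pressure is assumed; the field
    site corrections of a few percent for altitude are far below the
    +-1-3 dB beam-direction uncertainty of the calibration chain.
    """
    f_khz = np.asarray(frequency_khz, dtype=float)
    if np.any(f_khz < FREQ_BAND_KHZ[0]) or np.any(f_khz > FREQ_BAND_KHZ[1]):
        raise ValueError(
            f"frequency {frequency_khz} kHz outside supported band {FREQ_BAND_KHZ}"
        )
    f = f_khz * 1e3  # Hz
    T = env.temperature_C + 273.15
    T0 = 293.15
    T01 = 273.16
    pa = pr = 101.325  # kPa

    psat_over_pr = 10.0 ** (-6.8346 * (T01 / T) ** 1.261 + 4.6151)
    h = env.relative_humidity_pct * psat_over_pr / (pa / pr)  # molar conc. %

    fr_o = (pa / pr) * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    fr_n = (
        (pa / pr)
        * (T / T0) ** -0.5
        * (9.0 + 280.0 * h * np.exp(-4.170 * ((T / T0) ** (-1.0 / 3.0) - 1.0)))
    )
    alpha = (
        8.686
        * f**2
        * (
            1.84e-11 * (pr / pa) * (T / T0) ** 0.5
            + (T / T0) ** -2.5
            * (
                0.01275 * np.exp(-2239.1 / T) / (fr_o + f**2 / fr_o)
                + 0.1068 * np.exp(-3352.0 / T) / (fr_n + f**2 / fr_n)
            )
        )
    )
    return float(alpha) if np.ndim(alpha) == 0 else alpha


def transmission_loss(distance_m: float, frequency_khz: float, env: Environment) -> float:
    """One-way transmission loss from the 10 cm reference distance, dB.

    Spherical spreading plus excess atmospheric attenuation accrued from
    the reference distance: ``20 log10(d/0.1) + alpha (d - 0.1)``.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < REFERENCE_DISTANCE_M):
        raise ValueError(
            f"distance {distance_m} m below reference {REFERENCE_DISTANCE_M} m"
        )
    alpha = atmos_atten_coeff(frequency_khz, env)
    out = spreading_loss(d, REFERENCE_DISTANCE_M) + alpha * (d - REFERENCE_DISTANCE_M)
    return float(out) if np.ndim(out) == 0 else out


# --------------------------------------------------------------------------
# Sonar beam


@dataclass(frozen=True)
class BeamModel:
    """Phase-dependent *Myotis* sonar-beam directivity.

    Search and approach calls have a -6 dB full width of 80 deg (half
    width 40 deg); buzz calls broaden to 180 deg (half width 90 deg).
    Between the two anchors the falloff is parabolic in dB,
    ``gain(theta) = -6 (theta / theta_half)^2``, floored at ``floor_db``.
    """

    halfwidth_search_approach_deg: float = 40.0
    halfwidth_buzz_deg: float = 90.0
    floor_db: float = -40.0

    def halfwidth(self, phase: str) -> float:
        if phase == "buzz":
            return self.halfwidth_buzz_deg
        if phase in ("search", "approach"):
            return self.halfwidth_search_approach_deg
        raise ValueError(f"unknown echolocation phase {phase!r}")


def beam_gain(off_axis_deg: float, phase: str, beam: BeamModel | None = None) -> float:
    """Directivity gain (dB, <= 0) of a call at an off-axis angle.

    0 dB on axis, -6 dB at the phase's half width, monotone
    non-increasing, floored at ``beam.floor_db``.
    """
    beam = beam or BeamModel()
    theta = np.asarray(off_axis_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > 180):
        raise ValueError("off-axis angle must lie in [0, 180] degrees")
    g = np.maximum(-6.0 * (theta / beam.halfwidth(phase)) ** 2, beam.floor_db)
    return float(g) if g.ndim == 0 else g


# --------------------------------------------------------------------------
# Microphone


@dataclass(frozen=True)
class MicrophoneModel:
    """Sensitivity model of the miniature field microphone.

    ``freq_response`` holds the mic's gain (dB re the reference mic) at
    5 kHz steps over 20-100 kHz: negative values mean the mic under-reads
    and the correction to recover true SPL is the sign-flipped gain.
    ``directionality`` holds off-axis gain on a (frequency x angle) grid,
    22.5 deg steps over [0, 180] deg at 20-60 kHz.
    """

    freq_khz: np.ndarray
    freq_gain_db: np.ndarray
    dir_freq_khz: np.ndarray
    dir_angle_deg: np.ndarray
    dir_gain_db: np.ndarray  # shape (n_freq, n_angle)
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_khz", np.asarray(self.freq_khz, float))
        object.__setattr__(self, "freq_gain_db", np.asarray(self.freq_gain_db, float))
        object.__setattr__(self, "dir_freq_khz", np.asarray(self.dir_freq_khz, float))
        object.__setattr__(self, "dir_angle_deg", np.asarray(self.dir_angle_deg, float))
        object.__setattr__(self, "dir_gain_db", np.asarray(self.dir_gain_db, float))
        object.__setattr__(self, "position", np.asarray(self.position, float))
        ax = np.asarray(self.axis, float)
        object.__setattr__(self, "axis", ax / np.linalg.norm(ax))
        if not np.allclose(self.dir_gain_db[:, 0], 0.0):
            raise ValueError("directionality gain must be 0 dB on axis (0 deg)")

    def replace(self, **kw) -> "MicrophoneModel":
        from dataclasses import replace

        return replace(self, **kw)


def default_microphone(
    position=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0)
) -> MicrophoneModel:
    """Default sensitivity tables emulating the field microphone.

    Flat (0 dB) from 20-40 kHz, then sensitivity falling 5 dB per
    10 kHz up to 100 kHz. Directionality is mild (within +-4 dB), a
    parabolic-in-angle rolloff deepening with frequency from 2 dB at
    20 kHz to 4 dB at 60 kHz at the rear.
    """
    freq = np.arange(20.0, 105.0, 5.0)
    gain = np.where(freq <= 40.0, 0.0, -0.5 * (freq - 40.0))
    dfreq = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
    angles = np.arange(0.0, 202.5, 22.5)
    depth = 2.0 + 2.0 * (dfreq - 20.0) / 40.0  # 2 -> 4 dB rear dip
    dgain = -depth[:, None] * (angles[None, :] / 180.0) ** 2
    return MicrophoneModel(
        freq_khz=freq,
        freq_gain_db=gain,
        dir_freq_khz=dfreq,
        dir_angle_deg=angles,
        dir_gain_db=dgain,
        position=np.asarray(position, float),
        axis=np.asarray(axis, float),
    )


def mic_sensitivity(
    frequency_khz: float, off_axis_deg: float, mic: MicrophoneModel
) -> float:
    """Total mic gain (dB) applied to an arriving call by the sensor.

    The forward counterpart of :func:`mic_correction`: a recorded level
    equals true SPL at the mic plus this gain.
    """
    f = float(frequency_khz)
    if not mic.freq_khz[0] <= f <= mic.freq_khz[-1]:
        raise ValueError(
            f"frequency {f} kHz outside mic table range "
            f"[{mic.freq_khz[0]}, {mic.freq_khz[-1]}]"
        )
    a = float(off_axis_deg)
    if not 0.0 <= a <= 180.0:
        raise ValueError("off-axis angle must lie in [0, 180] degrees")
    fgain = np.interp(f, mic.freq_khz, mic.freq_gain_db)
    # directionality table only spans 20-60 kHz; clamp frequency to its edge
    fd = min(max(f, mic.dir_freq_khz[0]), mic.dir_freq_khz[-1])
    interp = getattr(mic, "_dir_interp", None)
    if interp is None:
        interp = RegularGridInterpolator(
            (mic.dir_freq_khz, mic.dir_angle_deg), mic.dir_gain_db, method="linear"
        )
        object.__setattr__(mic, "_dir_interp", interp)
    dgain = float(interp([[fd, a]])[0])
    return float(fgain + dgain)


def mic_correction(
    frequency_khz: float, off_axis_deg: float, mic: MicrophoneModel
) -> float:
    """dB correction to add to a recorded level to obtain true SPL at the mic.

    Bilinear interpolation between table nodes in frequency and angle.
    A mic that under-reads by 10 dB at 60 kHz yields a +10 dB correction.
    """
    return -mic_sensitivity(frequency_khz, off_axis_deg, mic)


# --------------------------------------------------------------------------
# Ensonified volume


def ensonified_volume(
    source_level_db: float,
    beam: BeamModel,
    phase: str,
    threshold_db: float,
    frequency_khz: float,
    env: Environment,
    n_theta: int = 181,
) -> float:
    """Volume of air (m^3) receiving at least ``threshold_db`` from one call.

    Assumes azimuthal symmetry about the beam axis; for each polar angle
    the range at which ``SL + beam_gain - transmission_loss`` crosses the
    threshold is found by bracketed root search, and the solid-angle
    integral of ``r^3 / 3`` is evaluated by Simpson quadrature.
    """
    if source_level_db <= threshold_db:
        return 0.0
    alpha = atmos_atten_coeff(frequency_khz, env)
    thetas = np.linspace(0.0, 180.0, n_theta)
    gains = beam_gain(thetas, phase, beam)

    def excess(r: float, g: float) -> float:
        tl = 20.0 * np.log10(r / REFERENCE_DISTANCE_M) + alpha * (r - REFERENCE_DISTANCE_M)
        return source_level_db + g - tl - threshold_db

    radii = np.empty_like(thetas)
    for i, g in enumerate(gains):
        lo = 1e-6
        hi = 1.0
        while excess(hi, g) > 0:
            hi *= 2.0
        radii[i] = brentq(excess, lo, hi, args=(g,), xtol=1e-10, rtol=1e-12)
    integrand = (radii**3 / 3.0) * 2.0 * np.pi * np.sin(np.radians(thetas))
    return float(simpson(integrand, x=np.radians(thetas)))
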