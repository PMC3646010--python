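"""Audio-calibration inverse: recorded mic levels -> source levels & levels at the moth.

The correction chain reverses the field recording path. For each call:

1. undo the microphone frequency response and directionality to get the
   true SPL at the microphone;
2. add the one-way transmission loss (spherical spreading from the 10 cm
   reference plus excess atmospheric attenuation) over the bat-mic
   distance, plus a fixed +3 dB compensating the average difference
   between the beam gain toward the mic and toward the moth, giving the
   source level at 10 cm in the moth's direction;
3. subtract the transmission loss over the bat-moth distance to get the
   level arriving at the moth.

Per-event features (clicking intensity/PI readouts), attack alignment
and centered trend fits for attack-aligned intensity and angle series
live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acoustics import Environment, MicrophoneModel, mic_correction, transmission_loss
from .echolocation import classify_phase
from .synth import AttackScenario, track_positions_at

__all__ = [
    "BEAM_DIRECTION_COMPENSATION_DB",
    "TrendFit",
    "estimate_spl_at_mic",
    "estimate_source_level",
    "estimate_spl_at_moth",
    "calibrate_scenario",
    "click_event_features",
    "align_attacks",
    "fit_trend",
]

#: Fixed compensation for the beam pointing at the moth rather than the
#: mic; applied exactly once, inside estimate_source_level.
BEAM_DIRECTION_COMPENSATION_DB = 3.0


def estimate_spl_at_mic(
    recorded_level_db: float,
    frequency_khz: float,
    mic_offaxis_deg: float,
    mic: MicrophoneModel,
) -> float:
    """True SPL at the microphone from the recorded (voltage-domain) level."""
    return recorded_level_db + mic_correction(frequency_khz, mic_offaxis_deg, mic)


def estimate_source_level(
    spl_at_mic_db: float,
    d_bat_mic_m: float,
    frequency_khz: float,
    env: Environment,
) -> float:
    """Source level at 10 cm, emitted in the moth's direction (dB peSPL).

    ``spl_at_mic + TL(d_bat_mic) + 3 dB``; the +3 dB is the fixed
    beam-direction compensation. This is the emission toward the moth,
    not necessarily the bat's on-axis maximum.
    """
    return (
        spl_at_mic_db
        + transmission_loss(d_bat_mic_m, frequency_khz, env)
        + BEAM_DIRECTION_COMPENSATION_DB
    )


def estimate_spl_at_moth(
    source_level_10cm_db: float,
    d_bat_moth_m: float,
    frequency_khz: float,
    env: Environment,
) -> float:
    """Level arriving at the moth from the moth-direction source level."""
    return source_level_10cm_db - transmission_loss(d_bat_moth_m, frequency_khz, env)


def calibrate_scenario(
    scn: AttackScenario, recorded: pd.DataFrame
) -> pd.DataFrame:
    """Run the full inverse chain over one scenario's recorded calls.

    ``recorded`` needs columns ``time_s``, ``recorded_level_db`` and
    ``freq_khz`` (the forward model's output qualifies). Geometry
    (distances, bat-moth/bat-mic angle, mic off-axis angle) is derived
    from the scenario's bat track by the same linear interpolation the
    forward model uses. Calls outside the track span are flagged invalid
    and excluded from the estimates.
    """
    t0, t1 = scn.bat_track.times[0], scn.bat_track.times[-1]
    out = recorded.copy()
    n = len(out)
    for col in (
        "spl_at_mic_db",
        "source_level_10cm_db",
        "spl_at_moth_db",
        "d_bat_mic_m",
        "d_bat_moth_m",
        "angle_batmoth_batmic_deg",
        "mic_offaxis_deg",
    ):
        out[col] = np.full(n, np.nan)
    out["valid"] = (out["time_s"] >= t0) & (out["time_s"] <= t1) & np.isfinite(
        out["recorded_level_db"]
    )
    for i, row in out.iterrows():
        if not row["valid"]:
            continue
        bat = track_positions_at(scn.bat_track, row["time_s"])
        to_moth = scn.focal_moth - bat
        to_mic = scn.mic.position - bat
        d_moth = max(float(np.linalg.norm(to_moth)), 0.1)
        d_mic = max(float(np.linalg.norm(to_mic)), 0.1)
        cosang = np.dot(to_moth, to_mic) / (
            np.linalg.norm(to_moth) * np.linalg.norm(to_mic)
        )
        mic_off = np.degrees(
            np.arccos(
                np.clip(
                    np.dot(scn.mic.axis, -to_mic) / np.linalg.norm(to_mic), -1.0, 1.0
                )
            )
        )
        f = float(row["freq_khz"])
        spl_mic = estimate_spl_at_mic(row["recorded_level_db"], f, mic_off, scn.mic)
        sl = estimate_source_level(spl_mic, d_mic, f, scn.env)
        spl_moth = estimate_spl_at_moth(sl, d_moth, f, scn.env)
        out.loc[i, "spl_at_mic_db"] = spl_mic
        out.loc[i, "source_level_10cm_db"] = sl
        out.loc[i, "spl_at_moth_db"] = spl_moth
        out.loc[i, "d_bat_mic_m"] = d_mic
        out.loc[i, "d_bat_moth_m"] = d_moth
        out.loc[i, "angle_batmoth_batmic_deg"] = float(
            np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        )
        out.loc[i, "mic_offaxis_deg"] = mic_off
    # phase from the measured start-to-start pulse interval
    times = out["time_s"].to_numpy()
    pis = np.full(n, np.nan)
    if n > 1:
        pis[:-1] = np.diff(times) * 1000.0
        pis[-1] = pis[-2] if n > 1 else np.nan
    out["measured_pi_ms"] = pis
    out["phase_from_pi"] = [
        classify_phase(p) if np.isfinite(p) and p > 0 else "unknown" for p in pis
    ]
    return out


# --------------------------------------------------------------------------
# Event features and trends


def click_event_features(
    times_s, levels_at_moth_db, click_time_s: float | None = None
) -> tuple[float, float, bool]:
    """Per-event (intensity dB, pulse interval ms) readout.

    Clicked events: the mean level of the two calls preceding the click
    and their start-to-start interval. Non-clicked events: the mean of
    the most intense call and its two neighbors, and the mean of the two
    adjacent intervals; when the most intense call is first or last the
    available neighbor is used and the event flagged.

    Returns ``(intensity_db, pulse_interval_ms, edge_flag)``.
    """
    t = np.asarray(times_s, float)
    lv = np.asarray(levels_at_moth_db, float)
    if t.shape != lv.shape or t.ndim != 1:
        raise ValueError("times and levels must be 1-D and equal length")
    if click_time_s is not None:
        idx = np.nonzero(t < click_time_s)[0]
        if idx.size < 2:
            raise ValueError("need at least 2 calls before the click")
        i, j = idx[-2], idx[-1]
        return float(np.mean(lv[[i, j]])), float((t[j] - t[i]) * 1000.0), False
    if t.size < 3:
        raise ValueError("need at least 3 calls for a non-clicked event")
    k = int(np.nanargmax(lv))
    flag = k == 0 or k == t.size - 1
    nbrs = [i for i in (k - 1, k, k + 1) if 0 <= i < t.size]
    intensity = float(np.mean(lv[nbrs]))
    intervals = [(t[i + 1] - t[i]) * 1000.0 for i in range(min(nbrs), max(nbrs))]
    return intensity, float(np.mean(intervals)), flag


def align_attacks(attacks: list[pd.DataFrame], mode: str = "end") -> list[pd.DataFrame]:
    """Shift each attack's time axis so t = 0 at the chosen anchor call.

    ``mode='end'`` anchors at the last call; ``mode='max_intensity'`` at
    the call of maximum source level (earliest such call on ties).
    Inter-call intervals are preserved exactly.
    """
    if mode not in ("end", "max_intensity"):
        raise ValueError("mode must be 'end' or 'max_intensity'")
    out = []
    for df in attacks:
        if len(df) == 0:
            raise ValueError("attacks must be non-empty")
        if mode == "end":
            t0 = df["time_s"].iloc[-1]
        else:
            col = (
                "source_level_10cm_db"
                if "source_level_10cm_db" in df
                else "source_level_db"
            )
            t0 = df["time_s"].iloc[int(np.nanargmax(df[col].to_numpy()))]
        shifted = df.copy()
        shifted["time_s"] = shifted["time_s"] - t0
        out.append(shifted)
    return out


@dataclass(frozen=True)
class TrendFit:
    """Within-attack centered least-squares trend fit."""

    b_time: float  # dB/s or deg/s
    b_time2: float  # dB/s^2 or deg/s^2 (0 for linear fits)
    offsets: dict  # per-attack mean of the response
    r_squared: float
    n_calls: int


def fit_trend(
    aligned: list[pd.DataFrame],
    response: str,
    quadratic: bool = True,
    time_col: str = "time_s",
) -> TrendFit:
    """Pooled trend of a response against (aligned) time across attacks.

    Two-stage, within-attack centered least squares: response and
    regressors are demeaned per attack, then pooled OLS on (time,
    time^2). This is the fixed-effects (within) estimator of the
    corresponding random-intercept model.
    """
    ys, xs, x2s, offsets = [], [], [], {}
    for k, df in enumerate(aligned):
        sub = df[np.isfinite(df[response].to_numpy())]
        if quadratic and len(sub) < 3:
            raise ValueError("need >= 3 points per attack for a quadratic fit")
        if len(sub) < 2:
            raise ValueError("need >= 2 points per attack")
        t = sub[time_col].to_numpy()
        y = sub[response].to_numpy()
        offsets[k] = float(np.mean(y))
        ys.append(y - y.mean())
        xs.append(t - t.mean())
        x2s.append(t**2 - np.mean(t**2))
    y = np.concatenate(ys)
    cols = [np.concatenate(xs)]
    if quadratic:
        cols.append(np.concatenate(x2s))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum(y**2))
    r2 = 0.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
    b1 = float(beta[0])
    b2 = float(beta[1]) if quadratic else 0.0
    if tss == 0:
        b1, b2 = 0.0, 0.0
    return TrendFit(
        b_time=b1, b_time2=b2, offsets=offsets, r_squared=max(r2, 0.0), n_calls=y.size
    )
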