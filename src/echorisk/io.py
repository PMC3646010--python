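"""Scenario-bundle file schemas, run configuration, and the end-to-end pipeline.

A scenario bundle is a directory of plain text::

    calls.csv    # one row per emission: time_s, freq_khz, duration_ms,
                 # source_level_db, beam_dx, beam_dy, beam_dz, phase (+extras)
    tracks.csv   # time_s, object_id, x_m, y_m, z_m  (bat frames + static markers)
    meta.json    # seed, threat type, environment, mic tables, parameter echo

All numeric columns carry SI-ish field units (m, s, dB, kHz), stated on
a leading ``# units:`` comment line in each CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time as _time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .acoustics import BeamModel, Environment, MicrophoneModel, default_microphone
from .calibration import calibrate_scenario, fit_trend, align_attacks
from .echolocation import Call, SequenceParams
from .kinematics import RawTrack
from .synth import (
    RAMP_PULSE_INTERVALS_MS,
    AttackScenario,
    MothResponseModel,
    ScenarioParams,
    make_attack_scenario,
    make_ramp_playback,
    simulate_moth_response,
    simulate_received_levels,
)
from .threat import (
    ThresholdCurve,
    auc_real_vs_false,
    extract_threshold_from_ramp,
    fit_discrimination,
    intensities_by_phase,
    threshold_curve_from_model,
)

__all__ = [
    "RunConfig",
    "write_scenario_bundle",
    "read_scenario_bundle",
    "run_pipeline",
]

log = logging.getLogger("echorisk")

_CALL_COLUMNS = [
    "time_s",
    "freq_khz",
    "duration_ms",
    "source_level_db",
    "beam_dx",
    "beam_dy",
    "beam_dz",
    "phase",
]
_TRACK_COLUMNS = ["time_s", "object_id", "x_m", "y_m", "z_m"]


def _write_csv(df: pd.DataFrame, path: str, units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: str, required: list[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"bundle file missing: {path}")
    df = pd.read_csv(path, comment="#")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{os.path.basename(path)}: missing column {col!r}")
    return df


def write_scenario_bundle(scn: AttackScenario, path: str) -> None:
    """Write one scenario as a calls.csv / tracks.csv / meta.json directory."""
    os.makedirs(path, exist_ok=True)
    calls = pd.DataFrame(
        {
            "time_s": [c.emission_time_s for c in scn.calls],
            "freq_khz": [c.peak_frequency_khz for c in scn.calls],
            "duration_ms": [c.duration_ms for c in scn.calls],
            "source_level_db": [c.source_level_db for c in scn.calls],
            "beam_dx": [c.beam_direction[0] for c in scn.calls],
            "beam_dy": [c.beam_direction[1] for c in scn.calls],
            "beam_dz": [c.beam_direction[2] for c in scn.calls],
            "phase": [c.phase for c in scn.calls],
            "pulse_interval_ms": [c.pulse_interval_ms for c in scn.calls],
            "gain_control": [c.gain_control for c in scn.calls],
        }
    )
    _write_csv(calls, os.path.join(path, "calls.csv"), "s, kHz, ms, dB peSPL re 20 uPa at 0.1 m, unit vector, -, ms, -")
    rows = [
        {
            "time_s": t,
            "object_id": "bat",
            "x_m": p[0],
            "y_m": p[1],
            "z_m": p[2],
        }
        for t, p in zip(scn.bat_track.times, scn.bat_track.positions)
    ]
    statics = {"focal_moth": scn.focal_moth, "mic": scn.mic.position}
    if scn.neighbor_moth is not None:
        statics["neighbor_moth"] = scn.neighbor_moth
    for name, p in statics.items():
        rows.append(
            {"time_s": 0.0, "object_id": name, "x_m": p[0], "y_m": p[1], "z_m": p[2]}
        )
    _write_csv(pd.DataFrame(rows), os.path.join(path, "tracks.csv"), "s, -, m, m, m")
    meta = {
        "seed": scn.seed,
        "threat_type": scn.threat_type,
        "env": {
            "temperature_C": scn.env.temperature_C,
            "relative_humidity_pct": scn.env.relative_humidity_pct,
        },
        "beam": asdict(scn.beam),
        "mic": {
            "axis": list(map(float, scn.mic.axis)),
            "freq_khz": scn.mic.freq_khz.tolist(),
            "freq_gain_db": scn.mic.freq_gain_db.tolist(),
            "dir_freq_khz": scn.mic.dir_freq_khz.tolist(),
            "dir_angle_deg": scn.mic.dir_angle_deg.tolist(),
            "dir_gain_db": scn.mic.dir_gain_db.tolist(),
        },
        "units": {"positions": "m", "times": "s", "levels": "dB peSPL re 20 uPa"},
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_scenario_bundle(path: str) -> AttackScenario:
    """Read a scenario bundle back into an :class:`AttackScenario`.

    Validates the schema (named errors for missing files/columns); extra
    unknown columns in calls.csv are preserved on ``scn.call_extras``.
    """
    calls_df = _read_csv(os.path.join(path, "calls.csv"), _CALL_COLUMNS)
    tracks = _read_csv(os.path.join(path, "tracks.csv"), _TRACK_COLUMNS)
    meta_path = os.path.join(path, "meta.json")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"bundle file missing: {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)

    bat = tracks[tracks["object_id"] == "bat"]
    if len(bat) == 0:
        raise ValueError("tracks.csv: no rows with object_id == 'bat'")

    def _static(name):
        sub = tracks[tracks["object_id"] == name]
        if len(sub) == 0:
            return None
        return sub[["x_m", "y_m", "z_m"]].to_numpy()[0]

    focal = _static("focal_moth")
    if focal is None:
        raise ValueError("tracks.csv: missing object_id 'focal_moth'")
    mic_pos = _static("mic")
    m = meta["mic"]
    mic = MicrophoneModel(
        freq_khz=m["freq_khz"],
        freq_gain_db=m["freq_gain_db"],
        dir_freq_khz=m["dir_freq_khz"],
        dir_angle_deg=m["dir_angle_deg"],
        dir_gain_db=m["dir_gain_db"],
        position=mic_pos if mic_pos is not None else np.zeros(3),
        axis=m["axis"],
    )
    if "pulse_interval_ms" not in calls_df.columns:
        pis = np.diff(calls_df["time_s"].to_numpy()) * 1000.0
        calls_df = calls_df.assign(
            pulse_interval_ms=np.append(pis, pis[-1] if len(pis) else np.nan)
        )
    if "gain_control" not in calls_df.columns:
        calls_df = calls_df.assign(gain_control=False)
    calls = [
        Call(
            emission_time_s=r.time_s,
            source_level_db=r.source_level_db,
            beam_direction=np.array([r.beam_dx, r.beam_dy, r.beam_dz]),
            phase=r.phase,
            pulse_interval_ms=r.pulse_interval_ms,
            peak_frequency_khz=r.freq_khz,
            duration_ms=r.duration_ms,
            gain_control=bool(r.gain_control),
        )
        for r in calls_df.itertuples()
    ]
    scn = AttackScenario(
        threat_type=meta["threat_type"],
        bat_track=RawTrack(
            times=bat["time_s"].to_numpy(), positions=bat[["x_m", "y_m", "z_m"]].to_numpy()
        ),
        focal_moth=np.asarray(focal, float),
        neighbor_moth=None if _static("neighbor_moth") is None else np.asarray(_static("neighbor_moth"), float),
        mic=mic,
        env=Environment(**meta["env"]),
        beam=BeamModel(**meta["beam"]),
        calls=calls,
        seed=meta.get("seed"),
    )
    known = set(_CALL_COLUMNS) | {"pulse_interval_ms", "gain_control"}
    extras = [c for c in calls_df.columns if c not in known]
    scn.call_extras = calls_df[extras] if extras else None
    return scn


# --------------------------------------------------------------------------
# End-to-end pipeline


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one reproducible run."""

    seed: int = 0
    n_real: int = 5
    n_false: int = 9
    noise_db: float = 0.0
    temperature_C: float = 20.0
    relative_humidity_pct: float = 50.0
    gain_setpoint_db: float = 95.3
    pi_grid_ms: tuple = RAMP_PULSE_INTERVALS_MS
    out_dir: str = "echorisk_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pi_grid_ms"] = list(self.pi_grid_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "pi_grid_ms" in d:
            d["pi_grid_ms"] = tuple(d["pi_grid_ms"])
        return cls(**d)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = _time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
            log.info("stage %s: %.2f s", name, _time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("simulate")
def _simulate(config: RunConfig):
    env = Environment(config.temperature_C, config.relative_humidity_pct)
    params = ScenarioParams(
        env=env,
        sequence=SequenceParams(gain_setpoint_db=config.gain_setpoint_db),
        noise_db=config.noise_db,
    )
    seeds = _child_seeds(config.seed, config.n_real + config.n_false)
    scns = [
        make_attack_scenario("real", params, s) for s in seeds[: config.n_real]
    ] + [make_attack_scenario("false", params, s) for s in seeds[config.n_real :]]
    return scns


@_stage("calibrate")
def _calibrate(config: RunConfig, scns):
    dfs = []
    noise_seeds = _child_seeds(config.seed + 1, len(scns))
    for k, (scn, s) in enumerate(zip(scns, noise_seeds)):
        fwd = simulate_received_levels(scn, noise_db=config.noise_db, seed=s)
        cal = calibrate_scenario(scn, fwd)
        cal.insert(0, "attack_id", k)
        cal.insert(1, "threat_type", scn.threat_type)
        dfs.append(cal)
    return dfs


@_stage("analyze")
def _analyze(config: RunConfig, calibrated):
    pooled = pd.concat(calibrated, ignore_index=True)
    ok = pooled[
        pooled["valid"]
        & np.isfinite(pooled["spl_at_moth_db"])
        & (pooled["measured_pi_ms"] > 0)
    ]
    feats = lambda df: np.column_stack(  # noqa: E731
        [np.log10(df["measured_pi_ms"]), df["spl_at_moth_db"]]
    )
    model = fit_discrimination(
        feats(ok[ok["threat_type"] == "real"]), feats(ok[ok["threat_type"] == "false"])
    )
    grid = np.asarray(config.pi_grid_ms, float)
    curves = {
        p: threshold_curve_from_model(model, p, grid) for p in (0.5, 0.75)
    }
    # ROC per phase on estimated level at the moth
    roc = {}
    by_phase_r = intensities_by_phase(
        ok[ok["threat_type"] == "real"]["measured_pi_ms"],
        ok[ok["threat_type"] == "real"]["spl_at_moth_db"],
    )
    by_phase_f = intensities_by_phase(
        ok[ok["threat_type"] == "false"]["measured_pi_ms"],
        ok[ok["threat_type"] == "false"]["spl_at_moth_db"],
    )
    for phase in ("search", "approach", "buzz"):
        r, f = by_phase_r[phase], by_phase_f[phase]
        if r.size and f.size:
            res = auc_real_vs_false(r, f)
            roc[phase] = {"aur": res.aur, "n_real": res.n_real, "n_false": res.n_false}
    # ramp arm: a moth whose true thresholds equal the p=0.75 curve
    ramp_rows = []
    if len(curves[0.75].pi_ms) >= 2:
        moth = MothResponseModel(threshold_curve=curves[0.75])
        for pi in RAMP_PULSE_INTERVALS_MS:
            stim = make_ramp_playback(pi)
            t_click = simulate_moth_response(stim, moth)
            try:
                thr = extract_threshold_from_ramp(stim, t_click)
            except ValueError:
                thr = None
            ramp_rows.append(
                {
                    "pi_ms": pi,
                    "threshold_db": np.nan if thr is None else thr,
                    "source": "ramp_measured",
                }
            )
    return pooled, model, curves, roc, ramp_rows


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> calibrate -> analyze; write all artifacts; return the report.

    Identical config and seed give identical outputs (report.json is
    byte-identical across runs).
    """
    scns = _simulate(config)
    calibrated = _calibrate(config, scns)
    pooled, model, curves, roc, ramp_rows = _analyze(config, calibrated)

    # trend characterization
    real = [df for df in calibrated if df["threat_type"].iloc[0] == "real"]
    false = [df for df in calibrated if df["threat_type"].iloc[0] == "false"]
    trends = {}
    t_real_end = fit_trend(align_attacks(real, "end"), "spl_at_moth_db", quadratic=True)
    t_false_end = fit_trend(align_attacks(false, "end"), "spl_at_moth_db", quadratic=False)
    aligned_max = align_attacks(real, "max_intensity")
    pre = [df[df["time_s"] <= 0] for df in aligned_max]
    post = [df[df["time_s"] >= 0] for df in aligned_max]
    t_loc = fit_trend(pre, "source_level_10cm_db", quadratic=False)
    t_gc = fit_trend(post, "source_level_10cm_db", quadratic=False)
    for name, tr in [
        ("real_level_at_moth_end_aligned", t_real_end),
        ("false_level_at_moth_end_aligned", t_false_end),
        ("real_source_level_localization", t_loc),
        ("real_source_level_gain_control", t_gc),
    ]:
        trends[name] = {
            "b_time": tr.b_time,
            "b_time2": tr.b_time2,
            "r_squared": tr.r_squared,
            "n_calls": tr.n_calls,
        }
    gc = pooled[pooled["gain_control"] & pooled["valid"]]
    mean_gc_level = float(gc["spl_at_moth_db"].mean()) if len(gc) else float("nan")

    cfg = config.to_dict()
    cfg.pop("out_dir")  # where results land is not part of what was computed
    run_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    report = {
        "config": cfg,
        "run_hash": run_hash,
        "roc": roc,
        "trends": trends,
        "mean_gain_control_level_at_moth_db": round(mean_gc_level, 6),
        "n_calls_total": int(len(pooled)),
    }

    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    _write_csv(
        pooled.round(9), os.path.join(out, "received_levels.csv"),
        "s, dB peSPL re 20 uPa, m, deg, ms",
    )
    thr_rows = [
        {"pi_ms": pi, "threshold_db": th, "source": f"model_p{int(p*100)}"}
        for p in (0.5, 0.75)
        for pi, th in zip(curves[p].pi_ms, curves[p].threshold_db)
    ] + ramp_rows
    _write_csv(
        pd.DataFrame(thr_rows).round(9), os.path.join(out, "thresholds.csv"),
        "ms, dB peSPL re 20 uPa, -",
    )
    with open(os.path.join(out, "model.json"), "w") as fh:
        json.dump(
            {
                "mean_real": model.mean_real.round(9).tolist(),
                "cov_real": model.cov_real.round(9).tolist(),
                "mean_false": model.mean_false.round(9).tolist(),
                "cov_false": model.cov_false.round(9).tolist(),
                "prior_real": model.prior_real,
                "features": ["log10_pulse_interval_ms", "spl_at_moth_db"],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    with open(os.path.join(out, "roc.json"), "w") as fh:
        json.dump(roc, fh, indent=1, sort_keys=True)
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
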