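"""Calibration inverse, event features, alignment and trend fits."""

import numpy as np
import pandas as pd
import pytest

from echorisk.acoustics import Environment, atmos_atten_coeff, default_microphone, transmission_loss
from echorisk.calibration import (
    align_attacks,
    calibrate_scenario,
    click_event_features,
    estimate_source_level,
    estimate_spl_at_mic,
    estimate_spl_at_moth,
    fit_trend,
)
from echorisk.synth import make_attack_scenario, simulate_received_levels


class TestInverseChain:
    def test_zero_correction_table_is_identity(self):
        mic = default_microphone()
        mic = mic.replace(
            freq_gain_db=np.zeros_like(mic.freq_gain_db),
            dir_gain_db=np.zeros_like(mic.dir_gain_db),
        )
        assert estimate_spl_at_mic(83.0, 40.0, 50.0, mic) == pytest.approx(83.0)

    def test_60khz_on_axis_adds_10db(self):
        assert estimate_spl_at_mic(80.0, 60.0, 0.0, default_microphone()) == pytest.approx(90.0)

    def test_source_level_at_reference_distance(self):
        assert estimate_source_level(90.0, 0.1, 40.0, Environment()) == pytest.approx(93.0)

    def test_source_level_component_arithmetic(self):
        env = Environment()
        alpha = atmos_atten_coeff(40.0, env)
        expected = 80.0 + 20.0 * np.log10(2.0 / 0.1) + alpha * 1.9 + 3.0
        assert estimate_source_level(80.0, 2.0, 40.0, env) == pytest.approx(expected)
        # with alpha ~1.3 dB/m this is 80 + 26.02 + ~2.5 + 3
        assert estimate_source_level(80.0, 2.0, 40.0, env) == pytest.approx(111.5, abs=0.1)

    def test_spl_at_moth_at_reference_equals_source_level(self):
        assert estimate_spl_at_moth(110.0, 0.1, 40.0, Environment()) == pytest.approx(110.0)

    def test_below_reference_rejected(self):
        with pytest.raises(ValueError):
            estimate_source_level(80.0, 0.05, 40.0, Environment())
        with pytest.raises(ValueError):
            estimate_spl_at_moth(80.0, 0.05, 40.0, Environment())


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("threat", ["real", "false"])
    def test_idealized_forward_inverse_is_exact(self, seed, threat):
        """With the exact -3 dB mic-vs-moth beam convention and no noise the
        inverse recovers source level and level at the moth to < 1e-6 dB."""
        scn = make_attack_scenario(threat, seed=seed)
        fwd = simulate_received_levels(scn, noise_db=0.0, idealized_mic_beam=True)
        cal = calibrate_scenario(scn, fwd)
        ok = cal[cal.valid]
        truth = fwd[cal.valid.to_numpy()]
        assert np.max(np.abs(ok.source_level_10cm_db - truth.true_source_level_toward_moth_db)) < 1e-6
        assert np.max(np.abs(ok.spl_at_moth_db - truth.true_spl_at_moth_db)) < 1e-6

    def test_realistic_beam_bias_bounded(self):
        """With the true beam geometry the recovery bias per call is exactly
        beam_gain(mic) - beam_gain(moth) + 3, and never exceeds its bound."""
        from echorisk.acoustics import beam_gain
        from echorisk.synth import track_positions_at

        scn = make_attack_scenario("real", seed=4)
        fwd = simulate_received_levels(scn, noise_db=0.0)
        cal = calibrate_scenario(scn, fwd)
        ok = cal[cal.valid]
        truth = fwd[cal.valid.to_numpy()]
        bias = (ok.spl_at_moth_db - truth.true_spl_at_moth_db).to_numpy()
        bounds = []
        for call in scn.calls:
            bat = track_positions_at(scn.bat_track, call.emission_time_s)
            ang = lambda v: np.degrees(  # noqa: E731
                np.arccos(np.clip(np.dot(call.beam_direction, v) / np.linalg.norm(v), -1, 1))
            )
            g_moth = beam_gain(ang(scn.focal_moth - bat), call.phase, scn.beam)
            g_mic = beam_gain(ang(scn.mic.position - bat), call.phase, scn.beam)
            bounds.append(abs(g_mic - g_moth + 3.0))
        assert np.max(np.abs(bias)) <= max(bounds) + 1e-9

    def test_gain_control_recovery_with_noise(self):
        """1 dB recording noise, >= 30 gain-control calls: the mean recovered
        level at the moth stays within 0.5 dB of the setpoint."""
        from echorisk.synth import ScenarioParams
        from echorisk.echolocation import SequenceParams

        params = ScenarioParams(
            speed_range_m_s=(2.0, 2.5), sequence=SequenceParams(gain_setpoint_db=95.3)
        )
        scn = make_attack_scenario("real", params, seed=8)
        fwd = simulate_received_levels(scn, noise_db=1.0, seed=8, idealized_mic_beam=True)
        cal = calibrate_scenario(scn, fwd)
        gc = cal[cal.valid & fwd.gain_control]
        assert len(gc) >= 30
        assert abs(gc.spl_at_moth_db.mean() - 95.3) < 0.5


class TestClickEventFeatures:
    def test_clicked_rule(self):
        t = np.array([0.0, 0.04, 0.08, 0.12])
        lv = np.array([85.0, 90.0, 94.0, 99.0])
        intensity, pi, flag = click_event_features(t, lv, click_time_s=0.10)
        assert intensity == pytest.approx(92.0)  # mean of the two pre-click calls
        assert pi == pytest.approx(40.0)
        assert not flag

    def test_nonclicked_rule(self):
        t = np.array([0.0, 0.05, 0.10, 0.15, 0.20])
        lv = np.array([80.0, 88.0, 95.0, 91.0, 85.0])
        intensity, pi, flag = click_event_features(t, lv)
        assert intensity == pytest.approx((88.0 + 95.0 + 91.0) / 3.0)
        assert pi == pytest.approx(50.0)
        assert not flag

    def test_nonclicked_edge_max_uses_available_neighbors(self):
        t = np.array([0.0, 0.05, 0.10])
        lv = np.array([95.0, 90.0, 85.0])
        intensity, pi, flag = click_event_features(t, lv)
        assert flag
        assert intensity == pytest.approx((95.0 + 90.0) / 2.0)

    def test_boundaries(self):
        t = np.array([0.0, 0.04, 0.08])
        lv = np.array([85.0, 90.0, 95.0])
        # exactly two prior calls: defined
        intensity, pi, _ = click_event_features(t, lv, click_time_s=0.06)
        assert intensity == pytest.approx(87.5)
        with pytest.raises(ValueError):
            click_event_features(t, lv, click_time_s=0.02)  # one prior call
        with pytest.raises(ValueError):
            click_event_features(t[:2], lv[:2])  # non-click needs >= 3


class TestAlignment:
    def _attack(self, times, sl):
        return pd.DataFrame({"time_s": times, "source_level_db": sl})

    def test_end_mode(self):
        out = align_attacks([self._attack([1.0, 1.5, 2.0], [100, 110, 105])], "end")[0]
        assert list(out.time_s) == [-1.0, -0.5, 0.0]

    def test_max_intensity_mode_with_tie_broken_earliest(self):
        out = align_attacks(
            [self._attack([0.0, 0.5, 1.0, 1.5], [100, 115, 115, 105])], "max_intensity"
        )[0]
        assert list(out.time_s) == [-0.5, 0.0, 0.5, 1.0]

    def test_single_call_attack(self):
        for mode in ("end", "max_intensity"):
            out = align_attacks([self._attack([3.0], [100.0])], mode)[0]
            assert list(out.time_s) == [0.0]

    def test_intervals_preserved(self):
        df = self._attack([0.0, 0.3, 0.9], [1, 2, 3])
        out = align_attacks([df], "end")[0]
        assert np.allclose(np.diff(out.time_s), np.diff(df.time_s))


class TestTrendFit:
    def _make(self, n_attacks=4, a=5.0, b=-2.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        dfs = []
        for k in range(n_attacks):
            t = np.linspace(-1.0, 0.0, 25)
            offset = rng.normal(0.0, 10.0)
            y = offset + a * t + b * t**2 + rng.normal(0.0, noise, t.size)
            dfs.append(pd.DataFrame({"time_s": t, "resp": y}))
        return dfs

    def test_constant_response_zero_trend(self):
        dfs = [pd.DataFrame({"time_s": np.linspace(0, 1, 10), "resp": np.full(10, 7.0)})]
        fit = fit_trend(dfs, "resp", quadratic=True)
        assert fit.b_time == 0.0 and fit.r_squared == 0.0

    def test_exact_quadratic_recovered(self):
        """Noise-free quadratic with per-attack offsets: coefficients to < 1e-8."""
        fit = fit_trend(self._make(noise=0.0), "resp", quadratic=True)
        assert fit.b_time == pytest.approx(5.0, abs=1e-8)
        assert fit.b_time2 == pytest.approx(-2.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_false_threat_trend_negative(self):
        """End-aligned synthetic false threats show falling level at the moth."""
        from echorisk.calibration import align_attacks

        dfs = []
        for seed in range(5):
            scn = make_attack_scenario("false", seed=seed)
            fwd = simulate_received_levels(scn, noise_db=0.0)
            cal = calibrate_scenario(scn, fwd)
            ok = cal[cal.valid].copy()
            dfs.append(ok[ok.time_s >= ok.time_s.max() - 1.0])
        fit = fit_trend(align_attacks(dfs, "end"), "spl_at_moth_db", quadratic=False)
        assert fit.b_time < 0

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"time_s": [0.0, 1.0], "resp": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_trend([df], "resp", quadratic=True)
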