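"""Threshold extraction, QDA threat boundaries, AUR, pass discrimination."""

import numpy as np
import pytest
from scipy import stats

from echorisk.synth import make_ramp_playback
from echorisk.threat import (
    DiscriminationModel,
    ThresholdCurve,
    auc_real_vs_false,
    discriminate_passes,
    extract_threshold_from_ramp,
    fit_discrimination,
    phase_mean_thresholds,
    threshold_curve_from_model,
)


class TestThresholdExtraction:
    def test_readout_is_pulse_before_click(self):
        stim = make_ramp_playback(100.0)
        assert extract_threshold_from_ramp(stim, 4.95) == pytest.approx(94.5)

    def test_click_just_after_first_pulse(self):
        stim = make_ramp_playback(100.0)
        assert extract_threshold_from_ramp(stim, 1e-4) == pytest.approx(70.0)

    def test_no_click_returns_none(self):
        assert extract_threshold_from_ramp(make_ramp_playback(30.0), None) is None

    def test_click_before_first_pulse_rejected(self):
        with pytest.raises(ValueError):
            extract_threshold_from_ramp(make_ramp_playback(30.0), 0.0)


class TestPhaseMeans:
    def _curve(self, mapping):
        pis = np.array(sorted(mapping))
        return ThresholdCurve(pis, np.array([mapping[p] for p in pis]))

    def test_search_mean(self):
        curve = self._curve({4: 99, 7: 97, 20: 85, 30: 84, 45: 86, 80: 95, 100: 97})
        means = phase_mean_thresholds(curve)
        assert means["search"] == pytest.approx(96.0)
        assert means["approach"] == pytest.approx((85 + 84 + 86) / 3)
        assert means["buzz"] == pytest.approx(98.0)

    def test_transitional_only_curve_rejected(self):
        curve = self._curve({12: 90, 60: 88})
        with pytest.raises(ValueError, match="missing"):
            phase_mean_thresholds(curve)

    def test_approach_minimum_ordering(self):
        """A moth most sensitive in the approach band has approach mean below
        both search and buzz means."""
        curve = self._curve({4: 100, 7: 96, 20: 84, 30: 84, 45: 86, 80: 92, 100: 94})
        means = phase_mean_thresholds(curve)
        assert means["approach"] < means["search"]
        assert means["approach"] < means["buzz"]


class TestDiscriminationModel:
    def _symmetric_model(self):
        cov = np.array([[0.04, 0.0], [0.0, 25.0]])
        return DiscriminationModel(
            mean_real=np.array([1.3, 95.0]),
            cov_real=cov,
            mean_false=np.array([1.3, 80.0]),
            cov_false=cov,
        )

    def test_midpoint_posterior_half(self):
        m = self._symmetric_model()
        assert m.posterior_real([1.3, 87.5]) == pytest.approx(0.5, abs=1e-12)

    def test_limit_deep_in_real_region(self):
        assert self._symmetric_model().posterior_real([1.3, 140.0]) > 0.999999

    def test_posterior_matches_brute_force_densities(self):
        """Posterior agrees with direct Gaussian-pdf evaluation on 100 points."""
        rng = np.random.default_rng(0)
        xr = rng.multivariate_normal([1.2, 95.0], [[0.02, 0.1], [0.1, 16.0]], 40)
        xf = rng.multivariate_normal([1.5, 82.0], [[0.05, -0.2], [-0.2, 30.0]], 40)
        model = fit_discrimination(xr, xf)
        pts = rng.uniform([0.5, 60.0], [2.0, 130.0], size=(100, 2))
        pr = stats.multivariate_normal.pdf(pts, model.mean_real, model.cov_real)
        pf = stats.multivariate_normal.pdf(pts, model.mean_false, model.cov_false)
        oracle = 0.5 * pr / (0.5 * pr + 0.5 * pf)
        assert np.max(np.abs(model.posterior_real(pts) - oracle)) < 1e-10

    def test_singular_covariance_mentions_regularization(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        y = x + 1.0
        with pytest.raises(ValueError, match="regulariz"):
            fit_discrimination(x, y)
        # with a ridge it fits
        fit_discrimination(x, y, regularization=1e-3)

    def test_needs_three_points_per_class(self):
        with pytest.raises(ValueError):
            fit_discrimination([[1.0, 2.0], [2.0, 3.0]], [[0.0, 0.0]] * 5)


class TestThresholdCurveFromModel:
    def test_equal_covariance_matches_linear_boundary(self):
        """With equal class covariances the p = 0.5 iso-posterior curve is the
        closed-form linear discriminant boundary."""
        cov = np.array([[0.05, 0.3], [0.3, 20.0]])
        mu_r = np.array([1.2, 96.0])
        mu_f = np.array([1.4, 82.0])
        model = DiscriminationModel(mu_r, cov, mu_f, cov)
        grid = np.array([4.0, 7.0, 12.0, 20.0, 30.0, 45.0, 60.0, 80.0, 100.0])
        curve = threshold_curve_from_model(model, 0.5, grid)
        # closed form: w . x = c with w = inv(cov) (mu_r - mu_f)
        w = np.linalg.solve(cov, mu_r - mu_f)
        c = 0.5 * (mu_r + mu_f) @ w
        for pi, th in zip(curve.pi_ms, curve.threshold_db):
            expected = (c - w[0] * np.log10(pi)) / w[1]
            assert th == pytest.approx(expected, abs=1e-6)

    def test_p75_above_p50_where_real_is_louder(self):
        cov = np.diag([0.05, 20.0])
        model = DiscriminationModel([1.2, 96.0], cov, [1.4, 82.0], cov)
        grid = np.array([10.0, 30.0, 60.0])
        c50 = threshold_curve_from_model(model, 0.5, grid)
        c75 = threshold_curve_from_model(model, 0.75, grid)
        assert np.all(c75.threshold_db > c50.threshold_db)

    def test_1d_equal_variance_midpoint(self):
        cov = np.diag([1e-6, 16.0])  # PI carries no information
        model = DiscriminationModel([1.0, 100.0], cov, [1.0, 90.0], cov)
        curve = threshold_curve_from_model(model, 0.5, np.array([10.0]))
        assert curve.threshold_db[0] == pytest.approx(95.0, abs=1e-6)

    def test_invalid_p_rejected(self):
        model = DiscriminationModel([1, 100], np.eye(2), [1, 90], np.eye(2))
        with pytest.raises(ValueError):
            threshold_curve_from_model(model, 1.5, np.array([10.0]))


class TestAUR:
    def test_complete_separation(self):
        assert auc_real_vs_false([3, 4, 5], [1, 2]).aur == 1.0

    def test_identical_groups_half(self):
        assert auc_real_vs_false([1, 2, 3], [1, 2, 3]).aur == 0.5

    def test_enumeration_example(self):
        assert auc_real_vs_false([1, 3], [2, 4]).aur == 0.25

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc_real_vs_false([], [1.0])

    def test_matches_rank_statistic_formulation(self):
        """Pairwise enumeration equals U / (n1 n2) from the rank formulation."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(2, 25, 2)
            r = rng.integers(0, 15, n1).astype(float)  # integer ties likely
            f = rng.integers(0, 15, n2).astype(float)
            u = stats.mannwhitneyu(r, f, alternative="two-sided").statistic
            assert auc_real_vs_false(r, f).aur == pytest.approx(u / (n1 * n2), abs=1e-12)


class TestDiscriminatePasses:
    def test_perfect_separation_gives_100_100(self):
        rng = np.random.default_rng(1)
        click = np.column_stack([rng.normal(95, 1, 20), rng.normal(30, 2, 20)])
        nonclick = np.column_stack([rng.normal(75, 1, 25), rng.normal(80, 2, 25)])
        result, ppv, npv = discriminate_passes(
            click, nonclick, ["intensity_db", "pi_ms"]
        )
        assert ppv == 100.0 and npv == 100.0
        assert "intensity_db" in result["selected"]

    def test_permuted_labels_admit_no_variable(self):
        rng = np.random.default_rng(3)
        pool = np.column_stack([rng.normal(85, 5, 60), rng.normal(50, 20, 60)])
        result, ppv, npv = discriminate_passes(
            pool[:30], pool[30:], ["intensity_db", "pi_ms"]
        )
        assert result["intercept_only"]

    def test_counts_agree_with_bruteforce_rule(self):
        rng = np.random.default_rng(5)
        click = np.column_stack([rng.normal(92, 3, 30), rng.normal(35, 8, 30)])
        nonclick = np.column_stack([rng.normal(82, 3, 40), rng.normal(60, 15, 40)])
        result, ppv, npv = discriminate_passes(click, nonclick, ["i", "pi"])
        clf = result["classifier"]
        cols = [["i", "pi"].index(v) for v in result["selected"]]
        X = np.vstack([click, nonclick])[:, cols]
        pred = clf.predict(X)
        y = result["labels"]
        assert ppv == pytest.approx(100.0 * np.mean(pred[y == 1] == 1))
        assert npv == pytest.approx(100.0 * np.mean(pred[y == 0] == 0))

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            discriminate_passes(np.zeros((3, 2)), np.zeros((10, 2)), ["a", "b"])
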