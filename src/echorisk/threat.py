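"""Decision analyses: clicking thresholds and threat discrimination.

Covers the analysis side of the moth's escape decision:

* extraction of clicking thresholds from ramped playbacks and their
  per-phase means;
* a two-class Gaussian (quadratic discriminant) model of real- vs
  false-threat calls over (log10 pulse interval, intensity), with
  iso-posterior threshold curves at p = 0.5 and p = 0.75;
* ROC area (AUR) as the probability that a random real-threat call is
  more intense than a random false-threat call;
* stepwise discriminant analysis of clicking vs non-clicking bat passes
  with positive/negative predictive value in the field sense (fraction
  of clicking / non-clicking interactions classified correctly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .echolocation import classify_phase

__all__ = [
    "ThresholdCurve",
    "DiscriminationModel",
    "ROCResult",
    "REPRESENTATIVE_PIS_MS",
    "extract_threshold_from_ramp",
    "phase_mean_thresholds",
    "fit_discrimination",
    "threshold_curve_from_model",
    "auc_real_vs_false",
    "discriminate_passes",
]

#: Representative pulse intervals (ms) per echolocation phase used for
#: phase-mean thresholds; 12 and 60 ms are transitional and excluded.
REPRESENTATIVE_PIS_MS = {
    "search": (80.0, 100.0),
    "approach": (20.0, 30.0, 45.0),
    "buzz": (4.0, 7.0),
}

INTENSITY_SEARCH_RANGE_DB = (60.0, 130.0)


@dataclass(frozen=True)
class ThresholdCurve:
    """Mapping pulse interval (ms) -> clicking intensity threshold (dB).

    Interpolation between nodes is linear in log10(PI), matching the
    logarithmic PI axis on which thresholds are naturally plotted;
    outside the node range the edge value is held.
    """

    pi_ms: np.ndarray
    threshold_db: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi_ms, float)
        th = np.asarray(self.threshold_db, float)
        if pi.shape != th.shape or pi.ndim != 1:
            raise ValueError("pi_ms and threshold_db must be 1-D and equal length")
        if np.any(np.diff(pi) <= 0):
            raise ValueError("pulse intervals must be strictly increasing")
        object.__setattr__(self, "pi_ms", pi)
        object.__setattr__(self, "threshold_db", th)

    def __call__(self, pi_ms: float) -> float:
        return float(
            np.interp(np.log10(pi_ms), np.log10(self.pi_ms), self.threshold_db)
        )


def extract_threshold_from_ramp(stimulus, first_click_time: float | None) -> float | None:
    """Clicking threshold (dB) read out from a ramped playback.

    The threshold is the level of the last pulse starting strictly
    before the first click. Returns None when the moth never clicked;
    raises if the click precedes every pulse.
    """
    if first_click_time is None:
        return None
    times = np.asarray(stimulus.pulse_times_s, float)
    levels = np.asarray(stimulus.pulse_levels_db, float)
    before = times < first_click_time
    if not before.any():
        raise ValueError("click time precedes the first pulse of the stimulus")
    return float(levels[before][-1])


def phase_mean_thresholds(curve: ThresholdCurve) -> dict[str, float]:
    """Mean measured threshold per echolocation phase.

    Averages the curve's values at the representative PIs of each phase
    (which must be present as curve nodes); the transitional 12 and
    60 ms intervals are never used.
    """
    nodes = {round(p, 6): t for p, t in zip(curve.pi_ms, curve.threshold_db)}
    out = {}
    for phase, pis in REPRESENTATIVE_PIS_MS.items():
        vals = []
        for pi in pis:
            if round(pi, 6) not in nodes:
                raise ValueError(
                    f"threshold curve missing representative PI {pi} ms ({phase})"
                )
            vals.append(nodes[round(pi, 6)])
        out[phase] = float(np.mean(vals))
    return out


# --------------------------------------------------------------------------
# Two-class Gaussian discrimination


@dataclass(frozen=True)
class DiscriminationModel:
    """Two-class Gaussian model over (log10 PI, intensity dB).

    Class 'real' is a bat attacking the focal moth, 'false' a bat
    attacking a neighbor. Posteriors follow from the two Gaussian
    densities and the class priors.
    """

    mean_real: np.ndarray
    cov_real: np.ndarray
    mean_false: np.ndarray
    cov_false: np.ndarray
    prior_real: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mean_real", "mean_false"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        for name in ("cov_real", "cov_false"):
            c = np.asarray(getattr(self, name), float)
            if not np.allclose(c, c.T):
                raise ValueError(f"{name} must be symmetric")
            try:
                np.linalg.cholesky(c)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"{name} is not positive definite; consider the "
                    "regularization option of fit_discrimination"
                ) from None
            object.__setattr__(self, name, c)
        if not 0.0 < self.prior_real < 1.0:
            raise ValueError("prior_real must lie in (0, 1)")

    def posterior_real(self, x) -> np.ndarray | float:
        """P(real | x) for feature vector(s) x = (log10 PI, intensity)."""
        x = np.atleast_2d(np.asarray(x, float))
        lr = stats.multivariate_normal.logpdf(x, self.mean_real, self.cov_real)
        lf = stats.multivariate_normal.logpdf(x, self.mean_false, self.cov_false)
        lr = lr + np.log(self.prior_real)
        lf = lf + np.log(1.0 - self.prior_real)
        m = np.maximum(lr, lf)
        post = np.exp(lr - m) / (np.exp(lr - m) + np.exp(lf - m))
        return float(post[0]) if post.shape == (1,) else post


def fit_discrimination(
    real_points,
    false_points,
    priors: tuple[float, float] = (0.5, 0.5),
    regularization: float = 0.0,
) -> DiscriminationModel:
    """Fit the two-class Gaussian model from per-call feature samples.

    Parameters
    ----------
    real_points, false_points : array-like, shape (n, 2)
        (log10 pulse interval ms, intensity dB) per call; at least 3
        points per class.
    priors : pair of floats summing to 1
        Class priors (real, false); equal by default.
    regularization : float
        Optional ridge added to each covariance diagonal, for
        near-singular sample covariances.
    """
    xr = np.atleast_2d(np.asarray(real_points, float))
    xf = np.atleast_2d(np.asarray(false_points, float))
    if xr.shape[0] < 3 or xf.shape[0] < 3:
        raise ValueError("need at least 3 points per class")
    if abs(priors[0] + priors[1] - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    eye = np.eye(xr.shape[1])
    return DiscriminationModel(
        mean_real=xr.mean(axis=0),
        cov_real=np.cov(xr, rowvar=False, ddof=1) + regularization * eye,
        mean_false=xf.mean(axis=0),
        cov_false=np.cov(xf, rowvar=False, ddof=1) + regularization * eye,
        prior_real=priors[0],
    )


def threshold_curve_from_model(
    model: DiscriminationModel,
    p: float,
    pi_grid_ms,
    intensity_range_db: tuple[float, float] = INTENSITY_SEARCH_RANGE_DB,
    scan_step_db: float = 0.25,
) -> ThresholdCurve:
    """Iso-posterior threat threshold curve at posterior level ``p``.

    For each grid pulse interval the lowest intensity at which
    P(real | log10 PI, intensity) >= p is located by a coarse scan plus
    bracketed root search. Grid PIs with no crossing inside the
    intensity range are dropped from the returned curve; if the
    posterior crosses ``p`` more than once the lowest crossing is
    returned and the multiplicity recorded in ``curve_flags``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    pi_grid = np.asarray(pi_grid_ms, float)
    lo, hi = intensity_range_db
    out_pi, out_th, flags = [], [], {}
    for pi in pi_grid:
        lpi = np.log10(pi)
        grid = np.arange(lo, hi + scan_step_db, scan_step_db)
        vals = model.posterior_real(np.column_stack([np.full_like(grid, lpi), grid])) - p
        sign_change = np.nonzero(np.diff(np.signbit(vals)))[0]
        if vals[0] >= 0:
            # already above p at the bottom of the range
            out_pi.append(pi)
            out_th.append(lo)
            if len(sign_change):
                flags[float(pi)] = "multiple_crossings"
            continue
        if len(sign_change) == 0:
            continue  # no crossing in range
        if len(sign_change) > 1:
            flags[float(pi)] = "multiple_crossings"
        i = sign_change[0]
        root = brentq(
            lambda I: model.posterior_real([lpi, I]) - p,
            grid[i],
            grid[i + 1],
            xtol=1e-9,
        )
        out_pi.append(pi)
        out_th.append(float(root))
    curve = ThresholdCurve(np.asarray(out_pi), np.asarray(out_th))
    object.__setattr__(curve, "curve_flags", flags)
    return curve


# --------------------------------------------------------------------------
# ROC / AUR


@dataclass(frozen=True)
class ROCResult:
    aur: float
    n_real: int
    n_false: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.aur <= 1.0:
            raise ValueError("AUR must lie in [0, 1]")


def auc_real_vs_false(real_intensities, false_intensities) -> ROCResult:
    """Area under the ROC curve by pairwise enumeration.

    The probability that a randomly chosen real-threat call is more
    intense than a randomly chosen false-threat call, ties counting 0.5.
    """
    r = np.asarray(real_intensities, float)
    f = np.asarray(false_intensities, float)
    if r.size == 0 or f.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = r[:, None] - f[None, :]
    aur = float(np.mean((diff > 0) + 0.5 * (diff == 0)))
    return ROCResult(aur=aur, n_real=r.size, n_false=f.size)


# --------------------------------------------------------------------------
# Clicking vs non-clicking pass discrimination


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for a two-group design."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in (0, 1):
        Xg = X[y == g]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    return float(np.linalg.det(W) / np.linalg.det(T))


def discriminate_passes(
    click_features,
    nonclick_features,
    candidate_vars: list[str],
    p_to_enter: float = 0.05,
):
    """Stepwise discriminant analysis of clicking vs non-clicking passes.

    Forward selection adds, at each step, the candidate variable with the
    smallest partial-F p-value below ``p_to_enter`` (partial F from the
    change in Wilks' lambda). The final linear discriminant classifies
    every pass; PPV is the fraction of clicking passes classified as
    clicking and NPV the fraction of non-clicking passes classified as
    non-clicking.

    Returns ``(result_dict, ppv_pct, npv_pct)``; the result dict carries
    the selected variables, the fitted classifier, per-event predictions
    and an ``intercept_only`` flag when no variable enters.
    """
    Xc = np.atleast_2d(np.asarray(click_features, float))
    Xn = np.atleast_2d(np.asarray(nonclick_features, float))
    if Xc.shape[0] < 5 or Xn.shape[0] < 5:
        raise ValueError("need at least 5 events per group")
    if Xc.shape[1] != len(candidate_vars) or Xn.shape[1] != len(candidate_vars):
        raise ValueError("feature columns must match candidate_vars")
    X = np.vstack([Xc, Xn])
    y = np.concatenate([np.ones(Xc.shape[0], int), np.zeros(Xn.shape[0], int)])
    n, g = X.shape[0], 2

    selected: list[int] = []
    remaining = list(range(len(candidate_vars)))
    trail = []
    while remaining:
        best = None
        lam_cur = _wilks_lambda(X[:, selected], y) if selected else 1.0
        for j in remaining:
            cols = selected + [j]
            lam_new = _wilks_lambda(X[:, cols], y)
            p_dim = len(selected)
            df2 = n - g - p_dim
            if df2 <= 0 or lam_new <= 0:
                continue
            F = (df2 / (g - 1)) * (lam_cur / lam_new - 1.0)
            pval = float(stats.f.sf(F, g - 1, df2))
            if best is None or pval < best[1]:
                best = (j, pval, F)
        if best is None or best[1] >= p_to_enter:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        trail.append(
            {"variable": candidate_vars[best[0]], "partial_F": best[2], "p": best[1]}
        )

    result = {
        "selected": [candidate_vars[j] for j in selected],
        "steps": trail,
        "intercept_only": not selected,
    }
    if not selected:
        # no discriminating variable: classify everything as the larger group
        pred = np.full(n, int(Xc.shape[0] >= Xn.shape[0]))
        result["classifier"] = None
    else:
        clf = LinearDiscriminantAnalysis()
        clf.fit(X[:, selected], y)
        pred = clf.predict(X[:, selected])
        result["classifier"] = clf
    result["predictions"] = pred
    result["labels"] = y
    ppv = 100.0 * float(np.mean(pred[y == 1] == 1))
    npv = 100.0 * float(np.mean(pred[y == 0] == 0))
    return result, ppv, npv


def intensities_by_phase(pulse_intervals_ms, intensities_db) -> dict[str, np.ndarray]:
    """Group per-call intensities by echolocation phase of their PI."""
    out: dict[str, list[float]] = {"search": [], "approach": [], "buzz": []}
    for pi, level in zip(np.asarray(pulse_intervals_ms), np.asarray(intensities_db)):
        if np.isfinite(pi) and pi > 0 and np.isfinite(level):
            out[classify_phase(pi)].append(float(level))
    return {k: np.asarray(v) for k, v in out.items()}
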