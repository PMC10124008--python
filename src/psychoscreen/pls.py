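"""Single-response PLS (NIPALS/PLS1) with leave-one-out Q², VIP scores and
Spearman utilities.

This is the modelling engine of the screen: one PLS1 model per mood factor,
evaluated by leave-one-out cross-validation (PRESS, RMSECV, Q² and the
Spearman correlation between cross-validated predictions and observed
scores), with Wold's VIP quantifying each feature's contribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class PLSModel:
    n_components: int
    weights: np.ndarray  # p x A, columns unit norm (on scaled X)
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray  # n x A
    coefficients: np.ndarray  # p, on the ORIGINAL X scale
    x_mean: np.ndarray
    y_mean: float
    scaling: np.ndarray  # per-feature divisor (ones when scale=False)

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        return x_new @ self.coefficients + self.intercept

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)


@dataclass
class PLSEvaluation:
    n_components: int
    q2: float
    rmsecv: float
    press: float
    loo_predictions: np.ndarray
    spearman_r: float
    spearman_p: float


def _prepare(x: np.ndarray, y: np.ndarray, scale: bool):
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = sd <= _EPS
        if zero.any():
            raise ValueError(
                f"zero-variance columns under scale=True: {np.where(zero)[0].tolist()}"
            )
        scaling = sd
    else:
        scaling = np.ones(x.shape[1])
    xc = (x - x_mean) / scaling
    yc = y - y_mean
    return xc, yc, x_mean, y_mean, scaling


def fit_pls(x: np.ndarray, y: np.ndarray, n_components: int,
            scale: bool = True) -> PLSModel:
    """Fit a PLS1 model by NIPALS deflation.

    X is column-centered (and unit-variance scaled when ``scale``); y is
    centered. Each component takes w_a ∝ X'y, scores t_a = X w_a, loadings
    p_a = X't_a/(t_a't_a) and q_a = t_a'y/(t_a't_a), then deflates X.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("X and y have different numbers of samples")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components={n_components} must lie in [1, min(n-1, p)={min(n - 1, p)}]"
        )
    xc, yc, x_mean, y_mean, scaling = _prepare(x, y, scale)

    weights = np.zeros((p, n_components))
    x_loadings = np.zeros((p, n_components))
    y_loadings = np.zeros(n_components)
    scores = np.zeros((n, n_components))
    xa = xc.copy()
    a_used = n_components
    for a in range(n_components):
        w = xa.T @ yc
        norm = np.linalg.norm(w)
        if norm <= _EPS:  # residual orthogonal to y: nothing left to extract
            a_used = a
            break
        w /= norm
        t = xa @ w
        tt = float(t @ t)
        if tt <= _EPS:
            a_used = a
            break
        p_a = xa.T @ t / tt
        q_a = float(t @ yc) / tt
        weights[:, a] = w
        x_loadings[:, a] = p_a
        y_loadings[a] = q_a
        scores[:, a] = t
        xa = xa - np.outer(t, p_a)
    weights = weights[:, :a_used]
    x_loadings = x_loadings[:, :a_used]
    y_loadings = y_loadings[:a_used]
    scores = scores[:, :a_used]
    if a_used == 0:
        raise ValueError("no PLS component could be extracted (y orthogonal to X)")

    # b on the scaled space: W (P'W)^{-1} q, then undo the scaling
    pw = x_loadings.T @ weights
    b_scaled = weights @ np.linalg.solve(pw, y_loadings)
    coefficients = b_scaled / scaling
    return PLSModel(
        n_components=a_used, weights=weights, x_loadings=x_loadings,
        y_loadings=y_loadings, scores=scores, coefficients=coefficients,
        x_mean=x_mean, y_mean=y_mean, scaling=scaling,
    )


def vip(model: PLSModel) -> np.ndarray:
    """Wold's Variable Importance in Projection.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ) with
    SS_a = q_a^2 (t_a ' t_a); the squares average to 1 over features.
    """
    w = model.weights
    p = w.shape[0]
    ss = model.y_loadings ** 2 * np.einsum("ia,ia->a", model.scores, model.scores)
    total = float(ss.sum())
    if total <= _EPS:
        raise ValueError("degenerate model: zero explained sum of squares")
    wnorm2 = (w ** 2).sum(axis=0)
    wnorm2[wnorm2 <= _EPS] = 1.0
    contrib = (w ** 2 / wnorm2) @ ss
    return np.sqrt(p * contrib / total)


def _loo_prediction_matrix(x: np.ndarray, y: np.ndarray, max_components: int,
                           scale: bool) -> np.ndarray:
    """n x max_components matrix of leave-one-out predictions: column a-1
    holds the prediction of each held-out sample from an a-component model
    refit (with re-centering/scaling) on the remaining n-1 samples.

    Folds where a feature has zero variance drop that feature within the
    fold (logged) rather than failing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    preds = np.full((n, max_components), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_tr, y_tr = x[mask], y[mask]
        cols = np.arange(p)
        if scale:
            sd = x_tr.std(axis=0, ddof=1)
            keep = sd > _EPS
            if not keep.all():
                logger.debug("LOO fold %d: dropping %d zero-variance features",
                             i, int((~keep).sum()))
                cols = cols[keep]
                x_tr = x_tr[:, keep]
        a_max = min(max_components, x_tr.shape[0] - 1, x_tr.shape[1])
        model = fit_pls(x_tr, y_tr, a_max, scale=scale)
        # predictions at every truncation 1..A from the fitted sequence
        xi = (x[i, cols] - model.x_mean) / model.scaling
        t = np.zeros(model.n_components)
        x_res = xi.copy()
        for a in range(model.n_components):
            t[a] = x_res @ model.weights[:, a]
            x_res = x_res - t[a] * model.x_loadings[:, a]
        cum = model.y_mean + np.cumsum(t * model.y_loadings)
        for a in range(max_components):
            preds[i, a] = cum[min(a, model.n_components - 1)]
    return preds


def _evaluate(y: np.ndarray, yhat: np.ndarray, n_components: int,
              p_method: str = "t_approx") -> PLSEvaluation:
    y = np.asarray(y, dtype=float).ravel()
    press = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss_tot
    rmsecv = math.sqrt(press / y.size)
    try:
        r, p = spearman(yhat, y, p_method=p_method)
    except ValueError:  # constant predictions
        r, p = float("nan"), float("nan")
    return PLSEvaluation(n_components=n_components, q2=q2, rmsecv=rmsecv,
                         press=press, loo_predictions=yhat,
                         spearman_r=r, spearman_p=p)


def loo_cv(x: np.ndarray, y: np.ndarray, n_components: int,
           scale: bool = True, p_method: str = "t_approx") -> PLSEvaluation:
    """Leave-one-out cross-validation of a PLS1 model.

    Each sample is predicted from a model refit on the other n-1 samples
    (centering/scaling recomputed inside each fold). Reports PRESS,
    RMSECV = sqrt(PRESS/n), Q² = 1 - PRESS / Σ(y - ȳ)² and the Spearman
    R/P between cross-validated predictions and the observed response.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < n_components + 2:
        raise ValueError(f"need n >= A + 2 samples; n={y.size}, A={n_components}")
    preds = _loo_prediction_matrix(x, y, n_components, scale)
    return _evaluate(y, preds[:, n_components - 1], n_components, p_method)


def select_components(x: np.ndarray, y: np.ndarray, max_components: int,
                      scale: bool = True) -> tuple[int, np.ndarray]:
    """Pick the component count 1..max_components maximizing LOO Q²; ties
    break toward the smaller count. Returns (A*, q2 per candidate)."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    a_cap = min(max_components, x.shape[0] - 2, x.shape[1])
    preds = _loo_prediction_matrix(x, y, a_cap, scale)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - np.sum((y[:, None] - preds) ** 2, axis=0) / ss_tot
    best = int(np.argmax(q2 > q2.max() - 1e-12)) + 1  # first index reaching max
    return best, q2


def spearman(x: np.ndarray, y: np.ndarray,
             p_method: str = "t_approx") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use midranks for ties. ``t_approx`` tests R via the usual
    t = R sqrt((n-2)/(1-R²)) reference; ``exact_perm`` enumerates all n!
    orderings (n <= 8 only) and counts |R_perm| >= |R_observed|.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.unique(x).size == n and np.unique(y).size == n:
        # tie-free: the classical d² formula, exact at R = +-1
        d = rx - ry
        r = 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))
    else:
        r = float(np.corrcoef(rx, ry)[0, 1])

    if p_method == "t_approx":
        if abs(r) >= 1.0:
            return (math.copysign(1.0, r), 0.0)
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        return r, min(p, 1.0)
    if p_method == "exact_perm":
        if n > 8:
            raise ValueError("exact_perm enumerates all n! orderings; use n <= 8")
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float((ry - ry.mean()) @ (ry - ry.mean())))
        count = 0
        total = 0
        ry_c = ry - ry.mean()
        target = abs(r) - 1e-12
        for perm in permutations(ry_c):
            rp = float(rx_c @ np.asarray(perm)) / denom
            if abs(rp) >= target:
                count += 1
            total += 1
        return r, count / total
    raise ValueError("p_method must be 't_approx' or 'exact_perm'")
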