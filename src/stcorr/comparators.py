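"""Conventional detrending baselines: moving averages and a Kalman filter.

Both comparators estimate a slow baseline trend, remove it, and
correlate the residuals.  The moving-average variant with window 2 is
special: detrending within non-overlapping trial pairs halves the
residual variances and covariance (each residual is half the within-pair
difference), but their *ratio* — the correlation coefficient — equals
the drift-robust pairwise estimator exactly.  Windows of 3 or more leave
part of the baseline trend in the residuals and bias the correlation:
under a trend shared by the pair the leftover common component drives
the estimate away from the true noise correlation, increasingly so for
wider windows and faster trends.

The state-space comparator assumes a scalar latent trend shared by all
neurons,

    mu_{t+1} = F mu_t + eta,        eta ~ N(0, q)
    X_t^(i)  = G_i mu_t + xi_i,     xi_i ~ N(0, r_i),

fits (F, G, q, r) by maximum likelihood through the Kalman-filter
prediction-error decomposition, removes the filtered (one-sided) trend
estimate G_i * m_t from each neuron, and correlates the residuals of the
target pair.  With few neurons the filtered trend absorbs part of the
correlated noise itself, biasing the residual correlation toward zero —
the failure mode the pairwise estimator avoids.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .estimator import pearson_correlation, short_term_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "StateSpaceModel",
    "moving_average_detrend",
    "ma_residual_covariances",
    "ma_residual_correlation",
    "fit_state_space",
    "kalman_filter",
    "kalman_residual_correlation",
]

_VAR_FLOOR = 1e-8


# ---------------------------------------------------------------------
# Moving averages
# ---------------------------------------------------------------------

def moving_average_detrend(series, window: int) -> np.ndarray:
    """Residuals after moving-average smoothing.

    window == 2
        Pairing-based variant: within each non-overlapping pair
        {2t-1, 2t} the residual is the deviation from the pair mean
        (an odd final point is dropped).
    window odd (>= 3)
        Centered window; only interior points with a full window are
        kept (edges truncated), so the residual series is shorter by
        window - 1.
    """
    series = np.asarray(series, dtype=float).ravel()
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > series.size:
        raise ValueError(f"window {window} exceeds series length {series.size}")
    if window == 2:
        n = 2 * (series.size // 2)
        pairs = series[:n].reshape(-1, 2)
        return (pairs - pairs.mean(axis=1, keepdims=True)).ravel()
    if window % 2 == 0:
        raise ValueError("even windows other than 2 are not defined")
    k = window // 2
    kernel = np.full(window, 1.0 / window)
    smooth = np.convolve(series, kernel, mode="valid")
    return series[k : series.size - k] - smooth


def ma_residual_covariances(x, y) -> tuple[float, float, float]:
    """Window-2 residual second moments (v_x, v_y, c_xy).

    These are exactly half the pairwise covariance estimates, hence on
    average half the true noise variances/covariance — e.g. true
    (1, 1, 0.2) is estimated as (0.5, 0.5, 0.1) — while their ratio
    still recovers the correlation coefficient.
    """
    rx = moving_average_detrend(x, 2)
    ry = moving_average_detrend(y, 2)
    n = rx.size
    # residuals have exactly zero pair means, so uncentered moments
    return float(rx @ rx) / n, float(ry @ ry) / n, float(rx @ ry) / n


def ma_residual_correlation(x, y, window: int) -> float:
    """Correlation of the moving-average residuals.

    For window 2 the uncentered residual correlation is returned; it
    coincides with the pairwise short-term estimator to machine
    precision.  For odd windows the ordinary Pearson correlation of the
    interior residuals is returned.
    """
    if window == 2:
        vx, vy, c = ma_residual_covariances(x, y)
        denom = vx * vy
        if denom <= 0:
            return float("nan")
        return c / float(np.sqrt(denom))
    rx = moving_average_detrend(x, window)
    ry = moving_average_detrend(y, window)
    return pearson_correlation(rx, ry)


# ---------------------------------------------------------------------
# State-space (Kalman) comparator
# ---------------------------------------------------------------------

@dataclass
class StateSpaceModel:
    """Scalar-latent-trend state-space model with per-neuron loadings."""

    F: float
    G: np.ndarray
    q: float
    r: np.ndarray
    mu0: float = 0.0
    P0: float = 1e4
    converged: bool = True
    loglik: float = np.nan
    message: str = ""


def _kalman_pass(
    data: np.ndarray, F: float, G: np.ndarray, q: float, r: np.ndarray,
    mu0: float, P0: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One filtering pass; returns filtered means, variances, loglik.

    With a scalar state the innovation covariance is diagonal plus
    rank one, S = P_p G G' + diag(r), so the update is computed in
    O(m) per step via Sherman-Morrison:
        S^-1 v  = v/r - (P_p a / (1 + P_p c)) * (G/r),  a = G'v/r,
        c = G'G/r,  log|S| = sum log r + log(1 + P_p c).
    """
    T, m = data.shape
    mu_f = np.empty(T)
    P_f = np.empty(T)
    mu, P = mu0, P0
    loglik = 0.0
    ln2pi = np.log(2.0 * np.pi)
    g_over_r = G / r
    c = float(G @ g_over_r)
    sum_log_r = float(np.sum(np.log(r)))
    F2 = F * F
    for t in range(T):
        mu_p = F * mu
        P_p = F2 * P + q
        v = data[t] - G * mu_p
        a = float(v @ g_over_r)
        denom = 1.0 + P_p * c
        # quadratic form v' S^-1 v and gain K = P_p G' S^-1
        quad = float(v @ (v / r)) - P_p * a * a / denom
        loglik += -0.5 * (m * ln2pi + sum_log_r + np.log(denom) + quad)
        gain_v = P_p * a / denom        # K @ v
        gain_g = P_p * c / denom        # K @ G
        mu = mu_p + gain_v
        P = P_p * (1.0 - gain_g)
        mu_f[t] = mu
        P_f[t] = max(P, 0.0)
    if not np.isfinite(loglik):
        return mu_f, P_f, -np.inf
    return mu_f, P_f, loglik


def kalman_filter(data, model: StateSpaceModel) -> np.ndarray:
    """Filtered (one-sided) latent-trend means m_t for each trial."""
    data = np.asarray(data, dtype=float)
    mu_f, _, _ = _kalman_pass(
        data, model.F, model.G, model.q, model.r, model.mu0, model.P0
    )
    return mu_f


def fit_state_space(
    data,
    max_iter: int = 200,
    mu0: float | None = None,
    P0: float | None = None,
) -> StateSpaceModel:
    """Maximum-likelihood fit of the shared-trend state-space model.

    Initialization: F = 1 (random-walk prior), loadings G at the
    per-neuron SD scale, observation variances from half the
    first-difference variances, trend innovation variance from the rest.
    Variances are optimized on the log scale with a floor of 1e-8.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be trials x neurons with >= 2 neurons")
    T, m = data.shape
    if T < 10:
        raise ValueError("need at least 10 trials")

    sd = data.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    diff_var = np.var(np.diff(data, axis=0), axis=0, ddof=1)
    r0 = np.maximum(diff_var / 2.0, _VAR_FLOOR)
    total_var = np.maximum(data.var(axis=0, ddof=1), _VAR_FLOOR)
    q0 = max(float(np.mean(np.maximum(total_var - r0, _VAR_FLOOR))) / 10.0, _VAR_FLOOR)
    if mu0 is None:
        mu0 = float(np.mean(data[0] / sd))
    if P0 is None:
        P0 = float(10.0 * np.max(total_var))

    x0 = np.concatenate([[1.0], sd, [np.log(q0)], np.log(r0)])

    def negloglik(params: np.ndarray) -> float:
        F = params[0]
        G = params[1 : 1 + m]
        q = np.exp(params[1 + m]) + _VAR_FLOOR
        r = np.exp(params[2 + m :]) + _VAR_FLOOR
        _, _, ll = _kalman_pass(data, F, G, q, r, mu0, P0)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    bounds = (
        [(-1.2, 1.2)]
        + [(None, None)] * m
        + [(np.log(_VAR_FLOOR), 20.0)] * (1 + m)
    )
    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter},
    )
    F = float(res.x[0])
    G = np.asarray(res.x[1 : 1 + m])
    q = float(np.exp(res.x[1 + m]) + _VAR_FLOOR)
    r = np.exp(res.x[2 + m :]) + _VAR_FLOOR
    if not res.success:
        logger.warning("state-space MLE did not converge: %s", res.message)
    return StateSpaceModel(
        F=F, G=G, q=q, r=r, mu0=mu0, P0=P0,
        converged=bool(res.success), loglik=float(-res.fun),
        message=str(res.message),
    )


def kalman_residual_correlation(
    data, model: StateSpaceModel, target_pair: tuple[int, int] = (0, 1)
) -> float:
    """Pearson correlation of two neurons' residuals after removing the
    filtered trend (G_i * m_t) from each."""
    data = np.asarray(data, dtype=float)
    mu_f = kalman_filter(data, model)
    i, j = target_pair
    res_i = data[:, i] - model.G[i] * mu_f
    res_j = data[:, j] - model.G[j] * mu_f
    return pearson_correlation(res_i, res_j)
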