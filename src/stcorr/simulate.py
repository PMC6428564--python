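"""Synthetic generators for drifting baselines and correlated noise.

The generative model throughout is additive: per-trial activity is a
slow deterministic-or-stochastic baseline trend plus Gaussian noise that
is correlated across neurons but independent across trials (long
intertrial intervals wash out temporal noise correlations).  Trend
families:

``constant``   flat baseline (stationary control)
``linear``     deterministic ramp
``stepwise``   piecewise-constant levels with change points
``sinusoid``   amplitude * sin(2 pi * n_cycles * t / N + phase)
``arima021``   twice-integrated MA(1) innovations (a smooth, wandering
               second-order random walk; the hardest drift case)

Full stimulus-structured sessions combine circular-Gaussian tuning
curves over 16 stimuli presented in 40 pseudo-random blocks, a
per-neuron drift added to all stimuli, multivariate Gaussian rate
noise, uniform trial durations in [1.0, 1.7] s, and integer spike
counts (rate x duration, floored at zero, rounded).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .session import SessionData
from ._rng import child_rng

logger = logging.getLogger(__name__)

__all__ = [
    "TrendSpec",
    "NoiseSpec",
    "PopulationSpec",
    "SessionSpec",
    "simulate_trend",
    "simulate_pair",
    "simulate_population",
    "simulate_drift_bias_pair",
    "simulate_session",
    "circular_gaussian_tuning",
]

TREND_FAMILIES = ("constant", "linear", "stepwise", "sinusoid", "arima021")


@dataclass(frozen=True)
class TrendSpec:
    """Parametric description of one baseline-drift realization family.

    params by family:
      constant: level (default 0)
      linear:   slope, intercept
      sinusoid: amplitude (default 0.5), n_cycles (default 7), phase
      stepwise: change_points (list of trial indices), levels
                (len(change_points) + 1 values)
      arima021: theta (MA coefficient, default 0.6), innovation_sd
                (default 0.01)
    """

    family: str
    n: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in TREND_FAMILIES:
            raise ValueError(
                f"unknown trend family {self.family!r}; choose from {TREND_FAMILIES}"
            )
        if self.n < 2:
            raise ValueError("trend length must be >= 2")
        if self.family == "sinusoid" and self.params.get("n_cycles", 7) <= 0:
            raise ValueError("sinusoid n_cycles must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Bivariate Gaussian noise: variances s11, s22 and correlation rho
    (so the covariance is rho * sqrt(s11 * s22))."""

    s11: float = 1.0
    s22: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.s11 <= 0 or self.s22 <= 0:
            raise ValueError("noise variances must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def cov(self) -> np.ndarray:
        c = self.rho * np.sqrt(self.s11 * self.s22)
        return np.array([[self.s11, c], [c, self.s22]])


@dataclass(frozen=True)
class PopulationSpec:
    """Multi-neuron design: all neurons share one baseline trend; only
    neurons 0 and 1 carry correlated noise, the rest are independent
    unit-variance Gaussians."""

    n_neurons: int
    shared_trend: TrendSpec
    pair_noise: NoiseSpec

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")


@dataclass(frozen=True)
class SessionSpec:
    """Stimulus-structured session design.

    tuning is an (n_neurons, n_stimuli) matrix of mean firing rates in
    spikes/s; drift is an optional per-neuron list of TrendSpec (length
    n_blocks * n_stimuli each) added to all stimuli; noise_cov is the
    (n_neurons, n_neurons) covariance of the additive Gaussian rate
    noise.
    """

    tuning: np.ndarray
    drift: Sequence[TrendSpec] | None = None
    noise_cov: np.ndarray | None = None
    n_stimuli: int = 16
    n_blocks: int = 40
    duration_range: tuple[float, float] = (1.0, 1.7)

    def __post_init__(self) -> None:
        tuning = np.asarray(self.tuning, dtype=float)
        object.__setattr__(self, "tuning", tuning)
        if tuning.ndim != 2 or tuning.shape[1] != self.n_stimuli:
            raise ValueError(
                f"tuning must be (n_neurons, {self.n_stimuli}), got {tuning.shape}"
            )
        n_trials = self.n_stimuli * self.n_blocks
        if self.drift is not None:
            if len(self.drift) != tuning.shape[0]:
                raise ValueError("one drift spec per neuron required")
            for spec in self.drift:
                if spec.n != n_trials:
                    raise ValueError(
                        f"drift length {spec.n} must equal n_trials {n_trials}"
                    )
        if self.noise_cov is not None:
            cov = np.asarray(self.noise_cov, dtype=float)
            object.__setattr__(self, "noise_cov", cov)
            if cov.shape != (tuning.shape[0],) * 2:
                raise ValueError("noise_cov must be n_neurons x n_neurons")

    @property
    def n_neurons(self) -> int:
        return self.tuning.shape[0]

    @property
    def n_trials(self) -> int:
        return self.n_stimuli * self.n_blocks


# ---------------------------------------------------------------------
# Trends
# ---------------------------------------------------------------------

def simulate_trend(spec: TrendSpec, seed: int = 0) -> np.ndarray:
    """Realize one baseline trend; deterministic given (spec, seed)."""
    n = spec.n
    p = spec.params
    if spec.family == "constant":
        return np.full(n, float(p.get("level", 0.0)))
    if spec.family == "linear":
        return p.get("intercept", 0.0) + p.get("slope", 0.05) * np.arange(n)
    if spec.family == "sinusoid":
        amp = p.get("amplitude", 0.5)
        cycles = p.get("n_cycles", 7)
        phase = p.get("phase", 0.0)
        t = np.arange(n)
        return amp * np.sin(2.0 * np.pi * cycles * t / n + phase)
    if spec.family == "stepwise":
        change_points = list(p.get("change_points", [n // 2]))
        levels = list(p.get("levels", [0.0, 2.0]))
        if len(levels) != len(change_points) + 1:
            raise ValueError("need len(change_points) + 1 levels")
        out = np.empty(n)
        edges = [0, *change_points, n]
        for lo, hi, level in zip(edges[:-1], edges[1:], levels):
            out[lo:hi] = level
        return out
    # arima021: x_t with second difference = MA(1) innovations
    theta = p.get("theta", 0.6)
    sd = p.get("innovation_sd", 0.01)
    rng = child_rng(seed, f"trend-arima021-{n}")
    eps = rng.standard_normal(n + 1) * sd
    ma = eps[1:] + theta * eps[:-1]
    return np.cumsum(np.cumsum(ma))


# ---------------------------------------------------------------------
# Pairs / populations
# ---------------------------------------------------------------------

def _bivariate_noise(
    n: int, noise: NoiseSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    L = np.linalg.cholesky(noise.cov)
    e = rng.standard_normal((n, 2)) @ L.T
    return e[:, 0], e[:, 1]


def simulate_pair(
    trend_x, trend_y, noise: NoiseSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two neurons' activities: given trends plus per-trial bivariate
    Gaussian noise (independent across trials)."""
    trend_x = np.asarray(trend_x, dtype=float).ravel()
    trend_y = np.asarray(trend_y, dtype=float).ravel()
    if trend_x.shape != trend_y.shape:
        raise ValueError("trend lengths differ")
    rng = child_rng(seed, "pair-noise")
    ex, ey = _bivariate_noise(trend_x.size, noise, rng)
    return trend_x + ex, trend_y + ey


def simulate_population(spec: PopulationSpec, seed: int = 0) -> np.ndarray:
    """Trials x neurons matrix: one shared trend; correlated noise only
    between neurons 0 and 1; unit-variance independent noise elsewhere."""
    trend = simulate_trend(spec.shared_trend, seed=seed)
    n = trend.size
    rng = child_rng(seed, "population-noise")
    ex, ey = _bivariate_noise(n, spec.pair_noise, rng)
    data = np.empty((n, spec.n_neurons))
    data[:, 0] = trend + ex
    data[:, 1] = trend + ey
    if spec.n_neurons > 2:
        data[:, 2:] = trend[:, None] + rng.standard_normal((n, spec.n_neurons - 2))
    return data


def simulate_drift_bias_pair(
    mu: float, eps: float, sigma: float, n_pairs: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Worst-case within-pair drift: consecutive trials have means
    mu - eps and mu + eps, with independent N(0, sigma^2) noise.

    Used to check that the variance estimate's drift bias is exactly
    2 * eps^2 (second order in the within-pair drift)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    means = np.tile([mu - eps, mu + eps], n_pairs)
    rng = child_rng(seed, "drift-bias-pair")
    x = means + sigma * rng.standard_normal(2 * n_pairs)
    y = means + sigma * rng.standard_normal(2 * n_pairs)
    return x, y


# ---------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------

def circular_gaussian_tuning(
    n_neurons: int,
    n_stimuli: int = 16,
    baseline: float = 10.0,
    amplitude: float = 10.0,
    width: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Circular-Gaussian tuning curves over equally spaced stimuli.

    Mean rate of neuron i to stimulus s is
    baseline + amplitude * exp(-d(s, pref_i)^2 / (2 width^2)) with
    circular stimulus distance d; preferred stimuli are drawn uniformly.
    Defaults give moderately tuned ~10-20 spikes/s responses.
    """
    rng = child_rng(seed, "tuning-curves")
    pref = rng.uniform(0, n_stimuli, size=n_neurons)
    s = np.arange(n_stimuli)
    d = np.abs(s[None, :] - pref[:, None])
    d = np.minimum(d, n_stimuli - d)
    return baseline + amplitude * np.exp(-(d**2) / (2.0 * width**2))


def simulate_session(spec: SessionSpec, seed: int = 0) -> SessionData:
    """Generate a full stimulus-structured session.

    Each of ``n_blocks`` consecutive blocks presents every stimulus
    exactly once in a seed-determined pseudo-random order.  Per-trial
    firing rate = tuning(neuron, stimulus) + drift(neuron, trial) +
    Gaussian noise; counts = round(max(rate, 0) * duration).
    """
    rng = child_rng(seed, "session")
    m, k, b = spec.n_neurons, spec.n_stimuli, spec.n_blocks
    n_trials = spec.n_trials
    stimulus = np.concatenate([rng.permutation(k) for _ in range(b)])
    duration = rng.uniform(*spec.duration_range, size=n_trials)

    means = spec.tuning[:, stimulus].T  # trials x neurons
    if spec.drift is not None:
        drift = np.column_stack(
            [simulate_trend(ts, seed=seed + 1 + j) for j, ts in enumerate(spec.drift)]
        )
        means = means + drift
    if spec.noise_cov is not None:
        L = np.linalg.cholesky(spec.noise_cov)
        noise = rng.standard_normal((n_trials, m)) @ L.T
    else:
        noise = rng.standard_normal((n_trials, m))
    rates = np.maximum(means + noise, 0.0)
    counts = np.round(rates * duration[:, None]).astype(np.int64)
    return SessionData(
        counts=counts,
        stimulus=stimulus,
        duration=duration,
        trial_index=np.arange(n_trials),
        neuron_ids=[f"n{i:03d}" for i in range(m)],
    )
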