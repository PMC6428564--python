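"""Drift-robust short-term noise-correlation estimator and comparators.

The short-term estimator measures the correlation of the *simultaneous*
trial-to-trial fluctuations of two neurons while being unbiased under an
arbitrary slow drift of their baseline firing.  It treats the trial
sequence in consecutive non-overlapping pairs {1,2}, {3,4}, ...; within
each pair the local mean is removed, so any baseline component that is
(approximately) constant across two neighbouring trials cancels exactly.
With pair differences dx_t = x_{2t-1} - x_{2t} the covariance estimates
reduce to

    S11 = (1/N) sum_t dx_t^2,   S12 = (1/N) sum_t dx_t dy_t,

where N is the (even) number of trials used, and the correlation is
rho = S12 / sqrt(S11 S22).  Each S is an unbiased estimate of the
corresponding noise covariance whatever the drift, and attains the
minimum variance S11*S22 + S12^2 (per pair) achievable by any estimator
that is unbiased for all drifts.

Note that rho, being a ratio of unbiased covariance estimates rather
than a Cauchy-Schwarz-bounded sample correlation, is *not* confined to
[-1, 1] in finite samples; values are reported unclipped because
clipping would distort the Monte-Carlo null distribution built from the
same statistic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CovarianceEstimate",
    "Correlogram",
    "InsufficientDataError",
    "local_pair_covariances",
    "short_term_correlation",
    "pearson_correlation",
    "cross_correlogram",
]

Method = Literal["proposed", "pearson"]


class InsufficientDataError(ValueError):
    """Fewer trials than the estimator requires."""


@dataclass(frozen=True)
class CovarianceEstimate:
    """Locally detrended covariance triple and the derived correlation.

    ``rho`` is NaN when either variance estimate is zero (the NA
    semantics used for silent neurons).  ``n_pairs`` is the number of
    consecutive-trial pairs actually used (N // 2).
    """

    s11: float
    s22: float
    s12: float
    rho: float
    n_pairs: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.rho)


@dataclass(frozen=True)
class Correlogram:
    """Correlation estimate as a function of integer trial shift."""

    lags: np.ndarray
    values: np.ndarray
    method: str


def _usable(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"series lengths differ: {x.size} vs {y.size}")
    if x.size < 2:
        raise InsufficientDataError(
            f"need at least 2 trials, got {x.size}"
        )
    n = 2 * (x.size // 2)
    if n != x.size:
        logger.debug("odd series length %d: dropping final trial", x.size)
    return x[:n], y[:n]


def local_pair_covariances(x, y) -> CovarianceEstimate:
    """Pairwise locally detrended covariance estimates for two series.

    Parameters
    ----------
    x, y:
        Per-trial activities (counts or rates) of the two neurons, in
        temporal order, equal length.  An odd final trial is dropped.
    """
    x, y = _usable(x, y)
    n = x.size
    dx = x[0::2] - x[1::2]
    dy = y[0::2] - y[1::2]
    s11 = float(dx @ dx) / n
    s22 = float(dy @ dy) / n
    s12 = float(dx @ dy) / n
    denom = s11 * s22
    rho = s12 / np.sqrt(denom) if denom > 0 else np.nan
    return CovarianceEstimate(s11=s11, s22=s22, s12=s12, rho=float(rho), n_pairs=n // 2)


def short_term_correlation(x, y) -> float:
    """The drift-robust short-term correlation coefficient (NaN if undefined)."""
    return local_pair_covariances(x, y).rho


def pearson_correlation(x, y) -> float:
    """Ordinary product-moment correlation; NaN when a series is constant."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"series lengths differ: {x.size} vs {y.size}")
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 trials, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(xc @ xc) * float(yc @ yc)
    if denom <= 0:
        return float("nan")
    return float(xc @ yc) / np.sqrt(denom)


def cross_correlogram(x, y, max_lag: int, method: Method = "proposed") -> Correlogram:
    """Trial-shifted correlogram: the estimate with ``y`` advanced by tau.

    At shift tau, ``x[t]`` is aligned with ``y[t + tau]`` over the
    overlapping segment (truncation, no wrap-around).  The shift grid
    steps by 2 for the pairwise estimator — shifting by an odd number of
    trials would scramble its pair structure — and by 1 for Pearson.
    Shifts with an overlap too short to estimate from yield NaN.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    n = x.size
    if max_lag < 0:
        raise ValueError("max_lag must be nonnegative")
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be smaller than series length {n}")
    if method == "proposed":
        step = 2
        max_lag -= max_lag % 2
        estimate = short_term_correlation
    elif method == "pearson":
        step = 1
        estimate = pearson_correlation
    else:
        raise ValueError(f"unknown method {method!r}")
    lags = np.arange(-max_lag, max_lag + 1, step)
    values = np.empty(lags.shape, dtype=np.float64)
    for i, tau in enumerate(lags):
        if tau >= 0:
            xs, ys = x[: n - tau] if tau else x, y[tau:]
        else:
            xs, ys = x[-tau:], y[:tau]
        try:
            values[i] = estimate(xs, ys)
        except InsufficientDataError:
            values[i] = np.nan
    return Correlogram(lags=lags, values=values, method=method)
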