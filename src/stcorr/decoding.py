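"""Population decoding of stimulus identity from per-trial firing rates.

A multi-class linear discriminant (pooled within-class covariance,
equal priors) classifies the 16 stimuli from the population rate
vector, session by session.  Four train/test schemes separate the
effects of slow baseline drift on decoder generalization:

``former_former``            leave-one-out within the first half of each
                             stimulus' trials (no drift across halves)
``former_latter``            train on the first half, test on the second
                             (a drifting baseline shifts the test data
                             away from the training distribution)
``former_latter_detrended``  as above, after per-period mean
                             subtraction (centering each half removes an
                             additive common drift)
``even_odd``                 train on even-numbered occurrences, test on
                             odd-numbered (interleaved, so both sets
                             sample the whole session)

Trial shuffling permutes each neuron's within-stimulus trial order
independently, preserving every single-neuron marginal while destroying
across-neuron simultaneity (and hence short-term noise correlations).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import (
    block_average,
    bonferroni_level,
    build_null_distribution,
    serial_correlation_test,
    short_term_test,
)
from .session import RateTable, RunConfig, SessionData, select_stimulus, to_rates
from ._rng import child_rng

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMES",
    "ClassificationResult",
    "split_by_scheme",
    "detrend_by_period_mean",
    "lda_fit",
    "lda_predict",
    "lda_decode",
    "decode_session",
    "trial_shuffle",
    "select_neurons",
    "tuning_curve_pca",
    "paired_rate_comparison",
]

SCHEMES = ("former_former", "former_latter", "former_latter_detrended", "even_odd")


@dataclass(frozen=True)
class ClassificationResult:
    scheme: str
    success_rate: float
    n_test_trials: int
    session_id: str = ""


def _occurrence_index(stimulus: np.ndarray) -> np.ndarray:
    """0-based occurrence rank of each trial within its stimulus."""
    occ = np.empty(stimulus.size, dtype=int)
    for label in np.unique(stimulus):
        idx = np.flatnonzero(stimulus == label)
        occ[idx] = np.arange(idx.size)
    return occ


def split_by_scheme(
    rates: RateTable, scheme: str
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-index masks (train, test) for a named scheme.

    ``former_former`` returns the former half for both masks; the
    leave-one-out rotation is handled by :func:`decode_session`.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    occ = _occurrence_index(rates.stimulus)
    counts = np.array(
        [np.sum(rates.stimulus == s) for s in np.unique(rates.stimulus)]
    )
    if np.any(counts % 2):
        raise ValueError("per-stimulus trial counts must be even")
    if np.any(counts < 4):
        raise ValueError("need at least 2 trials per stimulus per side")
    half = counts.min() // 2
    former = occ < half
    latter = ~former
    if scheme in ("former_latter", "former_latter_detrended"):
        return former, latter
    if scheme == "former_former":
        return former, former
    # even_odd: occurrences are 1-based in the experimental convention,
    # so even-numbered = occ 1, 3, ... (0-based odd) train, odd-numbered
    # = occ 0, 2, ... test.
    train = occ % 2 == 1
    return train, ~train


def detrend_by_period_mean(
    train_X: np.ndarray, test_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each period's own per-neuron grand mean (across all
    stimuli and trials of that period), equating the two periods' means
    and removing an additive common drift between them."""
    return (
        train_X - train_X.mean(axis=0, keepdims=True),
        test_X - test_X.mean(axis=0, keepdims=True),
    )


# ---------------------------------------------------------------------
# Linear discriminant analysis (pooled covariance, equal priors)
# ---------------------------------------------------------------------

def lda_fit(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit class means and a pooled within-class precision.

    The pooled covariance is regularized by ridge * (trace/p) * I; with
    ridge = 0 a singular covariance raises instructing ridge use.
    Returns (classes, class_means, precision).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    p = X.shape[1]
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    dof = 0
    for c, mu in zip(classes, means):
        Xc = X[y == c] - mu
        pooled += Xc.T @ Xc
        dof += Xc.shape[0] - 1
    if dof < 1:
        raise ValueError("need more than 1 training trial per class overall")
    pooled /= dof
    if ridge > 0:
        pooled = pooled + ridge * (np.trace(pooled) / p) * np.eye(p)
    elif np.linalg.matrix_rank(pooled) < p:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; pass ridge > 0 to regularize"
        )
    precision = np.linalg.inv(pooled)
    return classes, means, precision


def lda_predict(
    X: np.ndarray, classes: np.ndarray, means: np.ndarray, precision: np.ndarray
) -> np.ndarray:
    """Assign each row to the class with the largest discriminant score
    (equal priors)."""
    X = np.asarray(X, dtype=float)
    scores = X @ precision @ means.T - 0.5 * np.einsum(
        "ij,jk,ik->i", means, precision, means
    )
    return classes[np.argmax(scores, axis=1)]


def lda_decode(
    train_X, train_y, test_X, test_y, ridge: float = 1e-6
) -> ClassificationResult:
    """Train on (train_X, train_y), report accuracy on (test_X, test_y)."""
    classes, means, precision = lda_fit(train_X, train_y, ridge=ridge)
    pred = lda_predict(test_X, classes, means, precision)
    correct = int(np.sum(pred == np.asarray(test_y)))
    n = len(test_y)
    return ClassificationResult("custom", correct / n, n)


def decode_session(
    rates: RateTable,
    scheme: str,
    ridge: float = 1e-6,
    session_id: str = "",
) -> ClassificationResult:
    """Decode one session under a named train/test scheme."""
    train_mask, test_mask = split_by_scheme(rates, scheme)
    X, y = rates.rates, rates.stimulus
    if scheme == "former_former":
        # leave-one-out within the former half
        idx = np.flatnonzero(train_mask)
        correct = 0
        for hold in idx:
            keep = idx[idx != hold]
            classes, means, precision = lda_fit(X[keep], y[keep], ridge=ridge)
            pred = lda_predict(X[hold : hold + 1], classes, means, precision)
            correct += int(pred[0] == y[hold])
        return ClassificationResult(scheme, correct / idx.size, idx.size, session_id)
    train_X, test_X = X[train_mask], X[test_mask]
    if scheme == "former_latter_detrended":
        train_X, test_X = detrend_by_period_mean(train_X, test_X)
    res = lda_decode(train_X, y[train_mask], test_X, y[test_mask], ridge=ridge)
    return ClassificationResult(scheme, res.success_rate, res.n_test_trials, session_id)


# ---------------------------------------------------------------------
# Shuffling, selection, tuning-curve PCA, paired comparison
# ---------------------------------------------------------------------

def trial_shuffle(rates: RateTable, seed: int = 0) -> RateTable:
    """Independently permute each neuron's within-stimulus trial order.

    Per-neuron per-stimulus marginals are exactly preserved; only the
    across-neuron simultaneity (short-term correlation) is destroyed.
    """
    rng = child_rng(seed, "trial-shuffle")
    shuffled = rates.rates.copy()
    for label in np.unique(rates.stimulus):
        idx = np.flatnonzero(rates.stimulus == label)
        for j in range(rates.n_neurons):
            shuffled[idx, j] = shuffled[rng.permutation(idx), j]
    return RateTable(
        rates=shuffled,
        stimulus=rates.stimulus.copy(),
        duration=rates.duration.copy(),
        trial_index=rates.trial_index.copy(),
        neuron_ids=list(rates.neuron_ids),
    )


def select_neurons(
    session: SessionData,
    criterion: str,
    config: RunConfig,
) -> list[str]:
    """Select neurons free of long-term or short-term correlations.

    ``stationary``: keep neurons whose block-averaged rate series shows
    no significant lag-1 serial correlation at
    ``config.alpha_nonstationarity`` (uncorrected).
    ``no_short_term_pair``: keep neurons participating in no pair whose
    short-term correlation is significant at the Bonferroni level for
    any stimulus.
    """
    rates = to_rates(session)
    m = session.n_neurons
    if criterion == "stationary":
        keep = []
        for j in range(m):
            blocked = block_average(rates.rates[:, j], config.block_size)
            res = serial_correlation_test(
                blocked, alpha=config.alpha_nonstationarity
            )
            if res.defined and not res.significant:
                keep.append(session.neuron_ids[j])
        return keep
    if criterion == "no_short_term_pair":
        labels = session.stimulus_labels()
        level = bonferroni_level(
            m, n_stimuli=len(labels), base_alpha=config.alpha_pairwise_base
        )
        implicated = np.zeros(m, dtype=bool)
        null_cache: dict[int, object] = {}
        for label in labels:
            sub = select_stimulus(rates, label)
            n_used = 2 * (sub.n_trials // 2)
            if n_used not in null_cache:
                null_cache[n_used] = build_null_distribution(
                    n_used,
                    reps=config.monte_carlo_reps,
                    seed=config.seed,
                    cache_dir=config.cache_dir,
                )
            for i, j in itertools.combinations(range(m), 2):
                if implicated[i] and implicated[j]:
                    continue
                res = short_term_test(
                    sub.rates[:, i], sub.rates[:, j], null_cache[n_used], alpha=level
                )
                if res.defined and res.significant:
                    implicated[i] = implicated[j] = True
        return [session.neuron_ids[j] for j in range(m) if not implicated[j]]
    raise ValueError(f"unknown criterion {criterion!r}")


def tuning_curve_pca(
    rates: RateTable, half_size: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project former/latter-half tuning curves onto two principal axes.

    For each neuron and each session half, the mean response to every
    stimulus (the tuning curve) is computed; the neuron-half curves are
    stacked, centered (not variance-standardized, so weakly responsive
    neurons are not inflated), and projected onto the top two principal
    components.

    Returns (former_xy, latter_xy, components) with one row per neuron.
    """
    labels = np.sort(np.unique(rates.stimulus))
    occ = _occurrence_index(rates.stimulus)
    if half_size is None:
        half_size = min(int(np.sum(rates.stimulus == s)) for s in labels) // 2
    m = rates.n_neurons
    former = np.empty((m, labels.size))
    latter = np.empty((m, labels.size))
    for k, label in enumerate(labels):
        sel = rates.stimulus == label
        former[:, k] = rates.rates[sel & (occ < half_size)].mean(axis=0)
        latter[:, k] = rates.rates[sel & (occ >= half_size)].mean(axis=0)
    stacked = np.vstack([former, latter])
    centered = stacked - stacked.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("tuning curves are constant; principal axes undefined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    coords = centered @ vt[:2].T
    return coords[:m], coords[m:], vt[:2]


def paired_rate_comparison(rates_a, rates_b) -> dict:
    """Paired t test on matched per-session success rates."""
    a = np.asarray(rates_a, dtype=float).ravel()
    b = np.asarray(rates_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("session lists must be matched")
    if a.size < 2:
        raise ValueError("need at least 2 sessions")
    if np.allclose(a, b):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(a, b)
    return {
        "t": float(t_stat),
        "p_value": float(p),
        "mean_diff": float(np.mean(a - b)),
        "n_sessions": int(a.size),
    }
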