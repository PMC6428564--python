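"""Trial-structured session data model and delimited-text I/O.

A *session* is a sequence of trials in temporal order.  Each trial has a
stimulus label, a duration in seconds, and one spike count per recorded
neuron.  The reference experimental design presents 16 stimuli in 40
pseudo-random blocks (640 trials), with trial durations between 1.0 and
1.7 s; sessions of other shapes are accepted as long as the basic
invariants hold.

Files are tab-separated UTF-8 with a header line, one row per trial, and
neuron columns prefixed ``n`` (``n000``, ``n001``, ...).
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SessionData",
    "RateTable",
    "RunConfig",
    "SessionFormatError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "to_rates",
    "select_stimulus",
]

_META_COLUMNS = ("trial_index", "stimulus", "duration")


class SessionFormatError(ValueError):
    """A session file is structurally malformed (e.g. missing columns)."""


class SessionValidationError(ValueError):
    """Session contents violate an invariant (negative count, zero duration...)."""


def _as_trial_array(values, name: str, dtype) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise SessionValidationError(f"{name} must be one-dimensional")
    return arr.astype(dtype)


@dataclass
class SessionData:
    """Spike counts for one recording session.

    Attributes
    ----------
    counts:
        Integer matrix, trials x neurons, spikes per trial.
    stimulus:
        Per-trial stimulus label (integers or strings).
    duration:
        Per-trial stimulus duration in seconds.
    trial_index:
        Absolute temporal order of each trial within the session;
        strictly increasing.
    neuron_ids:
        Stable column identifiers, one per neuron.
    """

    counts: np.ndarray
    stimulus: np.ndarray
    duration: np.ndarray
    trial_index: np.ndarray
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise SessionValidationError("counts must be a trials x neurons matrix")
        self.counts = self.counts.astype(np.int64)
        self.stimulus = np.asarray(self.stimulus)
        self.duration = _as_trial_array(self.duration, "duration", np.float64)
        self.trial_index = _as_trial_array(self.trial_index, "trial_index", np.int64)
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:03d}" for i in range(self.counts.shape[1])]
        self.neuron_ids = list(self.neuron_ids)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        t, m = self.counts.shape
        for name in ("stimulus", "duration", "trial_index"):
            if len(getattr(self, name)) != t:
                raise SessionValidationError(
                    f"{name} has length {len(getattr(self, name))}, expected {t}"
                )
        if len(self.neuron_ids) != m:
            raise SessionValidationError(
                f"{len(self.neuron_ids)} neuron_ids for {m} neuron columns"
            )
        bad = np.argwhere(self.counts < 0)
        if bad.size:
            r, c = bad[0]
            raise SessionValidationError(f"negative spike count at row {r}, neuron {c}")
        bad_dur = np.flatnonzero(~(self.duration > 0))
        if bad_dur.size:
            raise SessionValidationError(
                f"nonpositive duration at row {int(bad_dur[0])}"
            )
        if t > 1 and not np.all(np.diff(self.trial_index) > 0):
            raise SessionValidationError("trial_index must be strictly increasing")

    # -- convenience ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.counts

    def stimulus_labels(self) -> np.ndarray:
        """Unique stimulus labels in order of first appearance."""
        _, first = np.unique(self.stimulus, return_index=True)
        return self.stimulus[np.sort(first)]

    def is_reference_design(self, n_stimuli: int = 16, n_repeats: int = 40) -> bool:
        """True if every consecutive block of ``n_stimuli`` trials presents
        each stimulus exactly once, ``n_repeats`` times over."""
        if self.n_trials != n_stimuli * n_repeats:
            return False
        labels = np.unique(self.stimulus)
        if len(labels) != n_stimuli:
            return False
        blocks = self.stimulus.reshape(n_repeats, n_stimuli)
        return all(len(np.unique(b)) == n_stimuli for b in blocks)


@dataclass
class RateTable:
    """Firing rates (spikes/s) with the same per-trial metadata as
    :class:`SessionData`; ``rates[t, i] = counts[t, i] / duration[t]``."""

    rates: np.ndarray
    stimulus: np.ndarray
    duration: np.ndarray
    trial_index: np.ndarray
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.ndim != 2:
            raise SessionValidationError("rates must be a trials x neurons matrix")
        if np.any(self.rates < 0):
            raise SessionValidationError("rates must be nonnegative")
        self.stimulus = np.asarray(self.stimulus)
        self.duration = _as_trial_array(self.duration, "duration", np.float64)
        self.trial_index = _as_trial_array(self.trial_index, "trial_index", np.int64)
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:03d}" for i in range(self.rates.shape[1])]
        self.neuron_ids = list(self.neuron_ids)

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.rates

    def stimulus_labels(self) -> np.ndarray:
        _, first = np.unique(self.stimulus, return_index=True)
        return self.stimulus[np.sort(first)]


@dataclass
class RunConfig:
    """Analysis-wide configuration; the single source of every seed."""

    seed: int = 0
    alpha_nonstationarity: float = 0.01
    alpha_pairwise_base: float = 0.01
    monte_carlo_reps: int = 1_000_000
    block_size: int = 16
    n_stimuli: int = 16
    cache_dir: str | None = None
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("alpha_nonstationarity", "alpha_pairwise_base"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.monte_carlo_reps < 1:
            raise ValueError("monte_carlo_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def read_session(path: str | Path, sep: str = "\t") -> SessionData:
    """Read a session TSV into a validated :class:`SessionData`.

    Required columns: ``trial_index``, ``stimulus``, ``duration`` and at
    least one neuron column (prefix ``n``).  Rows are sorted by
    ``trial_index`` before validation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing required columns {missing}")
    neuron_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not neuron_cols:
        raise SessionFormatError(f"{path}: no neuron columns found")
    df = df.sort_values("trial_index", kind="stable").reset_index(drop=True)
    counts = df[neuron_cols].to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise SessionFormatError(f"{path}: neuron columns must be integer counts")
    return SessionData(
        counts=counts.astype(np.int64),
        stimulus=df["stimulus"].to_numpy(),
        duration=df["duration"].to_numpy(dtype=float),
        trial_index=df["trial_index"].to_numpy(dtype=int),
        neuron_ids=neuron_cols,
    )


def write_session(session: SessionData, path: str | Path, sep: str = "\t") -> Path:
    """Write a session as TSV; ``read_session`` round-trips it exactly."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "trial_index": session.trial_index,
            "stimulus": session.stimulus,
            "duration": session.duration,
        }
    )
    for j, nid in enumerate(session.neuron_ids):
        df[nid] = session.counts[:, j]
    # str() of a Python float is its shortest exact decimal representation,
    # so durations survive the round trip bit-for-bit.
    df.to_csv(path, sep=sep, index=False)
    return path


def to_rates(session: SessionData) -> RateTable:
    """Convert spike counts to firing rates (count / trial duration)."""
    rates = session.counts / session.duration[:, None]
    return RateTable(
        rates=rates,
        stimulus=session.stimulus.copy(),
        duration=session.duration.copy(),
        trial_index=session.trial_index.copy(),
        neuron_ids=list(session.neuron_ids),
    )


def select_stimulus(source: SessionData | RateTable, stimulus):
    """Restrict a session (counts or rates) to the trials of one stimulus.

    The returned object preserves the original temporal order, so
    consecutive rows are consecutive *occurrences* of that stimulus.
    Raises ``KeyError`` for an unknown label.
    """
    mask = source.stimulus == stimulus
    if not mask.any():
        raise KeyError(f"stimulus {stimulus!r} not present in session")
    kwargs = dict(
        stimulus=source.stimulus[mask],
        duration=source.duration[mask],
        trial_index=source.trial_index[mask],
        neuron_ids=list(source.neuron_ids),
    )
    if isinstance(source, SessionData):
        return SessionData(counts=source.counts[mask], **kwargs)
    return RateTable(rates=source.rates[mask], **kwargs)
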