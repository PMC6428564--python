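import numpy as np
import pytest

from stcorr.session import SessionData
from stcorr.simulate import (
    SessionSpec,
    circular_gaussian_tuning,
    simulate_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_session():
    """2 neurons, 4 trials, 2 stimuli — small enough to check by hand."""
    return SessionData(
        counts=np.array([[3, 1], [5, 2], [4, 0], [6, 3]]),
        stimulus=np.array([0, 1, 0, 1]),
        duration=np.array([1.0, 1.25, 1.5, 1.7]),
        trial_index=np.array([0, 1, 2, 3]),
        neuron_ids=["n000", "n001"],
    )


@pytest.fixture(scope="session")
def reference_session():
    """A full 640-trial, 8-neuron session in the reference block design."""
    tuning = circular_gaussian_tuning(8, seed=3)
    return simulate_session(SessionSpec(tuning=tuning), seed=11)
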