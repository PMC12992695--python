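import numpy as np
import pytest

from locostate.io import EventTable, MarkerTrajectories, NeuralRecording
from locostate.synthetic import CohortSpec, generate_session


@pytest.fixture(scope="session")
def rodent_session():
    """One seeded synthetic lesioned-rat session (trajectories, neural, events)."""
    spec = CohortSpec(run_duration=20.0, seed=7)
    return generate_session(spec, group="lesioned", seed=7)


@pytest.fixture
def simple_trajectory():
    """Three markers moving at constant velocity along +x, 200 Hz."""
    n = 100
    t = np.arange(n) / 200.0
    pos = np.zeros((n, 3, 3))
    for j, z in enumerate((0.0, 10.0, 20.0)):
        pos[:, j, 0] = 300.0 * t
        pos[:, j, 2] = z
    return MarkerTrajectories(["a", "b", "toe"], pos, 200.0, run_id="r1",
                              subject_id="s1", day_id="d1")


def make_events(events, duration, vocabulary=("gait", "stationary", "akinesia")):
    return EventTable(list(events), duration, vocabulary)


def make_recording(signal, fs, names=None, hemis=None):
    signal = np.atleast_2d(signal)
    names = names or [f"ch{i}" for i in range(signal.shape[0])]
    hemis = hemis or (["left", "right"] * signal.shape[0])[: signal.shape[0]]
    return NeuralRecording(names, signal, fs, hemis, run_id="r1")
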