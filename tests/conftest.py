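import numpy as np
import pytest

from edlds.model import EpochSchedule
from edlds.session import SessionData, Task, TrialMeta, TrialType, UnitMeta
from edlds.simulate import SimConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_schedule():
    """Four epochs over 12 bins: sizes 3, 3, 4, 2."""
    return EpochSchedule((2, 5, 9, 11))


@pytest.fixture(scope="session")
def sim_session():
    """One mid-sized synthetic session shared by read-only tests."""
    cfg = SimConfig(seed=7, n_units_range=(10, 14), n_trials=120)
    return generate_session(cfg, 777)


def make_spike_session(n_trials=4, n_units=3, seed=0, task=Task.pole):
    """A tiny session with explicit spike times for binning tests."""
    rng = np.random.default_rng(seed)
    dur = {"pole": 4.4, "sound": 5.15}[task.value]
    t0 = -(dur - 1.0)
    spikes, trials, epochs = [], [], []
    for i in range(n_trials):
        spikes.append([np.sort(rng.uniform(t0, 1.0, size=rng.integers(5, 40)))
                       for _ in range(n_units)])
        trials.append(TrialMeta(trial_index=i,
                                trial_type=TrialType.contra if i % 2 else TrialType.ipsi,
                                correct=True))
        epochs.append([t0, t0 + 0.8, t0 + 2.1, 0.0] if task is Task.pole
                      else [t0, t0 + 0.8, t0 + 1.95, 0.0])
    return SessionData(session_id="toy", task=task,
                       units=[UnitMeta(f"u{j}") for j in range(n_units)],
                       trials=trials, epoch_times=np.array(epochs),
                       spikes=spikes)
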