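import numpy as np
import pytest

from adlkin.synthetic import GroupTaskParams, SimulationConfig, GROUPS, TASKS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def quick_cell(**overrides) -> GroupTaskParams:
    """A short, fast cell for structural tests (not the shipped calibration)."""
    kwargs = dict(
        burst_rate=1.0,
        burst_duration=(0.8, 0.2),
        burst_peak_amp=(1.0, 0.3),
        pause_fraction=0.3,
        trial_duration=(20.0, 2.0),
        noise_sd=0.05,
        orientation_wobble=0.05,
    )
    kwargs.update(overrides)
    return GroupTaskParams(**kwargs)


def quick_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A config with the same quick cell in all six group×task slots."""
    cell = quick_cell(**overrides)
    return SimulationConfig(
        params={(g, t): cell for g in GROUPS for t in TASKS}, seed=seed
    )


@pytest.fixture
def quick_sim():
    return quick_config()
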