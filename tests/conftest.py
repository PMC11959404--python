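import numpy as np
import pytest

from mvgt.simulate import SimulationConfig


def make_config(**overrides) -> SimulationConfig:
    """A moderately sized continuous crossed-design config."""
    defaults = dict(
        n_trainees=30,
        n_procedures=8,
        sigma_t=np.diag([0.06, 0.09, 0.03, 0.10]) + 0.02,
        sigma_p=np.diag([0.04, 0.08, 0.01, 0.02]),
        sigma_tp=np.diag([0.32, 0.31, 0.22, 0.15]) + 0.05,
        grand_means=[2.4, 2.3, 3.0, 2.7],
        seed=1,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def config_factory():
    return make_config


@pytest.fixture
def small_table():
    from mvgt.simulate import generate_dataset

    return generate_dataset(make_config())
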