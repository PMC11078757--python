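import numpy as np
import pytest

from deerfret import (
    GaussianComponent,
    MixtureModel,
    default_distance_axis,
    default_time_axis,
)


@pytest.fixture(scope="session")
def time_axis():
    return default_time_axis()


@pytest.fixture(scope="session")
def dist_axis():
    return default_distance_axis()


@pytest.fixture(scope="session")
def single_component_model():
    """One Gaussian at 33 A (sigma 3), depth 0.5, 50 uM."""
    return MixtureModel(
        components=[GaussianComponent(33.0, 3.0)],
        populations={"cond": np.array([1.0])},
        modulation_depths={"cond": 0.5},
        concentrations={"grp": 50.0},
        condition_groups={"cond": "grp"},
    )
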