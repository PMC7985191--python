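import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from emdamage.synthetic import ToyComplexSpec, build_toy_model, simulate_map


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec()


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    return build_toy_model(toy_spec)


@pytest.fixture(scope="session")
def toy_map(toy_spec, toy_model):
    """Noise-free Gaussian-atom map of the toy complex."""
    return simulate_map(
        toy_model, toy_spec.grid_shape, toy_spec.voxel_size
    )


@pytest.fixture(scope="session")
def cluster_fragment(toy_model):
    idx = [
        i for i, a in enumerate(toy_model) if a.resname in ("OEC", "HOH")
    ]
    return toy_model.subset(idx)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
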