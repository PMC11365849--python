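import numpy as np
import pytest

from sinussl.phantoms import PhantomParams, generate_anomalous_volume, generate_normal_volume
from sinussl.preprocess import MSVolume


@pytest.fixture(scope="session")
def small_params():
    """16-voxel phantom parameters used across fast unit tests."""
    return PhantomParams(cube_edge=16, seed=0)


@pytest.fixture(scope="session")
def normal_sample(small_params):
    return generate_normal_volume(small_params)


@pytest.fixture(scope="session")
def anomalous_sample(small_params):
    return generate_anomalous_volume(small_params)


def make_labelled_volumes(n_normal: int, n_anomalous: int, edge: int = 16,
                          seed: int = 0) -> list[MSVolume]:
    """Small labelled phantom set with one volume per synthetic patient."""
    out = []
    for i in range(n_normal):
        p = PhantomParams(cube_edge=edge, seed=seed * 10_000 + i)
        out.append(generate_normal_volume(p).volume)
    for i in range(n_anomalous):
        p = PhantomParams(cube_edge=edge, seed=seed * 10_000 + 5000 + i)
        out.append(generate_anomalous_volume(p).volume)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
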