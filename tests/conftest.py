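import numpy as np
import pytest

from croplab.simulate import (
    KHABAROVSKIY_PROFILES,
    SimulationConfig,
    generate_scene,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """Compact multi-look scene shared by pipeline tests: 2 fields/class, 10x10 px."""
    config = SimulationConfig(
        field_counts={"train": {"fallow": 2, "soybean": 2, "oat": 2}},
        field_shape=(10, 10),
        n_looks=100,
    )
    return generate_scene(config, KHABAROVSKIY_PROFILES, seed=0)


def random_psd_c2(rng, n):
    """Random 2x2 Hermitian PSD matrices built as A A^H (guaranteed PSD)."""
    a = rng.normal(size=(n, 2, 2)) + 1j * rng.normal(size=(n, 2, 2))
    mats = a @ a.conj().transpose(0, 2, 1)
    return mats
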