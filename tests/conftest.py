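import numpy as np
import pytest

from annosim import (InstanceMask, PhantomConfig, SurrogateQuality, Volume,
                     generate_phantom_dataset, surrogate_factory)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_tumor_dataset():
    """Five small tumor-like phantoms shared across tests (read-only)."""
    cfg = PhantomConfig(n_volumes=5, task="tumor", grid_shape=(24, 72, 72),
                        spacing_mm=(1.5, 0.8, 0.8), objects_per_volume=(1, 3),
                        object_radius_mm=(5.0, 10.0), contrast=0.35,
                        noise_sd=0.05, seed=11)
    return generate_phantom_dataset(cfg)


@pytest.fixture(scope="session")
def default_factory():
    return surrogate_factory(SurrogateQuality(seed=21))


@pytest.fixture(scope="session")
def perfect_factory():
    return surrogate_factory(SurrogateQuality.perfect(seed=22))


def make_volume(intensities, spacing=(1.0, 1.0, 1.0), axis=0):
    return Volume(intensities=np.asarray(intensities, dtype=np.float64),
                  spacing=spacing, slicing_axis=axis)


def make_mask(labels, spacing=(1.0, 1.0, 1.0), axis=0):
    return InstanceMask(labels=np.asarray(labels, dtype=np.int32),
                        spacing=spacing, slicing_axis=axis)
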