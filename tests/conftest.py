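import numpy as np
import pytest

from sphereloc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_cache():
    """Session cache of noise-free phantoms keyed by voxel size (seed 0)."""
    cache = {}

    def get(voxel_size: float):
        if voxel_size not in cache:
            spec = PhantomSpec(voxel_size=voxel_size, noise_sd=0.0, seed=0)
            cache[voxel_size] = generate_phantom(spec)
        return cache[voxel_size]

    return get


@pytest.fixture(scope="session")
def phantom_1mm(phantom_cache):
    """Standard 5-marker noise-free phantom at 1 mm isotropic voxels."""
    return phantom_cache(1.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact 2-marker phantom for fast unit tests."""
    spec = PhantomSpec(
        voxel_size=1.0, n_markers=2, noise_sd=0.0, seed=3,
        size_mm=80.0, head_semiaxes=(14.0, 12.0, 10.0),
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
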