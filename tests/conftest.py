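import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from octpt import phantom as ph

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_images(n: int, preset, seed: int, size: int = 64):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = ph.sample_phantom_spec(rng, size, size)
        refl = ph.make_reflectivity_map(spec)
        out.append(ph.simulate_bscan(refl, preset,
                                     int(rng.integers(0, 2 ** 31 - 1)),
                                     source_id=f"{preset.name}_{i}"))
    return out


@pytest.fixture(scope="session")
def image_factory():
    """Factory for phantom image sets: (n, preset, seed, size) -> images."""
    return make_images


@pytest.fixture(scope="session")
def tiny_sets():
    """8 images per preset at 32x32 for smoke runs."""
    return (make_images(8, ph.MACULAR_CUBE, seed=7, size=32),
            make_images(8, ph.SEVEN_LINES, seed=8, size=32))
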