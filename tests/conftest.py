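import numpy as np
import pytest

from pssahcs import HyperspectralCube, generate_cube, tea_like_spec


def make_cube(rng: np.random.Generator, a=12, b=14, c=3, n_bits=12) -> HyperspectralCube:
    """Small random integer cube for formula-level tests."""
    data = rng.integers(0, 2**n_bits, size=(a, b, c), dtype=np.uint16)
    return HyperspectralCube(data=data, bit_depth=n_bits)


@pytest.fixture(scope="session")
def small_tea():
    """One 64x64x12 leaf-scene cube with planted structure (seed 3)."""
    return generate_cube(tea_like_spec(a=64, b=64, c=12, seed=3))


@pytest.fixture(scope="session")
def full_tea():
    """The default 128x256x40 leaf-scene preset (seed 1)."""
    return generate_cube(tea_like_spec(seed=1))
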