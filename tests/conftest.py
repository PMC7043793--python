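import numpy as np
import pytest

from quantkit.synthetic_data import LatticeSpec, generate_eye_image, hex_lattice_sites


@pytest.fixture(scope="session")
def perfect_lattice_sites():
    """Ideal 10x10 hexagonal lattice coordinates, spacing 20 px."""
    return hex_lattice_sites(LatticeSpec(seed=0))


@pytest.fixture(scope="session")
def zero_jitter_eye():
    """Noiseless-lattice eye image plus its ground-truth centers."""
    spec = LatticeSpec(seed=7)
    image, centers = generate_eye_image(spec)
    return spec, image, centers


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
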