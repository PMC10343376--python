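import numpy as np
import pytest

from xbir3.pb import PBGridSpec
from xbir3.synthetic import EnsembleRecipe, make_ensemble, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Small parameterized receptor–ligand complex (4 residues, 2 groups)."""
    return make_toy_complex(4, seed=1)


@pytest.fixture(scope="session")
def toy_trajectory(toy_complex):
    """Short fluctuating ensemble over the toy complex."""
    return make_ensemble(EnsembleRecipe(toy_complex, sigma=0.1, n_frames=3, seed=2))


@pytest.fixture(scope="session")
def fast_pb_spec():
    """Coarse-but-valid PB grid settings for test-speed solves."""
    return PBGridSpec(spacing=0.8, padding=8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pair_system(rng, n_a=15, n_b=15, spread=8.0, min_sep=1.5):
    """Random charges/LJ params and well-separated coordinate sets."""
    coords_a = rng.uniform(-spread, 0.0, (n_a, 3)) - [min_sep, 0, 0]
    coords_b = rng.uniform(0.0, spread, (n_b, 3)) + [min_sep, 0, 0]
    qa = rng.uniform(-0.8, 0.8, n_a)
    qb = rng.uniform(-0.8, 0.8, n_b)
    ea = rng.uniform(0.05, 0.3, n_a)
    eb = rng.uniform(0.05, 0.3, n_b)
    ra = rng.uniform(1.2, 2.2, n_a)
    rb = rng.uniform(1.2, 2.2, n_b)
    return (qa, ea, ra, coords_a), (qb, eb, rb, coords_b)
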