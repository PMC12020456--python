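import numpy as np
import pytest

from dracopcm import FixtureSpec, load_parameters, random_molecule, water_like


@pytest.fixture(scope="session")
def params():
    """Shipped defaults: water-like dielectric, isogrid 194."""
    return load_parameters()


@pytest.fixture(scope="session")
def params_small(params):
    """Coarse grid for cheap cavity-heavy checks."""
    return load_parameters(overrides={"n_leb": 50})


@pytest.fixture(scope="session")
def water(params):
    return water_like()


@pytest.fixture
def cluster():
    """Factory for seeded random clusters."""

    def make(seed, n_atoms=5, **kw):
        return random_molecule(FixtureSpec(seed=seed, n_atoms=n_atoms, **kw))

    return make


def fd4(f, mol, delta=5.0e-3):
    """Four-point central difference of a scalar or vector function of the
    geometry; returns (..., N, 3).  Independent of the library's own
    numerical_gradient implementation."""
    n = mol.n_atoms
    probe = np.atleast_1d(np.asarray(f(mol), dtype=float))
    out = np.zeros(probe.shape + (n, 3))
    for a in range(n):
        for c in range(3):
            e = np.zeros(3)
            e[c] = delta
            fp2 = np.atleast_1d(f(mol.displaced(a, 2 * e)))
            fp1 = np.atleast_1d(f(mol.displaced(a, e)))
            fm1 = np.atleast_1d(f(mol.displaced(a, -e)))
            fm2 = np.atleast_1d(f(mol.displaced(a, -2 * e)))
            out[..., a, c] = (-fp2 + 8 * fp1 - 8 * fm1 + fm2) / (12 * delta)
    return out
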