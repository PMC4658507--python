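import numpy as np
import pytest

from nucdyn.core import MolecularSystem
from nucdyn.synthetic import ToySpec, build_toy_nucleosome


def make_system(coords, names=None, elements=None, resnums=None,
                resnames=None, chains=None, masses=None):
    """Hand-build a small MolecularSystem for unit tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    names = np.asarray(names if names is not None else [f"C{i}" for i in range(n)],
                       dtype=object)
    elements = np.asarray(elements if elements is not None else ["C"] * n,
                          dtype=object)
    resnums = np.asarray(resnums if resnums is not None else np.arange(1, n + 1),
                         dtype=int)
    resnames = np.asarray(resnames if resnames is not None else ["ALA"] * n,
                          dtype=object)
    chains = np.asarray(chains if chains is not None else ["A"] * n, dtype=object)
    masses = np.asarray(masses if masses is not None else [12.011] * n,
                        dtype=float)
    return MolecularSystem(atom_names=names, elements=elements,
                           residue_numbers=resnums, residue_names=resnames,
                           chain_ids=chains, masses=masses,
                           reference_coords=coords)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_protein():
    """Two short protein chains, no DNA."""
    spec = ToySpec(chains=[("H3-like", 30), ("H4", 20)], seed=11)
    return build_toy_nucleosome(spec)


@pytest.fixture
def toy_nucleosome():
    """Four-chain half core plus a 41-bp DNA duplex."""
    spec = ToySpec(chains=[("H3-like", 40), ("H4", 30), ("H2A", 30),
                           ("H2B", 30), ("DNA-I", 41), ("DNA-J", 41)], seed=11)
    return build_toy_nucleosome(spec)


@pytest.fixture
def toy_octamer():
    """All eight histone roles plus DNA (small chains, report-level tests)."""
    spec = ToySpec(chains=[("H3-like", 40), ("H4", 30), ("H2A", 30),
                           ("H2B", 30), ("H3-like'", 40), ("H4'", 30),
                           ("H2A'", 30), ("H2B'", 30),
                           ("DNA-I", 41), ("DNA-J", 41)], seed=11)
    return build_toy_nucleosome(spec)
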