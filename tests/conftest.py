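"""Shared fixtures: small synthetic structures and force-trace generators."""

import numpy as np
import pytest

from smdfan.structure import AtomRecord, Structure


def make_two_chain_structure(n_per_chain: int = 6, separation: float = 10.0,
                             seed: int = 0) -> Structure:
    """Two compact chains (A and B) separated along z; CA beads only."""
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    for chain, z0 in (("A", 0.0), ("B", separation)):
        for i in range(n_per_chain):
            x, y, z = rng.normal(scale=1.5, size=3)
            atoms.append(AtomRecord(
                serial=serial, name="CA", resname="GLY", chain=chain,
                resseq=i + 1, x=round(x, 3), y=round(y, 3),
                z=round(z + z0, 3), occupancy=1.0, beta=0.0,
                element="C", mass=12.011))
            serial += 1
    return Structure(atoms=atoms, title="two-chain fixture")


@pytest.fixture
def two_chain():
    return make_two_chain_structure()


@pytest.fixture
def toy_complex():
    from smdfan.toysim import make_anisotropic_complex
    return make_anisotropic_complex(seed=0)


def random_unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
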