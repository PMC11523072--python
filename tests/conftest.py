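import numpy as np
import pytest

from macronoe.molsys import MoleculeGraph
from macronoe.noe import ConformerEnsemble
from macronoe.synth import SynthSpec, make_toy_macrocycle, sample_ensemble


def ring_graph(n, element="C"):
    """Plain n-membered ring of one element."""
    atoms = [(i, element, f"{element}{i + 1}") for i in range(n)]
    bonds = [(i, (i + 1) % n) for i in range(n)]
    return MoleculeGraph(atoms, bonds)


@pytest.fixture
def ring15():
    return ring_graph(15)


@pytest.fixture
def ring15_tail():
    """15-ring with a 3-carbon exocyclic tail on atom 0."""
    atoms = [(i, "C", f"C{i + 1}") for i in range(15)]
    bonds = [(i, (i + 1) % 15) for i in range(15)]
    for k in range(3):
        atoms.append((15 + k, "C", f"CT{k + 1}"))
        bonds.append((14 + k if k else 0, 15 + k))
    bonds[15] = (0, 15)  # tail root on ring atom 0
    bonds[16] = (15, 16)
    bonds[17] = (16, 17)
    return MoleculeGraph(atoms, bonds)


@pytest.fixture
def methane():
    """One carbon with 3 H and 1 extra H (methyl-like probe for hydrogens_of)."""
    atoms = [(0, "C", "C1"), (1, "H", "H1"), (2, "H", "H2"), (3, "H", "H3")]
    bonds = [(0, 1), (0, 2), (0, 3)]
    return MoleculeGraph(atoms, bonds)


@pytest.fixture
def synth_spec():
    return SynthSpec(seed=42)


@pytest.fixture
def toy_macrocycle(synth_spec):
    graph, templates = make_toy_macrocycle(synth_spec)
    return graph, templates


@pytest.fixture
def small_ensemble(synth_spec):
    ens, labels = sample_ensemble(synth_spec, 40)
    return ens, labels


def random_ensemble(rng, n_frames=4, n_atoms=6, scale=0.4):
    """Random coordinates with a minimum inter-atom distance floor."""
    while True:
        coords = rng.uniform(-scale, scale, size=(n_frames, n_atoms, 3))
        d = coords[:, :, None, :] - coords[:, None, :, :]
        dist = np.sqrt((d ** 2).sum(-1))
        np.einsum("fii->fi", dist)[:] = 1.0
        if dist.min() > 0.05:
            return ConformerEnsemble(coords)
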