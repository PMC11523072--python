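"""Molecular graph model: rings, alignment, hydrogen expansion, regions."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macronoe.molsys import (MoleculeGraph, bond_separation, classify_region,
                             detect_macrocycle, hydrogens_of, load_structure,
                             map_graphs, save_structure)

from conftest import ring_graph


def brute_force_rings(graph):
    """All simple cycles by DFS enumeration (independent of networkx SSSR)."""
    adj = {a.index: set() for a in graph.atoms}
    for b in graph.bonds:
        i, j = tuple(b)
        adj[i].add(j)
        adj[j].add(i)
    cycles = set()

    def dfs(start, node, path):
        for nxt in adj[node]:
            if nxt == start and len(path) >= 3:
                cycles.add(frozenset(path))
            elif nxt not in path and nxt > start:
                dfs(start, nxt, path + [nxt])

    for s in adj:
        dfs(s, s, [s])
    return cycles


class TestDetectMacrocycle:
    def test_simple_15_ring_is_fully_macrocyclic(self, ring15):
        assert detect_macrocycle(ring15) == set(range(15))

    def test_benzene_sized_ring_is_not_macrocyclic(self):
        assert detect_macrocycle(ring_graph(6)) == set()

    def test_tail_atoms_excluded(self, ring15_tail):
        # oracle: enumerate all simple cycles; only the 15-ring exists
        cycles = brute_force_rings(ring15_tail)
        big = set().union(*(c for c in cycles if len(c) >= 12))
        assert big == set(range(15))
        assert detect_macrocycle(ring15_tail) == big

    def test_threshold_is_inclusive(self):
        g = ring_graph(12)
        assert detect_macrocycle(g, min_size=12) == set(range(12))
        assert detect_macrocycle(g, min_size=13) == set()

    def test_disconnected_graph_reports_components(self):
        atoms = [(0, "C", "a"), (1, "C", "b"), (2, "C", "c"), (3, "C", "d")]
        g = MoleculeGraph(atoms, [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="components"):
            detect_macrocycle(g)

    def test_invariant_under_reindexing(self, synth_spec):
        from macronoe.synth import make_toy_macrocycle
        graph, _ = make_toy_macrocycle(synth_spec)
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(graph))
        inv = np.argsort(perm)
        atoms = [(i, graph.atoms[perm[i]].element, graph.atoms[perm[i]].name)
                 for i in range(len(graph))]
        bonds = [(inv[a], inv[b]) for a, b in (tuple(x) for x in graph.bonds)]
        permuted = MoleculeGraph(atoms, bonds)
        expected = {int(inv[i]) for i in detect_macrocycle(graph)}
        assert detect_macrocycle(permuted) == expected


class TestMapGraphs:
    def test_identity_on_self(self, ring15_tail):
        m = map_graphs(ring15_tail, ring15_tail)
        assert m.permutation == tuple(range(len(ring15_tail)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_seeded_permutation_small(self, seed):
        # propane-ish chain C-C-C with distinct elements to pin the mapping
        atoms = [(0, "C", "C1"), (1, "N", "N1"), (2, "O", "O1"), (3, "C", "C2")]
        bonds = [(0, 1), (1, 2), (2, 3)]
        a = MoleculeGraph(atoms, bonds)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(4)
        inv = np.argsort(perm)
        b = MoleculeGraph(
            [(i, a.atoms[perm[i]].element, a.atoms[perm[i]].name) for i in range(4)],
            [(inv[i], inv[j]) for i, j in bonds])
        m = map_graphs(a, b)
        # brute-force oracle: search all element/bond-preserving bijections
        valid = []
        for p in itertools.permutations(range(4)):
            if all(a.atoms[i].element == b.atoms[p[i]].element for i in range(4)):
                if all(frozenset((p[i], p[j])) in b.bonds
                       for i, j in (tuple(x) for x in a.bonds)):
                    valid.append(p)
        assert m.permutation == min(valid)

    def test_element_mismatch_raises(self):
        ethane = MoleculeGraph([(0, "C", "C1"), (1, "C", "C2")], [(0, 1)])
        cn = MoleculeGraph([(0, "C", "C1"), (1, "N", "N1")], [(0, 1)])
        with pytest.raises(ValueError, match="multiset"):
            map_graphs(ethane, cn)

    def test_non_isomorphic_same_elements_raises(self):
        chain = MoleculeGraph([(i, "C", f"C{i}") for i in range(4)],
                              [(0, 1), (1, 2), (2, 3)])
        star = MoleculeGraph([(i, "C", f"C{i}") for i in range(4)],
                             [(0, 1), (0, 2), (0, 3)])
        with pytest.raises(ValueError, match="isomorphic"):
            map_graphs(chain, star)

    def test_roundtrip_composes_to_automorphism(self, ring15_tail):
        a = ring15_tail
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(a))
        inv = np.argsort(perm)
        b = MoleculeGraph(
            [(i, a.atoms[perm[i]].element, a.atoms[perm[i]].name)
             for i in range(len(a))],
            [(inv[i], inv[j]) for i, j in (tuple(x) for x in a.bonds)])
        ab = map_graphs(a, b)
        ba = map_graphs(b, a)
        comp = tuple(ba[ab[i]] for i in range(len(a)))
        # composition is an automorphism of a: preserves elements and bonds
        assert all(a.atoms[i].element == a.atoms[comp[i]].element
                   for i in range(len(a)))
        assert all(frozenset((comp[i], comp[j])) in a.bonds
                   for i, j in (tuple(x) for x in a.bonds))


class TestHydrogensOf:
    def test_methyl_carbon_has_three(self, methane):
        assert hydrogens_of(methane, 0) == [1, 2, 3]

    def test_bare_atom_has_none(self, ring15):
        assert hydrogens_of(ring15, 0) == []

    def test_single_hydrogen(self):
        g = MoleculeGraph([(0, "N", "N1"), (1, "H", "HN")], [(0, 1)])
        assert hydrogens_of(g, 0) == [1]

    def test_querying_a_hydrogen_raises(self, methane):
        with pytest.raises(ValueError, match="hydrogen"):
            hydrogens_of(methane, 1)


class TestBondSeparation:
    def test_basic_distances(self, methane):
        assert bond_separation(methane, 0, 1) == 1
        assert bond_separation(methane, 1, 2) == 2  # H-C-H
        assert bond_separation(methane, 1, 1) == 0

    def test_disconnected_raises(self):
        g = MoleculeGraph([(0, "C", "a"), (1, "C", "b"),
                           (2, "C", "c"), (3, "C", "d")], [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="disconnected"):
            bond_separation(g, 0, 2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_properties_on_random_trees_plus_edges(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        atoms = [(i, "C", f"C{i}") for i in range(n)]
        bonds = {(int(rng.integers(0, i)), i) for i in range(1, n)}  # random tree
        for _ in range(2):  # a couple of extra edges
            i, j = sorted(rng.choice(n, 2, replace=False))
            bonds.add((int(i), int(j)))
        g = MoleculeGraph(atoms, list(bonds))
        idx = rng.choice(n, 3, replace=True)
        i, j, k = (int(x) for x in idx)
        dij = bond_separation(g, i, j)
        assert dij == bond_separation(g, j, i)
        assert dij + bond_separation(g, j, k) >= bond_separation(g, i, k)
        assert (dij == 0) == (i == j)


class TestClassifyRegion:
    def test_three_way_classification(self, ring15_tail):
        macro = detect_macrocycle(ring15_tail)
        assert classify_region(ring15_tail, (0, 5), macro) == "macrocyclic"
        assert classify_region(ring15_tail, (15, 17), macro) == "extracyclic"
        assert classify_region(ring15_tail, (0, 16), macro) == "mixed"

    def test_invalid_anchor_raises(self, ring15_tail):
        with pytest.raises(ValueError, match="anchor"):
            classify_region(ring15_tail, (0, 99), set(range(15)))


def test_structure_json_roundtrip(tmp_path, ring15_tail):
    path = tmp_path / "structure.json"
    save_structure(ring15_tail, path)
    loaded = load_structure(path)
    assert [(a.index, a.element, a.name) for a in loaded.atoms] == \
        [(a.index, a.element, a.name) for a in ring15_tail.atoms]
    assert loaded.bonds == ring15_tail.bonds
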