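"""Molecular graphs for NOE restraint bookkeeping.

A :class:`MoleculeGraph` is the structural frame used throughout the
package: it knows atoms (index, element, name), bonds, which hydrogens
are equivalent (attached to the same heavy atom, e.g. a methyl group),
and which atoms belong to the macrocyclic ring. Coordinates live
elsewhere (:class:`macronoe.noe.ConformerEnsemble`); the graph is pure
connectivity.

Atom order differs between force-field topologies of the same compound,
so restraint assignments made on one topology are transferred to another
by aligning the molecular graphs (:func:`map_graphs`).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Atom",
    "MoleculeGraph",
    "AtomMapping",
    "detect_macrocycle",
    "map_graphs",
    "hydrogens_of",
    "bond_separation",
    "classify_region",
    "load_structure",
    "save_structure",
]

#: Upper bound on isomorphisms enumerated when searching for the
#: lexicographically smallest atom mapping. Methyl rotations and
#: prochiral swaps generate only small automorphism groups, so
#: realistic molecules stay far below this.
_MAX_ISOMORPHISMS = 20000


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    name: str

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


class MoleculeGraph:
    """Atoms + bonds + hydrogen equivalence groups.

    Parameters
    ----------
    atoms:
        Sequence of ``(index, element, name)`` triples (or :class:`Atom`).
        Indices must be ``0 .. n-1`` in order.
    bonds:
        Iterable of unordered index pairs.
    """

    def __init__(self, atoms, bonds):
        self.atoms: list[Atom] = [
            a if isinstance(a, Atom) else Atom(int(a[0]), str(a[1]), str(a[2]))
            for a in atoms
        ]
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValueError(f"atom indices must be 0..n-1 in order, got {a.index} at position {i}")
        n = len(self.atoms)
        self.bonds: set[frozenset[int]] = set()
        for i, j in bonds:
            i, j = int(i), int(j)
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")
            self.bonds.add(frozenset((i, j)))
        self._nx = nx.Graph()
        for a in self.atoms:
            self._nx.add_node(a.index, element=a.element)
        self._nx.add_edges_from(tuple(b) for b in self.bonds)
        self._check_hydrogens()

    # -- basic queries ------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def graph(self) -> nx.Graph:
        return self._nx

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._nx.neighbors(i))

    def element(self, i: int) -> str:
        return self.atoms[i].element

    def index_of(self, name: str) -> int:
        """Resolve a unique atom name to its index."""
        hits = [a.index for a in self.atoms if a.name == name]
        if not hits:
            raise KeyError(f"no atom named {name!r}")
        if len(hits) > 1:
            raise KeyError(f"atom name {name!r} is not unique (indices {hits})")
        return hits[0]

    def heavy_atoms(self) -> list[int]:
        return [a.index for a in self.atoms if not a.is_hydrogen]

    def heavy_neighbor_of_hydrogen(self, h: int) -> int:
        if not self.atoms[h].is_hydrogen:
            raise ValueError(f"atom {h} is not a hydrogen")
        heavies = [j for j in self._nx.neighbors(h) if not self.atoms[j].is_hydrogen]
        # _check_hydrogens guarantees exactly one
        return heavies[0]

    def _check_hydrogens(self):
        for a in self.atoms:
            if a.is_hydrogen:
                heavies = [j for j in self._nx.neighbors(a.index)
                           if not self.atoms[j].is_hydrogen]
                if len(heavies) != 1:
                    raise ValueError(
                        f"hydrogen {a.index} ({a.name}) must have exactly one bonded "
                        f"heavy atom, found {len(heavies)}")

    @property
    def equivalence_groups(self) -> list[tuple[int, ...]]:
        """Partition of hydrogens into groups bonded to the same heavy atom."""
        by_heavy: dict[int, list[int]] = {}
        for a in self.atoms:
            if a.is_hydrogen:
                by_heavy.setdefault(self.heavy_neighbor_of_hydrogen(a.index), []).append(a.index)
        return [tuple(sorted(v)) for _, v in sorted(by_heavy.items())]

    def __repr__(self):
        return f"MoleculeGraph(n_atoms={len(self)}, n_bonds={len(self.bonds)})"


@dataclass
class AtomMapping:
    """Element- and bond-preserving bijection between two graphs."""

    source: MoleculeGraph
    target: MoleculeGraph
    permutation: tuple[int, ...] = field(default_factory=tuple)

    def __getitem__(self, i: int) -> int:
        return self.permutation[i]

    def inverse(self) -> "AtomMapping":
        inv = [0] * len(self.permutation)
        for i, j in enumerate(self.permutation):
            inv[j] = i
        return AtomMapping(self.target, self.source, tuple(inv))


def _require_connected(graph: MoleculeGraph):
    if len(graph) and not nx.is_connected(graph.graph):
        comps = [sorted(c) for c in nx.connected_components(graph.graph)]
        raise ValueError(f"graph is disconnected; components: {comps}")


def detect_macrocycle(graph: MoleculeGraph, min_size: int = 12) -> set[int]:
    """Atoms belonging to any SSSR ring of ``min_size`` or more members.

    A macrocycle is a ring of 12 or more atoms; membership is decided on
    the smallest set of smallest rings so that fused small rings hanging
    off the macrocycle are not swept in.
    """
    _require_connected(graph)
    members: set[int] = set()
    for cycle in nx.minimum_cycle_basis(graph.graph):
        if len(cycle) >= min_size:
            members.update(cycle)
    return members


def ring_sizes(graph: MoleculeGraph) -> list[int]:
    """Sizes of the SSSR rings, sorted descending."""
    _require_connected(graph)
    return sorted((len(c) for c in nx.minimum_cycle_basis(graph.graph)), reverse=True)


def map_graphs(a: MoleculeGraph, b: MoleculeGraph) -> AtomMapping:
    """Element- and bond-preserving bijection from ``a`` onto ``b``.

    Among automorphic alternatives (methyl hydrogens, prochiral pairs)
    the lexicographically smallest image tuple is returned, so repeated
    runs give identical mappings.
    """
    from collections import Counter

    if Counter(x.element for x in a.atoms) != Counter(x.element for x in b.atoms):
        raise ValueError("element multisets differ; graphs cannot be aligned")
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        a.graph, b.graph,
        node_match=lambda na, nb: na["element"] == nb["element"],
    )
    best: tuple[int, ...] | None = None
    for count, iso in enumerate(matcher.isomorphisms_iter()):
        perm = tuple(iso[i] for i in range(len(a)))
        if best is None or perm < best:
            best = perm
        if count + 1 >= _MAX_ISOMORPHISMS:
            break
    if best is None:
        raise ValueError("graphs are not isomorphic under element-preserving matching")
    return AtomMapping(a, b, best)


def hydrogens_of(graph: MoleculeGraph, heavy_index: int) -> list[int]:
    """Hydrogens bonded to a heavy atom, sorted by index.

    Literature NOE tables name heavy atoms; this is the expansion into
    the equivalent-hydrogen group used for r^-6 averaging.
    """
    if graph.atoms[heavy_index].is_hydrogen:
        raise ValueError(f"atom {heavy_index} is a hydrogen, expected a heavy atom")
    return sorted(j for j in graph.graph.neighbors(heavy_index)
                  if graph.atoms[j].is_hydrogen)


def bond_separation(graph: MoleculeGraph, i: int, j: int) -> int:
    """Shortest path length in bonds between two atoms (0 if identical)."""
    try:
        return nx.shortest_path_length(graph.graph, i, j)
    except nx.NetworkXNoPath:
        raise ValueError(f"atoms {i} and {j} are in disconnected components") from None


def classify_region(graph: MoleculeGraph, restraint_heavy_anchors, macrocycle_atoms) -> str:
    """Classify a restraint as macrocyclic / extracyclic / mixed.

    The anchors are the two heavy atoms carrying the restrained hydrogen
    groups; a restraint is macrocyclic when both lie on the ring,
    extracyclic when neither does, and mixed otherwise.
    """
    i, j = restraint_heavy_anchors
    n = len(graph)
    for k in (i, j):
        if not (0 <= k < n):
            raise ValueError(f"invalid anchor index {k}")
    ins = (i in macrocycle_atoms, j in macrocycle_atoms)
    if all(ins):
        return "macrocyclic"
    if not any(ins):
        return "extracyclic"
    return "mixed"


# -- structure file I/O ----------------------------------------------


def load_structure(path) -> MoleculeGraph:
    """Read a structure JSON file: {"atoms": [[i, element, name], ...], "bonds": [[i, j], ...]}."""
    with open(path) as fh:
        data = json.load(fh)
    return MoleculeGraph(data["atoms"], data["bonds"])


def save_structure(graph: MoleculeGraph, path):
    data = {
        "atoms": [[a.index, a.element, a.name] for a in graph.atoms],
        "bonds": sorted(sorted(b) for b in graph.bonds),
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")
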