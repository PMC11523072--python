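"""Synthetic macrocycle ensembles with known ground truth.

Real validation data are MD ensembles of macrocyclic drugs plus
literature NOE tables; neither is reproducible at desk scale. This
module emulates the statistical structure that the validation pipeline
assumes, with every ground-truth quantity known by construction:

* a toy macrocycle graph — a ring of >= 12 carbons with exocyclic
  tail carbons, methyl equivalence groups and prochiral CH2 centers;
* a small number of conformational states (template coordinate sets
  differing by an exocyclic tail fold) mixed with chosen fractions,
  plus isotropic Gaussian jitter within each state;
* NOE bound tables derived from the ensemble itself, so that a chosen
  margin plants an exactly known violation on each restraint
  (margin >= 0 -> satisfied; margin = -v -> violation exactly v).

Geometry is schematic (idealized bond lengths, planar ring base), not
chemically minimized: the pipeline consumes distances only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .molsys import MoleculeGraph
from .noe import ConformerEnsemble, r6_average
from .restraints import NOERestraint, RestraintTable

__all__ = [
    "SynthSpec",
    "make_toy_macrocycle",
    "sample_ensemble",
    "make_restraint_pairs",
    "derive_bounds",
    "load_spec",
]

_CC_BOND = 0.15   # nm, idealized carbon-carbon bond
_CH_BOND = 0.11   # nm, idealized carbon-hydrogen bond


@dataclass
class SynthSpec:
    """Parameters of the synthetic two-state macrocycle generator.

    Defaults emulate the regime seen in converged macrocycle ensembles:
    one strongly dominant conformational state (97.3 % of frames)
    exchanging with a minor tail-folded state, and a small intra-state
    spread relative to the inter-state separation.
    """

    seed: int
    ring_size: int = 15
    n_tail: int = 3
    n_methyl: int = 1
    n_prochiral: int = 2
    state_fractions: tuple[float, ...] = (0.973, 0.027)
    jitter_sigma: float = 0.01  # nm, isotropic per-coordinate
    def __post_init__(self):
        if self.ring_size < 12:
            raise ValueError(f"ring size must be >= 12, got {self.ring_size}")
        if self.n_prochiral + self.n_methyl + (1 if self.n_tail else 0) > self.ring_size:
            raise ValueError("too many substituents for the ring size")
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")


def load_spec(path) -> SynthSpec:
    """Read a SynthSpec from YAML (keys match the dataclass fields)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "state_fractions" in data:
        data["state_fractions"] = tuple(data["state_fractions"])
    return SynthSpec(**data)


def make_toy_macrocycle(spec: SynthSpec):
    """Build the toy macrocycle graph and its per-state template coordinates.

    Returns ``(graph, templates)`` with templates of shape
    (n_states, n_atoms, 3) in nm. The ring lies in the xy-plane; the
    first ``n_prochiral`` ring carbons carry CH2 pairs (one hydrogen
    above, one below the plane), methyls and the tail attach radially;
    the second state folds the tail out of the plane.
    """
    n = spec.ring_size
    radius = _CC_BOND / (2.0 * math.sin(math.pi / n))
    atoms: list[tuple[int, str, str]] = []
    bonds: list[tuple[int, int]] = []
    coords: list[np.ndarray] = []

    def add_atom(element, name, xyz):
        idx = len(atoms)
        atoms.append((idx, element, name))
        coords.append(np.asarray(xyz, dtype=float))
        return idx

    ring_pos = []
    ring_idx = []
    for i in range(n):
        ang = 2.0 * math.pi * i / n
        pos = np.array([radius * math.cos(ang), radius * math.sin(ang), 0.0])
        ring_pos.append(pos)
        ring_idx.append(add_atom("C", f"C{i + 1}", pos))
    for i in range(n):
        bonds.append((ring_idx[i], ring_idx[(i + 1) % n]))

    def outward(i):
        p = ring_pos[i].copy()
        p[2] = 0.0
        return p / np.linalg.norm(p)

    # substituent placement: prochiral CH2 on ring carbons 0..n_prochiral-1,
    # methyls next, the tail on the opposite side of the ring
    methyl_carbons = list(range(spec.n_prochiral, spec.n_prochiral + spec.n_methyl))
    tail_carbon = n // 2 if spec.n_tail else None
    if tail_carbon is not None and tail_carbon in methyl_carbons:
        raise ValueError("substituent placement collision; use a larger ring")
    z = np.array([0.0, 0.0, 1.0])

    for i in range(n):
        if i < spec.n_prochiral:
            # prochiral CH2: distinguishable hydrogens above/below the plane
            base = ring_pos[i] + 0.4 * _CH_BOND * outward(i)
            add_and_bond = add_atom("H", f"H{i + 1}a", base + 0.9 * _CH_BOND * z)
            bonds.append((ring_idx[i], add_and_bond))
            hb = add_atom("H", f"H{i + 1}b", base - 0.9 * _CH_BOND * z)
            bonds.append((ring_idx[i], hb))
        elif i in methyl_carbons:
            m = methyl_carbons.index(i) + 1
            cpos = ring_pos[i] + _CC_BOND * outward(i)
            ci = add_atom("C", f"CM{m}", cpos)
            bonds.append((ring_idx[i], ci))
            for k, lab in enumerate("abc"):
                rot = 2.0 * math.pi * k / 3.0
                perp = np.cross(z, outward(i))
                offset = (0.5 * _CH_BOND * outward(i)
                          + 0.8 * _CH_BOND * (math.cos(rot) * z + math.sin(rot) * perp))
                hi = add_atom("H", f"HM{m}{lab}", cpos + offset)
                bonds.append((ci, hi))
        elif i == tail_carbon:
            prev = ring_idx[i]
            for k in range(spec.n_tail):
                cpos = ring_pos[i] + _CC_BOND * (k + 1) * outward(i)
                ci = add_atom("C", f"CT{k + 1}", cpos)
                bonds.append((prev, ci))
                hi = add_atom("H", f"HT{k + 1}", cpos + _CH_BOND * z)
                bonds.append((ci, hi))
                prev = ci
        else:
            hi = add_atom("H", f"H{i + 1}", ring_pos[i] + _CH_BOND * outward(i))
            bonds.append((ring_idx[i], hi))

    graph = MoleculeGraph(atoms, bonds)
    base = np.array(coords)
    n_states = len(spec.state_fractions)
    templates = np.repeat(base[None], n_states, axis=0)
    if n_states > 1 and spec.n_tail:
        # fold the tail out of plane in the minor state(s)
        folded = base.copy()
        out_dir = outward(tail_carbon)
        for a in graph.atoms:
            if a.name.startswith(("CT", "HT")):
                k = int(a.name[2:].rstrip("abc"))
                folded[a.index] += np.array([0.0, 0.0, 0.18 * k])
                folded[a.index] -= 0.35 * _CC_BOND * k * out_dir
        for s in range(1, n_states):
            templates[s] = folded
    return graph, templates


def sample_ensemble(spec: SynthSpec, n_frames: int):
    """Draw a jittered multi-state ensemble; returns (ensemble, state labels)."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    _, templates = make_toy_macrocycle(spec)
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(len(spec.state_fractions), size=n_frames,
                        p=np.asarray(spec.state_fractions, dtype=float))
    frames = templates[labels]
    if spec.jitter_sigma > 0:
        frames = frames + rng.normal(0.0, spec.jitter_sigma, size=frames.shape)
    return ConformerEnsemble(frames, window=1.0), labels


def make_restraint_pairs(graph: MoleculeGraph, n_restraints: int, seed: int,
                         min_bond_separation: int = 3):
    """Pick distinct hydrogen-group pairs as synthetic restraint targets.

    Groups are the hydrogen equivalence groups of the graph; pairs whose
    heavy anchors are closer than ``min_bond_separation`` bonds are
    skipped (trivially satisfied short contacts carry no information).
    Returns a list of ``(id, group_a, group_b)``.
    """
    from .molsys import bond_separation

    groups = graph.equivalence_groups
    rng = np.random.default_rng(seed)
    candidates = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ha = graph.heavy_neighbor_of_hydrogen(groups[i][0])
            hb = graph.heavy_neighbor_of_hydrogen(groups[j][0])
            if bond_separation(graph, ha, hb) >= min_bond_separation:
                candidates.append((groups[i], groups[j]))
    if n_restraints > len(candidates):
        raise ValueError(f"only {len(candidates)} candidate pairs available")
    chosen = rng.choice(len(candidates), size=n_restraints, replace=False)
    return [(f"r{k + 1}", *candidates[int(c)]) for k, c in enumerate(sorted(chosen))]


def derive_bounds(ensemble: ConformerEnsemble, restraint_pairs, margin,
                  graph: MoleculeGraph | None = None) -> RestraintTable:
    """Derive NOE bounds from the ensemble itself with planted margins.

    ``margin`` is a scalar or one value per restraint, in nm; the bound
    is set to the back-calculated r^-6 average plus the margin, so a
    nonnegative margin yields zero violation on this ensemble and a
    margin of -v plants a violation of exactly v.
    """
    pairs = list(restraint_pairs)
    margins = np.broadcast_to(np.asarray(margin, dtype=float), (len(pairs),))
    restraints = []
    for (rid, group_a, group_b), m in zip(pairs, margins):
        probe = NOERestraint(rid, tuple(group_a), tuple(group_b), d_ref=1.0)
        d_avg = r6_average(ensemble, probe)
        if d_avg + m <= 0:
            raise ValueError(f"restraint {rid}: margin {m} makes the bound nonpositive")
        def sel(group):
            if graph is None:
                return "+".join(str(h) for h in group)
            heavy = graph.heavy_neighbor_of_hydrogen(group[0])
            if tuple(sorted(
                    h for h in graph.graph.neighbors(heavy)
                    if graph.atoms[h].is_hydrogen)) == tuple(sorted(group)):
                return graph.atoms[heavy].name
            return graph.atoms[group[0]].name
        restraints.append(NOERestraint(
            rid, tuple(group_a), tuple(group_b), d_ref=float(d_avg + m),
            sel_a=sel(group_a), sel_b=sel(group_b)))
    return RestraintTable("synthetic", "none", restraints)
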