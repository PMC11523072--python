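"""NOE restraint tables: parsing, hydrogen expansion, prochiral assignment.

Literature NOE tables are tabulated in terms of heavy atoms; each heavy
atom stands for its bonded hydrogens (the equivalent group). The TSV
dialect used here has columns

    id <TAB> sel_a <TAB> sel_b <TAB> d_ref_nm [<TAB> flags]

where ``sel_*`` is a heavy-atom name (expanded to its hydrogens), an
explicit hydrogen name (a singleton group), or a ``/``-separated pair of
hydrogen names marking a prochiral CH2 whose assignment is ambiguous.
Lines starting with ``#`` are comments. Distances are in nm.

Prochiral hydrogens are assigned to best match the restraints: for each
prochiral center the two candidate assignments are enumerated (jointly
across centers that share restraints) and the choice minimizing the
total clamped violation against the ensemble is kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from . import noe as _noe
from .molsys import MoleculeGraph, hydrogens_of

__all__ = [
    "NOERestraint",
    "RestraintTable",
    "parse_restraint_table",
    "serialize_restraint_table",
    "assign_prochiral",
]

#: Joint enumeration over prochiral centers sharing restraints is capped
#: at 2**12 combinations per sharing set.
MAX_JOINT_CENTERS = 12


@dataclass
class NOERestraint:
    """Two hydrogen groups and an upper distance bound in nm.

    For a prochiral side, ``candidates_*`` holds the two alternative
    hydrogens and ``group_*`` the currently selected one (the
    lower-index hydrogen until :func:`assign_prochiral` decides).
    """

    id: str
    group_a: tuple[int, ...]
    group_b: tuple[int, ...]
    d_ref: float
    sel_a: str = ""
    sel_b: str = ""
    candidates_a: tuple[int, int] | None = None
    candidates_b: tuple[int, int] | None = None
    region: str | None = None

    def __post_init__(self):
        if self.d_ref <= 0:
            raise ValueError(f"restraint {self.id}: d_ref must be > 0, got {self.d_ref}")
        if not self.group_a or not self.group_b:
            raise ValueError(f"restraint {self.id}: empty hydrogen group")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"restraint {self.id}: hydrogen groups overlap")

    @property
    def prochiral_sides(self) -> str:
        s = ""
        if self.candidates_a:
            s += "a"
        if self.candidates_b:
            s += "b"
        return s

    def heavy_anchors(self, graph: MoleculeGraph) -> tuple[int, int]:
        """Heavy atom carrying each hydrogen group (for region classification)."""
        def anchor(group):
            heavies = {graph.heavy_neighbor_of_hydrogen(h) for h in group}
            if len(heavies) != 1:
                raise ValueError(
                    f"restraint {self.id}: group spans multiple heavy atoms {sorted(heavies)}")
            return heavies.pop()
        return anchor(self.group_a), anchor(self.group_b)


@dataclass
class RestraintTable:
    """Ordered NOE restraints for one compound in one solvent."""

    compound: str = ""
    solvent: str = ""
    restraints: list[NOERestraint] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.restraints]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate restraint ids: {dup}")

    def __iter__(self):
        return iter(self.restraints)

    def __len__(self):
        return len(self.restraints)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.restraints:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.restraints[key]

    def exclude(self, ids) -> "RestraintTable":
        ids = set(ids)
        return RestraintTable(self.compound, self.solvent,
                              [r for r in self.restraints if r.id not in ids])


def _expand_selection(sel: str, graph: MoleculeGraph, row_id: str):
    """Resolve a selection token into (group, candidates)."""
    if "/" in sel:
        names = sel.split("/")
        if len(names) != 2:
            raise ValueError(
                f"restraint {row_id}: prochiral selection {sel!r} must name exactly 2 hydrogens")
        idx = tuple(sorted(graph.index_of(n) for n in names))
        for h in idx:
            if not graph.atoms[h].is_hydrogen:
                raise ValueError(f"restraint {row_id}: {sel!r} names a non-hydrogen atom")
        if idx[0] == idx[1]:
            raise ValueError(f"restraint {row_id}: prochiral pair {sel!r} repeats an atom")
        return (idx[0],), idx  # default to the lower-index hydrogen
    i = graph.index_of(sel)
    if graph.atoms[i].is_hydrogen:
        return (i,), None
    hyds = tuple(hydrogens_of(graph, i))
    if not hyds:
        raise ValueError(f"restraint {row_id}: heavy atom {sel!r} carries no hydrogens")
    return hyds, None


def parse_restraint_table(path, graph: MoleculeGraph,
                          compound: str = "", solvent: str = "") -> RestraintTable:
    """Parse a restraint TSV and expand heavy-atom selections to hydrogens."""
    restraints = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "id":  # header
                continue
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 tab-separated columns")
            rid, sel_a, sel_b, d_ref_s = (f.strip() for f in fields[:4])
            flags = fields[4].strip() if len(fields) > 4 else ""
            try:
                d_ref = float(d_ref_s)
            except ValueError:
                raise ValueError(f"line {lineno} (restraint {rid}): bad distance {d_ref_s!r}") from None
            if d_ref <= 0:
                raise ValueError(f"line {lineno} (restraint {rid}): d_ref must be > 0")
            try:
                group_a, cand_a = _expand_selection(sel_a, graph, rid)
                group_b, cand_b = _expand_selection(sel_b, graph, rid)
            except KeyError as exc:
                raise ValueError(f"line {lineno} (restraint {rid}): {exc.args[0]}") from None
            # optional recorded assignment, e.g. "assign_a:H3b"
            for flag in flags.split():
                if flag.startswith("assign_a:"):
                    group_a = (graph.index_of(flag.split(":", 1)[1]),)
                elif flag.startswith("assign_b:"):
                    group_b = (graph.index_of(flag.split(":", 1)[1]),)
            restraints.append(NOERestraint(rid, group_a, group_b, d_ref,
                                           sel_a=sel_a, sel_b=sel_b,
                                           candidates_a=cand_a, candidates_b=cand_b))
    return RestraintTable(compound, solvent, restraints)


def serialize_restraint_table(table: RestraintTable, path, graph: MoleculeGraph | None = None):
    """Write a table back to the TSV dialect (round-trips with the parser)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tsel_a\tsel_b\td_ref_nm\tflags\n")
        for r in table:
            flags = []
            if r.candidates_a and graph is not None:
                flags.append(f"assign_a:{graph.atoms[r.group_a[0]].name}")
            if r.candidates_b and graph is not None:
                flags.append(f"assign_b:{graph.atoms[r.group_b[0]].name}")
            fh.write(f"{r.id}\t{r.sel_a}\t{r.sel_b}\t{r.d_ref:.6g}\t{' '.join(flags)}\n")


# -- prochiral assignment --------------------------------------------


def _prochiral_centers(table: RestraintTable, graph: MoleculeGraph):
    """Map prochiral center (heavy atom) -> candidate pair, and the sides using it."""
    centers: dict[int, tuple[int, int]] = {}
    usage: dict[int, list[tuple[int, str]]] = {}  # center -> [(restraint idx, side)]
    for ri, r in enumerate(table):
        for side, cand in (("a", r.candidates_a), ("b", r.candidates_b)):
            if cand is None:
                continue
            if len(cand) != 2:
                raise ValueError(f"restraint {r.id}: prochiral side must have exactly 2 candidates")
            heavy = {graph.heavy_neighbor_of_hydrogen(h) for h in cand}
            if len(heavy) != 1:
                raise ValueError(
                    f"restraint {r.id}: prochiral pair {cand} not bonded to one heavy atom")
            c = heavy.pop()
            prev = centers.setdefault(c, cand)
            if prev != cand:
                raise ValueError(f"center {c}: inconsistent candidate pairs {prev} vs {cand}")
            usage.setdefault(c, []).append((ri, side))
    return centers, usage


def _components(centers, usage, table):
    """Group centers that share a restraint (joint choices interact)."""
    restraint_centers: dict[int, set[int]] = {}
    for c, uses in usage.items():
        for ri, _ in uses:
            restraint_centers.setdefault(ri, set()).add(c)
    parent = {c: c for c in centers}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for cs in restraint_centers.values():
        cs = sorted(cs)
        for other in cs[1:]:
            parent[find(other)] = find(cs[0])
    comps: dict[int, list[int]] = {}
    for c in centers:
        comps.setdefault(find(c), []).append(c)
    return [sorted(v) for v in sorted(comps.values(), key=min)]


def assign_prochiral(table: RestraintTable, ensemble, graph: MoleculeGraph) -> RestraintTable:
    """Choose prochiral hydrogen assignments minimizing total clamped violation.

    Centers are independent unless they share a restraint; sharing sets
    are enumerated jointly (capped at ``MAX_JOINT_CENTERS``). Ties are
    broken toward the lower-index hydrogen, which is also the default
    for unassigned tables, so the operation is idempotent.
    """
    centers, usage = _prochiral_centers(table, graph)
    if not centers:
        return table
    new = [replace(r) for r in table]

    def total_violation(restraint_indices, choice: dict[int, int]):
        tot = 0.0
        for ri in restraint_indices:
            r = new[ri]
            ga, gb = r.group_a, r.group_b
            for side, cand in (("a", r.candidates_a), ("b", r.candidates_b)):
                if cand is None:
                    continue
                c = graph.heavy_neighbor_of_hydrogen(cand[0])
                if c in choice:
                    if side == "a":
                        ga = (choice[c],)
                    else:
                        gb = (choice[c],)
            probe = replace(r, group_a=ga, group_b=gb)
            tot += _noe.violation(_noe.r6_average(ensemble, probe), r.d_ref)
        return tot

    for comp in _components(centers, usage, table):
        if len(comp) > MAX_JOINT_CENTERS:
            raise ValueError(
                f"{len(comp)} prochiral centers share restraints; joint enumeration "
                f"capped at {MAX_JOINT_CENTERS}")
        affected = sorted({ri for c in comp for ri, _ in usage[c]})
        best_choice, best_val = None, None
        # candidates sorted ascending, so lexicographic product order makes
        # the first strict minimum the lower-index tie-break winner
        for combo in itertools.product(*(centers[c] for c in comp)):
            choice = dict(zip(comp, combo))
            val = total_violation(affected, choice)
            if best_val is None or val < best_val - 1e-15:
                best_choice, best_val = choice, val
        for c, h in best_choice.items():
            for ri, side in usage[c]:
                if side == "a":
                    new[ri].group_a = (h,)
                else:
                    new[ri].group_b = (h,)
    return RestraintTable(table.compound, table.solvent, new)
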