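"""REST2 machinery: lambda ladders, Hamiltonian scaling, exchange statistics.

In replica exchange with solute tempering (REST2) the dihedral terms
and intramolecular nonbonded interactions of the solute are scaled by a
factor lambda, while solute-solvent interactions are scaled by
sqrt(lambda); solvent-solvent terms are untouched. Scaling by lambda is
conceptually equivalent to heating the solute to an effective
temperature T0/lambda.

Two ladder schemes distribute lambda over the replicas between 1 and a
final scaling f:

* exponential:  lambda_i = f**(i / i_max)
* quadratic:    sqrt(lambda_i) linear in i from 1 to sqrt(f), i.e.
                lambda_i = (1 - (1 - sqrt(f)) * i / i_max)**2

The quadratic scheme spaces lambda more evenly near 1 and tends to give
more uniform neighbor exchange rates.

Topology scaling follows common partial-tempering practice: solute atom
types are duplicated with an ``_s`` suffix carrying the scaled LJ
epsilon, charges are scaled on the solute atom records, and solute
dihedral force constants are multiplied by lambda. Under geometric-mean
combination this yields intra-solute nonbonded terms scaled by lambda
and solute-solvent terms by sqrt(lambda) without touching the solvent.
Bond terms are never scaled (they are constrained in production MD);
bond-angle scaling is the opt-in gREST-style variant used for strained
rings.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LambdaSchedule",
    "exponential_lambdas",
    "quadratic_lambdas",
    "effective_temperature",
    "ScalableTopology",
    "MoleculeType",
    "parse_topology",
    "write_topology",
    "scale_topology",
    "ExchangeRecord",
    "exchange_acceptance",
    "exchange_statistics",
]


# -- lambda ladders ---------------------------------------------------


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered replica scaling factors, descending from 1 to f."""

    lambdas: tuple[float, ...]
    f: float
    scheme: str

    def __post_init__(self):
        lam = self.lambdas
        if len(lam) < 2:
            raise ValueError("need at least 2 replicas")
        if abs(lam[0] - 1.0) > 1e-12 or abs(lam[-1] - self.f) > 1e-12:
            raise ValueError("ladder endpoints must be 1 and f")
        if any(b >= a for a, b in zip(lam, lam[1:])):
            raise ValueError("lambdas must be strictly decreasing")

    @property
    def n(self) -> int:
        return len(self.lambdas)

    @property
    def tau(self) -> float:
        """Per-step decrement of sqrt(lambda) in the quadratic scheme."""
        return (1.0 - math.sqrt(self.f)) / (self.n - 1)

    def __iter__(self):
        return iter(self.lambdas)

    def __getitem__(self, i):
        return self.lambdas[i]


def _check_ladder_args(n: int, f: float):
    if n < 2:
        raise ValueError(f"need at least 2 replicas, got {n}")
    if not (0.0 < f < 1.0):
        raise ValueError(f"final scaling f must be in (0, 1), got {f}")


def exponential_lambdas(n: int = 12, f: float = 0.125) -> LambdaSchedule:
    """Exponential ladder lambda_i = f**(i / (n-1))."""
    _check_ladder_args(n, f)
    imax = n - 1
    lams = tuple(f ** (i / imax) for i in range(n))
    return LambdaSchedule(lams, f=f, scheme="exponential")


def quadratic_lambdas(n: int = 12, f: float = 0.125) -> LambdaSchedule:
    """Quadratic ladder: sqrt(lambda) linear in replica index from 1 to sqrt(f)."""
    _check_ladder_args(n, f)
    imax = n - 1
    s = math.sqrt(f)
    lams = tuple((1.0 - (1.0 - s) * i / imax) ** 2 for i in range(n))
    return LambdaSchedule(lams, f=f, scheme="quadratic")


def effective_temperature(lam: float, t0: float = 300.0) -> float:
    """Effective solute temperature T0 / lambda emulated by a scaled replica, K."""
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    return t0 / lam


# -- topology model ---------------------------------------------------


@dataclass
class MoleculeType:
    """One [moleculetype] block with its bonded-term sections."""

    name: str
    nrexcl: int
    # atoms: dicts with nr, type, resnr, resname, atomname, cgnr, charge, mass(optional)
    atoms: list[dict] = field(default_factory=list)
    # bonded terms: dicts with indices (tuple), funct, params (list of floats)
    bonds: list[dict] = field(default_factory=list)
    pairs: list[dict] = field(default_factory=list)
    angles: list[dict] = field(default_factory=list)
    dihedrals: list[dict] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class ScalableTopology:
    """Parsed GROMACS-style topology subset.

    Known directives ([defaults], [atomtypes], [moleculetype] blocks with
    [atoms]/[bonds]/[pairs]/[angles]/[dihedrals], [system], [molecules])
    are structured; unknown directives are preserved verbatim in order.
    """

    defaults: list[str] = field(default_factory=list)       # raw lines
    atomtypes: dict[str, dict] = field(default_factory=dict)  # name -> {prefix, sigma, epsilon}
    moleculetypes: list[MoleculeType] = field(default_factory=list)
    system: list[str] = field(default_factory=list)          # raw lines
    molecules: list[tuple[str, int]] = field(default_factory=list)
    extra_sections: list[tuple[str, list[str]]] = field(default_factory=list)

    def moleculetype(self, name: str) -> MoleculeType:
        for m in self.moleculetypes:
            if m.name == name:
                return m
        raise KeyError(f"no moleculetype named {name!r}")

    @property
    def comb_rule(self) -> int:
        for line in self.defaults:
            toks = line.split()
            if len(toks) >= 2:
                return int(toks[1])
        return 2


_N_INDICES = {"bonds": 2, "pairs": 2, "angles": 3, "dihedrals": 4}


def parse_topology(path_or_lines) -> ScalableTopology:
    """Parse the GROMACS .top subset (no #include / preprocessor support)."""
    if isinstance(path_or_lines, (list, tuple)):
        lines = list(path_or_lines)
    else:
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    top = ScalableTopology()
    section = None
    current_mol: MoleculeType | None = None
    for raw in lines:
        line = raw.split(";")[0].rstrip()
        if not line.strip():
            continue
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            section = stripped[1:-1].strip().lower()
            if section not in {"defaults", "atomtypes", "moleculetype", "atoms",
                               "bonds", "pairs", "angles", "dihedrals",
                               "system", "molecules"}:
                top.extra_sections.append((section, []))
            continue
        toks = stripped.split()
        if section == "defaults":
            top.defaults.append(stripped)
        elif section == "atomtypes":
            # name [...] charge ptype sigma epsilon : sigma/epsilon are the
            # last two floats; everything before them is kept verbatim
            top.atomtypes[toks[0]] = {
                "prefix": toks[:-2],
                "sigma": float(toks[-2]),
                "epsilon": float(toks[-1]),
            }
        elif section == "moleculetype":
            current_mol = MoleculeType(name=toks[0], nrexcl=int(toks[1]))
            top.moleculetypes.append(current_mol)
        elif section == "atoms":
            if current_mol is None:
                raise ValueError("[atoms] outside a [moleculetype]")
            atom = {
                "nr": int(toks[0]), "type": toks[1], "resnr": int(toks[2]),
                "resname": toks[3], "atomname": toks[4], "cgnr": int(toks[5]),
                "charge": float(toks[6]),
            }
            if len(toks) > 7:
                atom["mass"] = float(toks[7])
            current_mol.atoms.append(atom)
        elif section in _N_INDICES:
            if current_mol is None:
                raise ValueError(f"[{section}] outside a [moleculetype]")
            k = _N_INDICES[section]
            term = {
                "indices": tuple(int(t) for t in toks[:k]),
                "funct": int(toks[k]),
                "params": [float(t) for t in toks[k + 1:]],
            }
            getattr(current_mol, section).append(term)
        elif section == "system":
            top.system.append(stripped)
        elif section == "molecules":
            top.molecules.append((toks[0], int(toks[1])))
        elif section is not None:
            top.extra_sections[-1][1].append(stripped)
        else:
            raise ValueError(f"content before any [section]: {stripped!r}")
    return top


def write_topology(top: ScalableTopology, path=None) -> str:
    """Emit the topology in GROMACS format; returns the text."""
    out: list[str] = []
    if top.defaults:
        out.append("[ defaults ]")
        out.extend(top.defaults)
        out.append("")
    if top.atomtypes:
        out.append("[ atomtypes ]")
        for name, at in top.atomtypes.items():
            prefix = " ".join(at["prefix"])
            out.append(f"{prefix} {at['sigma']:.17g} {at['epsilon']:.17g}")
        out.append("")
    for mol in top.moleculetypes:
        out.append("[ moleculetype ]")
        out.append(f"{mol.name} {mol.nrexcl}")
        out.append("")
        out.append("[ atoms ]")
        for a in mol.atoms:
            line = (f"{a['nr']} {a['type']} {a['resnr']} {a['resname']} "
                    f"{a['atomname']} {a['cgnr']} {a['charge']:.17g}")
            if "mass" in a:
                line += f" {a['mass']:.17g}"
            out.append(line)
        out.append("")
        for sec in ("bonds", "pairs", "angles", "dihedrals"):
            terms = getattr(mol, sec)
            if not terms:
                continue
            out.append(f"[ {sec} ]")
            for t in terms:
                idx = " ".join(str(i) for i in t["indices"])
                params = " ".join(f"{p:.17g}" for p in t["params"])
                out.append(f"{idx} {t['funct']} {params}".rstrip())
            out.append("")
    for name, lines in top.extra_sections:
        out.append(f"[ {name} ]")
        out.extend(lines)
        out.append("")
    if top.system:
        out.append("[ system ]")
        out.extend(top.system)
        out.append("")
    if top.molecules:
        out.append("[ molecules ]")
        out.extend(f"{n} {c}" for n, c in top.molecules)
        out.append("")
    text = "\n".join(out)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


_SOLUTE_SUFFIX = "_s"


def scale_topology(top: ScalableTopology, lam: float, solute: str,
                   include_angles: bool = False) -> ScalableTopology:
    """REST2-scale the named solute moleculetype by lambda.

    Solute charges are multiplied by sqrt(lambda) and solute LJ epsilon
    by lambda (via duplicated ``_s`` atom types), so geometric-mean
    combination gives intra-solute nonbonded terms scaled by lambda and
    solute-solvent terms by sqrt(lambda). Solute dihedral force
    constants (proper and improper) scale by lambda; angle force
    constants only when ``include_angles``; bonds and all geometry
    parameters (equilibrium values, phases, multiplicities) never
    change. Scaling is a semigroup: applying lambda1 then lambda2
    equals applying lambda1*lambda2.
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    new = copy.deepcopy(top)
    if lam == 1.0:
        return new
    mol = new.moleculetype(solute)  # raises KeyError if absent
    sq = math.sqrt(lam)
    solute_types = {a["type"] for a in mol.atoms}
    for t in sorted(solute_types):
        if t.endswith(_SOLUTE_SUFFIX):
            new.atomtypes[t]["epsilon"] *= lam  # already a tempered copy
        else:
            at = copy.deepcopy(new.atomtypes[t])
            at["epsilon"] *= lam
            scaled_name = t + _SOLUTE_SUFFIX
            at["prefix"] = [scaled_name] + at["prefix"][1:]
            new.atomtypes[scaled_name] = at
    for a in mol.atoms:
        if not a["type"].endswith(_SOLUTE_SUFFIX):
            a["type"] = a["type"] + _SOLUTE_SUFFIX
        a["charge"] *= sq
    for dih in mol.dihedrals:
        if dih["funct"] in (9, 4) and len(dih["params"]) >= 2:
            dih["params"][1] *= lam  # (phase, k, mult): scale the barrier height
    if include_angles:
        for ang in mol.angles:
            if ang["funct"] == 1 and len(ang["params"]) >= 2:
                ang["params"][1] *= lam  # (theta0, k): scale the force constant
    return new


# -- exchange bookkeeping ---------------------------------------------


def exchange_acceptance(delta: float) -> float:
    """Metropolis acceptance min(1, exp(-delta)) for a Hamiltonian exchange.

    ``delta`` is beta * [(U_i(x_j) + U_j(x_i)) - (U_i(x_i) + U_j(x_j))]
    for neighbor replicas i, j.
    """
    if not math.isfinite(delta):
        raise ValueError(f"non-finite exchange energy difference: {delta}")
    return min(1.0, math.exp(-min(delta, 700.0)))


@dataclass(frozen=True)
class ExchangeRecord:
    """One neighbor-exchange attempt and the resulting slot assignment."""

    attempt: int
    pair: tuple[int, int]            # ladder slots (i, i+1)
    accepted: bool
    assignment: tuple[int, ...]      # configuration -> ladder slot, post-attempt


def exchange_statistics(records, n_replicas: int | None = None):
    """Per-pair acceptance rates, their spread, and demultiplexed trajectories.

    Validates that every assignment is a permutation consistent with the
    accept/reject history (starting from the identity), computes
    accepted/attempted per neighbor pair, the spread (max - min) over
    pairs, and the per-configuration sequence of ladder slots.

    Returns a dict with keys ``rates`` ({pair: rate}), ``spread``,
    ``attempts``, ``accepted`` and ``demux`` (array of shape
    (n_records + 1, n_replicas), row 0 the identity).
    """
    records = list(records)
    if n_replicas is None:
        if not records:
            raise ValueError("need records or an explicit replica count")
        n_replicas = len(records[0].assignment)
    state = tuple(range(n_replicas))
    demux = [state]
    attempts: dict[tuple[int, int], int] = {}
    accepted: dict[tuple[int, int], int] = {}
    for rec in records:
        pair = tuple(sorted(rec.pair))
        if pair[1] != pair[0] + 1:
            raise ValueError(f"exchange pair {pair} is not a ladder-neighbor pair")
        expected = list(state)
        if rec.accepted:
            ci = state.index(pair[0])
            cj = state.index(pair[1])
            expected[ci], expected[cj] = pair[1], pair[0]
        expected = tuple(expected)
        if sorted(rec.assignment) != list(range(n_replicas)):
            raise ValueError(f"attempt {rec.attempt}: assignment is not a permutation")
        if tuple(rec.assignment) != expected:
            raise ValueError(
                f"attempt {rec.attempt}: assignment {rec.assignment} inconsistent "
                f"with history (expected {expected})")
        state = expected
        demux.append(state)
        attempts[pair] = attempts.get(pair, 0) + 1
        accepted[pair] = accepted.get(pair, 0) + int(rec.accepted)
    rates = {p: accepted[p] / attempts[p] for p in sorted(attempts)}
    spread = (max(rates.values()) - min(rates.values())) if rates else 0.0
    return {
        "rates": rates,
        "spread": spread,
        "attempts": attempts,
        "accepted": accepted,
        "demux": np.array(demux),
    }
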