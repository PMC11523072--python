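"""Desk-scale torsional Monte Carlo with a REST2 replica-exchange driver.

The toy model is a single "solute" whose degrees of freedom are torsion
angles (plus optional bond angles) on a 4-atom chain geometry. Its
energy mirrors the term classes REST2 scales:

* periodic dihedral terms  k (1 + cos(m*phi - phi0))      -> scaled by lambda
* pairwise nonbonded terms (Coulomb + LJ on the 1-4 distance) -> scaled by lambda
* harmonic angle terms     k (theta - theta0)^2 / 2       -> scaled by lambda
  only when the model opts into bond-angle tempering (gREST-style),
  otherwise left unscaled

so toy_energy(model, s, lambda) == lambda * toy_energy(model, s, 1)
exactly when angle scaling is on. The replica-exchange driver performs
Metropolis single-variable moves within replicas and attempts
alternating even/odd neighbor exchanges with the standard Hamiltonian
Metropolis criterion.

This module also provides an energy evaluator for the GROMACS-subset
topologies of :mod:`macronoe.rest2`, used to verify that topology
scaling obeys the REST2 energy contract (intra-solute terms scale by
lambda, solute-solvent electrostatics by sqrt(lambda)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rest2 import LambdaSchedule, ExchangeRecord, exchange_acceptance

__all__ = [
    "ToyModel",
    "REMCResult",
    "toy_energy",
    "run_metropolis",
    "run_rest2_mc",
    "crossing_rate",
    "topology_energy",
]

#: kT at 300 K in kJ/mol, the production temperature convention.
KT_300K = 2.49435

#: Coulomb constant in kJ mol^-1 nm e^-2.
KE_COULOMB = 138.935458


# -- toy model --------------------------------------------------------


def _chain_r14(b: float, theta1: float, theta2: float, phi: float) -> float:
    """1-4 distance of a 4-atom chain with bond length b, angles theta, torsion phi.

    Closed form of the standard chain construction (p1 at the origin,
    p2 along x, p3 in the xy-plane by theta1, p4 placed by theta2 and
    the torsion phi about the p2-p3 bond).
    """
    c1, s1 = math.cos(theta1), math.sin(theta1)
    c2, s2 = math.cos(theta2), math.sin(theta2)
    cp = math.cos(phi)
    x = 1.0 - c1 + c1 * c2 - s1 * s2 * cp
    y = s1 - s1 * c2 - c1 * s2 * cp
    z = s2 * math.sin(phi)
    return b * math.sqrt(x * x + y * y + z * z)


@dataclass
class ToyModel:
    """Torsional toy solute.

    ``dihedral_terms``: (torsion_index, k, multiplicity, phase).
    ``angle_terms``: (angle_index, k, theta0); angle variables follow the
    torsions in the state vector.
    ``nonbonded_terms``: dicts with keys ``torsion``, ``qq`` (e^2),
    ``eps`` (kJ/mol), ``sigma`` (nm), ``bond_length`` (nm) and either
    ``angle`` (index of the angle variable controlling both chain
    angles) or ``theta`` (fixed chain angle, rad).
    """

    n_torsions: int = 1
    n_angles: int = 0
    dihedral_terms: list[tuple[int, float, int, float]] = field(default_factory=list)
    angle_terms: list[tuple[int, float, float]] = field(default_factory=list)
    nonbonded_terms: list[dict] = field(default_factory=list)
    angle_scaling: bool = False
    kT: float = KT_300K

    @property
    def n_vars(self) -> int:
        return self.n_torsions + self.n_angles

    def initial_state(self) -> np.ndarray:
        state = np.zeros(self.n_vars)
        for ai, _, theta0 in self.angle_terms:
            state[self.n_torsions + ai] = theta0
        return state


def toy_energy(model: ToyModel, state, lam: float = 1.0) -> float:
    """Toy potential energy (kJ/mol) at scaling factor lambda."""
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_vars,):
        raise ValueError(f"state must have {model.n_vars} entries, got {state.shape}")
    tors = state[:model.n_torsions]
    angs = state[model.n_torsions:]
    e_dih = sum(k * (1.0 + math.cos(m * tors[ti] - phi0))
                for ti, k, m, phi0 in model.dihedral_terms)
    e_ang = sum(0.5 * k * (angs[ai] - theta0) ** 2
                for ai, k, theta0 in model.angle_terms)
    e_nb = 0.0
    for term in model.nonbonded_terms:
        theta = angs[term["angle"]] if "angle" in term else term["theta"]
        r = _chain_r14(term["bond_length"], theta, theta,
                       tors[term["torsion"]] - term.get("phase", 0.0))
        sr6 = (term["sigma"] / r) ** 6
        e_nb += KE_COULOMB * term["qq"] / r + 4.0 * term["eps"] * (sr6 * sr6 - sr6)
    ang_factor = lam if model.angle_scaling else 1.0
    return lam * (e_dih + e_nb) + ang_factor * e_ang


def double_well_model(k: float = 10.0, kT: float = KT_300K) -> ToyModel:
    """One torsion in a symmetric double well k(1 + cos 2*phi).

    Wells at +-pi/2, barriers of height 2k at phi = 0 and pi.
    """
    return ToyModel(n_torsions=1, dihedral_terms=[(0, k, 2, 0.0)], kT=kT)


def tilted_double_well_model(k: float = 2.0, tilt: float = 1.0,
                             kT: float = KT_300K) -> ToyModel:
    """Asymmetric double well: k(1 + cos 2*phi) + tilt*(1 + cos(phi - 1)).

    The phase-shifted single-cosine term makes the two wells unequal,
    so the two-state Boltzmann populations are a nontrivial target for
    detailed-balance checks.
    """
    return ToyModel(n_torsions=1,
                    dihedral_terms=[(0, k, 2, 0.0), (0, tilt, 1, 1.0)], kT=kT)


def gated_angle_model(angle_scaling: bool, kT: float = KT_300K) -> ToyModel:
    """A strained-ring stand-in: a stiff bond angle gates the torsion flip.

    The torsion lives in a double well at +-pi/2. Both saddle regions
    (phi = 0 and phi = pi) carry LJ repulsion on the chain 1-4
    distance, which only relaxes when the stiff chain angle opens well
    beyond its 1.6 rad equilibrium; the angle opening costs ~9 kT
    unscaled, so the flip is frozen unless the angle term itself is
    tempered. Including the angle in the scaling (gREST-style) is what
    unlocks the flip at the high-ladder replicas, mirroring the
    behavior of short strained macrocycles.
    """
    gate = {"angle": 0, "qq": 0.0, "eps": 10.0, "sigma": 0.24,
            "bond_length": 0.15}
    return ToyModel(
        n_torsions=1, n_angles=1,
        dihedral_terms=[(0, 3.0, 2, 0.0)],
        angle_terms=[(0, 600.0, 1.6)],
        nonbonded_terms=[{"torsion": 0, "phase": 0.0, **gate},
                         {"torsion": 0, "phase": math.pi, **gate}],
        angle_scaling=angle_scaling, kT=kT)


# -- samplers ---------------------------------------------------------


def _mc_sweep(model, state, energy, lam, rng, sigma):
    """One Metropolis update of a randomly chosen variable; returns (state, energy)."""
    i = int(rng.integers(model.n_vars))
    prop = state.copy()
    prop[i] += rng.normal(0.0, sigma)
    if i < model.n_torsions:  # keep torsions on (-pi, pi]
        prop[i] = (prop[i] + math.pi) % (2.0 * math.pi) - math.pi
    e_new = toy_energy(model, prop, lam)
    if e_new <= energy or rng.random() < math.exp(-(e_new - energy) / model.kT):
        return prop, e_new
    return state, energy


def run_metropolis(model: ToyModel, n_steps: int, seed: int,
                   lam: float = 1.0, sigma: float = 0.3) -> np.ndarray:
    """Plain single-replica Metropolis reference sampler.

    Returns the (n_steps, n_vars) trajectory of post-move states.
    """
    rng = np.random.default_rng(seed)
    state = model.initial_state()
    energy = toy_energy(model, state, lam)
    traj = np.empty((n_steps, model.n_vars))
    for t in range(n_steps):
        state, energy = _mc_sweep(model, state, energy, lam, rng, sigma)
        traj[t] = state
    return traj


@dataclass
class REMCResult:
    """Outcome of a replica-exchange Monte Carlo run."""

    schedule: LambdaSchedule
    trajectories: np.ndarray          # (n_steps, n_replicas, n_vars), by ladder slot
    config_trajectories: np.ndarray   # (n_steps, n_replicas, n_vars), by configuration
    records: list[ExchangeRecord]
    assignment: tuple[int, ...]       # final configuration -> slot

    def slot_trajectory(self, slot: int = 0) -> np.ndarray:
        """Time series of the states simulated at one ladder slot."""
        return self.trajectories[:, slot, :]

    def config_trajectory(self, config: int) -> np.ndarray:
        """Continuous (demultiplexed) trajectory of one walker across slots."""
        return self.config_trajectories[:, config, :]

    def crossing_counts(self, barrier: float = 0.0, torsion: int = 0) -> list[int]:
        """Barrier crossings of each continuous walker's torsion trajectory."""
        n = self.config_trajectories.shape[0]
        return [int(round(crossing_rate(
            self.config_trajectories[:, c, torsion], barrier) * n))
            for c in range(self.config_trajectories.shape[1])]


def run_rest2_mc(model: ToyModel, schedule: LambdaSchedule, n_steps: int,
                 exchange_every: int = 100, seed: int = 0,
                 sigma: float = 0.3) -> REMCResult:
    """REST2-style replica-exchange MC on the toy model.

    Each ladder slot i runs Metropolis moves on the lambda_i-scaled
    Hamiltonian; every ``exchange_every`` steps, neighbor exchanges are
    attempted on alternating even/odd pairs with the Hamiltonian
    Metropolis criterion, swapping configurations between slots.
    """
    n = schedule.n
    if n < 2:
        raise ValueError("need at least 2 replicas")
    if n_steps % exchange_every:
        raise ValueError("n_steps must be a multiple of exchange_every")
    rng = np.random.default_rng(seed)
    beta = 1.0 / model.kT
    states = [model.initial_state() for _ in range(n)]
    energies = [toy_energy(model, states[r], schedule[r]) for r in range(n)]
    config_at_slot = list(range(n))      # slot -> configuration id
    traj = np.empty((n_steps, n, model.n_vars))
    traj_cfg = np.empty((n_steps, n, model.n_vars))
    records: list[ExchangeRecord] = []
    attempt = 0
    for t in range(n_steps):
        for r in range(n):
            states[r], energies[r] = _mc_sweep(
                model, states[r], energies[r], schedule[r], rng, sigma)
            traj[t, r] = states[r]
        for slot, cfg in enumerate(config_at_slot):
            traj_cfg[t, cfg] = states[slot]
        if (t + 1) % exchange_every == 0:
            parity = ((t + 1) // exchange_every - 1) % 2
            for i in range(parity, n - 1, 2):
                j = i + 1
                e_ij = toy_energy(model, states[j], schedule[i])
                e_ji = toy_energy(model, states[i], schedule[j])
                delta = beta * ((e_ij + e_ji) - (energies[i] + energies[j]))
                accepted = rng.random() < exchange_acceptance(delta)
                if accepted:
                    states[i], states[j] = states[j], states[i]
                    energies[i], energies[j] = e_ij, e_ji
                    config_at_slot[i], config_at_slot[j] = (
                        config_at_slot[j], config_at_slot[i])
                assignment = [0] * n
                for slot, cfg in enumerate(config_at_slot):
                    assignment[cfg] = slot
                records.append(ExchangeRecord(
                    attempt=attempt, pair=(i, j), accepted=accepted,
                    assignment=tuple(assignment)))
                attempt += 1
    final_assignment = [0] * n
    for slot, cfg in enumerate(config_at_slot):
        final_assignment[cfg] = slot
    return REMCResult(schedule=schedule, trajectories=traj,
                      config_trajectories=traj_cfg, records=records,
                      assignment=tuple(final_assignment))


def crossing_rate(trajectory, barrier: float = 0.0) -> float:
    """Barrier crossings per step: sign changes of (phi - barrier) after unwrapping."""
    series = np.asarray(trajectory, dtype=float).ravel()
    if series.size == 0:
        raise ValueError("empty trajectory")
    d = np.unwrap(series) - barrier
    signs = np.sign(d)
    # carry the previous sign across exact zeros
    for i in range(1, signs.size):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    crossings = int(np.sum(signs[1:] * signs[:-1] < 0))
    return crossings / series.size


def crossing_count(trajectory, barrier: float = 0.0) -> int:
    """Absolute number of barrier crossings in a trajectory."""
    series = np.asarray(trajectory, dtype=float).ravel()
    return int(round(crossing_rate(series, barrier) * series.size))


# -- topology energy evaluator ---------------------------------------


def _dihedral_angle(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.atan2(y, x)


def _angle(p0, p1, p2) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.acos(max(-1.0, min(1.0, c)))


def _bond_separations(mol, max_sep):
    """Dict (i, j) -> bond separation for separations <= max_sep (1-based atom nrs)."""
    adj: dict[int, set[int]] = {a["nr"]: set() for a in mol.atoms}
    for b in mol.bonds:
        i, j = b["indices"]
        adj[i].add(j)
        adj[j].add(i)
    seps = {}
    for start in adj:
        seen = {start: 0}
        frontier = [start]
        for depth in range(1, max_sep + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        for other, d in seen.items():
            if other > start:
                seps[(start, other)] = d
    return seps


def topology_energy(top, coords_nm, solute: str) -> dict:
    """Evaluate a GROMACS-subset topology's energy, partitioned by class.

    Molecules are expanded in [molecules] order; ``coords_nm`` is the
    (n_total_atoms, 3) coordinate array in nm. Nonbonded interactions
    exclude intramolecular pairs separated by <= nrexcl bonds; [pairs]
    entries are re-included at full strength. Returns a dict with
    bonded terms split by solute/solvent and nonbonded terms split into
    solute-solute (ss), solute-solvent (sv) and solvent-solvent (vv).
    """
    coords = np.asarray(coords_nm, dtype=float)
    comb_rule = top.comb_rule
    out = {k: 0.0 for k in (
        "bonds", "angles_solute", "angles_solvent", "dihedrals_solute",
        "dihedrals_solvent", "elec_ss", "elec_sv", "elec_vv",
        "lj_ss", "lj_sv", "lj_vv")}
    # expand molecule instances
    atoms = []   # (charge, sigma, eps, is_solute, mol_id)
    offset = 0
    mol_id = 0
    for name, count in top.molecules:
        mol = top.moleculetype(name)
        is_solute = name == solute
        seps = _bond_separations(mol, mol.nrexcl)
        pair_set = {tuple(sorted(p["indices"])) for p in mol.pairs}
        for _ in range(count):
            for a in mol.atoms:
                at = top.atomtypes[a["type"]]
                atoms.append((a["charge"], at["sigma"], at["epsilon"], is_solute, mol_id))
            base = offset

            def pos(nr):
                return coords[base + nr - 1]

            for b in mol.bonds:
                i, j = b["indices"]
                b0, kb = b["params"][:2]
                r = np.linalg.norm(pos(i) - pos(j))
                out["bonds"] += 0.5 * kb * (r - b0) ** 2
            key = "solute" if is_solute else "solvent"
            for ang in mol.angles:
                i, j, k = ang["indices"]
                th0, kth = ang["params"][:2]
                th = _angle(pos(i), pos(j), pos(k))
                out[f"angles_{key}"] += 0.5 * kth * (th - math.radians(th0)) ** 2
            for dih in mol.dihedrals:
                i, j, k, l = dih["indices"]
                phase, kd, mult = dih["params"][0], dih["params"][1], int(dih["params"][2])
                phi = _dihedral_angle(pos(i), pos(j), pos(k), pos(l))
                out[f"dihedrals_{key}"] += kd * (
                    1.0 + math.cos(mult * phi - math.radians(phase)))
            # 1-4 pairs re-included at full strength
            for i, j in pair_set:
                _accumulate_nb(out, atoms, coords, base + i - 1, base + j - 1, comb_rule)
            offset += mol.n_atoms
            mol_id += 1
    # nonbonded over all atom pairs, minus intramolecular exclusions
    n_total = len(atoms)
    excl_by_mol: dict[int, set] = {}
    offset = 0
    mol_id = 0
    excluded = set()
    for name, count in top.molecules:
        mol = top.moleculetype(name)
        seps = _bond_separations(mol, mol.nrexcl)
        for _ in range(count):
            for (i, j), d in seps.items():
                excluded.add((offset + i - 1, offset + j - 1))
            # [pairs] already handled explicitly above; exclude from the loop
            for p in mol.pairs:
                i, j = sorted(p["indices"])
                excluded.add((offset + i - 1, offset + j - 1))
            offset += mol.n_atoms
            mol_id += 1
    for i in range(n_total):
        for j in range(i + 1, n_total):
            if (i, j) in excluded:
                continue
            _accumulate_nb(out, atoms, coords, i, j, comb_rule)
    out["total"] = sum(v for k, v in out.items() if k != "total")
    return out


def _accumulate_nb(out, atoms, coords, i, j, comb_rule):
    qi, si, ei, sol_i, _ = atoms[i]
    qj, sj, ej, sol_j, _ = atoms[j]
    r = float(np.linalg.norm(coords[i] - coords[j]))
    if r == 0.0:
        raise ValueError(f"coincident atoms {i}, {j}")
    if comb_rule == 3:
        sigma = math.sqrt(si * sj)
    else:
        sigma = 0.5 * (si + sj)
    eps = math.sqrt(ei * ej)
    suffix = "ss" if (sol_i and sol_j) else ("vv" if not (sol_i or sol_j) else "sv")
    out[f"elec_{suffix}"] += KE_COULOMB * qi * qj / r
    sr6 = (sigma / r) ** 6
    out[f"lj_{suffix}"] += 4.0 * eps * (sr6 * sr6 - sr6)
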