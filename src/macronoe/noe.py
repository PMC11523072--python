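"""NOE back-calculation: r^-6 averaged distances, violations, split errors.

The experimental observable is an upper bound ``d_ref`` on the
ensemble-averaged distance between two hydrogen groups. Because NOE
intensity falls off as r^-6, the ensemble average is

    d_avg = < d_ab^-6 >^(-1/6)

with the mean running jointly over the analysis-window frames and over
all hydrogen pairs (a in group A, b in group B) of the equivalent
groups. The violation is the clamped excess max(0, d_avg - d_ref), and
a simulation's quality score is the fraction of restraints whose
violation exceeds 0.05 nm.

Convergence is assessed by splitting the analysis window into equal
contiguous segments, recomputing d_avg per segment, and reporting the
standard deviation over segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConformerEnsemble",
    "NOEResult",
    "r6_average",
    "violation",
    "fraction_violations",
    "split_errors",
    "load_ensemble",
    "write_ensemble_pdb",
]

#: Default violation threshold for the fraction-of-violations score, nm.
VIOLATION_THRESHOLD_NM = 0.05


@dataclass
class ConformerEnsemble:
    """Ordered conformer frames over a fixed atom set, coordinates in nm.

    ``window`` selects the trailing fraction of frames used for
    averaging; it generalizes the "analyze the last part of the
    trajectory" convention (window=0.5 keeps the last half).
    """

    coordinates: np.ndarray  # (n_frames, n_atoms, 3), nm
    window: float = 1.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if not (0.0 < self.window <= 1.0):
            raise ValueError(f"window must be in (0, 1], got {self.window}")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def window_frames(self) -> np.ndarray:
        """Coordinates of the trailing analysis window (at least one frame)."""
        n = self.n_frames
        k = max(1, int(round(n * self.window)))
        return self.coordinates[n - k:]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class NOEResult:
    """Back-calculated outcome for one restraint."""

    restraint_id: str
    d_avg: float          # r^-6 averaged distance, nm
    d_ref: float          # upper bound, nm
    violation: float      # clamped excess, nm
    split_std: float = 0.0
    region: str | None = None
    bond_separation: int | None = None


def _pair_distances(frames: np.ndarray, group_a, group_b) -> np.ndarray:
    """(n_frames, |A|*|B|) Euclidean distances between the two groups."""
    a = frames[:, list(group_a), :]          # (F, A, 3)
    b = frames[:, list(group_b), :]          # (F, B, 3)
    diff = a[:, :, None, :] - b[:, None, :, :]
    d = np.sqrt(np.einsum("fabx,fabx->fab", diff, diff))
    return d.reshape(frames.shape[0], -1)


def r6_average(ensemble: ConformerEnsemble, restraint) -> float:
    """r^-6 weighted average distance of a restraint over the window, nm.

    The mean of d^-6 is taken jointly over window frames and over all
    equivalent hydrogen pairs, then raised to the -1/6 power. No
    multiplicity (pseudo-atom) correction is applied.
    """
    frames = ensemble.window_frames()
    d = _pair_distances(frames, restraint.group_a, restraint.group_b)
    if np.any(d == 0.0):
        raise ValueError(
            f"restraint {restraint.id}: coincident atoms (zero distance) in a frame")
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


def violation(d_avg: float, d_ref: float) -> float:
    """Clamped violation max(0, d_avg - d_ref), nm."""
    if d_avg <= 0 or d_ref <= 0:
        raise ValueError("distances must be positive")
    return max(0.0, d_avg - d_ref)


def fraction_violations(results, threshold: float = VIOLATION_THRESHOLD_NM) -> float:
    """Share of restraints with violation strictly greater than ``threshold``."""
    results = list(results)
    if not results:
        raise ValueError("no NOE results to summarize")
    viol = [r.violation if isinstance(r, NOEResult) else float(r) for r in results]
    return sum(v > threshold for v in viol) / len(viol)


def split_errors(ensemble: ConformerEnsemble, table, n_segments: int = 5):
    """Per-restraint segment standard deviations and their RMS.

    The analysis window is divided into ``n_segments`` contiguous equal
    blocks (remainder frames at the end are dropped), d_avg is
    recomputed per block, and the population standard deviation over
    blocks is the per-restraint error bar. The scalar summary is the
    root mean square of those standard deviations over all restraints.

    Returns
    -------
    (dict restraint_id -> split_std, rms_split_std)
    """
    frames = ensemble.window_frames()
    n = frames.shape[0]
    if n < n_segments:
        raise ValueError(f"{n} window frames < {n_segments} segments")
    block = n // n_segments
    stds: dict[str, float] = {}
    for restraint in table:
        vals = []
        for s in range(n_segments):
            seg = ConformerEnsemble(frames[s * block:(s + 1) * block], window=1.0)
            vals.append(r6_average(seg, restraint))
        stds[restraint.id] = float(np.std(vals))  # population std over segments
    rms = float(np.sqrt(np.mean([v ** 2 for v in stds.values()]))) if stds else 0.0
    return stds, rms


# -- trajectory I/O ---------------------------------------------------


def load_ensemble(path, window: float = 1.0) -> ConformerEnsemble:
    """Read a multi-model PDB or XYZ trajectory; Angstrom converted to nm."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    return ConformerEnsemble(frames * 0.1, window=window)


def write_ensemble_pdb(ensemble: ConformerEnsemble, graph, path, frame_indices=None):
    """Write frames as a multi-model PDB (nm converted to Angstrom)."""
    import warnings

    import MDAnalysis as mda

    idx = range(ensemble.n_frames) if frame_indices is None else frame_indices
    n = ensemble.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", [a.name[:4] for a in graph.atoms])
    u.add_TopologyAttr("elements", [a.element for a in graph.atoms])
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("resnames", ["MOL"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for i in idx:
                u.atoms.positions = ensemble.coordinates[i] * 10.0
                w.write(u.atoms)
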