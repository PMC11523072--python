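"""Superposition, pairwise RMSD, and hierarchical clustering of conformers.

Clustering follows the common trajectory-analysis recipe: pairwise
heavy-atom RMSD after optimal (Kabsch) superposition as the metric,
average-linkage agglomerative merging, a fixed number of clusters
(default 5), and the member with the lowest mean distance to its
cluster (the medoid, standing in for the centroid of the RMSD metric
space) as the representative structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .noe import ConformerEnsemble

__all__ = [
    "Clustering",
    "kabsch_rmsd",
    "rmsd_matrix",
    "cluster_ensemble",
    "group_com_distance",
]

#: Pairwise RMSD matrices above this frame count need allow_large=True.
MAX_FRAMES_DEFAULT = 2000


@dataclass
class Clustering:
    """Cluster labels, populations, and medoid representatives."""

    labels: np.ndarray            # (n_frames,), 0-based cluster index
    representatives: list[int]    # frame index per cluster
    n_frames: int

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    @property
    def populations(self) -> list[Fraction]:
        """Exact population fraction per cluster (sums to 1)."""
        counts = np.bincount(self.labels, minlength=self.n_clusters)
        return [Fraction(int(c), self.n_frames) for c in counts]


def kabsch_rmsd(x: np.ndarray, y: np.ndarray, atom_subset=None) -> float:
    """RMSD (nm) over a subset after optimal translation + proper rotation of y onto x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if atom_subset is not None:
        x = x[list(atom_subset)]
        y = y[list(atom_subset)]
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms to determine the superposition")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # Kabsch: optimal proper rotation from the SVD of the covariance,
    # with the determinant sign flipped to exclude reflections
    u, s, vt = np.linalg.svd(yc.T @ xc)
    sign = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, sign]) @ vt).T
    resid = xc - yc @ rot.T
    return float(np.sqrt((resid ** 2).sum() / n))


def rmsd_matrix(ensemble: ConformerEnsemble, atom_subset=None,
                allow_large: bool = False) -> np.ndarray:
    """Symmetric pairwise Kabsch RMSD matrix over all frames."""
    n = ensemble.n_frames
    if n > MAX_FRAMES_DEFAULT and not allow_large:
        raise ValueError(
            f"{n} frames would need a {n}x{n} RMSD matrix; pass allow_large=True")
    coords = ensemble.coordinates
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_rmsd(coords[i], coords[j], atom_subset)
    return mat


def cluster_ensemble(ensemble: ConformerEnsemble, n_clusters: int = 5,
                     atom_subset=None, allow_large: bool = False) -> Clustering:
    """Average-linkage hierarchical clustering on the pairwise RMSD matrix.

    ``atom_subset`` is typically the heavy atoms. Representatives are
    the medoids (lowest mean RMSD to the other members of their own
    cluster; ties go to the lowest frame index).
    """
    n = ensemble.n_frames
    if n < n_clusters:
        raise ValueError(f"{n} frames < {n_clusters} clusters")
    mat = rmsd_matrix(ensemble, atom_subset, allow_large=allow_large)
    if n == n_clusters:
        labels = np.arange(n)
    else:
        z = linkage(squareform(mat, checks=False), method="average")
        labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    # renumber clusters by first occurrence for determinism
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels])
    reps = []
    for c in range(labels.max() + 1):
        members = np.flatnonzero(labels == c)
        mean_d = mat[np.ix_(members, members)].mean(axis=1)
        reps.append(int(members[int(np.argmin(mean_d))]))
    return Clustering(labels=labels, representatives=reps, n_frames=n)


def group_com_distance(frame: np.ndarray, group_a, group_b) -> float:
    """Distance between the unweighted centroids of two atom groups (nm).

    Used for visual reporting of restrained distances; the quantitative
    analysis always uses the r^-6 average instead.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("empty atom group")
    frame = np.asarray(frame, dtype=float)
    ca = frame[list(group_a)].mean(axis=0)
    cb = frame[list(group_b)].mean(axis=0)
    return float(np.linalg.norm(ca - cb))
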