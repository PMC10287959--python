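"""Symmetry-aware RMSD and conformational clustering.

For a self-complementary duplex the two strands are physically
interchangeable: the distance between two snapshots is the minimum
least-squares RMSD over rotations, translations *and* the strand-swap
permutation (C2 symmetry).  Two clusterings operate on that metric:

* :class:`GreedyRMSDClustering` — a deterministic leader algorithm with a
  1.0 A default cutoff: frames are scanned in order and joined to the
  nearest existing representative within the cutoff, else open a new
  cluster.
* :class:`AverageLinkageRMSDClustering` — average-linkage hierarchical
  agglomeration on the full symmetry-minimised RMSD matrix, cut at a
  1.2 A distance threshold; representatives are cluster medoids.

Cluster populations are reported as percentages, with clusters below a
reporting threshold (1% by default) aggregated into an "other" bucket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .model_io import Topology, Trajectory, select_atoms

__all__ = [
    "ClusterResult",
    "kabsch_rmsd",
    "symmetry_min_rmsd",
    "pairwise_symmetry_rmsd",
    "GreedyRMSDClustering",
    "AverageLinkageRMSDClustering",
    "greedy_cluster",
    "hier_cluster_average_linkage",
    "report_clusters",
]


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=-2, keepdims=True)


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition.

    Proper rotations only (no reflection), via the SVD form of the Kabsch
    solution.  Requires >= 3 atoms.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    Xc = _center(X)
    Yc = _center(Y)
    H = Xc.T @ Yc
    U, s, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    trace = s[0] + s[1] + sign * s[2]
    msd = (np.sum(Xc**2) + np.sum(Yc**2) - 2.0 * trace) / n
    return float(np.sqrt(max(msd, 0.0)))


def _kabsch_rmsd_many(stack: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """RMSD of one structure Y against a stack (m, n, 3), batched SVD."""
    Yc = _center(Y)
    Sc = _center(stack)
    n = Y.shape[0]
    H = np.einsum("mni,nj->mij", Sc, Yc)
    U, s, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    msd = (np.sum(Sc**2, axis=(1, 2)) + np.sum(Yc**2) - 2.0 * trace) / n
    return np.sqrt(np.clip(msd, 0.0, None))


def _permuted_selections(
    topology: Topology, selection: np.ndarray, symmetry: bool
) -> list[np.ndarray]:
    """Atom-index arrays equivalent to ``selection`` under each symmetry op."""
    if not symmetry:
        return [selection]
    return [perm[selection] for perm in topology.symmetry_perms]


def symmetry_min_rmsd(
    X: np.ndarray,
    Y: np.ndarray,
    topology: Topology,
    selection: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Minimum Kabsch RMSD over the topology's symmetry permutations.

    ``X`` and ``Y`` are full (n_atoms, 3) frames; the RMSD is computed on
    ``selection`` (all atoms if None).  Returns (rmsd, permutation used);
    ties break toward the identity (listed first).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if selection is None:
        selection = np.arange(topology.n_atoms)
    best = np.inf
    best_perm = topology.symmetry_perms[0]
    for perm in topology.symmetry_perms:
        r = kabsch_rmsd(X[selection], Y[perm[selection]])
        if r < best:
            best = r
            best_perm = perm
    return float(best), best_perm


def pairwise_symmetry_rmsd(
    coords: np.ndarray,
    topology: Topology,
    selection: np.ndarray,
    symmetry: bool = True,
) -> np.ndarray:
    """Full symmetry-minimised RMSD matrix for a frame stack (n, atoms, 3)."""
    sels = _permuted_selections(topology, selection, symmetry)
    n = coords.shape[0]
    base = coords[:, sels[0]]
    dm = np.zeros((n, n))
    for i in range(1, n):
        row = _kabsch_rmsd_many(base[:i], base[i])
        for sel_p in sels[1:]:
            alt = _kabsch_rmsd_many(base[:i], coords[i, sel_p])
            row = np.minimum(row, alt)
        dm[i, :i] = row
        dm[:i, i] = row
    return dm


@dataclass
class ClusterResult:
    """Per-frame labels, representatives and population percentages."""

    labels: np.ndarray  # (n_frames,) cluster ids 0..k-1
    representatives: np.ndarray  # (k,) frame index per cluster
    percentages: np.ndarray  # (k,) population * 100
    method: str = ""
    cutoff: float = np.nan
    selection: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def __post_init__(self) -> None:
        total = float(np.sum(self.percentages))
        if self.labels.size and abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, expected 100")


class _RMSDClusteringBase(ClusterMixin, BaseEstimator):
    """Shared plumbing: selection resolution and fitted-attribute contract."""

    def __init__(self, cutoff, selection=None, symmetry=True):
        self.cutoff = cutoff
        self.selection = selection
        self.symmetry = symmetry

    def _resolve_selection(self, topology: Topology) -> np.ndarray:
        if self.selection is None:
            return np.arange(topology.n_atoms)
        if isinstance(self.selection, str):
            return select_atoms(topology, self.selection)
        return np.asarray(self.selection, dtype=int)

    def fit_predict(self, traj: Trajectory, y=None) -> np.ndarray:
        self.fit(traj)
        return self.labels_

    def _finish(self, traj, labels, representatives, method) -> "ClusterResult":
        labels = np.asarray(labels)
        representatives = np.asarray(representatives)
        counts = np.bincount(labels, minlength=len(representatives))
        percentages = 100.0 * counts / labels.size
        self.labels_ = labels
        self.representatives_ = representatives
        self.percentages_ = percentages
        self.n_clusters_ = len(representatives)
        self.result_ = ClusterResult(
            labels, representatives, percentages,
            method=method, cutoff=self.cutoff, selection=self.selection_,
        )
        return self.result_


class GreedyRMSDClustering(_RMSDClusteringBase):
    """Deterministic leader clustering on symmetry-minimised RMSD.

    Frames are scanned in order; each frame joins the existing cluster whose
    representative (its founding frame) is nearest within ``cutoff``,
    otherwise it founds a new cluster.  Fully deterministic given frame
    order.

    Parameters
    ----------
    cutoff : float, default 1.0
        RMSD threshold in Angstrom.
    selection : str | array | None
        Atoms used both to superpose and to measure (e.g. loop heavy atoms).
    symmetry : bool, default True
        Minimise over the topology's strand-swap permutations.

    Attributes (after fit)
    ----------------------
    labels_, representatives_, percentages_, n_clusters_, result_
    """

    def __init__(self, cutoff: float = 1.0, selection=None, symmetry: bool = True):
        super().__init__(cutoff, selection, symmetry)

    def fit(self, traj: Trajectory, y=None):
        if traj.n_frames < 1:
            raise ValueError("need at least one frame")
        sel = self._resolve_selection(traj.topology)
        self.selection_ = sel
        sels = _permuted_selections(traj.topology, sel, self.symmetry)
        base = traj.coordinates[:, sels[0]]

        labels = np.empty(traj.n_frames, dtype=int)
        rep_frames: list[int] = []
        rep_stack: list[np.ndarray] = []
        for f in range(traj.n_frames):
            if rep_stack:
                stack = np.asarray(rep_stack)
                d = _kabsch_rmsd_many(stack, base[f])
                for sel_p in sels[1:]:
                    d = np.minimum(
                        d, _kabsch_rmsd_many(stack, traj.coordinates[f, sel_p])
                    )
                best = int(np.argmin(d))
                if d[best] <= self.cutoff:
                    labels[f] = best
                    continue
            labels[f] = len(rep_frames)
            rep_frames.append(f)
            rep_stack.append(base[f])
        return self._finish(traj, labels, rep_frames, "greedy")


class AverageLinkageRMSDClustering(_RMSDClusteringBase):
    """Average-linkage hierarchical clustering cut at an RMSD threshold.

    Agglomerates on the full symmetry-minimised RMSD matrix and cuts the
    dendrogram at ``cutoff`` (distance criterion, not cluster count).
    Representatives are medoids (minimum mean intra-cluster distance).

    Parameters mirror :class:`GreedyRMSDClustering`; default cutoff 1.2 A.
    ``max_frames`` caps the distance-matrix size; stride the trajectory
    beforehand for larger ensembles.
    """

    def __init__(
        self,
        cutoff: float = 1.2,
        selection=None,
        symmetry: bool = True,
        max_frames: int = 20_000,
    ):
        super().__init__(cutoff, selection, symmetry)
        self.max_frames = max_frames

    def fit(self, traj: Trajectory, y=None):
        if traj.n_frames > self.max_frames:
            raise ValueError(
                f"{traj.n_frames} frames exceed the distance-matrix cap "
                f"({self.max_frames}); stride the trajectory first"
            )
        sel = self._resolve_selection(traj.topology)
        self.selection_ = sel
        dm = pairwise_symmetry_rmsd(
            traj.coordinates, traj.topology, sel, self.symmetry
        )
        if traj.n_frames == 1:
            raw = np.zeros(1, dtype=int)
        else:
            Z = linkage(squareform(dm, checks=False), method="average")
            raw = fcluster(Z, t=self.cutoff, criterion="distance") - 1
        # relabel by order of first appearance for determinism
        order: dict[int, int] = {}
        labels = np.empty_like(raw)
        for f, r in enumerate(raw):
            if r not in order:
                order[r] = len(order)
            labels[f] = order[r]
        representatives = []
        for c in range(len(order)):
            members = np.flatnonzero(labels == c)
            sub = dm[np.ix_(members, members)]
            representatives.append(int(members[np.argmin(sub.mean(axis=1))]))
        return self._finish(traj, labels, representatives, "average_linkage")


def greedy_cluster(
    traj: Trajectory,
    cutoff: float = 1.0,
    selection=None,
    symmetry: bool = True,
) -> ClusterResult:
    """Functional wrapper over :class:`GreedyRMSDClustering`."""
    return GreedyRMSDClustering(cutoff, selection, symmetry).fit(traj)


def hier_cluster_average_linkage(
    traj: Trajectory,
    cutoff: float = 1.2,
    selection=None,
    symmetry: bool = True,
    max_frames: int = 20_000,
) -> ClusterResult:
    """Functional wrapper over :class:`AverageLinkageRMSDClustering`."""
    est = AverageLinkageRMSDClustering(cutoff, selection, symmetry, max_frames)
    return est.fit(traj)


def report_clusters(
    result: ClusterResult,
    min_pct: float = 1.0,
    state_labeler=None,
) -> pd.DataFrame:
    """Cluster report: percentage-sorted table with a sub-threshold bucket.

    Clusters below ``min_pct`` percent are aggregated into a single "other"
    row so the percentage column still sums to 100.  ``state_labeler`` is an
    optional callable mapping a representative frame index to a loop state
    label (e.g. "as/sa"), added as a ``state`` column.
    """
    order = np.argsort(-result.percentages, kind="stable")
    rows = []
    other_pct = 0.0
    other_n = 0
    for c in order:
        pct = result.percentages[c]
        if pct >= min_pct:
            row = {
                "cluster": int(c),
                "percentage": float(pct),
                "representative": int(result.representatives[c]),
            }
            if state_labeler is not None:
                row["state"] = str(state_labeler(int(result.representatives[c])))
            rows.append(row)
        else:
            other_pct += float(pct)
            other_n += 1
    if other_n:
        row = {"cluster": "other", "percentage": other_pct, "representative": None}
        if state_labeler is not None:
            row["state"] = None
        rows.append(row)
    return pd.DataFrame(rows)
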