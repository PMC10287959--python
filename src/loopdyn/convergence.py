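"""Sampling-convergence diagnostics: coordinate PCA, KLD(t) and population traces.

Two independent segments of an equilibrium ensemble should develop identical
distributions along collective coordinates.  The diagnostic used here is the
time-dependent Kullback-Leibler divergence

    KLD(t) = sum_i P(t, i) ln( P(t, i) / Q(t, i) )

where P(t, .) and Q(t, .) are Gaussian-KDE histograms (300 bins, normalised
to unit mass) of the principal-component projections of all data from time 0
to t in each segment.  A well-converged pair of segments drives KLD(t)
toward 0.  A complementary diagnostic tracks cluster population percentages
in a sliding window after an equilibration burn-in.

Principal components are computed from the covariance of RMS-fitted
coordinates: every frame is superposed on the ensemble-average structure to
remove rigid-body motion before the covariance matrix is diagonalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, TransformerMixin

from .ensemble_cluster import _center
from .model_io import Topology, Trajectory, select_atoms

__all__ = [
    "PCModel",
    "Histogram",
    "KLDSeries",
    "TrajectoryPCA",
    "fit_pca",
    "project",
    "kde_histogram",
    "kld",
    "kld_curve",
    "population_trace",
]


def _superpose_onto(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares fit every frame (n, k, 3) onto ref (k, 3), batched."""
    refc = _center(ref)
    Fc = _center(frames)
    H = np.einsum("mni,nj->mij", Fc, refc)
    U, s, Vt = np.linalg.svd(H)
    det = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.zeros_like(U)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = det
    R = np.einsum("mij,mjk,mkl->mil", U, D, Vt)  # rotation applied to Fc
    return np.einsum("mni,mij->mnj", Fc, R)


@dataclass
class PCModel:
    """Mean structure and covariance eigendecomposition of fitted coordinates."""

    mean_structure: np.ndarray  # (k, 3)
    eigenvectors: np.ndarray  # (modes, 3k), orthonormal rows, descending
    eigenvalues: np.ndarray  # (modes,) A^2, descending
    selection: np.ndarray


class TrajectoryPCA(TransformerMixin, BaseEstimator):
    """PCA of RMS-fitted Cartesian coordinates.

    fit() runs a two-pass procedure: superpose all frames on the first
    frame, average, re-superpose on that average and recompute the mean;
    the covariance of the re-fitted coordinates is then diagonalised.
    transform() RMS-fits new frames onto the fitted mean structure before
    projecting on the eigenvectors.

    Attributes (after fit): ``mean_structure_`` (k, 3), ``components_``
    (modes, 3k), ``explained_variance_`` (descending, A^2), ``model_``.
    """

    def __init__(self, selection=None):
        self.selection = selection

    def _resolve(self, topology: Topology) -> np.ndarray:
        if self.selection is None:
            return np.arange(topology.n_atoms)
        if isinstance(self.selection, str):
            return select_atoms(topology, self.selection)
        return np.asarray(self.selection, dtype=int)

    def fit(self, traj: Trajectory, y=None):
        if traj.n_frames < 2:
            raise ValueError("PCA requires at least two frames")
        sel = self._resolve(traj.topology)
        coords = traj.coordinates[:, sel]
        # iterate fit-to-average to its fixed point (2 passes typically
        # suffice; iterating makes transform(fit data) exactly consistent)
        ref = coords[0]
        for _ in range(20):
            fitted = _superpose_onto(coords, ref)
            mean = fitted.mean(axis=0)
            if np.max(np.abs(mean - _center(ref))) < 1e-12:
                break
            ref = mean
        X = (fitted - mean).reshape(traj.n_frames, -1)
        # SVD of the centred data matrix == covariance eigendecomposition
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        eigenvalues = s**2 / (traj.n_frames - 1)
        self.mean_structure_ = mean
        self.components_ = Vt
        self.explained_variance_ = eigenvalues
        self.selection_ = sel
        self.model_ = PCModel(mean, Vt, eigenvalues, sel)
        return self

    def transform(self, traj: Trajectory, modes=None) -> np.ndarray:
        fitted = _superpose_onto(
            traj.coordinates[:, self.selection_], self.mean_structure_
        )
        X = (fitted - _center(self.mean_structure_)).reshape(traj.n_frames, -1)
        proj = X @ self.components_.T
        if modes is not None:
            modes = np.asarray(modes, dtype=int)
            if np.any(modes >= self.components_.shape[0]):
                raise ValueError(
                    f"mode index out of range (have {self.components_.shape[0]} modes)"
                )
            proj = proj[:, modes]
        return proj


def fit_pca(traj: Trajectory, selection=None) -> PCModel:
    """Functional wrapper over :class:`TrajectoryPCA`."""
    return TrajectoryPCA(selection).fit(traj).model_


def project(traj: Trajectory, model: PCModel, modes=None) -> np.ndarray:
    """Project frames on a fitted PC model (frames x modes)."""
    est = TrajectoryPCA()
    est.mean_structure_ = model.mean_structure
    est.components_ = model.eigenvectors
    est.explained_variance_ = model.eigenvalues
    est.selection_ = model.selection
    return est.transform(traj, modes=modes)


@dataclass
class Histogram:
    """Normalised KDE histogram: bin centers and unit-sum masses."""

    centers: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        total = float(np.sum(self.masses))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"masses sum to {total}, expected 1.0")


def kde_histogram(
    values: np.ndarray,
    nbins: int = 300,
    bandwidth: str | float = "scott",
    value_range: tuple[float, float] | None = None,
) -> Histogram:
    """Gaussian-KDE density evaluated at equispaced bin centers, unit mass.

    ``value_range`` fixes the grid (needed to compare two data sets on a
    common support); default is the data range.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise ValueError("KDE requires at least two distinct values")
    lo, hi = value_range if value_range is not None else (values.min(), values.max())
    centers = np.linspace(lo, hi, nbins)
    kde = gaussian_kde(values, bw_method=bandwidth)
    masses = kde(centers)
    masses = masses / masses.sum()
    return Histogram(centers, masses)


def kld(P: Histogram, Q: Histogram, eps: float = 1e-10) -> float:
    """KL divergence sum_i P_i ln(P_i/Q_i) with epsilon-regularised bins.

    Finite samples leave empty bins; a mass floor of ``eps`` is added to
    both histograms (then renormalised) so the divergence stays finite.
    Non-negative by Gibbs' inequality.
    """
    p = P.masses + eps
    q = Q.masses + eps
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


@dataclass
class KLDSeries:
    """Time-resolved KL divergence of one projection mode."""

    times: np.ndarray  # evaluation times (cumulative-data endpoints)
    values: np.ndarray  # nats
    mode: int = 0


def kld_curve(
    projP: np.ndarray,
    projQ: np.ndarray,
    nbins: int = 300,
    n_eval: int = 200,
    bandwidth: str | float = "scott",
    eps: float = 1e-10,
    mode: int = 0,
) -> KLDSeries:
    """Cumulative-data KLD(t) between two projection series of one mode.

    At each evaluation time the histograms P and Q are Gaussian-KDE
    estimates of all data from 0 to t of each segment, on one shared grid
    spanning the union of both full data ranges, and
    KLD(t) = sum_i P(t,i) ln(P(t,i)/Q(t,i)).
    """
    projP = np.asarray(projP, dtype=float).ravel()
    projQ = np.asarray(projQ, dtype=float).ravel()
    if projP.size == 0 or projQ.size == 0:
        raise ValueError("both segments must be nonempty")
    lo = min(projP.min(), projQ.min())
    hi = max(projP.max(), projQ.max())
    n_eval = min(n_eval, min(projP.size, projQ.size))
    fracs = np.linspace(1.0 / n_eval, 1.0, n_eval)
    times = []
    values = []
    for frac in fracs:
        nP = max(2, int(round(frac * projP.size)))
        nQ = max(2, int(round(frac * projQ.size)))
        P = kde_histogram(projP[:nP], nbins, bandwidth, (lo, hi))
        Q = kde_histogram(projQ[:nQ], nbins, bandwidth, (lo, hi))
        times.append(frac)
        values.append(kld(P, Q, eps))
    return KLDSeries(np.asarray(times), np.asarray(values), mode)


def population_trace(
    labels: np.ndarray,
    window: int,
    burn_in: int = 0,
    track: list[int] | None = None,
) -> pd.DataFrame:
    """Sliding-window cluster population percentages.

    The first ``burn_in`` frames are discarded; at every subsequent
    evaluation index the percentage of each tracked cluster within the
    trailing window of ``window`` frames is reported.  Returns a long-format
    DataFrame (frame, cluster, percentage).
    """
    labels = np.asarray(labels)
    if window < 1:
        raise ValueError("window must be >= 1")
    if burn_in >= labels.size:
        raise ValueError("burn_in must leave at least one frame")
    work = labels[burn_in:]
    if window > work.size:
        raise ValueError(
            f"window ({window}) exceeds remaining frames ({work.size})"
        )
    if track is None:
        track = sorted(np.unique(work).tolist())
    rows = []
    for c in track:
        hits = (work == c).astype(float)
        # trailing-window mean via cumulative sums
        csum = np.concatenate([[0.0], np.cumsum(hits)])
        pct = 100.0 * (csum[window:] - csum[:-window]) / window
        frames = burn_in + np.arange(window - 1, work.size)
        rows.append(pd.DataFrame({"frame": frames, "cluster": c, "percentage": pct}))
    return pd.concat(rows, ignore_index=True)
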