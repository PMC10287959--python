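import numpy as np
import pytest
from scipy.stats import norm, spearmanr

from loopdyn.convergence import (
    TrajectoryPCA,
    fit_pca,
    kde_histogram,
    kld,
    kld_curve,
    population_trace,
    project,
)
from loopdyn.model_io import Trajectory

from conftest import random_rotation


class TestTrajectoryPCA:
    def test_rigid_transforms_have_zero_variance(self, duplex, rng):
        topo, frame = duplex
        frames = [
            frame @ random_rotation(rng).T + rng.normal(size=3) * 10
            for _ in range(8)
        ]
        model = fit_pca(Trajectory(np.stack(frames), topo))
        assert np.all(model.eigenvalues < 1e-8)

    def test_single_mode_construction(self, duplex, rng):
        topo, frame = duplex
        v = rng.normal(size=frame.shape)
        # Eckart conditions: remove translational and rotational content so
        # the RMS fit does not absorb part of the displacement direction
        v -= v.mean(axis=0)
        x = frame - frame.mean(axis=0)
        L = np.cross(x, v).sum(axis=0)
        inertia = (np.sum(x**2) * np.eye(3) - x.T @ x)
        omega = np.linalg.solve(inertia, L)
        v -= np.cross(omega, x)
        v /= np.linalg.norm(v)
        deltas = np.array([-0.02, -0.01, 0.01, 0.02])
        frames = np.stack([frame + d * v for d in deltas])
        traj = Trajectory(frames, topo)
        model = fit_pca(traj)
        expected = np.var(deltas, ddof=1)
        assert model.eigenvalues[0] == pytest.approx(expected, rel=1e-6)
        assert np.all(model.eigenvalues[1:] < 1e-10)
        proj = project(traj, model, modes=[0])[:, 0]
        # projections reproduce the construction sequence up to global sign
        sign = np.sign(proj[np.argmax(np.abs(proj))]) * np.sign(deltas[-1])
        np.testing.assert_allclose(sign * proj, deltas, atol=1e-8)

    def test_total_variance_equals_eigenvalue_sum(self, gg_small_ensemble):
        traj, _ = gg_small_ensemble
        est = TrajectoryPCA().fit(traj)
        proj = est.transform(traj)
        total = proj.var(axis=0, ddof=1).sum()
        assert total == pytest.approx(est.explained_variance_.sum(), rel=1e-8)

    def test_projection_variance_matches_eigenvalues(self, gg_small_ensemble):
        traj, _ = gg_small_ensemble
        est = TrajectoryPCA().fit(traj)
        proj = est.transform(traj)
        np.testing.assert_allclose(
            proj[:, :5].var(axis=0, ddof=1),
            est.explained_variance_[:5],
            rtol=1e-6, atol=1e-10,
        )

    def test_mean_structure_projects_to_zero(self, gg_small_ensemble):
        traj, _ = gg_small_ensemble
        est = TrajectoryPCA().fit(traj)
        mean_traj = Trajectory(est.mean_structure_[None], traj.topology)
        np.testing.assert_allclose(
            est.transform(mean_traj), 0.0, atol=1e-8
        )

    def test_eigenvalues_invariant_under_global_rigid_transform(
        self, gg_small_ensemble, rng
    ):
        traj, _ = gg_small_ensemble
        sub = traj.slice_frames(slice(0, 30))
        base = fit_pca(sub).eigenvalues
        R = random_rotation(rng)
        moved = Trajectory(sub.coordinates @ R.T + 7.5, sub.topology)
        np.testing.assert_allclose(fit_pca(moved).eigenvalues, base, atol=1e-6)

    def test_requires_two_frames(self, duplex):
        topo, frame = duplex
        with pytest.raises(ValueError, match="two frames"):
            fit_pca(Trajectory(frame[None], topo))

    def test_mode_out_of_range(self, gg_small_ensemble):
        traj, _ = gg_small_ensemble
        est = TrajectoryPCA().fit(traj)
        with pytest.raises(ValueError, match="mode"):
            est.transform(traj, modes=[10**6])


class TestKDEHistogram:
    def test_masses_sum_to_one(self, rng):
        h = kde_histogram(rng.normal(size=500))
        assert h.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_data_gives_symmetric_histogram(self, rng):
        x = rng.normal(size=2000)
        x = np.concatenate([x, -x])  # exactly symmetric sample
        h = kde_histogram(x, nbins=301, value_range=(-4, 4))
        np.testing.assert_allclose(h.masses, h.masses[::-1], atol=1e-10)

    def test_normal_sample_matches_density_quadrature(self, rng):
        x = rng.normal(size=400_000)
        h = kde_histogram(x, nbins=300, value_range=(-4, 4))
        # oracle: a Gaussian KDE of N(0,1) data estimates the convolution
        # N(0, 1 + bw^2); quadrature of that density on the same grid
        bw = x.std(ddof=1) * x.size ** (-1 / 5)  # Scott's rule, 1D
        expected = norm.pdf(h.centers, scale=np.sqrt(1.0 + bw**2))
        expected /= expected.sum()
        bulk = np.abs(h.centers) <= 1.5
        rel = np.abs(h.masses[bulk] - expected[bulk]) / expected[bulk]
        assert rel.max() < 0.02

    def test_degenerate_data_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            kde_histogram(np.ones(10))


class TestKLD:
    def test_self_divergence_is_zero(self, rng):
        x = rng.normal(size=3000)
        series = kld_curve(x, x, nbins=100, n_eval=5)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)

    def test_gaussian_closed_form(self, rng):
        # KL(N(0,1) || N(1,1)) = (mu1-mu2)^2 / 2 = 0.5 nats
        P = rng.normal(0.0, 1.0, 50_000)
        Q = rng.normal(1.0, 1.0, 50_000)
        lo = min(P.min(), Q.min())
        hi = max(P.max(), Q.max())
        hp = kde_histogram(P, 300, value_range=(lo, hi))
        hq = kde_histogram(Q, 300, value_range=(lo, hi))
        assert kld(hp, hq) == pytest.approx(0.5, abs=0.05)

    def test_nonnegative_and_decreasing_for_same_distribution(self, rng):
        P = rng.normal(size=6000)
        Q = rng.normal(size=6000)
        series = kld_curve(P, Q, nbins=150, n_eval=20)
        assert np.all(series.values >= 0)
        rho, _ = spearmanr(series.times, series.values)
        assert rho < 0  # divergence shrinks as cumulative data grows

    def test_empty_segment_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            kld_curve(np.array([]), np.array([1.0, 2.0]))


class TestPopulationTrace:
    def test_constant_labels_flat_100(self):
        trace = population_trace(np.zeros(50, dtype=int), window=10)
        assert (trace["percentage"] == 100.0).all()

    def test_alternating_labels_flat_50(self):
        labels = np.tile([0, 1], 30)
        trace = population_trace(labels, window=2)
        assert (trace["percentage"] == 50.0).all()

    def test_burn_in_discards_prefix(self):
        labels = np.concatenate([np.ones(20, dtype=int), np.zeros(30, dtype=int)])
        trace = population_trace(labels, window=10, burn_in=20, track=[0])
        assert (trace["percentage"] == 100.0).all()
        assert trace["frame"].min() == 29

    def test_windows_partition_to_100(self, rng):
        labels = rng.integers(0, 3, size=200)
        trace = population_trace(labels, window=25)
        sums = trace.groupby("frame")["percentage"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_markov_stationary_distribution(self):
        from loopdyn.synthetic_data import markov_labels

        T = np.array([[0.9, 0.1], [0.15, 0.85]])  # pi = (0.6, 0.4)
        labels = markov_labels(T, 50_000, seed=5)
        trace = population_trace(labels, window=20_000, track=[0, 1])
        mean0 = trace[trace["cluster"] == 0]["percentage"].mean()
        assert mean0 == pytest.approx(60.0, abs=3.0)

    def test_window_too_large_raises(self):
        with pytest.raises(ValueError, match="window"):
            population_trace(np.zeros(10, dtype=int), window=11)
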