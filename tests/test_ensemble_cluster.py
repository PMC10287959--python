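import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from loopdyn.ensemble_cluster import (
    AverageLinkageRMSDClustering,
    GreedyRMSDClustering,
    greedy_cluster,
    hier_cluster_average_linkage,
    kabsch_rmsd,
    pairwise_symmetry_rmsd,
    report_clusters,
    symmetry_min_rmsd,
)
from loopdyn.model_io import Trajectory

from conftest import random_rotation


def rmsd_minimize_oracle(X, Y):
    """Numeric minimisation over a rotation-vector parameterisation."""
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((Xc - Yc @ R.T) ** 2, axis=1)))

    best = np.inf
    for seed_rv in np.array(
        [[0, 0, 0], [np.pi, 0, 0], [0, np.pi, 0], [0, 0, np.pi],
         [1.1, 2.0, -0.5], [-2.0, 0.3, 1.7]]
    ):
        res = minimize(cost, seed_rv, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabschRMSD:
    def test_identity_is_zero(self, rng):
        X = rng.normal(size=(10, 3))
        assert kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-7)

    def test_rigid_transform_invariance(self, rng):
        X = rng.normal(size=(12, 3))
        Y = X @ random_rotation(rng).T + np.array([5.0, 5.0, 5.0])
        assert kabsch_rmsd(X, Y) == pytest.approx(0.0, abs=1e-9)

    def test_matches_numeric_minimisation_oracle(self, rng):
        for _ in range(3):
            X = rng.normal(size=(4, 3)) * 2
            Y = rng.normal(size=(4, 3)) * 2
            assert kabsch_rmsd(X, Y) == pytest.approx(
                rmsd_minimize_oracle(X, Y), abs=1e-6
            )

    def test_too_few_atoms_raise(self):
        with pytest.raises(ValueError, match="3 atoms"):
            kabsch_rmsd(np.zeros((2, 3)), np.ones((2, 3)))


class TestSymmetryMinRMSD:
    def test_strand_swapped_copy_is_distance_zero(self, duplex, loop_heavy):
        topo, frame = duplex
        # break the built-in C2 symmetry so identity RMSD is nonzero
        asym = frame.copy()
        res = topo.residues[5]
        asym[res.start:res.stop] += np.array([2.0, 0.0, 0.0])
        swap = topo.symmetry_perms[1]
        swapped = asym[swap]
        d_id = kabsch_rmsd(asym[loop_heavy], swapped[loop_heavy])
        d_sym, perm = symmetry_min_rmsd(asym, swapped, topo, loop_heavy)
        assert d_id > 0.5
        assert d_sym == pytest.approx(0.0, abs=1e-9)
        assert not np.array_equal(perm, topo.symmetry_perms[0])

    def test_identity_only_reduces_to_kabsch(self, duplex, loop_heavy, rng):
        topo, frame = duplex
        other = frame + rng.normal(scale=0.5, size=frame.shape)
        from loopdyn.model_io import Topology

        no_sym = Topology(topo.atoms, topo.residues)  # identity only
        d, perm = symmetry_min_rmsd(frame, other, no_sym, loop_heavy)
        assert d == pytest.approx(
            kabsch_rmsd(frame[loop_heavy], other[loop_heavy]), abs=1e-12
        )

    def test_min_over_perms_and_symmetric(self, duplex, loop_heavy, rng):
        topo, frame = duplex
        other = frame + rng.normal(scale=1.0, size=frame.shape)
        d, _ = symmetry_min_rmsd(frame, other, topo, loop_heavy)
        candidates = [
            kabsch_rmsd(frame[loop_heavy], other[perm[loop_heavy]])
            for perm in topo.symmetry_perms
        ]
        assert d == pytest.approx(min(candidates), abs=1e-12)
        d_rev, _ = symmetry_min_rmsd(other, frame, topo, loop_heavy)
        assert d == pytest.approx(d_rev, abs=1e-9)


def _two_bundle_traj(duplex, rng, n_a=12, n_b=8):
    topo, frame = duplex
    shifted = frame.copy()
    for r in (5, 6):
        res = topo.residues[r]
        shifted[res.start:res.stop] += np.array([0.0, 8.0, 0.0])
    frames = [frame + rng.normal(scale=0.05, size=frame.shape) for _ in range(n_a)]
    frames += [shifted + rng.normal(scale=0.05, size=frame.shape) for _ in range(n_b)]
    return Trajectory(np.stack(frames), topo)


class TestGreedyClustering:
    def test_identical_frames_one_cluster(self, duplex):
        topo, frame = duplex
        traj = Trajectory(np.repeat(frame[None], 6, axis=0), topo)
        result = greedy_cluster(traj, 1.0)
        assert result.n_clusters == 1
        assert result.percentages[0] == 100.0

    def test_two_bundles_recovered_with_proportions(self, duplex, loop_heavy, rng):
        traj = _two_bundle_traj(duplex, rng)
        result = greedy_cluster(traj, 1.0, loop_heavy)
        assert result.n_clusters == 2
        np.testing.assert_allclose(sorted(result.percentages), [40.0, 60.0])
        # oracle: thresholding the exhaustive pairwise distance matrix
        dm = pairwise_symmetry_rmsd(traj.coordinates, traj.topology, loop_heavy)
        same = dm < 1.0
        for i in range(traj.n_frames):
            for j in range(traj.n_frames):
                assert (result.labels[i] == result.labels[j]) == same[i, j]

    def test_symmetry_merges_strand_swapped_copies(self, duplex, loop_heavy, rng):
        topo, frame = duplex
        asym = frame.copy()
        res = topo.residues[5]
        asym[res.start:res.stop] += np.array([3.0, 0.0, 0.0])
        swap = topo.symmetry_perms[1]
        frames = [asym + rng.normal(scale=0.05, size=frame.shape) for _ in range(4)]
        frames += [asym[swap] + rng.normal(scale=0.05, size=frame.shape)
                   for _ in range(4)]
        traj = Trajectory(np.stack(frames), topo)
        with_sym = greedy_cluster(traj, 1.0, loop_heavy, symmetry=True)
        without = greedy_cluster(traj, 1.0, loop_heavy, symmetry=False)
        assert with_sym.n_clusters == 1
        assert without.n_clusters == 2

    def test_cutoff_limits(self, duplex, loop_heavy, rng):
        traj = _two_bundle_traj(duplex, rng, n_a=4, n_b=4)
        tiny = greedy_cluster(traj, 1e-9, loop_heavy)
        assert tiny.n_clusters == traj.n_frames  # every distinct frame alone
        huge = greedy_cluster(traj, 1e9, loop_heavy)
        assert huge.n_clusters == 1

    def test_percentages_always_sum_to_100(self, gg_small_ensemble, loop_heavy):
        traj, _ = gg_small_ensemble
        result = greedy_cluster(traj, 1.0, loop_heavy)
        assert result.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_estimator_api(self, duplex, loop_heavy, rng):
        traj = _two_bundle_traj(duplex, rng, n_a=3, n_b=3)
        est = GreedyRMSDClustering(cutoff=1.0, selection=loop_heavy)
        labels = est.fit_predict(traj)
        assert est.n_clusters_ == 2
        np.testing.assert_array_equal(labels, est.labels_)
        assert est.get_params()["cutoff"] == 1.0
        est.set_params(cutoff=2.5)
        assert est.cutoff == 2.5


def naive_average_linkage(dm, cutoff):
    """Brute-force O(n^3) agglomeration oracle."""
    clusters = [[i] for i in range(dm.shape[0])]
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dm[i, j] for i in clusters[a] for j in clusters[b]])
                if d < best[0]:
                    best = (d, a, b)
        if best[0] > cutoff:
            break
        d, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(dm.shape[0], dtype=int)
    # relabel by first frame for comparability
    firsts = sorted(range(len(clusters)), key=lambda c: min(clusters[c]))
    for new, c in enumerate(firsts):
        for i in clusters[c]:
            labels[i] = new
    return labels


class TestHierarchicalClustering:
    def test_identical_frames_one_cluster(self, duplex):
        topo, frame = duplex
        traj = Trajectory(np.repeat(frame[None], 4, axis=0), topo)
        assert hier_cluster_average_linkage(traj, 1.2).n_clusters == 1

    def test_three_separated_singletons(self, duplex, loop_heavy):
        topo, frame = duplex
        frames = [frame.copy() for _ in range(3)]
        for k, f in enumerate(frames[1:], start=1):
            for r in (5, 6):
                res = topo.residues[r]
                f[res.start:res.stop] += np.array([8.0 * k, 8.0 * k, 0.0])
        traj = Trajectory(np.stack(frames), topo)
        assert hier_cluster_average_linkage(traj, 1.2, loop_heavy).n_clusters == 3

    def test_matches_naive_agglomeration_oracle(self, gg_small_ensemble, loop_heavy):
        traj, _ = gg_small_ensemble
        sub = traj.slice_frames(slice(0, 14))
        result = hier_cluster_average_linkage(sub, 1.2, loop_heavy)
        dm = pairwise_symmetry_rmsd(sub.coordinates, sub.topology, loop_heavy)
        expected = naive_average_linkage(dm, 1.2)
        np.testing.assert_array_equal(result.labels, expected)

    def test_representative_is_medoid(self, duplex, loop_heavy, rng):
        traj = _two_bundle_traj(duplex, rng, n_a=5, n_b=4)
        result = hier_cluster_average_linkage(traj, 1.2, loop_heavy)
        dm = pairwise_symmetry_rmsd(traj.coordinates, traj.topology, loop_heavy)
        for c in range(result.n_clusters):
            members = np.flatnonzero(result.labels == c)
            sub = dm[np.ix_(members, members)]
            assert result.representatives[c] == members[np.argmin(sub.mean(axis=1))]

    def test_frame_cap(self, duplex):
        topo, frame = duplex
        traj = Trajectory(np.repeat(frame[None], 5, axis=0), topo)
        with pytest.raises(ValueError, match="stride"):
            AverageLinkageRMSDClustering(max_frames=4).fit(traj)


class TestReport:
    def _result(self, percentages):
        from loopdyn.ensemble_cluster import ClusterResult

        counts = np.asarray(percentages) * 2  # 200 frames total
        labels = np.concatenate(
            [np.full(int(c), k) for k, c in enumerate(counts)]
        )
        reps = [int(np.flatnonzero(labels == k)[0]) for k in range(len(counts))]
        return ClusterResult(labels, np.array(reps), np.asarray(percentages, float))

    def test_threshold_aggregates_other(self):
        result = self._result([60.0, 30.0, 9.5, 0.5])
        table = report_clusters(result, min_pct=1.0)
        assert len(table) == 4
        assert table.iloc[-1]["cluster"] == "other"
        assert table.iloc[-1]["percentage"] == pytest.approx(0.5)
        assert table["percentage"].sum() == pytest.approx(100.0)

    def test_min_pct_zero_reports_all(self):
        result = self._result([60.0, 30.0, 9.5, 0.5])
        table = report_clusters(result, min_pct=0.0)
        assert len(table) == 4
        assert list(table["percentage"]) == [60.0, 30.0, 9.5, 0.5]

    def test_ground_truth_recovery_with_state_labels(
        self, gg_small_ensemble, loop_heavy
    ):
        from loopdyn.torsion_states import chi_series, classify_states, loop_state_label

        traj, labels = gg_small_ensemble
        result = greedy_cluster(traj, 1.0, loop_heavy)
        chis = chi_series(traj, [5, 6, 17, 18])
        letters = classify_states(chis.values)

        def labeler(f):
            states = dict(zip([5, 6, 17, 18], letters[f]))
            return str(loop_state_label(states, ([5, 6], [17, 18])))

        table = report_clusters(result, 1.0, labeler)
        named = table[table["cluster"] != "other"]
        assert list(named["percentage"]) == [42.5, 36.0, 4.0, 3.5]
        assert list(named["state"]) == ["as/sa", "as/as", "aa/aa", "as/sa"]
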