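import numpy as np
import pytest

from mutshift.pca_states import (
    FrameWeights,
    MagnitudeMatrix,
    ProjectionSeries,
    fit_pca,
    magnitude_matrix,
    partition_states,
    project,
    state_weighted_frames,
)
from conftest import make_trajectory


def jacobi_eigh(a, sweeps=100, tol=1e-14):
    """Cyclic-Jacobi symmetric eigensolver (independent oracle)."""
    a = np.array(a, dtype=float)
    n = a.shape[0]
    v = np.eye(n)
    for _ in range(sweeps):
        off = np.sqrt(np.sum(np.tril(a, -1) ** 2))
        if off < tol:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(a[p, q]) < 1e-300:
                    continue
                theta = 0.5 * np.arctan2(2 * a[p, q], a[q, q] - a[p, p])
                c, s = np.cos(theta), np.sin(theta)
                rot = np.eye(n)
                rot[p, p] = rot[q, q] = c
                rot[p, q] = s
                rot[q, p] = -s
                a = rot.T @ a @ rot
                v = v @ rot
    return np.diag(a), v


class TestMagnitudeMatrix:
    def test_static_trajectory_gives_zeros(self):
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        traj = make_trajectory(np.repeat(frame[None], 5, axis=0), aligned=True)
        np.testing.assert_allclose(magnitude_matrix(traj).values, 0.0, atol=1e-12)

    def test_hand_computed_two_frame_case(self):
        # residue 1 alternates (0,0,0)/(2,0,0): mean (1,0,0), magnitudes 1, 1
        coords = np.array(
            [[[0.0, 0, 0], [0, 5, 0]], [[2.0, 0, 0], [0, 5, 0]]]
        )
        mag = magnitude_matrix(make_trajectory(coords, aligned=True))
        np.testing.assert_allclose(mag.values[0], [1.0, 1.0])
        np.testing.assert_allclose(mag.values[1], [0.0, 0.0], atol=1e-12)

    def test_matches_naive_double_loop(self, rng):
        coords = rng.normal(size=(5, 3, 3)) * 4
        mag = magnitude_matrix(make_trajectory(coords, aligned=True))
        for i in range(3):
            mean = coords[:, i, :].mean(axis=0)
            for m in range(5):
                expect = np.sqrt(np.sum((coords[m, i] - mean) ** 2))
                assert abs(mag.values[i, m] - expect) < 1e-12


class TestFitPCA:
    def test_zero_matrix(self):
        model = fit_pca(MagnitudeMatrix(np.zeros((3, 4))))
        np.testing.assert_allclose(model.covariance, 0.0)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-14)

    def test_two_by_two_closed_form(self):
        model = fit_pca(MagnitudeMatrix(np.ones((2, 2))))
        np.testing.assert_allclose(model.covariance, np.ones((2, 2)))
        np.testing.assert_allclose(model.eigenvalues, [2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(
            np.abs(model.eigenvectors[:, 0]), [1 / np.sqrt(2)] * 2
        )
        assert model.eigenvectors[:, 0][0] > 0  # sign convention

    def test_matches_jacobi_oracle(self, rng):
        a = np.abs(rng.normal(size=(5, 50)))
        model = fit_pca(MagnitudeMatrix(a))
        cov_oracle = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                cov_oracle[i, j] = np.sum(a[i] * a[j]) / 50
        np.testing.assert_allclose(model.covariance, cov_oracle, rtol=1e-12)
        evals, _ = jacobi_eigh(cov_oracle)
        np.testing.assert_allclose(
            np.sort(model.eigenvalues), np.sort(evals), rtol=1e-8
        )

    def test_no_row_centering(self):
        # rows with nonzero mean: covariance is the second-moment matrix,
        # not a mean-centered covariance
        a = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        model = fit_pca(MagnitudeMatrix(a))
        np.testing.assert_allclose(model.covariance, [[1.0, 2.0], [2.0, 4.0]])

    def test_trace_conservation(self, rng):
        a = np.abs(rng.normal(size=(6, 30)))
        model = fit_pca(MagnitudeMatrix(a))
        assert np.isclose(
            model.eigenvalues.sum(), np.trace(model.covariance), rtol=1e-8
        )

    def test_eigenpair_consistency(self, rng):
        a = np.abs(rng.normal(size=(4, 20)))
        model = fit_pca(MagnitudeMatrix(a))
        for k in range(4):
            lhs = model.covariance @ model.eigenvectors[:, k]
            rhs = model.eigenvalues[k] * model.eigenvectors[:, k]
            np.testing.assert_allclose(lhs, rhs, atol=1e-8)
        np.testing.assert_allclose(
            model.eigenvectors.T @ model.eigenvectors, np.eye(4), atol=1e-8
        )


class TestProject:
    def test_zero_matrix_zero_series(self):
        mag = MagnitudeMatrix(np.zeros((3, 5)))
        series = project(mag, fit_pca(mag), 1)
        np.testing.assert_allclose(series.values, 0.0)

    def test_explicit_sum_oracle(self, rng):
        a = np.abs(rng.normal(size=(5, 12)))
        mag = MagnitudeMatrix(a)
        model = fit_pca(mag)
        series = project(mag, model, 2)
        for m in range(12):
            expect = sum(model.eigenvectors[nn, 1] * a[nn, m] for nn in range(5))
            assert abs(series.values[m] - expect) < 1e-10

    def test_projection_variance_matches_eigenvalue(self, rng):
        a = np.abs(rng.normal(size=(4, 200)))
        mag = MagnitudeMatrix(a)
        model = fit_pca(mag)
        for mode in (1, 2):
            s = project(mag, model, mode).values
            # second moment of projection = eigenvalue (uncentered rows)
            assert np.isclose(np.mean(s**2), model.eigenvalues[mode - 1], rtol=1e-8)
            assert np.isclose(
                np.var(s), model.eigenvalues[mode - 1] - np.mean(s) ** 2, rtol=1e-6
            )

    def test_residual_orthogonal_to_mode(self, rng):
        a = np.abs(rng.normal(size=(4, 30)))
        mag = MagnitudeMatrix(a)
        model = fit_pca(mag)
        v1 = model.eigenvectors[:, 0]
        proj = project(mag, model, 1).values
        residual = a - np.outer(v1, proj)
        np.testing.assert_allclose(v1 @ residual, 0.0, atol=1e-8)

    def test_mode_out_of_range(self, rng):
        mag = MagnitudeMatrix(np.abs(rng.normal(size=(3, 5))))
        model = fit_pca(mag)
        with pytest.raises(ValueError):
            project(mag, model, 4)


def _series(x):
    return ProjectionSeries(mode_index=1, values=np.asarray(x, dtype=float))


class TestPartitionStates:
    def test_degenerate_single_state(self):
        part = partition_states(_series([1.0] * 10), _series([2.0] * 10))
        assert part.n_states == 1
        assert part.state_probabilities == {1: 1.0}
        assert np.all(part.state_labels == 1)

    def test_planted_clusters_80_20(self, rng):
        a = rng.normal(size=(80, 2)) * 0.3
        b = rng.normal(size=(20, 2)) * 0.3 + 10.0
        pts = np.vstack([a, b])
        part = partition_states(_series(pts[:, 0]), _series(pts[:, 1]))
        assert part.n_states == 2
        assert np.isclose(part.state_probabilities[1], 0.8)
        assert np.isclose(part.state_probabilities[2], 0.2)
        assert part.dominant_state == 1

    def test_even_split_tie_break(self, rng):
        a = rng.normal(size=(50, 2)) * 0.2
        b = rng.normal(size=(50, 2)) * 0.2 + 8.0
        pts = np.vstack([a, b])
        part = partition_states(_series(pts[:, 0]), _series(pts[:, 1]))
        assert part.n_states == 2
        assert part.dominant_state == 1  # lowest label wins the tie

    def test_permutation_invariance(self, rng):
        a = rng.normal(size=(80, 2)) * 0.3
        b = rng.normal(size=(20, 2)) * 0.3 + 10.0
        pts = np.vstack([a, b])
        perm = rng.permutation(100)
        p1 = partition_states(_series(pts[:, 0]), _series(pts[:, 1]))
        p2 = partition_states(_series(pts[perm, 0]), _series(pts[perm, 1]))
        assert p1.state_probabilities == p2.state_probabilities
        np.testing.assert_array_equal(p1.state_labels[perm], p2.state_labels)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            partition_states(_series([1, 2]), _series([1, 2, 3]))


class TestStateWeightedFrames:
    def test_single_state_all_frames_weight_one(self, rng):
        traj = make_trajectory(rng.normal(size=(10, 3, 3)), aligned=True)
        part = partition_states(_series(np.zeros(10)), _series(np.zeros(10)))
        fw = state_weighted_frames(part, traj)
        assert len(fw.frame_indices) == 10
        np.testing.assert_allclose(fw.weights, 1.0)

    def test_dominant_selection_and_total_weight(self, rng):
        traj = make_trajectory(rng.normal(size=(100, 3, 3)), aligned=True)
        a = rng.normal(size=(80,)) * 0.2
        b = rng.normal(size=(20,)) * 0.2 + 10.0
        pc1 = _series(np.concatenate([a, b]))
        part = partition_states(pc1, _series(np.zeros(100)))
        fw = state_weighted_frames(part, traj)
        assert len(fw.frame_indices) == 80
        np.testing.assert_allclose(fw.weights, 0.8)
        assert np.isclose(fw.total_weight, 64.0)

    def test_probability_scaled_mean_convention(self):
        """Probability-scaled weighting returns state mean × state probability."""
        values = np.concatenate([np.full(80, 5.0), np.full(20, 11.0)])
        fw = FrameWeights(np.arange(80), np.full(80, 0.8), convention="probability-scaled")
        assert np.isclose(fw.mean(values), 0.8 * 5.0)
        fw_norm = FrameWeights(np.arange(80), np.full(80, 0.8))
        assert np.isclose(fw_norm.mean(values), 5.0)
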