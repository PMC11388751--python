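"""Manifold embeddings: LLE, diffusion maps, Laplacian eigenmaps, and
the epoch-count decimation bookkeeping."""

import numpy as np
import pytest

from conftest import make_matrix
from ecgdetect.embedding import (
    DMParams,
    LEParams,
    LLEParams,
    decimate_epoch_count,
    decimate_epochs,
    diffusion_map_embed,
    graph_laplacian,
    laplacian_eigenmap_embed,
    le_cost,
    lle_embed,
    lle_reconstruction_weights,
)
from ecgdetect.epochs import EpochMatrix, SyntheticConfig, generate_synthetic_ecg


def trustworthiness_bruteforce(x, coords, k=10):
    """Neighbourhood-preservation score from brute-force pairwise
    distances (independent of the embedding code path)."""
    n = len(x)
    dx = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    dc = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    np.fill_diagonal(dx, np.inf)
    np.fill_diagonal(dc, np.inf)
    rank_x = np.argsort(np.argsort(dx, axis=1), axis=1)  # 0 = nearest
    t = 0.0
    for i in range(n):
        emb_nn = np.argsort(dc[i])[:k]
        for j in emb_nn:
            r = rank_x[i, j]
            if r >= k:
                t += r - k + 1
    norm = n * k * (2 * n - 3 * k - 1) / 2
    return 1.0 - 2.0 * t / norm


class TestLLE:
    def test_collinear_points_reconstruct_exactly(self):
        rng = np.random.default_rng(0)
        x = np.outer(np.linspace(0, 1, 50), rng.normal(size=10))
        w = lle_reconstruction_weights(x, 5, 1e-6)
        cost = float(((x - w @ x) ** 2).sum(axis=1).max())
        assert cost < 1e-10

    def test_weight_rows_sum_to_one(self, rng):
        x = rng.normal(size=(60, 8))
        w = lle_reconstruction_weights(x, 7, 1e-3)
        sums = np.asarray(w.sum(axis=1)).ravel()
        assert np.abs(sums - 1).max() < 1e-12

    def test_embedding_second_moment_is_identity(self, rng):
        mat = make_matrix(rng.normal(size=(80, 12)))
        res = lle_embed(mat, LLEParams(k_neighbors=10, target_dim=3))
        cov = res.coords.T @ res.coords / len(res.coords)
        assert np.abs(cov - np.eye(3)).max() < 1e-6

    def test_s_curve_trustworthiness(self):
        from sklearn.datasets import make_s_curve

        x, _ = make_s_curve(n_samples=400, random_state=3)
        mat = make_matrix(x)
        res = lle_embed(mat, LLEParams(k_neighbors=10, target_dim=2))
        assert trustworthiness_bruteforce(x, res.coords, k=10) >= 0.85

    def test_too_few_points_rejected(self, rng):
        mat = make_matrix(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="k_neighbors"):
            lle_embed(mat, LLEParams(k_neighbors=12, target_dim=2))


class TestDiffusionMaps:
    def test_transition_matrix_is_row_stochastic(self, rng):
        mat = make_matrix(rng.normal(size=(30, 6)))
        res = diffusion_map_embed(mat, DMParams(h=4))
        b = res.extras["transition_matrix"]
        assert np.abs(b.sum(axis=1) - 1).max() < 1e-12

    def test_coincident_points_have_zero_diffusion_distance(self, rng):
        pts = rng.normal(size=(10, 3))
        pts[4] = pts[7]
        res = diffusion_map_embed(make_matrix(pts), DMParams(h=3))
        b = res.extras["transition_matrix"]
        assert np.abs(b[4] - b[7]).max() < 1e-10
        assert np.abs(res.coords[4] - res.coords[7]).max() < 1e-10

    def test_three_point_line_matches_dense_oracle(self):
        """3 points at mutual distances {1,1,2}: coordinates equal a dense
        eigendecomposition computed independently, up to sign."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        res = diffusion_map_embed(make_matrix(pts), DMParams(sigma=1.0, t=1, h=2))
        b = res.extras["transition_matrix"]
        vals, vecs = np.linalg.eig(b)
        order = np.argsort(vals.real)[::-1]
        vals, vecs = vals.real[order], vecs.real[:, order]
        psi = vecs / vecs[:, 0:1]  # trivial eigenvector == 1
        oracle = psi[:, 1:3] * vals[1:3]
        for j in range(2):
            a = res.coords[:, j] / np.linalg.norm(res.coords[:, j])
            o = oracle[:, j] / np.linalg.norm(oracle[:, j])
            assert min(np.abs(a - o).max(), np.abs(a + o).max()) < 1e-8

    def test_coordinates_shrink_with_diffusion_time(self, rng):
        pts = rng.normal(size=(25, 4))
        norms = []
        for t in (1, 2, 4, 8):
            res = diffusion_map_embed(make_matrix(pts), DMParams(t=t, h=3))
            norms.append(np.abs(res.coords).max())
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_tiny_sigma_warns(self, rng):
        pts = rng.normal(size=(12, 3))
        with pytest.warns(RuntimeWarning, match="underflow"):
            diffusion_map_embed(make_matrix(pts), DMParams(sigma=1e-6, h=2))

    def test_h_too_large_rejected(self, rng):
        mat = make_matrix(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="h\\+1"):
            diffusion_map_embed(mat, DMParams(h=10))


class TestLaplacianEigenmaps:
    def test_laplacian_structure(self, rng):
        x = rng.normal(size=(25, 4))
        a, p, e = graph_laplacian(x, 4, 1.0)
        assert np.abs(e - e.T).max() < 1e-12
        assert np.abs(e.sum(axis=1)).max() < 1e-12

    def test_path_graph_eigenvalues(self):
        """Unweighted 3-node path: unnormalized Laplacian spectrum {0,1,3}."""
        pts = np.array([[0.0], [1.0], [2.0]])
        # huge kernel width makes edge weights 1 within tolerance
        _, _, e = graph_laplacian(pts, 1, 1e8)
        vals = np.linalg.eigvalsh(e)
        assert np.allclose(vals, [0.0, 1.0, 3.0], atol=1e-9)

    def test_constant_null_vector_excluded_from_coords(self, rng):
        mat = make_matrix(rng.normal(size=(30, 5)))
        res = laplacian_eigenmap_embed(mat, LEParams(m_neighbors=6, target_dim=2))
        vals = res.extras["eigenvalues"]
        assert vals[0] == pytest.approx(0.0, abs=1e-8)
        # generalized null vector is constant; returned columns are not
        for j in range(res.coords.shape[1]):
            assert res.coords[:, j].std() > 1e-8

    def test_disconnected_graph_rejected_with_component_sizes(self):
        pts = np.vstack(
            [np.random.default_rng(0).normal(0, 0.01, (10, 2)),
             np.random.default_rng(1).normal(100, 0.01, (5, 2))]
        )
        with pytest.raises(ValueError, match=r"2 components.*\[10, 5\]"):
            laplacian_eigenmap_embed(make_matrix(pts), LEParams(m_neighbors=3))

    def test_cost_beats_random_orthonormal_competitors(self, rng):
        mat = make_matrix(rng.normal(size=(40, 6)))
        res = laplacian_eigenmap_embed(mat, LEParams(m_neighbors=8, target_dim=2))
        e = res.extras["laplacian"]
        ours = le_cost(e, res.coords)
        for _ in range(20):
            q, _ = np.linalg.qr(rng.normal(size=(40, 2)))
            assert ours <= le_cost(e, q) + 1e-9


class TestDecimation:
    @pytest.mark.parametrize(
        "n,expected",
        [(43333, 2167), (57778, 2889), (84000, 4200), (141750, 7088), (20, 1)],
    )
    def test_counts(self, n, expected):
        assert decimate_epoch_count(n) == expected

    def test_decimate_epochs_matches_count_rule(self):
        mat = generate_synthetic_ecg(SyntheticConfig("NSR", 47, seed=0))
        dec = decimate_epochs(mat)
        assert dec.n_epochs == decimate_epoch_count(47)
        # first of each block of 20 is kept
        assert np.array_equal(dec.data[0], mat.data[0])
        assert np.array_equal(dec.data[1], mat.data[20])


class TestPermutationInvariance:
    @pytest.mark.parametrize("method", ["lle", "dm", "le"])
    def test_row_shuffle_changes_nothing_up_to_sign(self, method, rng):
        from ecgdetect.embedding import embed

        x = rng.normal(size=(40, 6))
        labels = np.array(["VT"] * 40, dtype=object)
        perm = rng.permutation(40)
        params = {
            "lle": LLEParams(k_neighbors=8, target_dim=2),
            "dm": DMParams(h=2),
            "le": LEParams(m_neighbors=8, target_dim=2),
        }[method]
        a = embed(EpochMatrix(x, 1.0, labels), method, params).coords
        b = embed(EpochMatrix(x[perm], 1.0, labels), method, params).coords
        # re-align through the permutation, then compare up to column sign
        b_aligned = np.empty_like(b)
        b_aligned[perm] = b
        for j in range(a.shape[1]):
            dev = min(
                np.abs(a[:, j] - b_aligned[:, j]).max(),
                np.abs(a[:, j] + b_aligned[:, j]).max(),
            )
            assert dev < 1e-6
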