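"""Ordination and clustering against brute-force linear-algebra oracles."""

import numpy as np
import pandas as pd
import pytest

from exudomics import ordination


class TestPCA:
    def test_rank_one_matrix_single_axis(self):
        u = np.arange(5.0)[:, None]
        v = np.array([[1.0, 2.0, 3.0]])
        res = ordination.pca(u @ v)
        assert len(res.eigenvalues) == 1
        assert res.axis_proportions[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        res = ordination.pca(X)
        total = ((X - X.mean(0)) ** 2).sum() / 9
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-12)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 5))
        res = ordination.pca(X)
        C = np.cov(X, rowvar=False)
        w = np.sort(np.linalg.eigvalsh(C))[::-1][: len(res.eigenvalues)]
        assert np.abs(w - res.eigenvalues).max() < 1e-10

    def test_constant_matrix_no_axes_no_error(self):
        res = ordination.pca(np.full((4, 3), 2.0))
        assert len(res.eigenvalues) == 0

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        res = ordination.pca(rng.normal(size=(12, 7)))
        S = res.site_scores.to_numpy()
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8


def _brute_force_rda(Y, X):
    """Hat-matrix + eigendecomposition oracle."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n = Y.shape[0]
    Yc = Y - Y.mean(0)
    Xc = X - X.mean(0)
    H = Xc @ np.linalg.pinv(Xc)
    Yh = H @ Yc
    w = np.sort(np.linalg.eigvalsh(Yh.T @ Yh / (n - 1)))[::-1]
    total = (Yc**2).sum() / (n - 1)
    return w[w > 1e-10], total


class TestRDA:
    def test_perfect_group_explanation(self):
        Y = np.repeat(np.array([[0.0, 1.0], [3.0, 5.0]]), 4, axis=0)
        X = ordination.one_hot(np.repeat(["a", "b"], 4))
        res = ordination.rda(Y, X)
        assert res.constrained_proportion == pytest.approx(1.0)

    def test_constant_predictor_explains_nothing(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(10, 4))
        res = ordination.rda(Y, np.ones((10, 1)))
        assert res.constrained_proportion == pytest.approx(0.0, abs=1e-12)

    def test_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(12, 6))
        X = ordination.one_hot(rng.choice(["a", "b", "c"], 12))
        res = ordination.rda(Y, X)
        w, total = _brute_force_rda(Y, X.to_numpy())
        assert np.abs(res.eigenvalues - w[: len(res.eigenvalues)]).max() \
            < 1e-8
        assert res.total_variance == pytest.approx(total)

    def test_variance_conservation(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(15, 8))
        X = rng.normal(size=(15, 3))
        res = ordination.rda(Y, X)
        assert (
            res.eigenvalues.sum() + res.residual_eigenvalues.sum()
        ) == pytest.approx(res.total_variance, abs=1e-8)

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            ordination.rda(rng.normal(size=(4, 3)),
                           rng.normal(size=(4, 5)))


class TestPartialRDA:
    def test_self_conditioning_removes_everything(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(12, 5))
        X = rng.normal(size=(12, 2))
        res = ordination.partial_rda(Y, X, X)
        assert res.constrained_proportion == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_conditioning_equals_plain_rda(self):
        rng = np.random.default_rng(9)
        n = 40
        # build Z orthogonal to both X and Y columns
        base = rng.normal(size=(n, 8))
        Q, _ = np.linalg.qr(base - base.mean(0))
        X = Q[:, :2]
        Z = Q[:, 2:4]
        Y = Q[:, 4:8] + 0.5 * X @ rng.normal(size=(2, 4))
        plain = ordination.rda(Y, X)
        part = ordination.partial_rda(Y, X, Z)
        assert np.abs(
            plain.eigenvalues - part.eigenvalues
        ).max() < 1e-8

    def test_conservation_with_conditioning(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(20, 6))
        X = rng.normal(size=(20, 3))
        Z = rng.normal(size=(20, 2))
        res = ordination.partial_rda(Y, X, Z)
        total = (
            res.eigenvalues.sum()
            + res.residual_eigenvalues.sum()
            + res.conditioned_proportion * res.total_variance
        )
        assert total == pytest.approx(res.total_variance, abs=1e-8)

    def test_noise_predictor_after_structure_conditioning(self):
        rng = np.random.default_rng(11)
        groups = np.repeat(["a", "b", "c", "d"], 25)
        Z = ordination.one_hot(groups)
        Y = Z.to_numpy() @ rng.normal(size=(4, 6)) + 0.1 * rng.normal(
            size=(100, 6)
        )
        X = rng.normal(size=(100, 2))
        res = ordination.partial_rda(Y, X, Z)
        assert res.constrained_proportion < 0.05


class TestDCA:
    def test_identical_rows_get_identical_axis1_scores(self):
        rng = np.random.default_rng(12)
        M = rng.poisson(4, size=(8, 10)).astype(float) + 0.1
        M[3] = M[0]
        res = ordination.dca(M)
        s = res.site_scores["DCA1"].to_numpy()
        assert s[3] == pytest.approx(s[0], abs=1e-8)

    def test_eigenvalues_within_ca_bounds(self):
        rng = np.random.default_rng(13)
        M = rng.poisson(3, size=(25, 12)).astype(float)
        M[M.sum(1) == 0, 0] = 1
        res = ordination.dca(M)
        assert ((res.eigenvalues >= 0) & (res.eigenvalues <= 1)).all()

    def test_axis1_recovers_simulated_gradient_order(self):
        # Gaussian response curves along one gradient
        rng = np.random.default_rng(14)
        grad = np.linspace(0, 10, 30)
        optima = np.linspace(0, 10, 15)
        M = np.exp(
            -((grad[:, None] - optima[None, :]) ** 2) / 2.0
        ) * 50
        M = rng.poisson(M).astype(float)
        M = M[M.sum(1) > 0]
        grad = grad[: M.shape[0]]
        res = ordination.dca(M)
        s = res.site_scores["DCA1"].to_numpy()
        rho = np.corrcoef(np.argsort(np.argsort(s)),
                          np.argsort(np.argsort(grad)))[0, 1]
        assert abs(rho) > 0.95

    def test_axis1_equals_plain_ca_axis1(self):
        rng = np.random.default_rng(15)
        M = rng.poisson(3, size=(20, 9)).astype(float) + 0.05
        res = ordination.dca(M)
        # independent CA axis 1 via the chi-square residual SVD
        P = M / M.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, s, Vt = np.linalg.svd(S)
        ca1 = U[:, 0] / np.sqrt(r)
        got = res.site_scores["DCA1"].to_numpy()
        rho = np.corrcoef(got, ca1)[0, 1]
        assert abs(rho) == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            ordination.dca(np.zeros((4, 4)))


def _naive_complete_linkage(X):
    """O(n^3) agglomeration oracle returning the cophenetic matrix."""
    n = X.shape[0]
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        keys = list(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = max(
                    D[x, y] for x in clusters[a] for y in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for x in clusters[a]:
            for y in clusters[b]:
                coph[x, y] = coph[y, x] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        X = np.array([[0, 0], [0, 0], [5, 5]], dtype=float)
        d = ordination.hierarchical_cluster(X)
        assert d.merges[0, 2] == 0.0
        assert set(d.merges[0, :2].astype(int)) == {0, 1}

    def test_distant_point_merges_last(self):
        X = np.array([[0.0, 0], [1, 0], [0.5, 1], [50, 50]])
        d = ordination.hierarchical_cluster(X)
        # the last merge height equals the max pairwise distance under
        # complete linkage: outlier (50,50) to the origin
        assert d.merges[-1, 2] == pytest.approx(np.sqrt(2) * 50, rel=1e-6)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(16)
        d = ordination.hierarchical_cluster(rng.normal(size=(20, 5)))
        assert (np.diff(d.merges[:, 2]) >= -1e-12).all()

    def test_cophenetic_matches_naive_oracle(self):
        rng = np.random.default_rng(17)
        X = (rng.random((10, 12)) > 0.5).astype(float)
        d = ordination.hierarchical_cluster(X)
        from scipy.spatial.distance import squareform

        got = squareform(d.cophenetic())
        want = _naive_complete_linkage(X)
        assert np.abs(got - want).max() < 1e-10

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(
            rng.normal(size=(5, 3)), index=list("abcde")
        )
        nwk = ordination.hierarchical_cluster(df).to_newick()
        for leaf in "abcde":
            assert leaf in nwk


class TestShannon:
    def test_single_species_zero(self):
        assert ordination.shannon_diversity([0, 7, 0]) == 0.0

    def test_uniform_four_species_ln4(self):
        assert ordination.shannon_diversity([2, 2, 2, 2]) == pytest.approx(
            np.log(4)
        )

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(19)
        x = rng.random(10)
        p = x / x.sum()
        oracle = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert ordination.shannon_diversity(x) == pytest.approx(oracle)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ordination.shannon_diversity([0.0, 0.0])
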