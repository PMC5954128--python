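import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ortho_group

from alboost.data_io import apply_normalizer, fit_normalizer
from alboost.embedding import (
    Embedding,
    _joint_probabilities,
    pca_embed,
    trust,
    tsne_embed,
)
from alboost.fixtures import FixtureSpec, make_two_class_table
from tests.conftest import random_feature_table


def _clustered(n_per=50, d=35, sep=6.0, seed=1):
    t = make_two_class_table(
        FixtureSpec(n_per_class=(n_per, n_per), d=d, separation=sep,
                    n_informative=min(30, d), seed=seed)
    )
    return apply_normalizer(t, fit_normalizer(t))


def _one_nn_label_agreement(coords, y):
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    return float((y[d.argmin(axis=1)] == y).mean())


class TestTsne:
    def test_shape_finiteness_and_determinism(self):
        t = _clustered(n_per=50)
        a = tsne_embed(t, dims=3, perplexity=20, iterations=250, seed=4)
        b = tsne_embed(t, dims=3, perplexity=20, iterations=250, seed=4)
        assert a.coordinates.shape == (100, 3)
        assert np.all(np.isfinite(a.coordinates))
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_joint_probabilities_symmetric_unit_sum(self):
        rng = np.random.default_rng(0)
        D2 = squareform(pdist(rng.standard_normal((30, 5)), "sqeuclidean"))
        P = _joint_probabilities(D2, perplexity=8.0)
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        np.testing.assert_allclose(P.sum(), 1.0, atol=1e-9)

    def test_separated_clusters_stay_separated_in_map(self):
        t = _clustered()
        emb = tsne_embed(t, dims=3, perplexity=30, iterations=1000, seed=0)
        assert _one_nn_label_agreement(emb.coordinates, t.y) >= 0.95
        # objective decreased over the run
        assert emb.kl_trace[-1] <= emb.kl_trace[0]

    def test_matches_reference_tsne_on_cluster_preservation(self):
        """Independent cross-check: scikit-learn's exact t-SNE preserves the
        same cluster structure on the same fixture."""
        from sklearn.manifold import TSNE

        t = _clustered()
        ours = tsne_embed(t, dims=2, perplexity=30, iterations=1000, seed=0)
        ref = TSNE(
            n_components=2, perplexity=30, method="exact", random_state=0,
            init="random",
        ).fit_transform(t.matrix)
        assert _one_nn_label_agreement(ours.coordinates, t.y) >= 0.95
        assert _one_nn_label_agreement(ref, t.y) >= 0.95
        # comparable neighborhood preservation between the two routes
        assert abs(trust(t, ours, 10).trust - trust(t, ref, 10).trust) < 0.15

    @pytest.mark.parametrize(
        "kwargs", [{"perplexity": 40.0}, {"dims": 4}, {"iterations": 10}]
    )
    def test_infeasible_parameters_rejected(self, kwargs):
        t = _clustered(n_per=30, d=5, sep=2.0)
        with pytest.raises(ValueError):
            tsne_embed(t, **{"dims": 2, "perplexity": 10.0, "iterations": 250, **kwargs})


class TestPca:
    def test_affine_3d_subspace_reconstructed_exactly(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal((40, 3))
        lift = rng.standard_normal((3, 10))
        t = random_feature_table(rng, n=40, d=10)
        t = t.with_matrix(latent @ lift + rng.standard_normal(10))
        emb = pca_embed(t, dims=3)
        # distances in the 3-D scores equal distances in the 10-D data
        np.testing.assert_allclose(
            pdist(emb.coordinates), pdist(t.matrix), atol=1e-8
        )

    def test_full_rank_projection_preserves_distances_and_trust(self):
        rng = np.random.default_rng(2)
        t = random_feature_table(rng, n=25, d=4)
        emb = pca_embed(t, dims=4)
        np.testing.assert_allclose(pdist(emb.coordinates), pdist(t.matrix), atol=1e-8)
        assert trust(t, emb, k=5).trust == 1.0

    def test_beats_random_projections_on_captured_variance(self):
        rng = np.random.default_rng(3)
        t = random_feature_table(rng, n=20, d=5)
        X = t.matrix - t.matrix.mean(axis=0)
        pca_var = pca_embed(t, dims=2).coordinates.var(axis=0, ddof=0).sum()
        for _ in range(200):
            Q, _ = np.linalg.qr(rng.standard_normal((5, 2)))
            assert (X @ Q).var(axis=0, ddof=0).sum() <= pca_var + 1e-9

    def test_dims_out_of_range(self):
        rng = np.random.default_rng(4)
        t = random_feature_table(rng, n=10, d=3)
        with pytest.raises(ValueError):
            pca_embed(t, dims=4)


def _brute_force_trust(X, Y, k):
    """Exhaustive neighbor-set oracle: sorted (distance, index) lists."""
    n = X.shape[0]
    total = 0
    for i in range(n):
        high = sorted((np.linalg.norm(X[i] - X[j]), j) for j in range(n) if j != i)
        low = sorted((np.linalg.norm(Y[i] - Y[j]), j) for j in range(n) if j != i)
        high_set = {j for _, j in high[:k]}
        low_set = {j for _, j in low[:k]}
        total += len(high_set & low_set)
    return total / (n * k)


class TestTrust:
    def test_identity_embedding_scores_one(self):
        rng = np.random.default_rng(5)
        t = random_feature_table(rng, n=15, d=3)
        assert trust(t, t.matrix, k=4).trust == 1.0

    @pytest.mark.parametrize("n,k", [(5, 1), (6, 2), (8, 3), (8, 7)])
    def test_matches_exhaustive_oracle(self, n, k):
        rng = np.random.default_rng(100 * n + k)
        X = rng.standard_normal((n, 4))
        Y = rng.standard_normal((n, 2))
        result = trust(X, Y, k=k)
        assert result.trust == pytest.approx(_brute_force_trust(X, Y, k))
        assert result.trust == pytest.approx(result.overlaps.mean() / k)

    def test_random_shuffle_scores_near_chance(self):
        rng = np.random.default_rng(6)
        n, k = 200, 10
        X = rng.standard_normal((n, 8))
        scores = [
            trust(X, X[rng.permutation(n)], k=k).trust for _ in range(20)
        ]
        assert np.mean(scores) == pytest.approx(k / (n - 1), abs=0.02)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        t = random_feature_table(rng, n=30, d=6)
        Y = rng.standard_normal((30, 3))
        base = trust(t, Y, k=5)
        R = ortho_group.rvs(3, random_state=8)
        moved = Y @ R + np.array([5.0, -3.0, 11.0])
        assert trust(t, moved, k=5).trust == base.trust

    def test_size_mismatch_and_bad_k(self):
        rng = np.random.default_rng(9)
        t = random_feature_table(rng, n=10, d=3)
        with pytest.raises(ValueError):
            trust(t, np.zeros((9, 2)), k=3)
        with pytest.raises(ValueError):
            trust(t, np.zeros((10, 2)), k=10)

    def test_accepts_embedding_objects(self):
        rng = np.random.default_rng(10)
        t = random_feature_table(rng, n=12, d=4)
        emb = Embedding(coordinates=t.matrix.copy(), method="pca", kl_trace=None, seed=None)
        assert trust(t, emb, k=3).trust == 1.0
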