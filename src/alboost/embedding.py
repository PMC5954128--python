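"""Low-dimensional maps of chemical space and the neighborhood trust score.

Two reducers are provided: exact t-SNE (Gaussian affinities in descriptor
space matched to a target perplexity, Student-t affinities in the map,
gradient descent on their Kullback-Leibler divergence) and PCA. Map
quality is scored by `trust`: the average fraction of each compound's k
nearest neighbors in the map that are also among its k nearest neighbors
in the original descriptor space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .data_io import FeatureTable

__all__ = ["Embedding", "TrustResult", "tsne_embed", "pca_embed", "trust"]

_EPS = 1e-12


@dataclass
class Embedding:
    coordinates: np.ndarray       # n x m map positions
    method: str                   # "tsne" or "pca"
    kl_trace: np.ndarray | None   # per-iteration KL divergence (t-SNE only)
    seed: int | None


@dataclass
class TrustResult:
    trust: float                  # mean neighborhood overlap fraction, in [0, 1]
    k: int
    overlaps: np.ndarray          # per-compound |map-NN  high-dim-NN|, each in 0..k

    def __post_init__(self) -> None:
        assert 0.0 <= self.trust <= 1.0


def _joint_probabilities(dist_sq: np.ndarray, perplexity: float) -> np.ndarray:
    """Symmetrized Gaussian joint probabilities with per-point bandwidths.

    For each compound the Gaussian precision beta_i is found by bisection so
    that the conditional distribution over the other compounds has entropy
    log(perplexity); the conditionals are then symmetrized and renormalized
    to a joint distribution summing to 1.
    """
    n = dist_sq.shape[0]
    target = np.log(perplexity)
    P = np.zeros((n, n))
    for i in range(n):
        d = np.delete(dist_sq[i], i)
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        for _ in range(64):
            w = np.exp(-d * beta)
            s = w.sum()
            if s <= 0:
                beta_hi = beta
                beta = (beta_lo + beta_hi) / 2
                continue
            entropy = np.log(s) + beta * (d * w).sum() / s
            if abs(entropy - target) < 1e-6:
                break
            if entropy > target:  # too spread out: sharpen
                beta_lo = beta
                beta = beta * 2 if np.isinf(beta_hi) else (beta_lo + beta_hi) / 2
            else:
                beta_hi = beta
                beta = (beta_lo + beta_hi) / 2
        P[i, np.arange(n) != i] = w / s
    P = (P + P.T) / (2 * n)
    return np.maximum(P, _EPS)


def tsne_embed(
    table: FeatureTable,
    dims: int = 3,
    perplexity: float = 30.0,
    iterations: int = 1000,
    seed: int = 0,
    learning_rate: float = 500.0,
    early_exaggeration: float = 4.0,
) -> Embedding:
    """Exact t-SNE of the feature matrix.

    Standard reference settings: early exaggeration x4 for the first 100
    iterations, momentum 0.5 switching to 0.8 at iteration 250, adaptive
    per-coordinate gains. The exact O(n^2) gradient is used throughout —
    the compound collections involved are small enough that fidelity wins
    over speed. Deterministic given `seed`.
    """
    X = np.asarray(table.matrix, dtype=float)
    n = X.shape[0]
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if dims >= table.d:
        raise ValueError("map dimension must be below the feature dimension")
    if not perplexity < (n - 1) / 3:
        raise ValueError(f"perplexity {perplexity} infeasible for n={n}")
    if iterations < 250:
        raise ValueError("need at least 250 iterations")

    P = _joint_probabilities(squareform(pdist(X, "sqeuclidean")), perplexity)

    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((n, dims)) * 1e-4
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    exag_iters = 100
    kl_trace = np.empty(iterations)

    for it in range(iterations):
        dist_sq = squareform(pdist(Y, "sqeuclidean"))
        num = 1.0 / (1.0 + dist_sq)
        np.fill_diagonal(num, 0.0)
        Q = np.maximum(num / num.sum(), _EPS)

        P_eff = P * early_exaggeration if it < exag_iters else P
        PQ = (P_eff - Q) * num
        grad = 4.0 * (PQ.sum(axis=1)[:, None] * Y - PQ @ Y)

        gains = np.where(np.sign(grad) != np.sign(update), gains + 0.2, gains * 0.8)
        np.clip(gains, 0.01, None, out=gains)
        momentum = 0.5 if it < 250 else 0.8
        update = momentum * update - learning_rate * gains * grad
        Y += update
        Y -= Y.mean(axis=0)
        # trace the un-exaggerated objective so the trace is comparable
        kl_trace[it] = float(np.sum(P * np.log(P / Q)))

    return Embedding(coordinates=Y, method="tsne", kl_trace=kl_trace, seed=seed)


def pca_embed(table: FeatureTable, dims: int = 3) -> Embedding:
    """Projection onto the top principal axes of the centered matrix."""
    if not 1 <= dims <= min(table.n, table.d):
        raise ValueError(f"dims must be in 1..min(n, d) = {min(table.n, table.d)}")
    coords = PCA(n_components=dims, svd_solver="full").fit_transform(table.matrix)
    return Embedding(coordinates=coords, method="pca", kl_trace=None, seed=None)


def _neighbor_sets(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors per row (self excluded).

    Ties in distance are broken by compound index order (stable sort), so
    results are reproducible across platforms.
    """
    d = squareform(pdist(X))
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def trust(
    high: FeatureTable | np.ndarray,
    low: Embedding | np.ndarray,
    k: int = 10,
) -> TrustResult:
    """Neighborhood preservation score of a low-dimensional map.

    For each compound i, overlap_i counts how many of its k nearest map
    neighbors are also among its k nearest neighbors in descriptor space;
    the trust is the mean overlap fraction, 1 for a perfect map and about
    k/(n-1) for an uninformative one.
    """
    X = high.matrix if isinstance(high, FeatureTable) else np.asarray(high, float)
    Y = low.coordinates if isinstance(low, Embedding) else np.asarray(low, float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError(f"row mismatch: high has {n}, low has {Y.shape[0]}")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in 1..{n - 1}")

    high_nn = _neighbor_sets(X, k)
    low_nn = _neighbor_sets(Y, k)
    overlaps = np.array(
        [len(set(low_nn[i]) & set(high_nn[i])) for i in range(n)], dtype=int
    )
    return TrustResult(trust=float(overlaps.sum() / (n * k)), k=k, overlaps=overlaps)
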