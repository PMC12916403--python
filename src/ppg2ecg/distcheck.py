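"""Distributional comparison of real vs generated ECG in critic-embedding
space: unbiased Gaussian-kernel MMD², energy distance, permutation p-values
and a 2-D stochastic-neighbour projection for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class EmbeddingSet:
    vectors: np.ndarray            # (n, d)
    label: str                     # "real" | "generated"
    source_ids: list | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, float)
        if self.vectors.ndim != 2 or len(self.vectors) < 2:
            raise ValueError("need an (n >= 2, d) matrix of embeddings")


def extract_embeddings(critic, windows: np.ndarray, label: str = "real",
                       batch: int = 32) -> EmbeddingSet:
    """Penultimate critic-head activation (2·d_model wide) per window."""
    windows = np.asarray(windows, float)
    outs = []
    critic.eval()
    with ad.no_grad():
        for lo in range(0, len(windows), batch):
            _, emb, _ = critic(Tensor(windows[lo:lo + batch]), mode="critic")
            outs.append(emb.data)
    return EmbeddingSet(np.concatenate(outs), label)


def _as_matrix(x) -> np.ndarray:
    return x.vectors if isinstance(x, EmbeddingSet) else np.asarray(x, float)


def median_bandwidth(X, Y) -> float:
    """Median pairwise Euclidean distance over the pooled sample."""
    Z = np.concatenate([_as_matrix(X), _as_matrix(Y)])
    d = cdist(Z, Z)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if med == 0:
        raise ValueError("all points identical: bandwidth undefined")
    return med


def mmd2(X, Y, bandwidth: float | None = None) -> float:
    """Unbiased U-statistic MMD² with a Gaussian kernel.

    Expectation is 0 when both samples share a distribution, so small
    negative values can occur under the null.
    """
    X, Y = _as_matrix(X), _as_matrix(Y)
    n, m = len(X), len(Y)
    if n < 2 or m < 2:
        raise ValueError("need at least 2 points per set")
    bw = bandwidth if bandwidth is not None else median_bandwidth(X, Y)
    gamma = 1.0 / (2.0 * bw**2)
    kxx = np.exp(-gamma * cdist(X, X, "sqeuclidean"))
    kyy = np.exp(-gamma * cdist(Y, Y, "sqeuclidean"))
    kxy = np.exp(-gamma * cdist(X, Y, "sqeuclidean"))
    sum_xx = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
    sum_yy = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    if n == m:
        # matched-pair estimator: the k(x_i, y_i) diagonal is excluded, so
        # identical multisets score exactly zero
        sum_xy = (kxy.sum() - np.trace(kxy)) / (n * (n - 1))
    else:
        sum_xy = kxy.mean()
    return float(sum_xx + sum_yy - 2.0 * sum_xy)


def energy_distance2(X, Y) -> float:
    """2·E‖x−y‖ − E‖x−x′‖ − E‖y−y′‖ with V-statistic (plug-in) means."""
    X, Y = _as_matrix(X), _as_matrix(Y)
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("empty set")
    return float(2.0 * cdist(X, Y).mean() - cdist(X, X).mean()
                 - cdist(Y, Y).mean())


def permutation_pvalue(statistic_fn, X, Y, n_perm: int = 1000,
                       seed: int = 0) -> dict:
    """Pooled-permutation p-value: p = (1 + #{perm ≥ observed}) / (1 + n_perm).

    Also reports the permutation-resampling SD of the statistic.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X, Y = _as_matrix(X), _as_matrix(Y)
    pool = np.concatenate([X, Y])
    n = len(X)
    observed = statistic_fn(X, Y)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(len(pool))
        perm_stats[i] = statistic_fn(pool[idx[:n]], pool[idx[n:]])
    p = (1.0 + np.sum(perm_stats >= observed)) / (1.0 + n_perm)
    return {"statistic": float(observed), "p_value": float(p),
            "perm_sd": float(perm_stats.std()), "n_perm": n_perm}


def project_2d(X, perplexity: float = 50.0, learning_rate: float = 600.0,
               seed: int = 0) -> np.ndarray:
    """2-D t-SNE projection (visualisation only; no exactness contract)."""
    X = _as_matrix(X)
    if len(X) <= 3 * perplexity:
        raise ValueError("perplexity too large for the sample size")
    tsne = TSNE(n_components=2, perplexity=perplexity,
                learning_rate=learning_rate, random_state=seed, init="pca")
    return tsne.fit_transform(X)


def distribution_report(real: EmbeddingSet, gen: EmbeddingSet,
                        n_perm: int = 1000, seed: int = 0) -> dict:
    """Headline two-sample report: MMD², ED² and their permutation p-values."""
    r_mmd = permutation_pvalue(lambda a, b: mmd2(a, b), real, gen,
                               n_perm=n_perm, seed=seed)
    r_ed = permutation_pvalue(energy_distance2, real, gen,
                              n_perm=n_perm, seed=seed + 1)
    return {"mmd2": r_mmd["statistic"], "mmd2_sd": r_mmd["perm_sd"],
            "p_mmd": r_mmd["p_value"],
            "ed2": r_ed["statistic"], "ed2_sd": r_ed["perm_sd"],
            "p_ed": r_ed["p_value"]}
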