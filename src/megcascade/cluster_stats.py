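"""One-sample sign-flip permutation cluster tests.

The single significance engine for the group-level analyses: element-wise
one-sample t statistics (against a chance level) are thresholded at a
cluster-forming p, adjacent supra-threshold elements are merged under an
adjacency graph (a chain over time, a grid over train x test time, or a
spatial-neighbors-graph x time-chain Cartesian product), and each cluster's
summed t is compared with the null distribution of the *maximum* cluster sum
obtained by randomly negating whole subjects.  Permutation p-values use the
add-one convention p = (1 + #{null >= observed}) / (1 + n_perm); the
``exhaustive`` path enumerates all 2^n sign patterns and returns exact
p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

__all__ = [
    "ClusterResult",
    "build_adjacency",
    "spatial_adjacency_from_coords",
    "cluster_test",
]


@dataclass
class ClusterResult:
    """Clusters (index masks over the flattened element axis), their summed-t
    statistics and permutation p-values."""

    clusters: list[np.ndarray]
    cluster_stats: np.ndarray
    p_values: np.ndarray
    t_map: np.ndarray
    n_permutations: int
    threshold_p: float
    shape: tuple = ()

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        """Union of clusters with p < alpha, reshaped to the element shape."""
        mask = np.zeros(self.t_map.size, bool)
        for cl, p in zip(self.clusters, self.p_values):
            if p < alpha:
                mask[cl] = True
        return mask.reshape(self.shape) if self.shape else mask


def build_adjacency(kind: str, geometry) -> sp.csr_matrix:
    """Adjacency graph for clustering.

    - ``time_chain``: geometry = n_times; consecutive samples are neighbors.
    - ``tg_grid``: geometry = (n_rows, n_cols); 4-connectivity.
    - ``space_time``: geometry = (spatial adjacency matrix, n_times);
      Cartesian product of the spatial graph with a time chain.  Elements are
      ordered space-fastest, i.e. flattened from a (time, space) array.
    """
    if kind == "time_chain":
        n = int(geometry)
        return _chain(n)
    if kind == "tg_grid":
        r, c = (int(g) for g in geometry)
        return _grid(r, c)
    if kind == "space_time":
        spatial, n_times = geometry
        spatial = sp.csr_matrix(spatial)
        n_comp, _ = connected_components(spatial, directed=False)
        if n_comp > 1:
            warnings.warn(
                f"spatial adjacency graph has {n_comp} disconnected components",
                RuntimeWarning,
            )
        n_times = int(n_times)
        n_s = spatial.shape[0]
        eye_s = sp.identity(n_s, format="csr")
        adj = sp.kron(sp.identity(n_times, format="csr"), spatial) + sp.kron(
            _chain(n_times), eye_s
        )
        return sp.csr_matrix(adj)
    raise ValueError(f"unknown adjacency kind {kind!r}")


def _chain(n: int) -> sp.csr_matrix:
    if n < 1:
        raise ValueError("chain length must be >= 1")
    if n == 1:
        return sp.csr_matrix((1, 1))
    i = np.arange(n - 1)
    return sp.csr_matrix(
        (np.ones(2 * (n - 1)), (np.r_[i, i + 1], np.r_[i + 1, i])), shape=(n, n)
    )


def _grid(r: int, c: int) -> sp.csr_matrix:
    idx = np.arange(r * c).reshape(r, c)
    rows, cols = [], []
    for a, b in ((idx[:-1, :], idx[1:, :]), (idx[:, :-1], idx[:, 1:])):
        rows.extend([a.ravel(), b.ravel()])
        cols.extend([b.ravel(), a.ravel()])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    return sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(r * c, r * c))


def _t_maps(flipped_means: np.ndarray, sumsq: np.ndarray, n_sub: int) -> np.ndarray:
    """t statistics given per-permutation means; x^2 is sign-invariant."""
    var = (sumsq / n_sub - flipped_means**2) * (n_sub / (n_sub - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = flipped_means / np.sqrt(var / n_sub)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _clusters_from_mask(mask: np.ndarray, adjacency: sp.csr_matrix,
                        is_chain: bool) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    if is_chain:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        return [np.asarray(run) for run in np.split(idx, breaks + 1)]
    sub = adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == k] for k in range(n_comp)]


def _max_cluster_sum(t_map: np.ndarray, thr: float, adjacency: sp.csr_matrix,
                     is_chain: bool, tail: int) -> float:
    best = 0.0
    masks = [t_map > thr] if tail == 1 else [t_map > thr, t_map < -thr]
    for mask in masks:
        for cl in _clusters_from_mask(mask, adjacency, is_chain):
            s = abs(float(t_map[cl].sum()))
            if s > best:
                best = s
    return best


def cluster_test(
    values: np.ndarray,
    chance: float = 0.0,
    adjacency: sp.csr_matrix | None = None,
    n_perm: int = 1000,
    cluster_p: float = 0.05,
    seed: int = 0,
    tail: int = 1,
    exhaustive: bool = False,
) -> ClusterResult:
    """One-sample sign-flip permutation cluster test across subjects.

    ``values`` is subjects x elements (any trailing shape; it is flattened and
    the element shape is kept for masks).  ``tail=1`` tests for values above
    chance (the decoding use case); ``tail=0`` is two-sided.  With
    ``exhaustive=True`` (or whenever 2^n_subjects <= n_perm) all sign
    patterns are enumerated and p-values are exact.
    """
    values = np.asarray(values, float)
    if values.ndim < 2:
        raise ValueError("values must be subjects x elements")
    n_sub = values.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects for a one-sample t-test")
    if n_sub < 5:
        warnings.warn("fewer than 5 subjects; permutation null is very coarse",
                      RuntimeWarning)
    shape = values.shape[1:]
    d = values.reshape(n_sub, -1) - chance
    n_el = d.shape[1]

    if adjacency is None:
        adjacency = _chain(n_el)
    adjacency = sp.csr_matrix(adjacency)
    if adjacency.shape != (n_el, n_el):
        raise ValueError("adjacency size does not match number of elements")
    is_chain = _is_chain(adjacency)

    df = n_sub - 1
    thr = float(t_dist.ppf(1 - cluster_p, df) if tail == 1
                else t_dist.ppf(1 - cluster_p / 2, df))
    sumsq = (d**2).sum(axis=0)
    t_obs = _t_maps(d.mean(axis=0), sumsq, n_sub)

    obs_masks = [t_obs > thr] if tail == 1 else [t_obs > thr, t_obs < -thr]
    clusters: list[np.ndarray] = []
    for mask in obs_masks:
        clusters.extend(_clusters_from_mask(mask, adjacency, is_chain))
    cluster_sums = np.array([float(t_obs[cl].sum()) for cl in clusters])

    if exhaustive or 2**n_sub <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_sub)))
        n_null = signs.shape[0]
        add_one = 0
    else:
        if n_perm < 100:
            warnings.warn("n_perm < 100 gives a very coarse p-value",
                          RuntimeWarning)
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n_sub))
        n_null = n_perm
        add_one = 1

    flipped_means = signs @ d / n_sub
    t_null = _t_maps(flipped_means, sumsq[None, :], n_sub)
    null_max = np.array(
        [_max_cluster_sum(t_null[p], thr, adjacency, is_chain, tail)
         for p in range(n_null)]
    )

    if cluster_sums.size:
        obs_abs = np.abs(cluster_sums)
        p_values = (add_one + (null_max[None, :] >= obs_abs[:, None]).sum(axis=1)
                    ) / (add_one + n_null)
    else:
        p_values = np.array([])

    return ClusterResult(
        clusters=clusters,
        cluster_stats=cluster_sums,
        p_values=p_values,
        t_map=t_obs.reshape(shape) if shape else t_obs,
        n_permutations=n_null,
        threshold_p=cluster_p,
        shape=shape,
    )


def _is_chain(adjacency: sp.csr_matrix) -> bool:
    """Fast-path detection of a 1D time chain (super/sub-diagonal only)."""
    n = adjacency.shape[0]
    coo = adjacency.tocoo()
    if coo.nnz != max(0, 2 * (n - 1)):
        return False
    return bool(np.all(np.abs(coo.row - coo.col) == 1))


def spatial_adjacency_from_coords(coords: np.ndarray, k: int = 6) -> sp.csr_matrix:
    """Symmetric k-nearest-neighbor graph over source coordinates."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    k = min(k, n - 1)
    nn = np.argsort(d2, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(rows.size), (rows, nn.ravel())), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(float)
    return sp.csr_matrix(adj)
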