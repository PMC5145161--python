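"""Superparamagnetic clustering: a Potts model swept over temperatures.

Each data point carries a q-state Potts spin. Neighboring points (mutual
k-nearest neighbors) interact ferromagnetically with a coupling that decays
with distance, ``J_ij = (1/K) exp(-|x_i - x_j|^2 / (2 a^2))`` where ``a`` is
the mean neighbor distance and ``K`` the mean neighbor count. At each
temperature the model is simulated with the Swendsen-Wang cluster algorithm;
the pairwise spin-spin correlation estimates ``G_ij = P(s_i = s_j)`` are
normalized to ``c_ij = (q G_ij - 1)/(q - 1)`` and points whose correlation
exceeds a threshold (default 0.5) are linked. Connected components of those
links are the clusters at that temperature.

At low temperature all spins align (one cluster); at high temperature the
system is disordered (many fragments). In between — the superparamagnetic
phase — spins align within natural data clusters but not across them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .params import SPCHyper, SortParams

__all__ = ["SPCResult", "spc_run", "build_interaction_graph"]


@dataclass
class SPCResult:
    """Per-temperature partitions from one clustering run.

    ``labels`` is (n_T, n_spikes); each row is a partition of the points
    with arbitrary (dense) integer labels. ``sizes[j]`` lists the cluster
    sizes at temperature j in descending order.
    """

    temperatures: np.ndarray
    labels: np.ndarray

    @property
    def n_t(self) -> int:
        return self.labels.shape[0]

    @property
    def n(self) -> int:
        return self.labels.shape[1]

    def sizes(self, j: int) -> np.ndarray:
        """Cluster sizes at temperature j, descending."""
        return np.sort(np.bincount(self.labels[j]))[::-1]

    def clusters_at(self, j: int) -> list[np.ndarray]:
        """Member indices per cluster at temperature j, by descending size."""
        lab = self.labels[j]
        counts = np.bincount(lab)
        order = np.argsort(-counts, kind="stable")
        return [np.flatnonzero(lab == c) for c in order if counts[c] > 0]


def build_interaction_graph(features: np.ndarray, k_nn: int):
    """Mutual k-NN graph with Gaussian couplings; connected by construction.

    Returns ``(edges_i, edges_j, J)``. When the mutual graph splits into
    several components, the nearest inter-component point pairs are added as
    extra edges so that the zero-temperature limit is a single cluster. If
    there are fewer than ``k_nn + 1`` points the complete graph is used.
    """
    x = np.asarray(features, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if n <= k_nn:
        warnings.warn("fewer points than k_nn + 1: using complete graph",
                      stacklevel=2)
        ii, jj = np.triu_indices(n, k=1)
        dist = np.linalg.norm(x[ii] - x[jj], axis=1)
    else:
        nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(x)
        dists, idx = nn.kneighbors(x)
        dists, idx = dists[:, 1:], idx[:, 1:]  # drop self
        rows = np.repeat(np.arange(n), k_nn)
        cols = idx.ravel()
        # mutual: keep (i, j) only if j lists i as well
        adj = csr_matrix((np.ones(rows.size, bool), (rows, cols)), shape=(n, n))
        mutual = adj.multiply(adj.T).tocoo()
        sel = mutual.row < mutual.col
        ii, jj = mutual.row[sel], mutual.col[sel]
        dist = np.linalg.norm(x[ii] - x[jj], axis=1)
        # reconnect isolated components through their nearest outside pair
        ii, jj, dist = _reconnect(x, ii, jj, dist, n)
    mean_k = 2 * len(ii) / n
    a = dist.mean() if dist.size else 1.0
    if a == 0:
        a = 1.0
    coupling = np.exp(-(dist ** 2) / (2 * a ** 2)) / max(mean_k, 1.0)
    return ii.astype(np.int64), jj.astype(np.int64), coupling


def _reconnect(x, ii, jj, dist, n):
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, comp = connected_components(graph, directed=False)
    while n_comp > 1:
        # link the smallest component to its nearest point outside
        sizes = np.bincount(comp).astype(float)
        sizes[sizes == 0] = np.inf  # labels emptied by earlier relinking
        small = int(np.argmin(sizes))
        inside = np.flatnonzero(comp == small)
        outside = np.flatnonzero(comp != small)
        nn = NearestNeighbors(n_neighbors=1).fit(x[outside])
        d, j = nn.kneighbors(x[inside])
        best = int(np.argmin(d[:, 0]))
        a_idx, b_idx = inside[best], outside[j[best, 0]]
        ii = np.append(ii, min(a_idx, b_idx))
        jj = np.append(jj, max(a_idx, b_idx))
        dist = np.append(dist, d[best, 0])
        comp[comp == small] = comp[b_idx]
        n_comp -= 1
    return ii, jj, dist


def _sweep_labels(ei, ej, frozen, n) -> tuple[int, np.ndarray]:
    graph = coo_matrix(
        (np.ones(int(frozen.sum()), dtype=np.int8), (ei[frozen], ej[frozen])),
        shape=(n, n),
    )
    return connected_components(graph, directed=False)


def spc_run(features, params: SortParams | None = None,
            hyper: SPCHyper | None = None, seed: int | None = None) -> SPCResult:
    """Run the temperature sweep and read out per-temperature partitions.

    ``features`` may be a FeatureMatrix or a plain (n, d) array. The
    temperatures are ``params.n_t`` values equally spaced over
    ``[params.t_min, params.t_max]``. The run is deterministic given
    features, parameters and seed (``hyper.seed`` unless ``seed`` is given).
    """
    params = params or SortParams()
    hyper = hyper or SPCHyper()
    x = getattr(features, "values", features)
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    temperatures = np.linspace(params.t_min, params.t_max, params.n_t)
    rng = np.random.default_rng(hyper.seed if seed is None else seed)

    ei, ej, coupling = build_interaction_graph(x, hyper.k_nn)
    n_edges = ei.size
    labels = np.empty((params.n_t, n), dtype=np.int64)

    for ti, temp in enumerate(temperatures):
        if temp <= 0:
            # ferromagnetic ground state: every bond effectively frozen
            _, comp = _sweep_labels(ei, ej, np.ones(n_edges, bool), n)
            labels[ti] = comp
            continue
        p_freeze = 1.0 - np.exp(-coupling / temp)
        spins = rng.integers(hyper.q, size=n)
        hits = np.zeros(n_edges, dtype=np.int64)
        for sweep in range(hyper.burn_in + hyper.sweeps):
            same = spins[ei] == spins[ej]
            frozen = same & (rng.random(n_edges) < p_freeze)
            n_comp, comp = _sweep_labels(ei, ej, frozen, n)
            spins = rng.integers(hyper.q, size=n_comp)[comp]
            if sweep >= hyper.burn_in:
                hits += spins[ei] == spins[ej]
        g = hits / hyper.sweeps
        corr = (hyper.q * g - 1.0) / (hyper.q - 1.0)
        linked = corr > hyper.corr_thresh
        _, comp = _sweep_labels(ei, ej, linked, n)
        labels[ti] = comp

    return SPCResult(temperatures=temperatures, labels=labels)
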