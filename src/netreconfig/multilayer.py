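"""Multilayer modularity maximization with a generalized Louvain algorithm.

A stack of L weighted, undirected connectivity layers over the same N nodes
is partitioned by maximizing the multilayer modularity

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma_l * P_ijl) delta_lr
                               + delta_ij * omega_jlr ] * delta(g_il, g_jr)

where P is the Newman-Girvan null model of each layer, gamma_l the intra-layer
resolution, and omega the inter-layer coupling between copies of the same node
in temporally adjacent layers (ordinal coupling).  mu is the total multilayer
edge weight: mu = sum_l m_l + omega * N * (L - 1).

The optimizer is the standard two-phase Louvain heuristic applied to the
supra-modularity matrix B: a greedy node-sweep phase (seeded random sweep
order, reshuffled every pass) followed by community aggregation, repeated
until no move improves Q.  The heuristic is stochastic; ensembles of seeded
runs are the intended usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MultilayerPartition",
    "newman_girvan_null",
    "multilayer_q",
    "genlouvain",
    "run_ensemble",
    "canonical_labels",
]

#: absolute gain below which a candidate move is not taken
DELTA_Q_TOL = 1e-10

#: hard cap on aggregation levels (unreachable in practice)
MAX_LEVELS = 50


@dataclass
class MultilayerPartition:
    """Community labels of an N x L node-layer grid with (gamma, omega) provenance."""

    labels: np.ndarray          # (N, L) int, contiguous positive ints from 1
    gamma: float
    omega: float
    q_value: float
    seed: int | None = None
    n_communities: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        self.n_communities = len(np.unique(self.labels))

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as 1, 2, ... by first appearance (layer-major scan)."""
    labels = np.asarray(labels)
    flat = labels.ravel(order="F")
    mapping: dict[int, int] = {}
    out = np.empty_like(flat)
    for i, v in enumerate(flat):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out.reshape(labels.shape, order="F")


def newman_girvan_null(layer: np.ndarray) -> tuple[np.ndarray, float]:
    """Expected-weight matrix P_ij = k_i k_j / (2m) and total weight m of one layer.

    Degrees are weighted row sums; m is half the total weight.  Raises on an
    empty layer (m == 0), for which the null model is undefined.
    """
    layer = np.asarray(layer, dtype=float)
    if layer.ndim != 2 or layer.shape[0] != layer.shape[1]:
        raise ValueError("layer must be a square matrix")
    k = layer.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("empty layer: total edge weight is zero")
    return np.outer(k, k) / two_m, two_m / 2.0


def _as_layer_stack(layers: np.ndarray) -> np.ndarray:
    layers = np.asarray(layers, dtype=float)
    if layers.ndim == 2:
        layers = layers[None, :, :]
    if layers.ndim != 3 or layers.shape[1] != layers.shape[2]:
        raise ValueError("layers must be an (L, N, N) stack of square matrices")
    return layers


def _gamma_vector(gamma, n_layers: int) -> np.ndarray:
    g = np.asarray(gamma, dtype=float)
    if g.ndim == 0:
        g = np.full(n_layers, float(g))
    if g.shape != (n_layers,):
        raise ValueError("gamma must be scalar or one value per layer")
    return g


def _supra_modularity(layers: np.ndarray, gamma, omega: float) -> tuple[np.ndarray, float]:
    """Dense supra-modularity matrix B (NL x NL, layer-major) and 2*mu."""
    L, N, _ = layers.shape
    g = _gamma_vector(gamma, L)
    B = np.zeros((N * L, N * L))
    two_mu = 0.0
    for l in range(L):
        P, m = newman_girvan_null(layers[l])
        sl = slice(l * N, (l + 1) * N)
        B[sl, sl] = layers[l] - g[l] * P
        two_mu += 2.0 * m
    for l in range(L - 1):
        idx = np.arange(N)
        B[l * N + idx, (l + 1) * N + idx] = omega
        B[(l + 1) * N + idx, l * N + idx] = omega
    two_mu += 2.0 * omega * N * (L - 1)
    return B, two_mu


def multilayer_q(labels: np.ndarray, layers: np.ndarray, gamma=1.0,
                 omega: float = 1.0) -> float:
    """Evaluate multilayer modularity Q of a given N x L labeling.

    Direct evaluation of the quality function; invariant under any permutation
    of the community ids.
    """
    layers = _as_layer_stack(layers)
    L, N, _ = layers.shape
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    if labels.shape != (N, L):
        raise ValueError(f"labels must have shape ({N}, {L}), got {labels.shape}")
    g = _gamma_vector(gamma, L)
    total = 0.0
    two_mu = 0.0
    for l in range(L):
        P, m = newman_girvan_null(layers[l])
        same = labels[:, l][:, None] == labels[:, l][None, :]
        total += ((layers[l] - g[l] * P) * same).sum()
        two_mu += 2.0 * m
    # ordinal coupling: same node, adjacent layers, same label; both ordered pairs
    for l in range(L - 1):
        total += 2.0 * omega * np.count_nonzero(labels[:, l] == labels[:, l + 1])
    two_mu += 2.0 * omega * N * (L - 1)
    return total / two_mu


@njit
def _sweep(B, labels, order, tol):  # pragma: no cover - exercised via genlouvain
    """One greedy pass: move each node to the community with the largest
    positive quality gain (ties to the lowest community id).  Returns the
    number of moves made."""
    n = B.shape[0]
    n_moves = 0
    w = np.zeros(n)
    for t in range(n):
        i = order[t]
        li = labels[i]
        for c in range(n):
            w[c] = 0.0
        for j in range(n):
            if j != i:
                w[labels[j]] += B[i, j]
        base = w[li]
        best_c = li
        best_gain = 0.0
        for c in range(n):
            gain = w[c] - base
            if gain > best_gain + tol:
                best_gain = gain
                best_c = c
        if best_c != li:
            labels[i] = best_c
            n_moves += 1
    return n_moves


def _louvain_on_matrix(B: np.ndarray, rng: np.random.Generator,
                       tol: float = DELTA_Q_TOL) -> np.ndarray:
    """Louvain phases on a (signed) quality matrix B; returns flat labels."""
    n0 = B.shape[0]
    assignment = np.arange(n0)
    B_cur = np.ascontiguousarray(B)
    for _ in range(MAX_LEVELS):
        n = B_cur.shape[0]
        labels = np.arange(n)
        moved_any = False
        while True:
            order = rng.permutation(n)
            n_moves = _sweep(B_cur, labels, order, tol)
            if n_moves == 0:
                break
            moved_any = True
        if not moved_any:
            return assignment
        # aggregate: contract each community to a single node
        uniq, compact = np.unique(labels, return_inverse=True)
        k = len(uniq)
        assignment = compact[assignment]
        if k == n:
            return assignment
        onehot = np.zeros((n, k))
        onehot[np.arange(n), compact] = 1.0
        B_cur = np.ascontiguousarray(onehot.T @ B_cur @ onehot)
    raise RuntimeError(f"Louvain did not converge within {MAX_LEVELS} levels")


def genlouvain(layers: np.ndarray, gamma=1.0, omega: float = 1.0,
               seed: int | None = None) -> MultilayerPartition:
    """One seeded generalized-Louvain run on a stack of layers.

    Parameters
    ----------
    layers : (L, N, N) or (N, N) array
        Symmetric weighted adjacency per layer (thresholded connectivity).
    gamma : float or (L,) array
        Intra-layer resolution parameter(s); default 1.
    omega : float
        Inter-layer (ordinal, nearest-neighbor) coupling weight; default 1.
    seed : int, optional
        Seed of the sweep-order stream; fixed seed gives an identical partition.
    """
    layers = _as_layer_stack(layers)
    L, N, _ = layers.shape
    if not np.all(np.isfinite(layers)):
        raise ValueError("layers contain non-finite weights")
    B, _ = _supra_modularity(layers, gamma, omega)
    rng = np.random.default_rng(seed)
    flat = _louvain_on_matrix(B, rng)
    labels = canonical_labels(flat.reshape(L, N).T)
    q = multilayer_q(labels, layers, gamma=gamma, omega=omega)
    return MultilayerPartition(labels=labels, gamma=float(np.mean(gamma)),
                               omega=float(omega), q_value=q, seed=seed)


def run_ensemble(layers: np.ndarray, gamma=1.0, omega: float = 1.0,
                 n_iter: int = 100, seed: int | None = None) -> list[MultilayerPartition]:
    """n_iter independent seeded generalized-Louvain runs (child seeds spawned
    from the master seed)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(n_iter) >> 1]
    return [genlouvain(layers, gamma=gamma, omega=omega, seed=cs)
            for cs in child_seeds]
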