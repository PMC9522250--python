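"""Module allegiance and consensus community detection.

An ensemble of community partitions is summarized by the module-allegiance
matrix T, whose entry T_ij is the frequency with which nodes i and j share a
community label (over detection iterations, time windows, and/or subjects).
A single representative partition is obtained by iterating: average the
allegiance of the ensemble, build a permutation null by shuffling each
assignment vector across nodes, zero all entries not exceeding the null
maximum, re-cluster the thresholded allegiance 100 times with single-layer
Louvain, and repeat on the 100 outputs until they are unanimous.

Group-level consensus averages allegiance across subjects (optionally within
early/middle/late time-bin periods), applies the same null-threshold loop,
and removes disconnected nodes and communities below a minimum size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multilayer import canonical_labels, genlouvain

logger = logging.getLogger(__name__)

__all__ = [
    "AllegianceMatrix",
    "ConsensusPartition",
    "allegiance_from_partitions",
    "permuted_null_allegiance",
    "consensus_iterate",
    "group_consensus",
    "map_to_common",
    "region_allegiance",
    "coassignment",
]

MISSING = -1  # label marking a node with no assignment (masked / excluded)


@dataclass
class AllegianceMatrix:
    """N x N co-assignment frequencies in [0, 1], symmetric, unit diagonal."""

    values: np.ndarray
    averaged_over: str = "iterations"
    node_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ConsensusPartition:
    """Representative labels on the retained nodes; excluded nodes listed."""

    labels: np.ndarray              # full-length vector, MISSING where excluded
    excluded_nodes: np.ndarray = field(default_factory=lambda: np.array([], int))
    n_outer_iterations: int = 0
    min_community_size: int = 1

    @property
    def included(self) -> np.ndarray:
        return np.flatnonzero(self.labels != MISSING)


def _vectors_from_partitions(partitions) -> list[np.ndarray]:
    """Normalize an ensemble to a flat list of 1-D assignment vectors.

    Accepts MultilayerPartition objects, (N, L) arrays (each layer becomes a
    vector), or 1-D vectors.  All vectors must cover the same node set.
    """
    vectors: list[np.ndarray] = []
    for p in partitions:
        arr = np.asarray(getattr(p, "labels", p))
        if arr.ndim == 1:
            vectors.append(arr.astype(int))
        elif arr.ndim == 2:
            vectors.extend(arr[:, l].astype(int) for l in range(arr.shape[1]))
        else:
            raise ValueError("partitions must be 1-D or 2-D label arrays")
    if not vectors:
        raise ValueError("empty partition ensemble")
    n = len(vectors[0])
    if any(len(v) != n for v in vectors):
        raise ValueError("all partitions must cover the same node set")
    return vectors


def coassignment(labels: np.ndarray) -> np.ndarray:
    """Binary co-assignment matrix of one assignment vector (MISSING -> NaN)."""
    labels = np.asarray(labels)
    same = (labels[:, None] == labels[None, :]).astype(float)
    miss = labels == MISSING
    same[miss, :] = np.nan
    same[:, miss] = np.nan
    return same


def _mean_allegiance(vectors: list[np.ndarray]) -> np.ndarray:
    """Pairwise-complete mean co-assignment over assignment vectors."""
    n = len(vectors[0])
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for v in vectors:
        valid = v != MISSING
        pair_ok = np.outer(valid, valid)
        same = v[:, None] == v[None, :]
        total += np.where(pair_ok & same, 1.0, 0.0)
        count += pair_ok
    with np.errstate(invalid="ignore"):
        T = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    np.fill_diagonal(T, 1.0)
    return T


def allegiance_from_partitions(partitions, averaged_over: str = "iterations"
                               ) -> AllegianceMatrix:
    """Mean co-assignment frequency over an ensemble of partitions.

    For multilayer partitions, co-assignment is evaluated within each layer
    and averaged over layers and partitions.
    """
    vectors = _vectors_from_partitions(partitions)
    return AllegianceMatrix(values=_mean_allegiance(vectors),
                            averaged_over=averaged_over)


def _permute_vectors(vectors: list[np.ndarray], rng: np.random.Generator
                     ) -> list[np.ndarray]:
    """One random node-permutation of each assignment vector (per layer),
    preserving each vector's community-size distribution.  Masked nodes keep
    their mask; only the observed labels are shuffled among observed nodes."""
    out = []
    for v in vectors:
        w = v.copy()
        idx = np.flatnonzero(v != MISSING)
        w[idx] = v[idx][rng.permutation(len(idx))]
        out.append(w)
    return out


def permuted_null_allegiance(partitions, seed=None) -> AllegianceMatrix:
    """Null allegiance: permute each assignment vector once, then average."""
    vectors = _vectors_from_partitions(partitions)
    rng = np.random.default_rng(seed)
    return AllegianceMatrix(values=_mean_allegiance(_permute_vectors(vectors, rng)),
                            averaged_over="null permutation")


def _partition_key(v: np.ndarray) -> tuple:
    """Relabeling-invariant key of an assignment vector (mask preserved)."""
    w = v.copy()
    ok = w != MISSING
    if ok.any():
        w[ok] = canonical_labels(w[ok]).ravel()
    return tuple(w)


def _louvain_labels(W: np.ndarray, seed: int) -> np.ndarray:
    """Single-layer Louvain (gamma=1) on a weighted matrix; canonical labels."""
    part = genlouvain(W[None, :, :], gamma=1.0, omega=0.0, seed=seed)
    return part.labels[:, 0]


def _null_threshold(T: np.ndarray, Tnull: np.ndarray) -> np.ndarray:
    """Zero entries of T not exceeding the off-diagonal maximum of the null."""
    n = T.shape[0]
    off = ~np.eye(n, dtype=bool)
    thr = Tnull[off].max() if n > 1 else 0.0
    W = np.where(T > thr, T, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def _consensus_loop(vectors: list[np.ndarray], seed, max_outer: int,
                    n_louvain: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Shared inner loop of within-individual and group consensus.

    Returns (labels, excluded_nodes, n_outer).  ``labels`` is full-length with
    MISSING on excluded (isolated) nodes.
    """
    n = len(vectors[0])
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * max_outer) >> 1
    excluded: set[int] = set(np.flatnonzero(
        np.all([v == MISSING for v in vectors], axis=0)))
    current = vectors
    for outer in range(1, max_outer + 1):
        uniq = {_partition_key(v) for v in current}
        if len(uniq) == 1:
            labels = current[0].copy()
            labels[list(excluded)] = MISSING
            return labels, np.array(sorted(excluded), int), outer - 1
        T = _mean_allegiance(current)
        perm_seed = int(states[2 * (outer - 1)])
        louvain_seed = int(states[2 * (outer - 1) + 1])
        Tnull = _mean_allegiance(
            _permute_vectors(current, np.random.default_rng(perm_seed)))
        W = _null_threshold(T, Tnull)
        isolated = np.flatnonzero((W.sum(axis=1) == 0))
        newly = [i for i in isolated if i not in excluded]
        if newly:
            logger.info("consensus: %d nodes isolated by null thresholding", len(newly))
            excluded.update(newly)
        keep = np.array([i for i in range(n) if i not in excluded], int)
        if len(keep) == 0:
            raise RuntimeError("consensus thresholding isolated every node")
        sub = W[np.ix_(keep, keep)]
        child = np.random.SeedSequence(louvain_seed).generate_state(n_louvain) >> 1
        new_vectors = []
        for cs in child:
            lab = np.full(n, MISSING, int)
            lab[keep] = _louvain_labels(sub, int(cs))
            new_vectors.append(lab)
        current = new_vectors
    hist, edges = np.histogram(_mean_allegiance(current), bins=10, range=(0, 1))
    raise RuntimeError(
        f"consensus did not converge within {max_outer} outer iterations; "
        f"allegiance histogram {hist.tolist()} (bin edges {edges.round(2).tolist()})")


def consensus_iterate(partitions, seed=None, max_outer: int = 50,
                      n_louvain: int = 100) -> ConsensusPartition:
    """Within-individual consensus over an ensemble of partitions.

    Loop: average allegiance -> permutation null -> zero entries at or below
    the null maximum -> single-layer Louvain ``n_louvain`` times -> if all
    outputs identical, done; else recurse on the outputs.  Nodes isolated by
    thresholding are excluded and reported.
    """
    vectors = _vectors_from_partitions(partitions)
    labels, excluded, n_outer = _consensus_loop(vectors, seed, max_outer, n_louvain)
    ok = labels != MISSING
    labels[ok] = canonical_labels(labels[ok]).ravel()
    return ConsensusPartition(labels=labels, excluded_nodes=excluded,
                              n_outer_iterations=n_outer, min_community_size=1)


def group_consensus(assignment_vectors, seed=None, min_community_size: int = 20,
                    max_outer: int = 50, n_louvain: int = 100) -> ConsensusPartition:
    """Group-level consensus over per-subject (and per-bin) assignment vectors.

    ``assignment_vectors`` is the pooled list of consensus assignment vectors
    on the common node space contributing to one group (e.g., all subjects x
    all bins of one condition, or all subjects x the bins of one period);
    MISSING entries mark unmapped nodes and are handled by pairwise-complete
    averaging.  After convergence, communities smaller than
    ``min_community_size`` are dropped and their nodes excluded.
    """
    vectors = _vectors_from_partitions(assignment_vectors)
    labels, excluded, n_outer = _consensus_loop(vectors, seed, max_outer, n_louvain)
    # drop small communities (the voxel-count exclusion, applied at group level)
    ids, counts = np.unique(labels[labels != MISSING], return_counts=True)
    small = ids[counts < min_community_size]
    if len(small):
        drop = np.isin(labels, small)
        logger.info("group consensus: dropping %d communities (<%d nodes, %d nodes)",
                    len(small), min_community_size, int(drop.sum()))
        labels = labels.copy()
        labels[drop] = MISSING
        excluded = np.union1d(excluded, np.flatnonzero(drop))
    ok = labels != MISSING
    if ok.any():
        labels[ok] = canonical_labels(labels[ok]).ravel()
    return ConsensusPartition(labels=labels, excluded_nodes=excluded,
                              n_outer_iterations=n_outer,
                              min_community_size=min_community_size)


def map_to_common(obj, mapping: dict, n_common: int):
    """Carry labels or an AllegianceMatrix through a one-to-one node mapping.

    ``mapping`` maps native node index -> common node index and must be
    injective.  Common nodes without a native counterpart are marked MISSING
    (labels) or NaN (allegiance) and excluded from group averages by
    pairwise-complete counting.
    """
    values = list(mapping.values())
    if len(set(values)) != len(values):
        raise ValueError("node mapping must be injective")
    if isinstance(obj, AllegianceMatrix):
        out = np.full((n_common, n_common), np.nan)
        native = np.array(list(mapping.keys()), int)
        common = np.array(values, int)
        out[np.ix_(common, common)] = obj.values[np.ix_(native, native)]
        return AllegianceMatrix(values=out, averaged_over=obj.averaged_over)
    labels = np.asarray(obj)
    out = np.full(n_common, MISSING, int)
    for nat, com in mapping.items():
        out[com] = labels[nat]
    return out


def region_allegiance(allegiance: AllegianceMatrix | np.ndarray,
                      parcellation: pd.Series | np.ndarray) -> tuple[np.ndarray, list]:
    """Average a node-level allegiance matrix into an R x R region matrix.

    ``parcellation`` maps each node to exactly one region.  The (r, s) entry,
    r != s, is the mean of T_ij over i in r, j in s; the diagonal (r, r) is
    the mean over distinct within-region pairs (1 for singleton regions).
    Returns (matrix, region_labels).
    """
    T = allegiance.values if isinstance(allegiance, AllegianceMatrix) else np.asarray(allegiance)
    labels = pd.Series(parcellation).to_numpy()
    if len(labels) != T.shape[0]:
        raise ValueError("parcellation must cover all nodes")
    regions = list(pd.unique(labels))
    idx = {r: np.flatnonzero(labels == r) for r in regions}
    for r, members in idx.items():
        if len(members) == 0:
            raise ValueError(f"empty region {r}")
    R = len(regions)
    out = np.empty((R, R))
    for a in range(R):
        ia = idx[regions[a]]
        for b in range(a, R):
            ib = idx[regions[b]]
            block = T[np.ix_(ia, ib)]
            if a == b:
                if len(ia) == 1:
                    val = 1.0
                else:
                    off = ~np.eye(len(ia), dtype=bool)
                    val = np.nanmean(block[off])
            else:
                val = np.nanmean(block)
            out[a, b] = out[b, a] = val
    return out, regions
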