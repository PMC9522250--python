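"""Windowed functional connectivity, proportional thresholding, and global
graph attributes used for network-density selection.

The run is split into ``n_bins`` equal, nonoverlapping windows (2-minute
windows on a 20-minute run give 10 time-bins); each window yields one Pearson
correlation layer.  Proportional thresholding retains a fixed top fraction
``d`` of the strongest connections by signed value, keeping their weights
(no binarization).  Five binary-graph attributes (assortativity, transitivity,
characteristic path, global efficiency, modularity) summarize each graph, and
the density maximizing the summed absolute paired z-statistics of the
condition contrast is selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .multilayer import run_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicConnectivity",
    "GlobalAttributes",
    "ATTRIBUTE_NAMES",
    "DEFAULT_DENSITY_CANDIDATES",
    "windowed_fc",
    "proportional_threshold",
    "binarize",
    "global_attributes",
    "condition_z_scores",
    "select_density",
]

ATTRIBUTE_NAMES = (
    "assortativity",
    "transitivity",
    "characteristic_path",
    "global_efficiency",
    "modularity",
)

DEFAULT_DENSITY_CANDIDATES = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40)


@dataclass
class DynamicConnectivity:
    """Stack of L symmetric N x N connectivity matrices for one run."""

    matrices: np.ndarray                 # (L, N, N)
    density: float | str = "unthresholded"
    binarized: bool = False
    node_ids: list[str] | None = None
    window_spec: tuple[int, int] | None = None   # (n_bins, samples per bin)

    @property
    def n_layers(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


@dataclass
class GlobalAttributes:
    assortativity: float
    transitivity: float
    characteristic_path: float
    global_efficiency: float
    modularity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, a) for a in ATTRIBUTE_NAMES])


def windowed_fc(series: np.ndarray, n_bins: int,
                node_ids: list[str] | None = None) -> DynamicConnectivity:
    """Pearson correlation within each of ``n_bins`` contiguous equal windows.

    Trailing samples (``T mod n_bins``) are dropped.  A constant signal inside
    any window is rejected (correlation undefined), naming node and window.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a T x N matrix")
    T, N = series.shape
    if n_bins < 1 or T < n_bins * 20:
        raise ValueError(f"need at least {n_bins * 20} samples for {n_bins} windows")
    seg = T // n_bins
    mats = np.empty((n_bins, N, N))
    for l in range(n_bins):
        window = series[l * seg:(l + 1) * seg]
        spread = np.ptp(window, axis=0)
        if np.any(spread == 0):
            node = int(np.flatnonzero(spread == 0)[0])
            raise ValueError(f"constant signal for node {node} in window {l}")
        C = np.corrcoef(window, rowvar=False)
        np.fill_diagonal(C, 1.0)
        mats[l] = (C + C.T) / 2.0
    return DynamicConnectivity(matrices=mats, density="unthresholded",
                               binarized=False, node_ids=node_ids,
                               window_spec=(n_bins, seg))


def proportional_threshold(matrix: np.ndarray, density: float) -> np.ndarray:
    """Keep the top round(d*E) off-diagonal connections by signed value.

    Retained weights are preserved (no binarization); the result is symmetric
    with a zero diagonal.  Ties are broken by ascending (i, j) index order.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    N = M.shape[0]
    iu, ju = np.triu_indices(N, k=1)
    vals = M[iu, ju]
    E = len(vals)
    k = int(np.rint(density * E))
    out = np.zeros_like(M)
    if k > 0:
        # stable sort on descending value; equal values keep (i, j) order
        order = np.argsort(-vals, kind="stable")[:k]
        out[iu[order], ju[order]] = vals[order]
        out = out + out.T
    return out


def binarize(matrix: np.ndarray) -> np.ndarray:
    """0/1 adjacency: nonzero entries become 1 (idempotent)."""
    return (np.asarray(matrix) != 0).astype(float)


def threshold_stack(dc: DynamicConnectivity, density: float) -> DynamicConnectivity:
    """Proportional-threshold every layer of a DynamicConnectivity stack."""
    mats = np.stack([proportional_threshold(m, density) for m in dc.matrices])
    return DynamicConnectivity(matrices=mats, density=density, binarized=False,
                               node_ids=dc.node_ids, window_spec=dc.window_spec)


def global_attributes(adjacency: np.ndarray, n_louvain: int = 20,
                      seed: int | None = 0) -> GlobalAttributes:
    """Five global attributes of an undirected binary graph.

    assortativity: Pearson correlation of degrees over connected node pairs
    (NaN for degree-regular graphs); transitivity: 3*triangles / triplets;
    characteristic path: mean shortest-path length over connected pairs;
    global efficiency: mean 1/distance over all distinct pairs (1/inf = 0);
    modularity: best single-layer Newman-Girvan Q over a seeded Louvain
    ensemble of size ``n_louvain``.
    """
    A = binarize(adjacency)
    np.fill_diagonal(A, 0)
    N = A.shape[0]
    G = nx.from_numpy_array(A)
    n_edges = G.number_of_edges()
    if n_edges == 0:
        logger.info("empty graph: all attributes NaN")
        return GlobalAttributes(*([np.nan] * 5))
    degrees = A.sum(axis=1)
    if np.all(degrees == degrees[0]):
        logger.info("degree-regular graph: assortativity undefined (NaN)")
        assort = np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assort = nx.degree_assortativity_coefficient(G)
        if not np.isfinite(assort):
            assort = np.nan
    trans = nx.transitivity(G)
    # distances over connected pairs only; disconnected pairs contribute 0
    # to efficiency and are excluded from the characteristic path
    path_sum = 0.0
    n_conn_pairs = 0
    inv_sum = 0.0
    for src, dist in nx.all_pairs_shortest_path_length(G):
        for dst, d in dist.items():
            if dst == src:
                continue
            path_sum += d
            n_conn_pairs += 1
            inv_sum += 1.0 / d
    char_path = path_sum / n_conn_pairs if n_conn_pairs else np.nan
    geff = inv_sum / (N * (N - 1))
    ensemble = run_ensemble(A[None, :, :], gamma=1.0, omega=0.0,
                            n_iter=n_louvain, seed=seed)
    modularity = max(p.q_value for p in ensemble)
    return GlobalAttributes(assortativity=assort, transitivity=trans,
                            characteristic_path=char_path,
                            global_efficiency=geff, modularity=modularity)


def condition_z_scores(attrs_a: np.ndarray, attrs_b: np.ndarray) -> np.ndarray:
    """Paired z per attribute: mean difference / (sd of differences / sqrt(n)).

    ``attrs_a``/``attrs_b`` are (n_subjects, 5) arrays of paired attribute
    values.  NaN pairs are excluded per attribute (pairwise, with a logged
    count); an attribute with < 2 usable pairs or zero variance yields NaN.
    """
    a = np.asarray(attrs_a, dtype=float)
    b = np.asarray(attrs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("paired attribute arrays must have identical (n, 5) shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 paired subjects")
    z = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        d = a[:, j] - b[:, j]
        ok = np.isfinite(d)
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("attribute %d: %d NaN pairs excluded", j, n_drop)
        d = d[ok]
        if len(d) < 2:
            continue
        sd = d.std(ddof=1)
        if sd == 0:
            z[j] = 0.0 if d.mean() == 0 else np.nan
        else:
            z[j] = d.mean() / (sd / np.sqrt(len(d)))
    return z


def select_density(avg_fc_a: np.ndarray, avg_fc_b: np.ndarray,
                   candidates=DEFAULT_DENSITY_CANDIDATES,
                   n_louvain: int = 20, seed: int | None = 0
                   ) -> tuple[float, pd.DataFrame]:
    """Pick the network density maximizing the condition contrast.

    ``avg_fc_a``/``avg_fc_b`` are (n_subjects, N, N) stacks of time-averaged
    connectivity per run for the two conditions.  For each candidate density
    the five binary-graph attributes are computed per subject and condition,
    paired z-statistics taken, and the density with the largest sum of |z|
    returned (ties toward the smallest density).  The full z table is
    returned for reporting.
    """
    candidates = sorted(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate densities")
    A = np.asarray(avg_fc_a, dtype=float)
    B = np.asarray(avg_fc_b, dtype=float)
    if A.shape != B.shape or A.ndim != 3:
        raise ValueError("need paired (n_subjects, N, N) stacks")
    rows = []
    for d in candidates:
        za = np.array([global_attributes(proportional_threshold(m, d),
                                         n_louvain=n_louvain, seed=seed).as_array()
                       for m in A])
        zb = np.array([global_attributes(proportional_threshold(m, d),
                                         n_louvain=n_louvain, seed=seed).as_array()
                       for m in B])
        z = condition_z_scores(za, zb)
        rows.append(dict(zip(ATTRIBUTE_NAMES, z), density=d,
                         abs_z_sum=np.nansum(np.abs(z))))
    table = pd.DataFrame(rows).set_index("density")
    best = table["abs_z_sum"].idxmax()  # first occurrence wins: smallest density
    return float(best), table
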