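"""Statistical inference on community structures and rating behavior.

Regional change between two group consensus structures is quantified by the
Phi coefficient between a node's binary co-assignment profiles, with a
subject-level label-exchange permutation null; seed-based allegiance maps are
contrasted with paired t-tests; forced-choice accuracies are tested with the
exact two-tailed binomial test; continuous rating traces are averaged into
equal time-bins with an early/middle/late period scheme; and a two-level GLM
with subject-level bootstrap tests the condition effect on ratings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .consensus import MISSING, coassignment, group_consensus

logger = logging.getLogger(__name__)

__all__ = [
    "PhiResult",
    "RatingBins",
    "phi_coefficient",
    "phi_change_map",
    "seed_allegiance_map",
    "paired_t_map",
    "binomial_two_tailed",
    "fdr_bh",
    "bin_ratings",
    "periods_for",
    "condition_effect_glm",
]


@dataclass
class PhiResult:
    phi: np.ndarray       # per-node Phi coefficient (NaN where excluded)
    p: np.ndarray         # per-node one-tailed permutation p-value
    n_perm: int


@dataclass
class RatingBins:
    bin_means: np.ndarray
    periods: dict[str, list[int]]   # period name -> 0-based bin indices


def phi_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two binary vectors (the Phi coefficient).

    Equals (n11*n00 - n10*n01) / sqrt(r1*r0*c1*c0) from the 2x2 contingency
    table.  NaN (with a logged reason) if either vector is constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if a.std() == 0 or b.std() == 0:
        logger.info("phi undefined: constant input vector")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _phi_profile(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    """Per-node phi between co-assignment rows of two full-length labelings.

    Nodes missing from either labeling are NaN; each node's profile spans the
    nodes present in both (self excluded)."""
    n = len(labels_a)
    both = (labels_a != MISSING) & (labels_b != MISSING)
    Ca = coassignment(labels_a)
    Cb = coassignment(labels_b)
    out = np.full(n, np.nan)
    idx = np.flatnonzero(both)
    for i in idx:
        cols = idx[idx != i]
        ra, rb = Ca[i, cols], Cb[i, cols]
        if ra.std() == 0 or rb.std() == 0:
            continue
        out[i] = np.corrcoef(ra, rb)[0, 1]
    return out


def phi_change_map(vectors_a, vectors_b, n_perm: int = 1000, seed=None,
                   min_community_size: int = 1, n_louvain: int = 100,
                   consensus_seed: int = 0) -> PhiResult:
    """Permutation test of regional community change between two labels A, B.

    ``vectors_a``/``vectors_b``: per-subject lists of assignment vectors on
    the common node space (e.g., per-bin consensus labels under two
    conditions, or the early vs late period of one condition).  The observed
    statistic is the per-node Phi between the binary co-assignment profiles
    of the two group consensus structures.  The null exchanges the A/B labels
    of each subject's contributing vectors at random and recomputes both
    structures.  One-tailed p: the probability of a null Phi at most as large
    as the observed one (smaller Phi = more dissimilar), with add-one
    smoothing, so p is never 0 and ties count as extreme.
    """
    if len(vectors_a) != len(vectors_b):
        raise ValueError("need the same subjects in both groups")
    n_subj = len(vectors_a)

    def _consensus_pair(va, vb):
        ga = group_consensus([v for sub in va for v in sub], seed=consensus_seed,
                             min_community_size=min_community_size,
                             n_louvain=n_louvain)
        gb = group_consensus([v for sub in vb for v in sub], seed=consensus_seed,
                             min_community_size=min_community_size,
                             n_louvain=n_louvain)
        return _phi_profile(ga.labels, gb.labels)

    obs = _consensus_pair(vectors_a, vectors_b)
    rng = np.random.default_rng(seed)
    n = len(obs)
    count = np.zeros(n)
    n_valid = np.zeros(n)
    for _ in range(n_perm):
        flip = rng.random(n_subj) < 0.5
        va = [vectors_b[s] if flip[s] else vectors_a[s] for s in range(n_subj)]
        vb = [vectors_a[s] if flip[s] else vectors_b[s] for s in range(n_subj)]
        null = _consensus_pair(va, vb)
        ok = np.isfinite(null) & np.isfinite(obs)
        count[ok] += null[ok] <= obs[ok] + 1e-12
        n_valid[ok] += 1
    p = np.full(n, np.nan)
    ok = np.isfinite(obs) & (n_valid > 0)
    p[ok] = (1.0 + count[ok]) / (n_valid[ok] + 1.0)
    return PhiResult(phi=obs, p=p, n_perm=n_perm)


def seed_allegiance_map(allegiance: np.ndarray, seed_nodes) -> np.ndarray:
    """Mean allegiance between a seed region and every node.

    ``allegiance`` is one subject's N x N matrix; the map at node j is the
    mean of T_ij over seed nodes i, with self-seed entries excluded (a seed
    node's own value averages only the other seed rows; NaN for a singleton
    seed at its own position).
    """
    T = np.asarray(allegiance, dtype=float)
    seed_nodes = np.asarray(seed_nodes, int)
    if len(seed_nodes) == 0:
        raise ValueError("empty seed region")
    n = T.shape[0]
    out = np.empty(n)
    for j in range(n):
        rows = seed_nodes[seed_nodes != j]
        out[j] = np.nan if len(rows) == 0 else T[rows, j].mean()
    return out


def paired_t_map(maps_a: np.ndarray, maps_b: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-node paired t (df = n-1) and two-tailed p between condition maps.

    ``maps_a``/``maps_b``: (n_subjects, N).  Nodes where every difference is
    zero get t = 0, p = 1 (exact-tie rule) instead of an infinite statistic.
    """
    A = np.asarray(maps_a, float)
    B = np.asarray(maps_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] < 3:
        raise ValueError("need paired (n_subjects >= 3, N) maps")
    d = A - B
    t = np.zeros(d.shape[1])
    p = np.ones(d.shape[1])
    sd = d.std(axis=0, ddof=1)
    nz = sd > 0
    res = sps.ttest_rel(A[:, nz], B[:, nz], axis=0)
    t[nz] = res.statistic
    p[nz] = res.pvalue
    zero_var_nonzero_mean = (~nz) & (d.mean(axis=0) != 0)
    if zero_var_nonzero_mean.any():
        # constant nonzero difference: maximally significant at this n
        t[zero_var_nonzero_mean] = np.sign(d.mean(axis=0)[zero_var_nonzero_mean]) * np.inf
        p[zero_var_nonzero_mean] = 0.0
    return t, p


def binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p-value, defined as 2*min(tails) capped at 1."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q.

    Returns (rejection mask, largest rejected p); threshold is NaN when
    nothing is rejected.  NaN p-values are never rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.nan
    mask = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        rej, _, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        mask[ok] = rej
    thr = float(p[mask].max()) if mask.any() else np.nan
    return mask, thr


def periods_for(n_bins: int) -> dict[str, list[int]]:
    """Early/middle/late period scheme: bins 1-3 / 4-7 / 8-10 for 10 bins,
    a proportional 30/40/30 split otherwise."""
    if n_bins == 10:
        cuts = (3, 7)
    else:
        cuts = (int(round(0.3 * n_bins)), int(round(0.7 * n_bins)))
    return {
        "early": list(range(0, cuts[0])),
        "middle": list(range(cuts[0], cuts[1])),
        "late": list(range(cuts[1], n_bins)),
    }


def bin_ratings(times: np.ndarray, values: np.ndarray, n_bins: int = 10,
                run_length: float | None = None) -> RatingBins:
    """Mean rating within each of ``n_bins`` equal-duration bins.

    Bin b spans [b*L/n_bins, (b+1)*L/n_bins) of the run length L (the last
    bin is closed on the right).  Empty bins yield NaN with a logged note.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if run_length is None:
        run_length = float(times[-1])
    edges = np.linspace(0, run_length, n_bins + 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if b < n_bins - 1:
            m = (times >= edges[b]) & (times < edges[b + 1])
        else:
            m = (times >= edges[b]) & (times <= edges[b + 1])
        if not m.any():
            logger.info("bin %d is empty; NaN", b)
            continue
        means[b] = values[m].mean()
    return RatingBins(bin_means=means, periods=periods_for(n_bins))


def condition_effect_glm(bin_ratings_by_subject: np.ndarray,
                         condition_codes: np.ndarray,
                         covariates: np.ndarray | None = None,
                         n_boot: int = 10000, seed=None
                         ) -> dict[str, float]:
    """Two-level GLM of the condition effect on ratings with bootstrap test.

    Level 1: per subject, OLS of the bin ratings on the condition code
    (+1/-1), pooled over the subject's rows, giving a per-subject effect
    beta_s.  Level 2: the subject-level betas are adjusted for between-subject
    covariates (intercept of an OLS of beta on centered covariates) and the
    adjusted mean is bootstrapped over subjects ``n_boot`` times;
    z = bootstrap mean / bootstrap sd, two-tailed normal p.

    ``bin_ratings_by_subject``: (n_subjects, n_rows) ratings;
    ``condition_codes``: (n_rows,) +1/-1 per row (same design per subject);
    ``covariates``: (n_subjects, k) between-subject covariates, optional.
    """
    Y = np.asarray(bin_ratings_by_subject, float)
    c = np.asarray(condition_codes, float)
    n_subj = Y.shape[0]
    X1 = np.column_stack([np.ones_like(c), c])
    betas = np.full(n_subj, np.nan)
    for s in range(n_subj):
        y = Y[s]
        ok = np.isfinite(y)
        if ok.sum() < 2 or np.ptp(c[ok]) == 0:
            logger.info("subject %d dropped: singular level-1 design", s)
            continue
        coef, *_ = np.linalg.lstsq(X1[ok], y[ok], rcond=None)
        betas[s] = coef[1]
    ok = np.isfinite(betas)
    betas = betas[ok]
    n = len(betas)
    if n < 3:
        raise ValueError("need at least 3 subjects with estimable effects")
    if covariates is not None:
        Z = np.asarray(covariates, float)[ok]
        Z = Z - Z.mean(axis=0)
        X2 = np.column_stack([np.ones(n), Z])
    else:
        X2 = np.ones((n, 1))

    def adjusted_mean(idx):
        coef, *_ = np.linalg.lstsq(X2[idx], betas[idx], rcond=None)
        return coef[0]

    beta_hat = adjusted_mean(np.arange(n))
    rng = np.random.default_rng(seed)
    boots = np.array([adjusted_mean(rng.integers(0, n, n)) for _ in range(n_boot)])
    sd = boots.std(ddof=1)
    tol = 1e-12 * max(1.0, float(np.abs(betas).max()))
    if sd > tol:
        z = beta_hat / sd
        p = 2.0 * sps.norm.sf(abs(z))
    elif abs(beta_hat) <= tol:   # numerically zero effect in every resample
        z, p = 0.0, 1.0
    else:                        # constant nonzero effect
        z, p = np.inf * np.sign(beta_hat), 0.0
    return {"beta": float(beta_hat), "se": float(sd), "z": float(z),
            "p": float(p), "n_subjects": n, "n_boot": n_boot}
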