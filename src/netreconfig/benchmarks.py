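"""Desk-scale benchmark runs exercising the full pipeline end to end.

Each function generates its inputs with the synthetic cohort module, runs
the analysis, and measures the result; they are the computations behind the
package's self-validation (tests and the acceptance script).  Problem sizes
are desk-scale: the default effect cohort (20 subjects, 60 nodes, 10 bins),
a 48-subject effect cohort for the group-level Phi permutation test
(matching the size regime the test is designed for), pooled low-SNR null
cohorts for calibration, and a 5-bin transfer cohort.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import models, pipeline, stats, synthetic
from .consensus import MISSING, consensus_iterate, group_consensus
from .multilayer import genlouvain, multilayer_q

__all__ = [
    "enumeration_gap",
    "noisy_copy_consensus_ari",
    "period_consensus_recovery",
    "phi_null_fpr",
    "phi_planted_detection",
    "classification_and_regression",
    "transfer_accuracy",
    "determinism_check",
]


def _spawn(seed, n):
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


# ---------------------------------------------------------------- modularity

def _enumerate_partitions(n_units):
    def grow(prefix, k):
        if len(prefix) == n_units:
            yield prefix
            return
        for c in range(k + 1):
            yield from grow(prefix + [c], max(k, c + 1))
    yield from grow([], 0)


def enumeration_gap(seed=0, n_instances=6, n_starts=20) -> dict:
    """Exhaustive-maximum check of multilayer Q optimization on toys.

    Enumerates every partition of small instances (N <= 5, L <= 2) and
    compares the seeded generalized-Louvain ensemble maximum with the global
    maximum.  Returns the largest absolute gap and the largest amount by
    which the heuristic exceeded the enumerated bound (must be ~0).
    """
    rng = np.random.default_rng(seed)
    shapes = [(1, 4), (1, 5), (2, 3), (2, 4), (2, 5)]
    worst_gap = 0.0
    worst_excess = 0.0
    n_done = 0
    for i in range(n_instances):
        L, N = shapes[i % len(shapes)]
        A = rng.random((L, N, N))
        A = (A + A.transpose(0, 2, 1)) / 2
        for l in range(L):
            np.fill_diagonal(A[l], 0)
        q_star = -np.inf
        for flat in _enumerate_partitions(N * L):
            lab = np.array(flat).reshape(L, N).T
            q_star = max(q_star, multilayer_q(lab, A))
        qs = [genlouvain(A, seed=s).q_value
              for s in _spawn(seed * 1000 + i, n_starts)]
        worst_excess = max(worst_excess, max(qs) - q_star)
        worst_gap = max(worst_gap, q_star - max(qs))
        n_done += 1
    return {"max_gap": worst_gap, "max_excess": worst_excess, "n": n_done}


# ----------------------------------------------------------------- consensus

def noisy_copy_consensus_ari(seed=0, n_copies=100, flip_frac=0.10) -> dict:
    """Recovery of a planted 3-block partition from noisy ensemble copies."""
    rng = np.random.default_rng(seed)
    base = np.repeat([1, 2, 3], 10)
    ensemble = []
    for _ in range(n_copies):
        v = base.copy()
        idx = rng.choice(len(base), size=int(flip_frac * len(base)),
                         replace=False)
        v[idx] = rng.integers(1, 4, size=len(idx))
        ensemble.append(v)
    cp = consensus_iterate(ensemble, seed=seed + 1)
    ok = cp.labels != MISSING
    return {"ari": adjusted_rand_score(base[ok], cp.labels[ok]),
            "n": n_copies}


def period_consensus_recovery(seed=0, n_seeds=10, n_iter=50) -> dict:
    """Group consensus vs planted per-period partitions on the default
    cohort (pain condition), Monte-Carlo over cohort seeds."""
    aris = []
    rep_layer = {"early": 0, "middle": 4, "late": 9}
    for cs in _spawn(seed, n_seeds):
        coh = synthetic.generate_cohort(synthetic.CohortConfig(), seed=cs)
        ana = pipeline.analyze_cohort(coh, n_iter=n_iter, seed=cs + 1,
                                      conditions=("pain",))
        truth = coh.ground_truth["pain"].labels_by_layer
        for period, vecs in ana.period_vectors("pain").items():
            flat = [v for sub in vecs for v in sub]
            cp = group_consensus(flat, seed=cs + 2, min_community_size=4)
            ok = cp.labels != MISSING
            aris.append(adjusted_rand_score(truth[ok, rep_layer[period]],
                                            cp.labels[ok]))
    return {"min_ari": float(np.min(aris)), "mean_ari": float(np.mean(aris)),
            "n": len(aris)}


# ----------------------------------------------------------------- phi test

def phi_null_fpr(seed=0, n_cohorts=5, n_perm=200, n_iter=50) -> dict:
    """Pooled per-node false-positive rate of the Phi permutation test at
    alpha = 0.05 on low-SNR null cohorts (no planted change)."""
    hits, total = 0, 0
    for cs in _spawn(seed, n_cohorts):
        coh = synthetic.generate_cohort(synthetic.noisy_null_config(), seed=cs)
        ana = pipeline.analyze_cohort(coh, n_iter=n_iter, seed=cs + 1)
        res = stats.phi_change_map(ana.condition_vectors("pain"),
                                   ana.condition_vectors("control"),
                                   n_perm=n_perm, seed=cs + 2,
                                   min_community_size=2)
        ok = np.isfinite(res.p)
        hits += int((res.p[ok] <= 0.05).sum())
        total += int(ok.sum())
    return {"fpr": hits / total, "n": total}


def phi_planted_detection(seed=0, n_subjects=48, n_perm=200, n_iter=50) -> dict:
    """Fraction of planted-change (migrating) nodes detected at p <= 0.05 by
    the Phi test between the pain-like and control group consensus."""
    coh = synthetic.generate_cohort(
        synthetic.CohortConfig(n_subjects=n_subjects), seed=seed)
    ana = pipeline.analyze_cohort(coh, n_iter=n_iter, seed=seed + 1)
    res = stats.phi_change_map(ana.condition_vectors("pain"),
                               ana.condition_vectors("control"),
                               n_perm=n_perm, seed=seed + 2,
                               min_community_size=2)
    gt = coh.ground_truth
    changed = np.any(gt["pain"].labels_by_layer != gt["control"].labels_by_layer,
                     axis=1)
    det = float(np.mean(res.p[changed] <= 0.05))
    return {"detection_rate": det, "n": int(changed.sum()),
            "fpr_unchanged": float(np.nanmean(res.p[~changed] <= 0.05))}


# ------------------------------------------------------------------- models

def _feature_tables(analysis, cohort):
    mats_c, _ = pipeline.region_feature_matrices(analysis, "classification")
    ft_c = models.build_features(mats_c, "classification")
    mats_r, _ = pipeline.region_feature_matrices(analysis, "regression")
    ft_r = models.build_features(mats_r, "regression")
    subj_r = ft_r.rows["subject"].to_numpy()
    bins = ft_r.rows["bin"].to_numpy()
    y_r = np.array([cohort.subjects[s]["rating_bins"]["pain"][b]
                    for s, b in zip(subj_r, bins)])
    return ft_c, ft_r, y_r


def classification_and_regression(analysis, cohort, n_boot=2000, seed=0,
                                  pc_candidates=range(1, 11)) -> dict:
    """LOPO forced-choice SVM and nested-CV PCR performance on one cohort."""
    ft_c, ft_r, y_r = _feature_tables(analysis, cohort)
    y = ft_c.rows["condition"].to_numpy()
    subj = ft_c.rows["subject"].to_numpy()
    pred = models.lopo_cv(lambda X, yy: models.svm_train(X, yy, C=1.0),
                          ft_c.X, y, subj)
    fc = models.forced_choice_eval(pred[y == "pain"], pred[y == "control"])
    subj_r = ft_r.rows["subject"].to_numpy()
    pred_n, chosen = models.nested_lopo_cv(ft_r.X, y_r, subj_r, pc_candidates)
    ev = models.evaluate_regression(pred_n, y_r, subj_r, n_boot=n_boot,
                                    seed=seed)
    return {"accuracy": fc["accuracy"], "accuracy_p": fc["p"],
            "n_pairs": fc["n_pairs"], "mean_r": ev["mean_r"],
            "r_p": ev["p"], "n_pc_mean": float(np.mean(chosen)),
            "n_pc_sem": float(np.std(chosen, ddof=1) / np.sqrt(len(chosen)))}


def transfer_accuracy(train_analysis, seed=0, n_subjects=15, n_bins=5,
                      n_iter=50) -> dict:
    """Forced-choice accuracy of a classifier trained on one cohort and
    applied to a shorter-run cohort generated with a different seed."""
    mats, _ = pipeline.region_feature_matrices(train_analysis, "classification")
    ft = models.build_features(mats, "classification")
    model = models.svm_train(ft.X, ft.rows["condition"].to_numpy(), C=1.0)
    cfg = synthetic.CohortConfig(n_subjects=n_subjects, n_layers=n_bins,
                                 n_timepoints=n_bins * 300)
    cfg.scenario = synthetic.default_scenario(cfg.n_nodes)
    cfg.scenario.late_start = max(1, int(round(0.7 * n_bins)))
    coh_b = synthetic.generate_cohort(cfg, seed=seed)
    ana_b = pipeline.analyze_cohort(coh_b, n_iter=n_iter, seed=seed + 1)
    mats_b, _ = pipeline.region_feature_matrices(ana_b, "classification")
    ft_b = models.build_features(mats_b, "classification")
    resp = models.model_response(model.w, model.intercept, ft_b.X)
    y_b = ft_b.rows["condition"].to_numpy()
    fc = models.forced_choice_eval(resp[y_b == "pain"], resp[y_b == "control"])
    return {"accuracy": fc["accuracy"], "p": fc["p"], "n_pairs": fc["n_pairs"]}


# -------------------------------------------------------------- determinism

def determinism_check(seed=0) -> dict:
    """Bit-identity of every stage under a fixed master seed."""
    cfg = synthetic.CohortConfig(n_subjects=2, n_nodes=24, n_layers=4,
                                 n_timepoints=480)
    a = synthetic.generate_cohort(cfg, seed=seed)
    b = synthetic.generate_cohort(cfg, seed=seed)
    same_cohort = all(
        np.array_equal(ra["series"][c], rb["series"][c])
        and np.array_equal(ra["ratings"][c].values, rb["ratings"][c].values)
        for ra, rb in zip(a.subjects, b.subjects) for c in ("pain", "control"))
    r1 = pipeline.analyze_run(a.subjects[0]["series"]["pain"], 4, 0.3,
                              n_iter=10, seed=seed + 1)
    r2 = pipeline.analyze_run(a.subjects[0]["series"]["pain"], 4, 0.3,
                              n_iter=10, seed=seed + 1)
    same_run = (np.array_equal(r1.layer_labels, r2.layer_labels)
                and np.array_equal(r1.q_values, r2.q_values))
    ens = [np.repeat([1, 2], 5) for _ in range(10)]
    c1 = consensus_iterate(ens, seed=seed + 2)
    c2 = consensus_iterate(ens, seed=seed + 2)
    same_consensus = np.array_equal(c1.labels, c2.labels)
    return {"deterministic": bool(same_cohort and same_run and same_consensus),
            "n": 3}
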