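"""Allegiance-feature predictive models.

Region-pair module allegiances (the strict upper triangle of the R x R
region allegiance matrix, R(R-1)/2 features in [0, 1]) feed two linear
models: a soft-margin linear SVM (C = 1) classifying the pain-like versus
control condition, evaluated with a paired forced two-choice test, and a
principal-component regression (PCR) of continuous ratings, with the PC
count chosen by leave-one-participant-out (LOPO) cross-validation and a
nested LOPO variant separating hyperparameter selection from testing.
Feature-level inference uses subject-level bootstrap resampling.  Features
are not standardized (allegiance is already bounded and commensurate); PCA
uses centering only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from statsmodels.stats.multitest import multipletests

from .stats import binomial_two_tailed

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "LinearModelWeights",
    "WeightStats",
    "upper_triangle",
    "build_features",
    "svm_train",
    "forced_choice_eval",
    "lopo_cv",
    "pcr_train",
    "select_n_pc",
    "nested_lopo_cv",
    "evaluate_regression",
    "bootstrap_weight_stats",
    "hub_regions",
    "model_response",
]


@dataclass
class FeatureTable:
    """Observations x region-pair allegiance features with row metadata."""

    X: np.ndarray
    rows: pd.DataFrame            # columns: subject, condition and/or bin
    feature_pairs: list[tuple]    # (region_a, region_b) per column

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class LinearModelWeights:
    w: np.ndarray
    intercept: float
    model_kind: str               # "svm" | "pcr"
    hyper: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


@dataclass
class WeightStats:
    mean: np.ndarray
    sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    degenerate: np.ndarray        # features with zero bootstrap sd
    n_boot: int


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix, row-major (R(R-1)/2 values)."""
    M = np.asarray(matrix)
    iu, ju = np.triu_indices(M.shape[0], k=1)
    return M[iu, ju]


def build_features(region_matrices: dict, mode: str,
                   region_labels: list | None = None) -> FeatureTable:
    """Vectorize region allegiance matrices into a feature table.

    ``region_matrices`` maps row keys to R x R matrices:
    classification mode -> keys (subject, condition), one bin-averaged matrix
    per subject and condition; regression mode -> keys (subject, bin), one
    matrix per subject and time-bin.
    """
    if mode not in ("classification", "regression"):
        raise ValueError("mode must be 'classification' or 'regression'")
    keys = sorted(region_matrices)
    mats = [np.asarray(region_matrices[k]) for k in keys]
    R = mats[0].shape[0]
    if any(m.shape != (R, R) for m in mats):
        raise ValueError("inconsistent region counts across inputs")
    X = np.array([upper_triangle(m) for m in mats])
    col = "condition" if mode == "classification" else "bin"
    rows = pd.DataFrame(keys, columns=["subject", col])
    if mode == "regression":
        # every subject must contribute every bin
        bins = sorted(rows["bin"].unique())
        missing = [(s, b) for s in rows["subject"].unique() for b in bins
                   if (s, b) not in region_matrices]
        if missing:
            raise ValueError(f"missing bins: {missing}")
    if region_labels is None:
        region_labels = list(range(R))
    iu, ju = np.triu_indices(R, k=1)
    pairs = [(region_labels[i], region_labels[j]) for i, j in zip(iu, ju)]
    return FeatureTable(X=X, rows=rows, feature_pairs=pairs)


def svm_train(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              manifest: dict | None = None) -> LinearModelWeights:
    """Linear soft-margin SVM in the original feature space (no scaling).

    ``y`` holds two class labels; the pain-like class is coded +1 so that a
    larger response means more pain-like.  Labels "pain"/+1/True are treated
    as the positive class.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    positive = classes[-1]
    for cand in ("pain", 1, True):
        if cand in classes.tolist():
            positive = cand
            break
    yy = np.where(y == positive, 1, -1)
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, yy)
    return LinearModelWeights(w=clf.coef_.ravel().copy(),
                              intercept=float(clf.intercept_[0]),
                              model_kind="svm", hyper={"C": C},
                              manifest=manifest or {})


def model_response(w: np.ndarray, b: float, x: np.ndarray) -> float | np.ndarray:
    """Pattern-expression response: dot product of weights with test data
    (+ intercept), for transfer application to held-out cohorts."""
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    if x.shape[-1] != w.shape[0]:
        raise ValueError(f"dimension mismatch: {x.shape[-1]} != {w.shape[0]}")
    return x @ w + b


def forced_choice_eval(decision_pain: np.ndarray, decision_control: np.ndarray
                       ) -> dict:
    """Paired forced two-choice test on per-subject decision values.

    A pair is correct iff the pain-like run's decision value exceeds the
    control run's (ties count as incorrect, logged).  Significance is the
    exact two-tailed binomial test at chance 0.5; the ROC is computed over
    the paired decision-value differences (each pair contributes d and -d).
    """
    dp = np.asarray(decision_pain, float)
    dc = np.asarray(decision_control, float)
    if dp.shape != dc.shape:
        raise ValueError("need one pain and one control value per subject")
    d = dp - dc
    ties = int((d == 0).sum())
    if ties:
        logger.info("forced choice: %d tied pairs counted incorrect", ties)
    correct = d > 0
    n = len(d)
    k = int(correct.sum())
    scores = np.concatenate([d, -d])
    labels = np.concatenate([np.ones(n), np.zeros(n)])
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(labels[order] == 1) / n
    fp = np.cumsum(labels[order] == 0) / n
    auc = float(np.trapezoid(tp, fp))
    return {"accuracy": k / n, "n_correct": k, "n_pairs": n,
            "p": binomial_two_tailed(k, n), "outcomes": correct,
            "roc": (fp, tp), "auc": auc}


def lopo_cv(trainer, X: np.ndarray, y: np.ndarray, subjects: np.ndarray,
            predict=None) -> np.ndarray:
    """Leave-one-participant-out predictions (all rows of a subject held out
    together; the held-out subject never contributes to training)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    uniq = pd.unique(subjects)
    if len(uniq) < 3:
        raise ValueError("need at least 3 subjects")
    if predict is None:
        predict = lambda model, Xt: model_response(model.w, model.intercept, Xt)
    pred = np.empty(len(y), dtype=float)
    for s in uniq:
        test = subjects == s
        model = trainer(X[~test], y[~test])
        pred[test] = predict(model, X[test])
    return pred


def pcr_train(X: np.ndarray, y: np.ndarray, n_pc: int,
              manifest: dict | None = None) -> LinearModelWeights:
    """Principal-component regression: centering-only PCA on the training
    rows, OLS of y on the top ``n_pc`` scores, weights back-projected to
    feature space with an intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if n_pc < 1:
        raise ValueError("n_pc must be >= 1")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_pc > max_rank:
        raise ValueError(f"n_pc={n_pc} exceeds the training rank {max_rank}")
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(X)
    design = np.column_stack([np.ones(len(y)), scores])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    w = pca.components_.T @ coef[1:]
    b = float(coef[0] - pca.mean_ @ w)
    return LinearModelWeights(w=w, intercept=b, model_kind="pcr",
                              hyper={"n_pc": n_pc}, manifest=manifest or {})


def _mean_subject_z(pred: np.ndarray, y: np.ndarray, subjects: np.ndarray) -> float:
    """Mean Fisher-z of within-subject prediction-outcome correlations."""
    zs = []
    for s in pd.unique(subjects):
        m = subjects == s
        if np.ptp(pred[m]) == 0 or np.ptp(y[m]) == 0:
            continue
        r = np.clip(np.corrcoef(pred[m], y[m])[0, 1], -0.999999, 0.999999)
        zs.append(np.arctanh(r))
    return float(np.mean(zs)) if zs else -np.inf


def select_n_pc(X: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                candidates) -> int:
    """PC count maximizing LOPO-CV mean within-subject prediction-outcome
    correlation (r-to-z averaged); ties to the smaller count."""
    candidates = sorted(candidates)
    if not candidates or candidates[0] < 1:
        raise ValueError("candidates must be >= 1")
    best, best_z = candidates[0], -np.inf
    for n_pc in candidates:
        trainer = lambda Xt, yt: pcr_train(Xt, yt, n_pc)
        try:
            pred = lopo_cv(trainer, X, y, subjects)
        except ValueError:
            continue
        z = _mean_subject_z(pred, y, subjects)
        if z > best_z + 1e-12:
            best, best_z = n_pc, z
    if not np.isfinite(best_z):
        logger.info("select_n_pc: flat performance profile; returning %d", best)
    return best


def nested_lopo_cv(X: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                   candidates) -> tuple[np.ndarray, np.ndarray]:
    """Nested LOPO CV: the inner loop (over training subjects only) selects
    the PC count; the outer loop predicts the held-out subject.

    Returns (held-out predictions, per-fold selected n_pc)."""
    subjects = np.asarray(subjects)
    uniq = pd.unique(subjects)
    if len(uniq) < 4:
        raise ValueError("need at least 4 subjects for nested CV")
    pred = np.empty(len(y), dtype=float)
    chosen = []
    for s in uniq:
        test = subjects == s
        n_pc = select_n_pc(X[~test], np.asarray(y)[~test], subjects[~test],
                           candidates)
        model = pcr_train(X[~test], np.asarray(y)[~test], n_pc)
        pred[test] = model_response(model.w, model.intercept, X[test])
        chosen.append(n_pc)
    return pred, np.array(chosen)


def evaluate_regression(pred: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                        n_boot: int = 10000, seed=None) -> dict:
    """Within-subject prediction-outcome correlations with a subject-level
    bootstrap test of the mean Fisher z (two-tailed normal p); the mean r is
    reported back-transformed.  MSE is mean +/- SEM across subjects.
    Subjects with constant predictions are flagged and excluded (logged)."""
    pred = np.asarray(pred, float)
    y = np.asarray(y, float)
    subjects = np.asarray(subjects)
    zs, mses, flagged = [], [], []
    for s in pd.unique(subjects):
        m = subjects == s
        if m.sum() < 3:
            raise ValueError(f"subject {s}: need >= 3 bins")
        mses.append(np.mean((pred[m] - y[m]) ** 2))
        if np.ptp(pred[m]) == 0 or np.ptp(y[m]) == 0:
            flagged.append(s)
            continue
        r = np.clip(np.corrcoef(pred[m], y[m])[0, 1], -0.999999, 0.999999)
        zs.append(np.arctanh(r))
    if flagged:
        logger.info("evaluate_regression: %d subjects with undefined r excluded: %s",
                    len(flagged), flagged)
    zs = np.array(zs)
    rng = np.random.default_rng(seed)
    n = len(zs)
    boots = rng.choice(zs, size=(n_boot, n), replace=True).mean(axis=1)
    sd = boots.std(ddof=1)
    zstat = zs.mean() / sd if sd > 0 else np.inf * np.sign(zs.mean())
    p = 2.0 * sps.norm.sf(abs(zstat)) if np.isfinite(zstat) else 0.0
    return {"mean_r": float(np.tanh(zs.mean())), "p": float(p), "z": float(zstat),
            "mse_mean": float(np.mean(mses)),
            "mse_sem": float(np.std(mses, ddof=1) / np.sqrt(len(mses))),
            "n_subjects": n, "excluded_subjects": flagged}


def bootstrap_weight_stats(trainer, X: np.ndarray, y: np.ndarray,
                           subjects: np.ndarray, n_boot: int = 10000,
                           seed=None) -> WeightStats:
    """Subject-level bootstrap of model weights: resample subjects with
    replacement, retrain, and test each feature weight with z = mean/sd and a
    two-tailed normal p, BH-FDR corrected.  Features whose bootstrap sd is 0
    are flagged degenerate and excluded from inference."""
    if n_boot < 100:
        logger.warning("n_boot=%d < 100: smoke mode only", n_boot)
    X = np.asarray(X, float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    uniq = pd.unique(subjects)
    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        take = rng.integers(0, len(uniq), len(uniq))
        rows = np.concatenate([np.flatnonzero(subjects == uniq[t]) for t in take])
        W[b] = trainer(X[rows], y[rows]).w
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    degenerate = sd == 0
    z = np.full(X.shape[1], np.nan)
    z[~degenerate] = mean[~degenerate] / sd[~degenerate]
    p = np.full(X.shape[1], np.nan)
    p[~degenerate] = 2.0 * sps.norm.sf(np.abs(z[~degenerate]))
    q = np.full(X.shape[1], np.nan)
    if (~degenerate).any():
        _, q_ok, _, _ = multipletests(p[~degenerate], method="fdr_bh")
        q[~degenerate] = q_ok
    return WeightStats(mean=mean, sd=sd, z=z, p=p, q=q,
                       degenerate=degenerate, n_boot=n_boot)


def hub_regions(weight_matrix: np.ndarray) -> dict[str, int | None]:
    """Hub region per weight sign: the region maximizing the summed |weight|
    of surviving (thresholded) incident pairs; ties to the lowest region
    index (logged).  None when no weights of that sign survive."""
    Wm = np.asarray(weight_matrix, float)
    out: dict[str, int | None] = {}
    for sign, name in ((1, "positive"), (-1, "negative")):
        part = np.where(np.sign(Wm) == sign, np.abs(Wm), 0.0)
        strength = part.sum(axis=1)
        if strength.max() == 0:
            logger.info("no surviving %s weights; no hub", name)
            out[name] = None
            continue
        best = int(np.argmax(strength))
        ties = np.flatnonzero(strength == strength[best])
        if len(ties) > 1:
            logger.info("%s hub tie among regions %s; lowest index kept",
                        name, ties.tolist())
        out[name] = best
    return out
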