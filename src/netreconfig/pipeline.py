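"""End-to-end orchestration: time series -> windowed FC -> thresholding ->
multilayer community ensembles -> per-layer consensus -> region allegiance ->
group consensus and predictive-model feature tables.

These helpers wire the stage modules together with a per-stage seeding
discipline (a master seed spawns named child streams) so that any stage can
be re-run independently and the full pipeline is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import threshold_stack, windowed_fc
from .consensus import (MISSING, coassignment, consensus_iterate,
                        region_allegiance)
from .multilayer import run_ensemble
from .stats import periods_for
from .synthetic import SyntheticCohort, synthetic_parcellation

logger = logging.getLogger(__name__)

__all__ = ["SubjectRunResult", "CohortAnalysis", "analyze_run", "analyze_cohort",
            "region_feature_matrices"]

DEFAULT_DENSITY = 0.30
DEFAULT_N_ITER = 100


@dataclass
class SubjectRunResult:
    """Per-layer consensus labels and allegiance of one subject run."""

    layer_labels: np.ndarray          # (N, L), MISSING where excluded
    q_values: np.ndarray              # (n_iter,) achieved Q of the ensemble
    density: float

    @property
    def n_layers(self) -> int:
        return self.layer_labels.shape[1]

    def layer_allegiance(self, layer: int) -> np.ndarray:
        """Binary co-assignment of one layer's consensus labels (NaN on
        excluded nodes)."""
        return coassignment(self.layer_labels[:, layer])

    def mean_allegiance(self) -> np.ndarray:
        """Allegiance averaged over layers (pairwise-complete)."""
        stack = np.stack([self.layer_allegiance(l) for l in range(self.n_layers)])
        with np.errstate(invalid="ignore"):
            return np.nanmean(stack, axis=0)


@dataclass
class CohortAnalysis:
    """Per-subject, per-condition pipeline results for a whole cohort."""

    runs: dict                        # (subject, condition) -> SubjectRunResult
    parcellation: pd.DataFrame | None = None
    density: float = DEFAULT_DENSITY
    config: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list:
        return sorted({s for s, _ in self.runs})

    def condition_vectors(self, condition: str, bins=None) -> list:
        """Per-subject lists of per-bin assignment vectors for one condition
        (optionally restricted to a bin subset), for group consensus and the
        Phi permutation test."""
        out = []
        for s in self.subjects:
            run = self.runs[(s, condition)]
            use = range(run.n_layers) if bins is None else bins
            out.append([run.layer_labels[:, l] for l in use])
        return out

    def period_vectors(self, condition: str) -> dict[str, list]:
        periods = periods_for(next(iter(self.runs.values())).n_layers)
        return {name: self.condition_vectors(condition, bins)
                for name, bins in periods.items()}


def analyze_run(series: np.ndarray, n_bins: int, density: float,
                gamma: float = 1.0, omega: float = 1.0,
                n_iter: int = DEFAULT_N_ITER, seed=None,
                n_louvain_consensus: int = 100) -> SubjectRunResult:
    """Full single-run analysis: windowed FC, proportional thresholding,
    a generalized-Louvain ensemble, and a per-layer consensus partition."""
    fc = windowed_fc(series, n_bins)
    thr = threshold_stack(fc, density)
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(1 + n_bins) >> 1
    ensemble = run_ensemble(thr.matrices, gamma=gamma, omega=omega,
                            n_iter=n_iter, seed=int(states[0]))
    N = thr.n_nodes
    layer_labels = np.full((N, n_bins), MISSING, int)
    for l in range(n_bins):
        vecs = [p.labels[:, l] for p in ensemble]
        cp = consensus_iterate(vecs, seed=int(states[1 + l]),
                               n_louvain=n_louvain_consensus)
        layer_labels[:, l] = cp.labels
    return SubjectRunResult(layer_labels=layer_labels,
                            q_values=np.array([p.q_value for p in ensemble]),
                            density=density)


def analyze_cohort(cohort: SyntheticCohort, density: float = DEFAULT_DENSITY,
                   gamma: float = 1.0, omega: float = 1.0,
                   n_iter: int = DEFAULT_N_ITER, seed=None,
                   n_louvain_consensus: int = 100,
                   parcellation: pd.DataFrame | None = None,
                   conditions: tuple = ("pain", "control")) -> CohortAnalysis:
    """Run the per-subject pipeline on every run of a synthetic cohort."""
    if parcellation is None:
        parcellation = synthetic_parcellation(cohort.config.resolved_scenario())
    n_bins = cohort.config.n_layers
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * cohort.n_subjects) >> 1
    runs = {}
    for s, record in enumerate(cohort.subjects):
        for j, cond in enumerate(conditions):
            runs[(s, cond)] = analyze_run(
                record["series"][cond], n_bins=n_bins, density=density,
                gamma=gamma, omega=omega, n_iter=n_iter,
                seed=int(states[2 * s + j]),
                n_louvain_consensus=n_louvain_consensus)
    return CohortAnalysis(runs=runs, parcellation=parcellation, density=density,
                          config={"gamma": gamma, "omega": omega,
                                  "n_iter": n_iter, "seed": seed})


def region_feature_matrices(analysis: CohortAnalysis, mode: str,
                            condition: str = "pain") -> tuple[dict, list]:
    """Region allegiance matrices keyed for the two predictive-model designs.

    classification -> {(subject, condition): bin-averaged R x R matrix} over
    both conditions; regression -> {(subject, bin): R x R matrix} for the
    pain-like condition.  Returns (matrices, region_labels).
    """
    parc = analysis.parcellation.sort_values("node")["region"]
    out = {}
    region_labels = None
    if mode == "classification":
        for (s, cond), run in analysis.runs.items():
            mat, region_labels = region_allegiance(run.mean_allegiance(), parc)
            out[(s, cond)] = np.nan_to_num(mat, nan=0.0)
    elif mode == "regression":
        for s in analysis.subjects:
            run = analysis.runs[(s, condition)]
            for l in range(run.n_layers):
                mat, region_labels = region_allegiance(run.layer_allegiance(l), parc)
                # a fully excluded region pair carries no co-assignment evidence
                out[(s, l)] = np.nan_to_num(mat, nan=0.0)
    else:
        raise ValueError("mode must be 'classification' or 'regression'")
    return out, region_labels
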