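"""Synthetic two-condition cohorts with planted time-evolving community
structure and coupled rating traces.

The generator emulates the statistical structure that the downstream analysis
assumes: per subject and condition, a multivariate time series whose windowed
correlation follows a planted block structure that reorganizes over time in
the pain-like condition only, together with a continuous rating trace on a
labeled-magnitude scale exhibiting a rise-and-fall profile coupled to the
planted reconfiguration.

Planted scenario (the analog of the empirical finding): baseline blocks named
after canonical networks (SM somatomotor, FP frontoparietal, SUB subcortical,
CB cerebellar, DMN default-mode).  In the pain-like condition a configured
subset of FP and SUB nodes migrates into the SM block during the early and
middle time windows and moves back out late (FP migrants to their own block,
SUB migrants to the CB block); in addition, the between-block correlation of
the coupled block pairs (all pairs among SM, FP, SUB) increases by kappa
times the current rating, so the continuous rating has a network correlate
in every window.  The control condition keeps its labels in all layers and
its rating near zero.

Within each window, samples are i.i.d. draws from a zero-mean multivariate
normal (windows independent; no autocorrelation); an optional AR(1)
coefficient exists but is off by default, because the downstream analysis
operates on per-window correlations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GLMS_ANCHORS",
    "PlantedStructure",
    "RatingTrace",
    "Scenario",
    "CohortConfig",
    "SyntheticCohort",
    "default_scenario",
    "generate_planted_partitions",
    "layer_correlation",
    "simulate_timeseries",
    "generate_ratings",
    "generate_cohort",
    "zero_effect_config",
    "noisy_null_config",
    "aversive_control_config",
    "synthetic_parcellation",
]

#: labeled-magnitude scale anchors (value in [0, 1])
GLMS_ANCHORS = {
    "Not at all": 0.0,
    "A little bit": 0.061,
    "Moderately": 0.172,
    "Strongly": 0.354,
    "Very strongly": 0.533,
    "Most": 1.0,
}

PSD_TOL = -1e-10


@dataclass
class Scenario:
    """Named baseline blocks, a migration schedule, and coupled block pairs.

    ``blocks``: ordered mapping block name -> size.
    ``migrations``: list of dicts with keys ``block`` (source block name),
    ``n`` (how many of its nodes migrate), ``early_target`` / ``late_target``
    (block names joined during the early+middle and late layers), applied to
    the pain-like condition only.
    ``coupled_pairs``: block-name pairs whose between-block correlation gains
    kappa * rating.
    ``late_start``: first 0-based layer of the late phase.
    """

    blocks: dict[str, int]
    migrations: list[dict] = field(default_factory=list)
    coupled_pairs: list[tuple[str, str]] = field(default_factory=list)
    late_start: int = 7


@dataclass
class PlantedStructure:
    """Per-layer block labels plus the correlation parameters implying them."""

    labels_by_layer: np.ndarray       # (N, L) int block ids
    rho_in: float
    rho_out: float
    kappa: float
    block_names: list[str]
    coupled_blocks: list[tuple[int, int]]   # block-id pairs

    @property
    def n_nodes(self) -> int:
        return self.labels_by_layer.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels_by_layer.shape[1]


@dataclass
class RatingTrace:
    times: np.ndarray                 # seconds, strictly increasing
    values: np.ndarray                # in [0, 1]
    anchors: dict[str, float] = field(default_factory=lambda: dict(GLMS_ANCHORS))


@dataclass
class CohortConfig:
    """Desk-scale defaults: 20 subjects, 60 nodes, 10 windows, 3000 samples."""

    n_subjects: int = 20
    n_nodes: int = 60
    n_layers: int = 10
    n_timepoints: int = 3000
    tr: float = 0.4                   # seconds per sample
    rho_in: float = 0.55
    rho_out: float = 0.08
    kappa: float = 0.15
    rating_peak: float = 0.85
    rating_peak_time_frac: float = 0.22   # peak at ~22% of the run
    rating_shape: float = 2.5             # gamma-curve shape parameter
    rating_noise: float = 0.03
    subject_amp_jitter: float = 0.12
    subject_peak_jitter: float = 0.08
    control_rating_level: float = 0.02
    scenario: Scenario | None = None
    ar1: float = 0.0                  # optional AR(1) within windows, off
    variance_coupling: float = 0.0    # rating-coupled global variance gain

    def resolved_scenario(self) -> Scenario:
        return self.scenario if self.scenario is not None else default_scenario(self.n_nodes)


@dataclass
class SyntheticCohort:
    subjects: list[dict]              # {series: {cond: T x N}, ratings: {cond: RatingTrace},
                                      #  rating_bins: {cond: (L,)}, effects: {...}}
    ground_truth: dict                # cond -> PlantedStructure
    config: CohortConfig = None
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def default_scenario(n_nodes: int = 60) -> Scenario:
    """Default planted scenario: five blocks scaled to ``n_nodes``; four FP
    and four SUB nodes (at the 60-node scale) migrate into SM early and move
    to FP / CB respectively in the late layers."""
    if n_nodes < 12:
        raise ValueError("need at least 12 nodes")
    base = {"SM": 14, "FP": 12, "SUB": 10, "CB": 12, "DMN": 12}
    scale = n_nodes / 60.0
    blocks = {k: max(2, int(round(v * scale))) for k, v in base.items()}
    drift = n_nodes - sum(blocks.values())
    blocks["SM"] += drift
    n_mig = max(2, int(round(4 * scale)))
    return Scenario(
        blocks=blocks,
        migrations=[
            {"block": "FP", "n": n_mig, "early_target": "SM", "late_target": "FP"},
            {"block": "SUB", "n": n_mig, "early_target": "SM", "late_target": "CB"},
        ],
        # the extended pain-like community integrates jointly: all pairwise
        # couplings among its member blocks rise with the rating (a star
        # coupling would not stay positive semidefinite)
        coupled_pairs=[("SM", "FP"), ("SM", "SUB"), ("FP", "SUB")],
        late_start=7,
    )


def _block_labels(scenario: Scenario) -> tuple[np.ndarray, dict[str, int], dict[str, np.ndarray]]:
    names = list(scenario.blocks)
    ids = {name: i + 1 for i, name in enumerate(names)}
    labels = np.concatenate([np.full(size, ids[name])
                             for name, size in scenario.blocks.items()])
    nodes = {}
    start = 0
    for name, size in scenario.blocks.items():
        nodes[name] = np.arange(start, start + size)
        start += size
    return labels, ids, nodes


def generate_planted_partitions(n_nodes: int, n_layers: int,
                                scenario: Scenario,
                                rho_in: float = 0.55, rho_out: float = 0.08,
                                kappa: float = 0.15) -> dict[str, PlantedStructure]:
    """Planted per-layer block labels for the control and pain conditions.

    The control condition has identical labels in every layer; the pain
    condition moves each migration's nodes into its ``early_target`` block
    for the layers before ``late_start`` and into its ``late_target`` block
    from ``late_start`` on.  Rejects configurations leaving any block with
    fewer than 2 nodes in any layer.
    """
    if n_nodes < 12 or n_layers < 2:
        raise ValueError("need n_nodes >= 12 and n_layers >= 2")
    if sum(scenario.blocks.values()) != n_nodes:
        raise ValueError("block sizes must sum to n_nodes")
    base, ids, nodes = _block_labels(scenario)
    names = list(scenario.blocks)
    control = np.tile(base[:, None], (1, n_layers))
    pain = control.copy()
    taken: dict[str, int] = {}
    for mig in scenario.migrations:
        src = mig["block"]
        start = taken.get(src, 0)
        members = nodes[src][start:start + mig["n"]]
        if len(members) < mig["n"]:
            raise ValueError(f"block {src} has too few nodes to migrate {mig['n']}")
        taken[src] = start + mig["n"]
        for l in range(n_layers):
            target = mig["early_target"] if l < scenario.late_start else mig["late_target"]
            pain[members, l] = ids[target]
    for cond_labels in (control, pain):
        for l in range(n_layers):
            _, counts = np.unique(cond_labels[:, l], return_counts=True)
            if counts.min() < 2:
                raise ValueError(
                    f"migration schedule leaves a block with <2 nodes in layer {l}")
    coupled = [(ids[a], ids[b]) for a, b in scenario.coupled_pairs]
    mk = lambda lab: PlantedStructure(labels_by_layer=lab, rho_in=rho_in,
                                      rho_out=rho_out, kappa=kappa,
                                      block_names=names, coupled_blocks=coupled)
    return {"control": mk(control), "pain": mk(pain)}


def layer_correlation(planted: PlantedStructure, layer: int,
                      rating: float = 0.0) -> np.ndarray:
    """Correlation matrix implied by one layer's labels and the rating level.

    rho_in within blocks, rho_out + kappa*rating on coupled block pairs,
    rho_out elsewhere, unit diagonal.  Raises if the result is not positive
    semidefinite (smallest eigenvalue < -1e-10).
    """
    lab = planted.labels_by_layer[:, layer]
    C = np.full((planted.n_nodes, planted.n_nodes), planted.rho_out)
    same = lab[:, None] == lab[None, :]
    C[same] = planted.rho_in
    boost = planted.rho_out + planted.kappa * rating
    for a, b in planted.coupled_blocks:
        mask = (lab[:, None] == a) & (lab[None, :] == b)
        C[mask | mask.T] = boost
    np.fill_diagonal(C, 1.0)
    w = np.linalg.eigvalsh(C)
    if w[0] < PSD_TOL:
        raise ValueError(
            f"implied correlation for layer {layer} is not PSD "
            f"(min eigenvalue {w[0]:.3e}); reduce kappa or rho contrasts")
    return C


def simulate_timeseries(planted: PlantedStructure, rating_bins: np.ndarray,
                        T: int, n_layers: int, seed=None,
                        ar1: float = 0.0,
                        variance_coupling: float = 0.0) -> np.ndarray:
    """T x N series: per layer, i.i.d. zero-mean multivariate normal samples
    with the layer's implied correlation; contiguous equal segments,
    independent across layers.

    ``variance_coupling`` scales every node's amplitude by
    1 + variance_coupling * rating in each window: an arousal-like global
    variance change that leaves the correlation structure untouched (used by
    the aversive-control specificity probe)."""
    if T % n_layers != 0 or T // n_layers < 20:
        raise ValueError("T must divide into n_layers segments of >= 20 samples")
    rating_bins = np.asarray(rating_bins, float)
    if len(rating_bins) != n_layers:
        raise ValueError("need one rating level per layer")
    seg = T // n_layers
    rng = np.random.default_rng(seed)
    out = np.empty((T, planted.n_nodes))
    for l in range(n_layers):
        C = layer_correlation(planted, l, rating_bins[l])
        Lc = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
        z = rng.standard_normal((seg, planted.n_nodes))
        if ar1:
            for t in range(1, seg):
                z[t] = ar1 * z[t - 1] + np.sqrt(1 - ar1 ** 2) * z[t]
        block = z @ Lc.T
        if variance_coupling:
            block = block * (1.0 + variance_coupling * rating_bins[l])
        out[l * seg:(l + 1) * seg] = block
    return out


def generate_ratings(n_samples: int, tr: float, peak: float,
                     peak_time_frac: float, shape: float = 2.5,
                     noise: float = 0.0, amp_jitter: float = 0.0,
                     peak_jitter: float = 0.0, baseline: float = 0.0,
                     seed=None) -> RatingTrace:
    """Unimodal rise-and-fall rating curve (gamma-shaped), subject-jittered
    in amplitude and peak time, with additive noise, clipped to [0, 1].

    ``peak`` = 0 with ``baseline`` = 0 gives an all-zero trace (the control
    condition uses a small positive baseline instead).
    """
    if not (0 <= peak <= 1):
        raise ValueError("peak must be in [0, 1]")
    if not (0 < peak_time_frac < 1):
        raise ValueError("time-to-peak must fall inside the run")
    rng = np.random.default_rng(seed)
    times = np.arange(1, n_samples + 1) * tr
    run_len = n_samples * tr
    amp = peak * max(0.0, 1.0 + amp_jitter * rng.standard_normal()) if peak > 0 else 0.0
    tp = run_len * peak_time_frac * (1.0 + peak_jitter * rng.standard_normal())
    tp = min(max(tp, tr), run_len * 0.9)
    x = times / tp
    curve = amp * np.power(x, shape) * np.exp(shape * (1.0 - x))
    values = baseline + curve
    if noise > 0:
        values = values + noise * rng.standard_normal(n_samples)
    return RatingTrace(times=times, values=np.clip(values, 0.0, 1.0))


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    seg = len(values) // n_bins
    return values[:seg * n_bins].reshape(n_bins, seg).mean(axis=1)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = 0
                    ) -> SyntheticCohort:
    """Deterministic cohort generation: a master seed spawns independent
    child streams per subject and condition, so subjects are independent yet
    the whole cohort is bit-identical under the same seed."""
    config = config or CohortConfig()
    scenario = config.resolved_scenario()
    planted = generate_planted_partitions(
        config.n_nodes, config.n_layers, scenario,
        rho_in=config.rho_in, rho_out=config.rho_out, kappa=config.kappa)
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(4 * config.n_subjects) >> 1
    subjects = []
    for s in range(config.n_subjects):
        rate_seed_p, rate_seed_c, ts_seed_p, ts_seed_c = (
            int(v) for v in states[4 * s: 4 * s + 4])
        trace_pain = generate_ratings(
            config.n_timepoints, config.tr, config.rating_peak,
            config.rating_peak_time_frac, shape=config.rating_shape,
            noise=config.rating_noise, amp_jitter=config.subject_amp_jitter,
            peak_jitter=config.subject_peak_jitter, baseline=0.0,
            seed=rate_seed_p)
        trace_ctrl = generate_ratings(
            config.n_timepoints, config.tr, 0.0, config.rating_peak_time_frac,
            noise=config.rating_noise, baseline=config.control_rating_level,
            seed=rate_seed_c)
        bins_pain = _bin_means(trace_pain.values, config.n_layers)
        bins_ctrl = _bin_means(trace_ctrl.values, config.n_layers)
        series = {
            "pain": simulate_timeseries(planted["pain"], bins_pain,
                                        config.n_timepoints, config.n_layers,
                                        seed=ts_seed_p, ar1=config.ar1,
                                        variance_coupling=config.variance_coupling),
            "control": simulate_timeseries(planted["control"], bins_ctrl,
                                           config.n_timepoints, config.n_layers,
                                           seed=ts_seed_c, ar1=config.ar1,
                                           variance_coupling=config.variance_coupling),
        }
        subjects.append({
            "series": series,
            "ratings": {"pain": trace_pain, "control": trace_ctrl},
            "rating_bins": {"pain": bins_pain, "control": bins_ctrl},
        })
    return SyntheticCohort(subjects=subjects, ground_truth=planted,
                           config=config, seed=seed)


def _no_migration_scenario(n_nodes: int) -> Scenario:
    sc = default_scenario(n_nodes)
    return Scenario(blocks=sc.blocks, migrations=[],
                    coupled_pairs=sc.coupled_pairs, late_start=sc.late_start)


def zero_effect_config(**overrides) -> CohortConfig:
    """Null cohort: no migrations and no rating-network coupling, so the two
    conditions differ only in their rating traces.  Downstream group
    statistics are exchangeable under condition relabeling.

    The default SNR is deliberately low (weak blocks, short windows): at the
    effect-cohort SNR the detected partitions are bit-identical across runs,
    every forced-choice comparison ties, and chance-level behavior has no
    sampling distribution to land in.
    """
    defaults = dict(kappa=0.0, rho_in=0.13, rho_out=0.10, n_timepoints=1200)
    defaults.update(overrides)
    cfg = CohortConfig(**defaults)
    cfg.scenario = _no_migration_scenario(cfg.n_nodes)
    return cfg


def noisy_null_config(**overrides) -> CohortConfig:
    """Low-SNR null cohort for permutation-test calibration.

    Weak blocks and short windows make each subject's detected community
    structure genuinely variable, so group-level statistics have a
    non-degenerate sampling distribution (a strong-SNR null collapses every
    permutation statistic onto a single tie, which exercises nothing).
    """
    defaults = dict(n_subjects=8, n_nodes=40, n_timepoints=1200,
                    rho_in=0.12, rho_out=0.10, kappa=0.0)
    defaults.update(overrides)
    cfg = CohortConfig(**defaults)
    cfg.scenario = _no_migration_scenario(cfg.n_nodes)
    return cfg


def aversive_control_config(**overrides) -> CohortConfig:
    """Specificity probe: an arousal-like, rating-coupled global variance
    change with no community reconfiguration at all."""
    cfg = CohortConfig(kappa=0.0, variance_coupling=0.3, **overrides)
    cfg.scenario = _no_migration_scenario(cfg.n_nodes)
    return cfg


def synthetic_parcellation(scenario: Scenario, nodes_per_region: int = 5
                           ) -> pd.DataFrame:
    """Node -> region table for a synthetic scenario: each baseline block is
    split into contiguous regions of about ``nodes_per_region`` nodes, tagged
    with the block's canonical-network name."""
    rows = []
    start = 0
    region_id = 0
    for name, size in scenario.blocks.items():
        n_regions = max(1, int(round(size / nodes_per_region)))
        bounds = np.linspace(0, size, n_regions + 1).astype(int)
        for r in range(n_regions):
            for node in range(start + bounds[r], start + bounds[r + 1]):
                rows.append({"node": node, "region": region_id, "network": name})
            region_id += 1
        start += size
    return pd.DataFrame(rows)
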