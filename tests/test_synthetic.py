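"""Synthetic cohort generator: planted partitions, ratings, and the implied
correlation structure."""

import numpy as np
import pytest

from netreconfig import synthetic
from netreconfig.synthetic import (CohortConfig, Scenario, default_scenario,
                                   generate_cohort, generate_planted_partitions,
                                   generate_ratings, layer_correlation,
                                   simulate_timeseries, synthetic_parcellation)


class TestPlantedPartitions:
    def test_no_migrations_equals_control(self):
        sc = default_scenario(60)
        sc.migrations = []
        out = generate_planted_partitions(60, 10, sc)
        assert np.array_equal(out["pain"].labels_by_layer,
                              out["control"].labels_by_layer)

    def test_migration_differences_counted_exactly(self):
        blocks = {"SM": 8, "FP": 6, "SUB": 4, "CB": 6}
        sc = Scenario(blocks=blocks,
                      migrations=[{"block": "FP", "n": 4,
                                   "early_target": "SM", "late_target": "FP"}],
                      late_start=3)
        out = generate_planted_partitions(24, 10, sc)
        diff = out["pain"].labels_by_layer != out["control"].labels_by_layer
        # 4 FP nodes differ in the 3 early layers only (late target is home)
        assert diff.sum() == 4 * 3
        assert np.array_equal(np.unique(np.flatnonzero(diff.any(axis=1))),
                              np.arange(8, 12))

    def test_default_scenario_early_to_late_shift(self):
        # early: FP and SUB migrants sit in the SM block; late: FP migrants
        # return home and SUB migrants join the CB block
        out = generate_planted_partitions(60, 10, default_scenario(60))
        pain, ctrl = out["pain"], out["control"]
        names = pain.block_names
        sm, fp, sub, cb = (names.index(n) + 1 for n in ("SM", "FP", "SUB", "CB"))
        mig = np.flatnonzero((pain.labels_by_layer[:, 0] == sm)
                             & (ctrl.labels_by_layer[:, 0] != sm))
        assert len(mig) > 0
        fp_mig = mig[ctrl.labels_by_layer[mig, 0] == fp]
        sub_mig = mig[ctrl.labels_by_layer[mig, 0] == sub]
        assert np.all(pain.labels_by_layer[fp_mig, -1] == fp)
        assert np.all(pain.labels_by_layer[sub_mig, -1] == cb)

    def test_small_block_rejected(self):
        sc = Scenario(blocks={"SM": 6, "FP": 3, "CB": 3},
                      migrations=[{"block": "FP", "n": 2,
                                   "early_target": "SM", "late_target": "FP"}])
        with pytest.raises(ValueError, match="<2 nodes"):
            generate_planted_partitions(12, 4, sc)


class TestLayerCorrelation:
    def test_psd_across_seeds_and_layers(self):
        cfg = CohortConfig()
        planted = generate_planted_partitions(
            cfg.n_nodes, cfg.n_layers, cfg.resolved_scenario(),
            rho_in=cfg.rho_in, rho_out=cfg.rho_out, kappa=cfg.kappa)
        for cond in ("pain", "control"):
            for l in range(cfg.n_layers):
                for rating in (0.0, 0.5, 1.0):
                    C = layer_correlation(planted[cond], l, rating)
                    assert np.linalg.eigvalsh(C)[0] >= -1e-10
                    assert np.all(np.diag(C) == 1.0)

    def test_empirical_within_block_correlation(self):
        cfg = CohortConfig(rho_in=0.6, rho_out=0.1, kappa=0.0)
        planted = generate_planted_partitions(
            cfg.n_nodes, cfg.n_layers, cfg.resolved_scenario(),
            rho_in=0.6, rho_out=0.1, kappa=0.0)["control"]
        series = simulate_timeseries(planted, np.zeros(10), 3000, 10, seed=0)
        seg = series[:300]
        C = np.corrcoef(seg, rowvar=False)
        lab = planted.labels_by_layer[:, 0]
        same = (lab[:, None] == lab[None, :]) & ~np.eye(len(lab), dtype=bool)
        assert C[same].mean() == pytest.approx(0.6, abs=0.05)

    def test_degenerate_equal_rhos_no_block_structure(self):
        cfg = CohortConfig(rho_in=0.3, rho_out=0.3, kappa=0.0)
        planted = generate_planted_partitions(
            cfg.n_nodes, cfg.n_layers, cfg.resolved_scenario(),
            rho_in=0.3, rho_out=0.3, kappa=0.0)["control"]
        series = simulate_timeseries(planted, np.zeros(10), 3000, 10, seed=1)
        C = np.corrcoef(series[:300], rowvar=False)
        lab = planted.labels_by_layer[:, 0]
        off = ~np.eye(len(lab), dtype=bool)
        same = (lab[:, None] == lab[None, :]) & off
        diff_mask = (lab[:, None] != lab[None, :])
        gap = C[same].mean() - C[diff_mask].mean()
        # three standard errors of a correlation estimate at n=300
        assert abs(gap) < 3 * (1 / np.sqrt(300))

    def test_coupled_pairs_track_rating_profile(self):
        # per-layer mean correlation over all coupled block pairs follows the
        # rise-and-fall rating profile in rank order; 900-sample windows keep
        # the sampling noise of the estimate well below the kappa-driven range
        from scipy.stats import spearmanr
        cfg = CohortConfig()
        planted = generate_planted_partitions(
            cfg.n_nodes, cfg.n_layers, cfg.resolved_scenario(),
            rho_in=cfg.rho_in, rho_out=cfg.rho_out, kappa=cfg.kappa)["control"]
        ratings = np.array([0.1, 0.5, 0.9, 0.8, 0.6, 0.45, 0.3, 0.2, 0.12, 0.05])
        series = simulate_timeseries(planted, ratings, 9000, 10, seed=2)
        lab = planted.labels_by_layer[:, 0]
        mask = np.zeros((cfg.n_nodes, cfg.n_nodes), bool)
        for a, b in planted.coupled_blocks:
            m = (lab[:, None] == a) & (lab[None, :] == b)
            mask |= m | m.T
        per_layer = [np.corrcoef(series[l * 900:(l + 1) * 900],
                                 rowvar=False)[mask].mean() for l in range(10)]
        rho, _ = spearmanr(per_layer, ratings)
        assert rho > 0.8

    def test_kappa_monotonicity(self):
        means = []
        for kappa in (0.0, 0.2, 0.4):
            cfg = CohortConfig(kappa=kappa)
            planted = generate_planted_partitions(
                cfg.n_nodes, cfg.n_layers, cfg.resolved_scenario(),
                rho_in=cfg.rho_in, rho_out=cfg.rho_out, kappa=kappa)["control"]
            series = simulate_timeseries(planted, np.full(10, 0.8), 3000, 10,
                                         seed=3)
            lab = planted.labels_by_layer[:, 0]
            names = planted.block_names
            a = lab == names.index("SM") + 1
            b = lab == names.index("FP") + 1
            C = np.corrcoef(series[:300], rowvar=False)
            means.append(C[np.ix_(a, b)].mean())
        assert means[0] <= means[1] <= means[2]

    def test_indivisible_run_rejected(self):
        planted = generate_planted_partitions(60, 10, default_scenario(60))["control"]
        with pytest.raises(ValueError, match="segments"):
            simulate_timeseries(planted, np.zeros(10), 3001, 10, seed=0)


class TestRatings:
    def test_zero_amplitude_all_zero(self):
        trace = generate_ratings(1000, 0.4, peak=0.0, peak_time_frac=0.2, seed=0)
        assert np.all(trace.values == 0.0)

    def test_noiseless_profile_unimodal(self):
        trace = generate_ratings(3000, 0.4, peak=0.85, peak_time_frac=0.22,
                                 noise=0.0, seed=1)
        bins = trace.values[:3000].reshape(10, 300).mean(axis=1)
        peaks = sum(1 for i in range(1, 9)
                    if bins[i] > bins[i - 1] and bins[i] > bins[i + 1])
        assert peaks <= 1
        assert bins.argmax() <= 3

    def test_anchor_values(self):
        trace = generate_ratings(100, 0.4, 0.5, 0.3, seed=2)
        assert trace.anchors["A little bit"] == 0.061
        assert trace.anchors["Moderately"] == 0.172
        assert trace.anchors["Most"] == 1.0

    def test_pain_exceeds_control_early_converges_late(self):
        cfg = CohortConfig(n_subjects=8)
        coh = generate_cohort(cfg, seed=3)
        pain = np.array([s["rating_bins"]["pain"] for s in coh.subjects])
        ctrl = np.array([s["rating_bins"]["control"] for s in coh.subjects])
        diff = pain.mean(axis=0) - ctrl.mean(axis=0)
        assert np.all(diff[1:5] > 0.2)
        assert diff[-1] < 0.1        # converged by the final bins

    def test_values_clipped_and_times_increasing(self):
        trace = generate_ratings(500, 0.5, 1.0, 0.1, noise=0.5, seed=4)
        assert np.all((trace.values >= 0) & (trace.values <= 1))
        assert np.all(np.diff(trace.times) > 0)


class TestCohort:
    def test_same_seed_identical(self):
        cfg = CohortConfig(n_subjects=2, n_nodes=24, n_layers=4,
                           n_timepoints=400)
        a = generate_cohort(cfg, seed=9)
        b = generate_cohort(cfg, seed=9)
        for ra, rb in zip(a.subjects, b.subjects):
            for cond in ("pain", "control"):
                assert np.array_equal(ra["series"][cond], rb["series"][cond])
                assert np.array_equal(ra["ratings"][cond].values,
                                      rb["ratings"][cond].values)

    def test_different_seed_differs(self):
        cfg = CohortConfig(n_subjects=1, n_nodes=24, n_layers=4,
                           n_timepoints=400)
        a = generate_cohort(cfg, seed=1)
        b = generate_cohort(cfg, seed=2)
        assert not np.array_equal(a.subjects[0]["series"]["pain"],
                                  b.subjects[0]["series"]["pain"])

    def test_psd_guard_never_triggers_across_seeds(self):
        cfg = CohortConfig(n_subjects=1, n_nodes=60, n_layers=10,
                           n_timepoints=200 * 10 // 10 * 10)
        cfg.n_timepoints = 2000
        for seed in range(100):
            generate_cohort(cfg, seed=seed)   # raises on any PSD violation

    def test_null_presets_have_no_planted_difference(self):
        for maker in (synthetic.zero_effect_config,
                      synthetic.noisy_null_config,
                      synthetic.aversive_control_config):
            cfg = maker()
            assert cfg.kappa == 0.0
            assert cfg.resolved_scenario().migrations == []


class TestParcellation:
    def test_covers_all_nodes_nonempty_regions(self):
        sc = default_scenario(60)
        parc = synthetic_parcellation(sc, nodes_per_region=5)
        assert sorted(parc["node"]) == list(range(60))
        sizes = parc.groupby("region").size()
        assert sizes.min() >= 2
        assert set(parc["network"]) == set(sc.blocks)
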