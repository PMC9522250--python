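# netreconfig

Dynamic brain-network reconfiguration analysis: time-windowed functional
connectivity, multilayer community detection, module-allegiance consensus
structures, permutation inference, and allegiance-based predictive models —
with a synthetic cohort generator that plants the time-evolving community
structure the analysis is built to recover.

## The problem

Sustained experiences (the motivating case is tonic pain over a ~20-minute
scan) reorganize whole-brain functional networks over time: regions change
community membership as the experience rises and resolves.  Standard static
connectivity analyses cannot see this.  `netreconfig` implements the
analysis chain for such questions:

1. **Dynamic connectivity.** Split each run into nonoverlapping windows
   (default ten 2-minute bins), compute Pearson correlation per window, and
   apply proportional thresholding — keep the top fraction *d* of
   connections by signed value, without binarization.  The density is chosen
   by maximizing the condition contrast (summed |z| of five global graph
   attributes) over candidate densities.
2. **Multilayer communities.** Maximize the multilayer modularity

   Q = (1/2μ) Σ_{ijlr} [(A_ijl − γ_l P_ijl) δ_lr + δ_ij ω_jlr] δ(g_il, g_jr)

   with the Newman–Girvan null P = k_i k_j / 2m, γ = ω = 1, and ordinal
   inter-layer coupling, using a seeded generalized Louvain heuristic
   (ensembles of 100 runs).
3. **Allegiance and consensus.** Convert partition ensembles to module
   allegiance matrices T (T_ij = frequency of co-assignment), threshold at
   the maximum of a permutation null, and re-cluster to unanimity — per
   subject and window, and at the group level per condition or per
   early/middle/late period.
4. **Inference.** Phi-coefficient permutation tests for regional community
   change, seed-based allegiance contrasts with paired t-tests, exact
   binomial tests for forced-choice accuracies, BH-FDR, and a two-level GLM
   with bootstrap for rating effects.
5. **Predictive models.** Linear SVM (C = 1) on bin-averaged region-pair
   allegiances with paired forced two-choice evaluation, and
   principal-component regression of per-bin ratings with (nested)
   leave-one-participant-out cross-validation, subject-level bootstrap
   weight inference, hub identification, and transfer to held-out cohorts.

Everything is exercised end to end on synthetic cohorts with planted,
condition- and time-dependent block structure and coupled rating traces; see
`docs/methods.md` for the generative model and design choices.

## Worked example

```python
import numpy as np
from netreconfig import models, pipeline, synthetic

# a 20-subject cohort with the default planted reconfiguration
cohort = synthetic.generate_cohort(synthetic.CohortConfig(), seed=10)
analysis = pipeline.analyze_cohort(cohort, density=0.30, n_iter=100, seed=11)

# forced-choice classification, leave-one-participant-out
mats, _ = pipeline.region_feature_matrices(analysis, "classification")
ft = models.build_features(mats, "classification")
y, subj = ft.rows["condition"].to_numpy(), ft.rows["subject"].to_numpy()
pred = models.lopo_cv(lambda X, yy: models.svm_train(X, yy, C=1.0),
                      ft.X, y, subj)
fc = models.forced_choice_eval(pred[y == "pain"], pred[y == "control"])
print(f"forced-choice accuracy {fc['accuracy']:.2f} "
      f"({fc['n_correct']}/{fc['n_pairs']}), p = {fc['p']:.2e}")

# rating prediction, nested LOPO cross-validation
mats_r, _ = pipeline.region_feature_matrices(analysis, "regression")
ftr = models.build_features(mats_r, "regression")
sr, b = ftr.rows["subject"].to_numpy(), ftr.rows["bin"].to_numpy()
yr = np.array([cohort.subjects[s]["rating_bins"]["pain"][k]
               for s, k in zip(sr, b)])
pred_r, n_pc = models.nested_lopo_cv(ftr.X, yr, sr, range(1, 11))
ev = models.evaluate_regression(pred_r, yr, sr, n_boot=2000, seed=1)
print(f"mean within-subject r = {ev['mean_r']:.2f}, p = {ev['p']:.1e}, "
      f"PCs = {np.mean(n_pc):.1f}")
```

prints

```
forced-choice accuracy 1.00 (20/20), p = 1.91e-06
mean within-subject r = 0.65, p = 0.0e+00, PCs = 3.0
```

Every subject's pain-like run scores above its control run (the exact
two-tailed binomial p for 20/20 at chance 1/2), and the regression tracks
each subject's rise-and-fall rating profile across the ten bins with a mean
within-subject correlation of 0.65 — the planted effect is recovered from
the community structure alone, with no access to the generator's labels.

A command-line interface mirrors the stages
(`netreconfig simulate | fc | density-select | communities | consensus |
phi | seedmap | behavior | train-svm | train-pcr | evaluate | apply`); run
`netreconfig --help`.

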