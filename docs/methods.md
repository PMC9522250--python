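# Methods

`netreconfig` implements a dynamic brain-network analysis chain — windowed
functional connectivity, multilayer community detection, module-allegiance
consensus, permutation inference, and allegiance-based predictive models —
together with a synthetic cohort generator that plants the time-evolving
community structure the chain is designed to detect.  This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## Windowed connectivity and thresholding

A run of T samples over N nodes is split into `n_bins` contiguous,
nonoverlapping windows of equal length (trailing `T mod n_bins` samples are
dropped); each window yields one Pearson correlation layer.  The default of
10 bins corresponds to 2-minute windows on a 20-minute run.

Proportional thresholding retains the top `round(d * N(N-1)/2)` off-diagonal
entries by **signed** value (the convention of correlation-network toolboxes),
preserves the retained weights (no binarization for the community analysis),
and zeroes the diagonal.  Ties are broken by ascending (i, j) order, which
makes the edge count exact and the operation deterministic.  Five global
attributes (assortativity, transitivity, characteristic path, global
efficiency, modularity) are computed on the *binarized* thresholded graph;
the modularity attribute reuses the community optimizer (single layer,
resolution 1, ensemble maximum) so all five attributes describe the same
binary graph.  Density selection maximizes the summed absolute paired
z-statistics (mean difference over its standard error) of the five attributes
between conditions, over candidate densities
(0.01, 0.05, 0.10, 0.20, 0.30, 0.40); ties go to the sparsest candidate.
Characteristic path averages over connected pairs only and disconnected pairs
contribute zero to efficiency — the convention must be fixed explicitly
because thresholded graphs can disconnect.

## Multilayer modularity and generalized Louvain

The partition quality of labels g_il over nodes i and layers l is

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma_l P_ijl) delta_lr
                               + delta_ij omega_jlr ] delta(g_il, g_jr)

with the Newman–Girvan null P_ijl = k_il k_jl / (2 m_l), resolution
gamma_l = 1, and inter-layer coupling omega = 1 between copies of the same
node in **adjacent** layers (ordinal coupling — the temporal-network
convention; all-pairs coupling is a different model and is not implemented).
The normalizer is mu = sum_l m_l + omega N (L-1).  Because the literature
varies in where the coupling weights enter mu, absolute Q values are
comparable only within one convention; partitions are the meaningful output.

The optimizer builds the dense supra-modularity matrix
B = blockdiag(A_l - gamma_l P_l) + omega * (adjacent-layer identity) and runs
two-phase Louvain on it: greedy sweeps over node–layer units in a seeded
random order (reshuffled every pass), moving each unit to the community with
the largest quality gain above 1e-10 (ties to the lowest community id),
followed by community aggregation, until no move improves Q.  The sweep is
numba-compiled; a 60-node, 10-layer problem takes ~10 ms, so the 100-run
ensembles used throughout are cheap.  Negative weights surviving the top-d
threshold are kept as-is in A and in the degree sums; at the densities used
on correlation networks they are rare and small.

Validation: on every instance small enough to enumerate (N <= 5, L <= 2, all
set partitions of the node-layer units), the seeded ensemble attains the
enumerated global maximum and never exceeds it.

## Allegiance and consensus

The module allegiance T_ij of an ensemble is the frequency with which nodes
i and j share a label, averaged over detection iterations and (for
multilayer partitions) layers.  The consensus procedure iterates: average
allegiance; build a null by permuting each assignment vector once across
nodes (independently per layer, preserving each layer's community-size
distribution); zero all entries at or below the off-diagonal maximum of the
null; cluster the thresholded matrix 100 times with single-layer Louvain;
stop when all 100 outputs are identical (up to relabeling), else recurse on
them.  Nodes isolated by thresholding are excluded and reported.  An outer
cap of 50 iterations turns pathological non-convergence into a hard error
with diagnostics rather than a silent loop.

Within-individual consensus is computed per layer (each time window gets its
own consensus partition), giving time-resolved binary allegiance per subject.
Group consensus averages assignment-vector allegiance across subjects (and
across the bins of a period: early = bins 1–3, middle = 4–7, late = 8–10 of
10), thresholds against the same kind of permutation null, and finally drops
communities below `min_community_size` (default 20, the voxel-scale
convention; desk-scale synthetic runs use 2–4 because blocks have ~10
nodes).  Partial node coverage (unmapped nodes after a native-to-common
mapping) is handled by pairwise-complete averaging.

Region-level allegiance averages T over node pairs across two regions; the
diagonal is the mean over distinct within-region pairs (1 for singletons).
Model features are the strict upper triangle: R(R-1)/2 values, 34,453 at the
full scale of 263 regions.

## Phi permutation test

Regional change between two group consensus structures is the Phi
coefficient (Pearson correlation of binary vectors) between a node's
co-assignment profiles under the two structures, self excluded.  The null
exchanges the two labels of each subject's contributing assignment vectors
with probability 1/2 and recomputes both group structures; p is the
probability of a null Phi at most as large as the observed one (smaller Phi
= more dissimilar), with add-one smoothing.  Ties count as extreme: this is
what keeps the test level-valid when the consensus is discrete, and it makes
the degenerate identical-structures case maximally non-significant rather
than spuriously significant.

Two properties of this test shape the study design:

- **Calibration needs noise.**  When the planted structure is strong, every
  run's consensus is identical, all statistics tie, and the false-positive
  rate is trivially zero.  Null calibration therefore uses a low-SNR preset
  (rho_in = 0.12 vs rho_out = 0.10, 120-sample windows, 8 subjects) where
  partitions genuinely vary; the per-node rate at alpha = 0.05 is pooled
  over several seeded cohorts because nodes within a cohort share the same
  permutations and are strongly dependent.
- **Detection power scales with the cohort, not the effect.**  A sign-flip
  null over a winner-take-all consensus has an "imbalance tipping" tail: a
  sufficiently lopsided flip reproduces the observed pair of structures
  exactly, and those permutations tie with the observation no matter how
  large the effect is.  Empirically the consensus tips when one condition
  reaches about 70% of the mixture, so the tail is roughly
  2·P(Bin(n, 1/2) <= 0.3 n): about 0.06 at n = 20 and below 0.01 at n = 48.
  The planted-change analysis therefore uses a 48-subject cohort — the
  group-size regime this kind of test is designed for.

## Predictive models

Classification: linear soft-margin SVM (C = 1) on bin-averaged region
allegiance, one row per subject and condition, no feature scaling
(allegiances are already bounded and commensurate).  Evaluation is a paired
forced two-choice test — a subject is counted correct iff the pain-like
run's decision value exceeds the control run's; ties count incorrect —
with exact two-tailed binomial inference at chance 1/2, under
leave-one-participant-out (LOPO) cross-validation (all rows of the held-out
subject leave together).

Regression: principal-component regression of per-bin ratings on per-bin
region allegiance (centering-only PCA fitted on training rows, OLS on the
top n_pc scores, weights back-projected to feature space).  The PC count
maximizes the LOPO mean within-subject prediction–outcome correlation
(Fisher z averaged; ties to the smaller count); the nested variant selects
n_pc in an inner LOPO loop over the training subjects only.  Performance is
the back-transformed mean of within-subject Fisher z, tested with a
subject-level bootstrap (two-tailed normal p on mean/sd of the bootstrap
distribution).  Feature-level inference resamples subjects with replacement,
retrains, and forms z = mean/sd per feature with BH-FDR correction;
zero-variance features are flagged and excluded.

Transfer applies a trained model by dot product (response = w·x + b) to a
cohort generated with a different seed and a different run length; the
classifier is bin-count invariant because its features are bin-averaged.

## Synthetic cohorts

The generator plants exactly the structure the chain assumes.  Baseline
blocks emulate canonical networks (SM 14, FP 12, SUB 10, CB 12, DMN 12 nodes
at the 60-node default).  In the pain-like condition, 4 FP and 4 SUB nodes
migrate into the SM block for layers 1–7 and move out in layers 8–10 (FP
migrants home, SUB migrants to CB) — the discrete reconfiguration that the
consensus and Phi stages detect.  In addition, the between-block correlation
of all pairs among {SM, FP, SUB} rises by kappa times the current rating
bin — a continuous coupling that gives every window a rating correlate.  A
star coupling (SM–FP and SM–SUB without FP–SUB) is not positive
semidefinite at useful strengths; the joint coupling is, and is also the
scientifically intended structure (one extended, jointly integrated
community).

kappa is deliberately kept below the community-merging threshold
(kappa = 0.15: peak coupled correlation ~0.23 against 0.55 within blocks, with margin for per-subject rating-amplitude jitter).
At larger kappa the coupled blocks genuinely merge at high-rating bins, the
planted labels stop being the modularity-optimal description of the
generated data, and — because the inter-layer coupling omega = 1 smooths
labels across time — the merge persists into low-rating bins.  With the
label ground truth self-consistent, the rating signal that the regression
stage exploits comes mainly from the timing of the planted migration
relative to each subject's rating profile, not from threshold-crossing
merges.

Within each window, samples are i.i.d. zero-mean multivariate normal with
the implied correlation (rho_in = 0.55 within blocks, rho_out = 0.08
between, plus kappa·rating up to ~0.2 on coupled pairs); windows are
independent.  Every implied correlation matrix is eigenvalue-checked
(smallest >= -1e-10) and generation fails loudly otherwise.  An AR(1) knob
exists but is off by default: the analysis consumes per-window correlations
only, and the within-run autocorrelation of low-pass-filtered physiological
data is not characterized well enough to commit to a value.

Ratings follow a gamma-shaped rise-and-fall (peak 0.85 at ~22% of the run,
shape 2.5) on a labeled-magnitude scale with anchors
{0, 0.061, 0.172, 0.354, 0.533, 1}, with per-subject amplitude (12%) and
peak-time (8%) jitter and additive noise (sd 0.03), clipped to [0, 1]; the
control trace sits near 0.02.  The pain–control rating difference is large
in early/middle bins and converges by the final bins.

Defaults: 20 subjects, 60 nodes, 10 layers, 3000 samples at 0.4 s — a
desk-scale cohort that runs end to end in about a minute.  A full-scale
preset (48 subjects, 0.46 s sampling) mirrors the empirical design.  A
master seed spawns independent child streams per subject and condition, so
cohorts are bit-identical under the same seed and subjects are independent.

Null presets: `zero_effect_config` (no migration, kappa = 0, low SNR) for
chance-band checks — low SNR is essential, because at effect-cohort SNR the
pipeline is deterministic, pain and control features are bit-identical, and
every forced-choice comparison ties (ties count incorrect, so "accuracy"
collapses to 0 rather than scattering around 1/2); `noisy_null_config` for
Phi calibration; `aversive_control_config` adds a rating-coupled global
variance change with no correlation change, as a specificity probe.

## What the synthetic validation shows — and does not

Passing the planted-recovery, calibration, and transfer checks shows that
the implementation detects the structure it claims to detect, at correct
test levels, under the generator's assumptions: Gaussian i.i.d. windows,
block-constant correlations, a shared block layout across subjects, and
reconfiguration schedules aligned to window boundaries.  Real data violate
all of these (autocorrelation, hemodynamics, spatially graded connectivity,
idiosyncratic anatomy, motion and physiological confounds), so these results
certify the machinery, not empirical claims about any real cohort.

## Problem sizes and numerical choices

- Ensembles: 100 generalized-Louvain runs per subject-run in headline
  analyses; Monte-Carlo sweeps (the 10-seed consensus recovery, the
  calibration cohorts) use 50 to keep a desk-scale full validation under
  ~15 minutes on one core.
- Permutations: 200 for the Phi test in the validation runs (1000 is the
  full-scale setting); bootstrap tests use 2000 resamples in validation
  (10,000 at full scale).
- Move tolerance 1e-10 in Louvain; consensus outer cap 50; PSD tolerance
  -1e-10; permutation p-values use add-one smoothing and are never 0.
- Thresholding tie-break: ascending (i, j); Louvain tie-break: lowest
  community id; forced-choice tie: incorrect; all chosen so every stage is
  a deterministic function of (data, seed).

## Known limitations

- Ordinal vs all-pairs inter-layer coupling changes Q and can change
  partitions; only ordinal coupling is implemented.
- The Phi test inherits the imbalance-tipping floor described above; at
  small n it cannot reach small p-values regardless of effect size.
- The two-level GLM is a summary-statistics approximation of a mixed model
  (per-subject OLS, subject-level bootstrap), appropriate for balanced
  designs only.
- `min_community_size` interacts with node count; the voxel-scale default
  (20) is too aggressive for cohorts with ~10-node blocks.
- NIfTI/volume ingestion is out of scope; the node-mapping abstraction
  (injective native-to-common maps) stands in for anatomical projection.
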