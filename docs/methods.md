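# Methods

## Fold scheme

`make_folds` implements repeated random subsampling (Monte Carlo
cross-validation): K independent shuffled partitions of the full index set,
each with test size ⌊(1 − f)·n⌋ and train size n − ⌊(1 − f)·n⌋. With
n = 319 and f = 0.7 this yields the reference 224/95 split, which rotating
k-fold cannot produce (a 10-fold scheme would give 95% train / 10% test
blocks per rotation). Folds therefore overlap in their test parts; fold
metrics are averaged arithmetically and are not independent in the
k-fold sense. Sub-seeds are `seed + fold_index` so any fold can be
regenerated alone. Stratified shuffling is available behind a flag but off
by default — plain shuffling is the reference behaviour.

## Rotation Forest

Each of the `n_estimators` trees draws its own random feature partition:
group sizes are sampled uniformly from `[min_group, max_group]` against a
shuffled feature pool, allowing at most one smaller remainder group. For
each group, ⌊`remove_proportion`·n⌋ training rows are removed uniformly at
random and the principal-component loadings of the survivors (restricted to
the group's columns, all components retained) form that group's block of
the p×p rotation matrix. `remove_proportion` is interpreted as instance
subsampling before the PCA — consistent with the classic algorithm's
75%-subsample step and with the parameter's observed range (≈0.42–0.50);
the trees themselves always train on every row of the rotated data. The
classic random class-subset draw before PCA is not performed. With
`remove_proportion = 0` each block is an orthonormal eigenbasis and the
whole matrix is orthogonal to 1e−8; eigenvector sign is fixed by making
each loading's largest-magnitude entry positive, so fits are deterministic
given the seed.

Trees are CART with Gini impurity, grown to purity with no depth limit or
pruning. On duplicate-conflict-free data the ensemble therefore fits its
training set exactly — training accuracy/F1/precision/recall are
identically 100%, which is a structural property of the configuration, not
a measure of generalisation. Prediction is a per-tree majority vote with
ties broken toward the lower class label; `predict_proba` averages per-tree
leaf class frequencies (for purity-grown trees this equals the vote
fraction). Zero-variance groups fall back to an identity block with a
logged warning. Internally the rotated matrices are cast to float32 before
the tree fit — sklearn does this cast anyway, so results are unchanged —
and input re-validation is skipped for speed.

Models serialize to a single JSON document (tree node arrays plus rotation
matrices); a deserialized model predicts by explicit node traversal and
reproduces the original predictions bit-for-bit.

## Bald Eagle Search

The optimizer maintains N agents in [0,1]^D. Every epoch applies the three
phases in the order select space → search space → swoop:

- select: `P_best + α·r·(P_mean − P_i)`, r ~ U[0,1] per agent;
- search: `P_i + y_i·(P_i − P_{i+1}) + x_i·(P_i − P_mean)`,
  x_i, y_i ~ U[−1,1], with circular neighbour indexing;
- swoop: `rand·P_best + x1_i·(P_i − c1·P_mean) + y1_i·(P_i − c2·P_best)`.

Design choices where the algorithm description is open: candidates are
accepted per agent only when strictly better (greedy elitism), which makes
the best-fitness history monotone; the search phase uses plain U[−1,1]
draws rather than the original polar-spiral parametrisation; `P_mean` is
the mean of the current population (not of all points ever visited);
out-of-box candidates are clipped to [0,1]^D. Defaults N = 30, T = 50,
α = 2, c1 = c2 = 2 are configurable — there is no canonical setting for
this problem class.

## Wrapper encoding and fitness

A position in [0,1]^(p+4) decodes to a candidate configuration: mask
coordinates ≥ 0.5 select features (an all-off mask falls back to the single
largest coordinate, lowest index on ties); the last four coordinates map
affinely onto the hyperparameter bounds, integer fields rounded half-up,
group bounds swapped if inverted. Default bounds — `n_estimators`
[100, 150], `min_group` [2, 5], `max_group` [5, 8], `remove_proportion`
[0.40, 0.51] — bracket the values observed in the reference 10-fold run and
are fully configurable.

Fitness is the positive-class F1 on the fold's training portion. Two modes:

- `inner_holdout` (default): fit on a stratified 80% of the fold's training
  rows, score on the remaining 20%, averaged over 3 independent splits
  (configurable). The search sees an estimate of generalisation. The
  averaging matters: a single ~45-row holdout is noisy enough that weak
  candidates occasionally score a perfect F1, and because replacement is
  greedy-elitist, the first saturating candidate would freeze the search;
  averaging makes spurious saturation roughly cube as rare while leaving
  genuinely strong candidates near the top.
- `train`: fit and score on the same rows. Because trees are grown to
  purity this is 1.0 for essentially any candidate on conflict-free data —
  the fitness curve saturates in the first epoch and the search degenerates
  to random selection among perfect-scoring candidates. The mode exists
  because it reproduces that first-epoch-saturation behaviour faithfully;
  it should not be used for actual feature selection.

Fitness is deterministic given the decoded candidate and the fold seed, so
evaluations are memoized per decoded configuration (distinct positions
frequently decode identically once the swarm concentrates).

The fold's test rows are structurally unreachable during optimization:
`optimize_fold` receives only the training subset. After the search, a
fresh forest with the selected features and hyperparameters is re-fitted on
the full training portion and scored once on the held-out test rows.

## Consolidation

A feature is retained iff it appears in strictly more than K/2 fold
selections — a feature chosen in exactly half the folds is excluded.
Hyperparameters are consolidated as arithmetic means with integer fields
rounded half-up (mean group minima of 3.5 consolidate to 4); group bounds
are swapped if rounding inverts them. The consolidated configuration is
re-fitted per fold on that fold's training rows and evaluated on its test
rows; it is never fitted on pooled train+test data, preserving the leakage
guard.

## Metrics

Positive class is label 1 throughout. Ratio metrics with empty denominators
are reported as 0 with an `undefined` flag instead of being dropped, so fold
tables stay rectangular. The ROC curve comes from a threshold sweep over
unique scores and AUC from trapezoidal integration, which equals the
Mann–Whitney U statistic with 0.5 credit for ties. The fold-average AUC is
the mean of per-fold AUCs (not a pooled-prediction AUC).

## Shapley attributions

Because the trees split on rotated features, tree-path attribution does not
apply in the original feature space; attributions are estimated
model-agnostically by permutation sampling: for each sampled (ordering,
background row) pair, features are switched one at a time from the
background row's values to the explained row's values and credited with the
change in positive-class probability. The estimate converges to the Shapley
value, and the per-sample credits telescope, giving the efficiency property
`base_value + Σ_j φ_j ≈ f(x)` up to Monte Carlo error (exact under full
permutation enumeration, which is available for small p). The explained
quantity is the positive-class probability; the background set is the
training rows of the explained fold. The global ranking orders features by
mean absolute attribution (ties by index); signed means are also exposed
because clinical readers often want direction as well as magnitude.

## Synthetic generator

`generate_synthetic` emulates the reference table's shape: n = 319 rows,
p = 38 unit-variance Gaussian features, labels Bernoulli(class_balance)
with both classes guaranteed. The first `n_informative` features receive a
class-1 mean shift of `effect_size` (in noise-SD units); remaining features
are pure noise, optionally organised into consecutive blocks of
`block_size` sharing pairwise correlation `block_corr` through a latent
factor (x = √ρ·z + √(1−ρ)·ε, giving corr = ρ exactly in expectation).
Defaults: 5 informative features at effect size 1.5 — strong but not
trivial univariate signal (per-feature AUC ≈ 0.86), comparable to the
discriminative strength of the dominant markers in the reference data.

What the generator does *not* emulate: heteroscedastic or skewed laboratory
distributions, mixed discrete/continuous features, interactions without
main effects, label noise, and correlation between informative features.
Passing recovery tests therefore show that the wrapper finds additive
Gaussian mean-shift signal at realistic n/p — not that it handles every
clinical data pathology.

## Study sizes and numerical choices

- Recovery/efficiency study: 10 seeds, one optimized fold per seed, BES at
  N = 15, T = 20, `n_estimators` bounds narrowed to [8, 16] — a handful of
  planted additive features does not need 100+ trees, and with the
  3-split-averaged fitness small ensembles keep the wrapper search quick
  without the saturation problems a single noisy holdout would cause. The
  consolidated configuration is then scored over 10 folds against an
  all-features baseline of the same ensemble size.
- The acceptance script runs the same study at 5 seeds.
- Orthogonality tolerance 1e−8 (matrix max-norm); PCA uses `eigh` on the
  sample covariance (ddof = 1).
- Degenerate inputs: single-class training data is rejected; candidates
  whose selected columns are all constant receive fitness 0; an empty
  consolidated feature set is reported as empty, never padded.

## Known limitations

- Fold test parts overlap across folds, so fold-metric variance
  understates sampling variance.
- The `train` fitness mode is deliberately degenerate (see above).
- The wrapper search maximises a noisy holdout estimate; with strongly
  separable data the fitness can still saturate, after which feature
  selection among perfect-scoring candidates is arbitrary. Recovery is
  therefore probabilistic, which is why the validation study is run over
  seeds and thresholds are stated as seed fractions.
- Wall-clock timings in the fold tables are informational only.
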