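"""Wrapper feature selection and hyperparameter tuning for the rotation forest.

A BES position in [0,1]^(p+4) encodes a candidate configuration: the first p
coordinates are a feature mask (thresholded at 0.5), the last four map
affinely onto the hyperparameter bounds (ensemble size, group-size bounds and
the PCA instance-removal proportion).  Each cross-validation fold is optimized
independently, with F1 on the fold's *training* portion as the fitness — the
fold's test rows are never passed to the optimizer.

Two fitness modes exist.  ``inner_holdout`` (default) splits the fold's
training portion 80/20 and scores F1 on the inner 20%, so the search sees
generalisation.  ``train`` scores F1 on the same rows the forest was fitted
on; because trees are grown to purity, this is 1.0 from the first epoch on
conflict-free data and makes the search degenerate — it exists to replicate
that training-set-fitness behaviour faithfully.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from .bes import BESConfig, optimize
from .datasets import Dataset, FoldSpec
from .metrics import (MetricsRecord, classification_metrics, confusion,
                      f1_score, roc_auc)
from .rotation_forest import RoFHyperparams, fit_rof

__all__ = [
    "SearchSpace",
    "CandidateConfig",
    "FoldOptimizationResult",
    "decode_position",
    "fold_fitness",
    "optimize_fold",
    "evaluate_fold",
    "run_experiment",
    "run_baseline",
]


@dataclass(frozen=True)
class SearchSpace:
    """Encoding of the (feature mask | hyperparameters) search box.

    Dimension is p + 4.  Default hyperparameter bounds cover ensembles of
    100–150 trees, group-size bounds 2–5 / 5–8 and removal proportions
    0.40–0.51.
    """

    p: int
    mask_threshold: float = 0.5
    n_estimators_bounds: tuple[int, int] = (100, 150)
    min_group_bounds: tuple[int, int] = (2, 5)
    max_group_bounds: tuple[int, int] = (5, 8)
    remove_proportion_bounds: tuple[float, float] = (0.40, 0.51)

    @property
    def dimension(self) -> int:
        return self.p + 4

    def __post_init__(self) -> None:
        for lo, hi in (self.n_estimators_bounds, self.min_group_bounds,
                       self.max_group_bounds, self.remove_proportion_bounds):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError("hyperparameter bounds must be finite with lo <= hi")


@dataclass(frozen=True)
class CandidateConfig:
    """A decoded BES position: selected features plus hyperparameters."""

    feature_indices: tuple[int, ...]
    hyperparams: RoFHyperparams

    def __post_init__(self) -> None:
        if len(self.feature_indices) == 0:
            raise ValueError("candidate must select at least one feature")


@dataclass
class FoldOptimizationResult:
    fold_id: int
    selected_features: list[int]
    hyperparams: RoFHyperparams
    fitness_history: list[float]
    best_fitness: float


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _affine(u: float, lo: float, hi: float) -> float:
    return lo + u * (hi - lo)


def decode_position(position: np.ndarray, space: SearchSpace) -> CandidateConfig:
    """Decode a [0,1]^(p+4) position into features + hyperparameters.

    Mask coordinates >= threshold select their feature; an all-off mask falls
    back to the single largest coordinate (lowest index on ties).  Integer
    hyperparameters are rounded half-up; inverted group bounds are swapped.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dimension,):
        raise ValueError(f"expected position of length {space.dimension}")
    mask = position[: space.p]
    selected = np.flatnonzero(mask >= space.mask_threshold)
    if selected.size == 0:
        selected = np.array([int(np.argmax(mask))])

    u_est, u_min, u_max, u_rm = position[space.p :]
    n_estimators = _round_half_up(_affine(u_est, *space.n_estimators_bounds))
    min_group = _round_half_up(_affine(u_min, *space.min_group_bounds))
    max_group = _round_half_up(_affine(u_max, *space.max_group_bounds))
    remove_proportion = _affine(u_rm, *space.remove_proportion_bounds)
    if min_group > max_group:
        min_group, max_group = max_group, min_group
    # group bounds wider than a narrow feature subset are clamped at fit time

    hp = RoFHyperparams(
        n_estimators=n_estimators,
        min_group=min_group,
        max_group=max_group,
        remove_proportion=remove_proportion,
    )
    return CandidateConfig(feature_indices=tuple(int(i) for i in selected),
                           hyperparams=hp)


def _inner_split(train: Dataset, seed: int, holdout_fraction: float = 0.2
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified inner split of the fold's training rows (fit / score)."""
    rng = np.random.default_rng(seed)
    n = train.n
    holdout: list[np.ndarray] = []
    for c in np.unique(train.y):
        members = rng.permutation(np.flatnonzero(train.y == c))
        k = max(1, int(math.floor(holdout_fraction * len(members))))
        holdout.append(members[:k])
    score_idx = np.sort(np.concatenate(holdout))
    fit_idx = np.setdiff1d(np.arange(n), score_idx)
    return fit_idx, score_idx


def fold_fitness(
    candidate: CandidateConfig,
    fold_train: Dataset,
    mode: str = "inner_holdout",
    seed: int = 0,
    n_inner_splits: int = 3,
) -> float:
    """F1 fitness of a candidate configuration on a fold's training portion.

    ``inner_holdout``: fit the forest on a stratified 80% of the training
    rows (features restricted to the candidate's subset) and score F1 on the
    remaining 20%, averaged over ``n_inner_splits`` independent splits — a
    single small holdout is noisy enough for lucky candidates to saturate it,
    which would stall the search.  ``train``: fit and score on the same rows.
    Candidates whose selected columns are all constant score 0.
    """
    sub = fold_train.subset_features(list(candidate.feature_indices))
    if np.allclose(sub.X.var(axis=0), 0.0):
        return 0.0
    if mode == "train":
        model = fit_rof(sub, candidate.hyperparams, seed=seed)
        return f1_score(sub.y, model.predict(sub.X))
    if mode != "inner_holdout":
        raise ValueError(f"unknown fitness mode {mode!r}")
    scores = []
    for j in range(n_inner_splits):
        fit_idx, score_idx = _inner_split(sub, seed + 104729 * j)
        fit_part = sub.subset_rows(fit_idx)
        model = fit_rof(fit_part, candidate.hyperparams, seed=seed + j)
        scores.append(f1_score(sub.y[score_idx], model.predict(sub.X[score_idx])))
    return float(np.mean(scores))


def optimize_fold(
    fold_train: Dataset,
    space: SearchSpace | None = None,
    bes_config: BESConfig | None = None,
    seed: int = 0,
    mode: str = "inner_holdout",
    fold_id: int = 0,
    n_inner_splits: int = 3,
) -> FoldOptimizationResult:
    """Run BES over the (mask | hyperparameter) box for one fold.

    Only the fold's training Dataset is accepted, so the held-out test rows
    are structurally unreachable during the search.
    """
    if space is None:
        space = SearchSpace(p=fold_train.p)
    if bes_config is None:
        bes_config = BESConfig(seed=seed)
    elif bes_config.seed != seed:
        bes_config = BESConfig(
            population=bes_config.population, epochs=bes_config.epochs,
            alpha=bes_config.alpha, c1=bes_config.c1, c2=bes_config.c2,
            seed=seed, maximize=True,
        )

    # fitness depends only on the decoded discrete candidate (and the fixed
    # seed), and distinct positions often decode identically, so memoize
    cache: dict[tuple, float] = {}

    def fitness(position: np.ndarray) -> float:
        cand = decode_position(position, space)
        key = (cand.feature_indices, cand.hyperparams.n_estimators,
               cand.hyperparams.min_group, cand.hyperparams.max_group,
               round(cand.hyperparams.remove_proportion, 12))
        if key not in cache:
            cache[key] = fold_fitness(cand, fold_train, mode=mode, seed=seed,
                                      n_inner_splits=n_inner_splits)
        return cache[key]

    best_pos, best_fit, history = optimize(fitness, space.dimension, bes_config)
    best = decode_position(best_pos, space)
    return FoldOptimizationResult(
        fold_id=fold_id,
        selected_features=sorted(best.feature_indices),
        hyperparams=best.hyperparams,
        fitness_history=history,
        best_fitness=float(best_fit),
    )


def evaluate_fold(
    data: Dataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    feature_indices: list[int] | None,
    hp: RoFHyperparams,
    seed: int = 0,
) -> tuple[MetricsRecord, MetricsRecord]:
    """Fit on the fold's train rows, score train and test; returns records.

    ``feature_indices=None`` uses all features.  The test record carries the
    fold AUC from the positive-class score.
    """
    if feature_indices is not None:
        data = data.subset_features(feature_indices)
    train = data.subset_rows(train_idx)
    t0 = time.perf_counter()
    model = fit_rof(train, hp, seed=seed)
    train_time = time.perf_counter() - t0

    train_rec = classification_metrics(confusion(train.y, model.predict(train.X)))
    train_rec.train_time = train_time

    X_test, y_test = data.X[test_idx], data.y[test_idx]
    t0 = time.perf_counter()
    y_pred = model.predict(X_test)
    test_time = time.perf_counter() - t0
    cm = confusion(y_test, y_pred)
    test_rec = classification_metrics(cm)
    test_rec.test_time = test_time
    test_rec.cm = cm
    _, auc = roc_auc(y_test, model.predict_proba(X_test)[:, 1])
    test_rec.auc = auc
    return train_rec, test_rec


@dataclass
class ExperimentResult:
    """Per-fold optimization results and train/test metric records."""

    fold_results: list[FoldOptimizationResult]
    train_records: list[MetricsRecord]
    test_records: list[MetricsRecord]


def run_experiment(
    data: Dataset,
    foldspec: FoldSpec,
    space: SearchSpace | None = None,
    bes_config: BESConfig | None = None,
    mode: str = "inner_holdout",
    seed: int = 0,
) -> ExperimentResult:
    """Optimize every fold, refit with its best configuration, score the test.

    Per fold: BES wrapper search on the training rows only, then a fresh
    rotation forest with the selected features and hyperparameters is fitted
    on the full training portion and evaluated once on the held-out test rows.
    Per-fold seeds are ``seed + fold_id``.
    """
    if space is None:
        space = SearchSpace(p=data.p)
    fold_results: list[FoldOptimizationResult] = []
    train_records: list[MetricsRecord] = []
    test_records: list[MetricsRecord] = []
    for fold_id, (train_idx, test_idx) in enumerate(foldspec.folds):
        fold_seed = seed + fold_id
        try:
            result = optimize_fold(
                data.subset_rows(train_idx), space=space, bes_config=bes_config,
                seed=fold_seed, mode=mode, fold_id=fold_id,
            )
            train_rec, test_rec = evaluate_fold(
                data, train_idx, test_idx, result.selected_features,
                result.hyperparams, seed=fold_seed,
            )
        except Exception as exc:  # noqa: BLE001 - annotate failing fold
            raise RuntimeError(f"fold {fold_id} failed: {exc}") from exc
        fold_results.append(result)
        train_records.append(train_rec)
        test_records.append(test_rec)
    return ExperimentResult(fold_results, train_records, test_records)


def run_baseline(
    data: Dataset,
    foldspec: FoldSpec,
    hp: RoFHyperparams | None = None,
    seed: int = 0,
) -> tuple[list[MetricsRecord], list[MetricsRecord]]:
    """Unoptimized rotation forest on all features, every fold (baseline)."""
    if hp is None:
        hp = RoFHyperparams()
    train_records, test_records = [], []
    for fold_id, (train_idx, test_idx) in enumerate(foldspec.folds):
        train_rec, test_rec = evaluate_fold(
            data, train_idx, test_idx, None, hp, seed=seed + fold_id,
        )
        train_records.append(train_rec)
        test_records.append(test_rec)
    return train_records, test_records
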