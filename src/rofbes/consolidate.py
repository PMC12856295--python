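"""Final-model construction from per-fold optimization results.

A feature is retained only if it was selected in strictly more than half of
the folds (majority voting); hyperparameters are consolidated as arithmetic
means, with integer fields rounded half-up and the group bounds swapped if
rounding inverts them.  The consolidated configuration is then re-fitted per
fold on that fold's training rows and scored once on its untouched test rows.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .datasets import Dataset, FoldSpec
from .metrics import MetricsRecord, aggregate_folds
from .pipeline import evaluate_fold
from .rotation_forest import RoFHyperparams

__all__ = [
    "ConsolidatedConfig",
    "vote_features",
    "mean_hyperparams",
    "consolidate_folds",
    "evaluate_final",
]


@dataclass
class ConsolidatedConfig:
    """Majority-voted feature list plus averaged hyperparameters."""

    features: list[int]
    hyperparams: RoFHyperparams
    vote_counts: dict[int, int]
    source_folds: int

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "features": self.features,
            **self.hyperparams.as_dict(),
            "vote_counts": {str(k): v for k, v in sorted(self.vote_counts.items())},
            "source_folds": self.source_folds,
        }
        text = json.dumps(obj)
        if path is not None:
            Path(path).write_text(text)
        return text


def vote_features(
    fold_feature_sets: Sequence[Iterable[int]],
) -> tuple[list[int], dict[int, int]]:
    """Retain feature i iff it appears in strictly more than K/2 fold sets.

    A feature in exactly half the folds is excluded.  Returns the sorted
    retained list and the full per-feature vote counts.  An empty retained
    set is reported as empty, never padded.
    """
    k = len(fold_feature_sets)
    if k < 1:
        raise ValueError("need at least one fold feature set")
    counts: Counter[int] = Counter()
    for s in fold_feature_sets:
        uniq = set(int(i) for i in s)
        if any(i < 0 for i in uniq):
            raise ValueError("feature indices must be non-negative")
        counts.update(uniq)
    retained = sorted(i for i, c in counts.items() if c > k / 2)
    return retained, dict(sorted(counts.items()))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mean_hyperparams(fold_hparams: Sequence[RoFHyperparams]) -> RoFHyperparams:
    """Arithmetic mean per field; integer fields rounded half-up.

    remove_proportion keeps full precision.  If rounding inverts the group
    bounds, they are swapped.  Permutation-invariant in the input list.
    """
    if not fold_hparams:
        raise ValueError("need at least one hyperparameter set")
    k = len(fold_hparams)
    n_estimators = _round_half_up(sum(h.n_estimators for h in fold_hparams) / k)
    min_group = _round_half_up(sum(h.min_group for h in fold_hparams) / k)
    max_group = _round_half_up(sum(h.max_group for h in fold_hparams) / k)
    remove_proportion = sum(h.remove_proportion for h in fold_hparams) / k
    if min_group > max_group:
        min_group, max_group = max_group, min_group
    return RoFHyperparams(
        n_estimators=n_estimators, min_group=min_group, max_group=max_group,
        remove_proportion=remove_proportion,
    )


def consolidate_folds(
    fold_feature_sets: Sequence[Iterable[int]],
    fold_hparams: Sequence[RoFHyperparams],
) -> ConsolidatedConfig:
    """Vote features and average hyperparameters across folds."""
    if len(fold_feature_sets) != len(fold_hparams):
        raise ValueError("feature sets and hyperparameter lists must align")
    features, vote_counts = vote_features(fold_feature_sets)
    hp = mean_hyperparams(fold_hparams)
    return ConsolidatedConfig(
        features=features, hyperparams=hp, vote_counts=vote_counts,
        source_folds=len(fold_feature_sets),
    )


def evaluate_final(
    data: Dataset,
    foldspec: FoldSpec,
    consolidated: ConsolidatedConfig,
    seed: int = 0,
) -> tuple[list[MetricsRecord], list[MetricsRecord], MetricsRecord]:
    """Score the consolidated configuration on every fold.

    Per fold the forest is re-fitted on the fold's training rows restricted to
    the voted features and evaluated on the fold's test rows; returns the
    per-fold train records, test records and the test average.
    """
    if consolidated.features and max(consolidated.features) >= data.p:
        raise ValueError("consolidated features exceed dataset width")
    features = consolidated.features if consolidated.features else None
    if features is None:
        raise ValueError("consolidated feature set is empty")
    train_records, test_records = [], []
    for fold_id, (train_idx, test_idx) in enumerate(foldspec.folds):
        train_rec, test_rec = evaluate_fold(
            data, train_idx, test_idx, features, consolidated.hyperparams,
            seed=seed + fold_id,
        )
        train_records.append(train_rec)
        test_records.append(test_rec)
    return train_records, test_records, aggregate_folds(test_records)
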