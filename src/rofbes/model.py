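"""Model/Results facade for the optimized rotation-forest workflow.

:class:`BESRotationForest` is constructed from data (array pair, DataFrame or
CSV); its :meth:`~BESRotationForest.fit` runs the full study design — repeated
random-subsampling folds, an unoptimized all-features baseline, per-fold BES
wrapper optimization, majority-vote consolidation and the final per-fold
evaluation — and returns a :class:`BESRotationForestResults` carrying the
estimates, per-fold diagnostics and a ``summary()`` table.  Attribution and
plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bes import BESConfig
from .consolidate import ConsolidatedConfig, consolidate_folds, evaluate_final
from .datasets import Dataset, FoldSpec, make_folds, read_tabular
from .explain import AttributionMatrix, importance_ranking, shap_values
from .metrics import MetricsRecord, aggregate_folds
from .pipeline import (ExperimentResult, SearchSpace, run_baseline,
                       run_experiment)
from .rotation_forest import RoFHyperparams, RoFModel, fit_rof

__all__ = ["BESRotationForest", "BESRotationForestResults", "fold_table"]


def fold_table(train_records: list[MetricsRecord],
               test_records: list[MetricsRecord]) -> pd.DataFrame:
    """Fold-wise metric table (percentages), one row per (fold, split)."""
    rows = []
    for split, records in (("train", train_records), ("test", test_records)):
        for fold, r in enumerate(records, start=1):
            rows.append({
                "fold": fold, "split": split,
                "acc": 100 * r.accuracy, "f1": 100 * r.f1,
                "precision": 100 * r.precision, "recall": 100 * r.recall,
                "auc": r.auc,
                "time": r.train_time if split == "train" else r.test_time,
            })
    return pd.DataFrame(rows)


class BESRotationForest:
    """Rotation forest with BES wrapper optimization, fitted to one dataset."""

    def __init__(self, data: Dataset) -> None:
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str) -> "BESRotationForest":
        y_raw = df[label_column]
        distinct = sorted(pd.unique(y_raw), key=lambda v: (str(type(v)), v))
        if len(distinct) != 2:
            raise ValueError("label column must have exactly 2 distinct values")
        y = y_raw.map({distinct[0]: 0, distinct[1]: 1}).to_numpy(dtype=int)
        features = df.drop(columns=[label_column])
        return cls(Dataset(
            X=features.to_numpy(dtype=float), y=y,
            feature_names=[str(c) for c in features.columns],
            provenance="dataframe",
        ))

    @classmethod
    def from_csv(cls, path, label_column: str) -> "BESRotationForest":
        return cls(read_tabular(path, label_column))

    def fit(
        self,
        k: int = 10,
        train_fraction: float = 0.7,
        seed: int = 0,
        space: SearchSpace | None = None,
        bes_config: BESConfig | None = None,
        mode: str = "inner_holdout",
        baseline_hp: RoFHyperparams | None = None,
        foldspec: FoldSpec | None = None,
    ) -> "BESRotationForestResults":
        """Run the baseline, per-fold optimization and consolidation."""
        data = self.data
        if foldspec is None:
            foldspec = make_folds(data.n, k=k, train_fraction=train_fraction,
                                  seed=seed)
        if space is None:
            space = SearchSpace(p=data.p)
        if baseline_hp is None:
            baseline_hp = RoFHyperparams()

        baseline_train, baseline_test = run_baseline(
            data, foldspec, hp=baseline_hp, seed=seed)
        experiment = run_experiment(
            data, foldspec, space=space, bes_config=bes_config, mode=mode,
            seed=seed)
        consolidated = consolidate_folds(
            [r.selected_features for r in experiment.fold_results],
            [r.hyperparams for r in experiment.fold_results],
        )
        final_train, final_test, final_avg = evaluate_final(
            data, foldspec, consolidated, seed=seed)

        return BESRotationForestResults(
            model=self, foldspec=foldspec, space=space, seed=seed, mode=mode,
            baseline_train=baseline_train, baseline_test=baseline_test,
            experiment=experiment, consolidated=consolidated,
            final_train=final_train, final_test=final_test,
            final_average=final_avg,
        )


@dataclass
class BESRotationForestResults:
    """Estimates and diagnostics of a fitted :class:`BESRotationForest`."""

    model: BESRotationForest
    foldspec: FoldSpec
    space: SearchSpace
    seed: int
    mode: str
    baseline_train: list[MetricsRecord]
    baseline_test: list[MetricsRecord]
    experiment: ExperimentResult
    consolidated: ConsolidatedConfig
    final_train: list[MetricsRecord]
    final_test: list[MetricsRecord]
    final_average: MetricsRecord

    # -- tables ---------------------------------------------------------

    def baseline_table(self) -> pd.DataFrame:
        return fold_table(self.baseline_train, self.baseline_test)

    def optimized_table(self) -> pd.DataFrame:
        return fold_table(self.experiment.train_records,
                          self.experiment.test_records)

    def final_table(self) -> pd.DataFrame:
        return fold_table(self.final_train, self.final_test)

    def selected_feature_names(self) -> list[str]:
        names = self.model.data.feature_names
        return [names[i] for i in self.consolidated.features]

    def summary(self) -> str:
        """Plain-text overview in the style of a model-results summary."""
        base = aggregate_folds(self.baseline_test)
        final = self.final_average
        hp = self.consolidated.hyperparams
        data = self.model.data
        lines = [
            "BES-optimized Rotation Forest results",
            "=" * 54,
            f"data: n={data.n}, p={data.p}  ({data.provenance})",
            f"folds: {self.foldspec.k} x "
            f"{self.foldspec.train_fraction:.0%} train (seed={self.seed}, "
            f"fitness mode={self.mode})",
            "-" * 54,
            "baseline (all features)      optimized + consolidated",
            f"  accuracy  {100 * base.accuracy:7.3f} %        "
            f"accuracy  {100 * final.accuracy:7.3f} %",
            f"  F1        {100 * base.f1:7.3f} %        "
            f"F1        {100 * final.f1:7.3f} %",
            f"  precision {100 * base.precision:7.3f} %        "
            f"precision {100 * final.precision:7.3f} %",
            f"  recall    {100 * base.recall:7.3f} %        "
            f"recall    {100 * final.recall:7.3f} %",
        ]
        if base.auc is not None and final.auc is not None:
            lines.append(
                f"  AUC       {base.auc:7.3f}          "
                f"AUC       {final.auc:7.3f}"
            )
        lines += [
            "-" * 54,
            f"consolidated features ({len(self.consolidated.features)} of "
            f"{data.p}, vote > {self.consolidated.source_folds / 2:.0f}"
            f"/{self.consolidated.source_folds}):",
            "  " + ", ".join(self.selected_feature_names()),
            f"consolidated hyperparameters: n_estimators={hp.n_estimators}, "
            f"min_group={hp.min_group}, max_group={hp.max_group}, "
            f"remove_proportion={hp.remove_proportion:.3f}",
            "=" * 54,
        ]
        return "\n".join(lines)

    # -- final model + attribution ---------------------------------------

    def fit_final_model(self, fold: int = 0) -> tuple[RoFModel, Dataset, Dataset]:
        """Re-fit the consolidated configuration on one fold's training rows.

        Returns (model, train subset, test subset), both restricted to the
        consolidated features.
        """
        data = self.model.data.subset_features(self.consolidated.features)
        train_idx, test_idx = self.foldspec.folds[fold]
        train = data.subset_rows(train_idx)
        test = data.subset_rows(test_idx)
        model = fit_rof(train, self.consolidated.hyperparams,
                        seed=self.seed + fold)
        return model, train, test

    def explain(
        self,
        fold: int = 0,
        n_explain: int = 20,
        n_samples: int = 64,
        seed: int | None = None,
    ) -> tuple[AttributionMatrix, list[tuple[str, float]]]:
        """Shapley attributions for the final model on one fold's test rows.

        The background set is the fold's training rows (the data the model
        saw); returns the attribution matrix and the global importance
        ranking over the consolidated features.
        """
        if seed is None:
            seed = self.seed
        model, train, test = self.fit_final_model(fold)
        X_explain = test.X[:n_explain]
        attr = shap_values(model, X_explain, train.X, n_samples=n_samples,
                           seed=seed)
        ranking = importance_ranking(attr, train.feature_names)
        return attr, ranking
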