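"""Synthetic validation studies for the optimized rotation-forest workflow.

These run the whole method on generated data with known ground truth: a
planted-feature recovery study (does the wrapper search find the informative
features?) and a consolidation-efficiency comparison (does the majority-voted
feature subset match the all-features baseline's test accuracy?).
"""

from __future__ import annotations

from dataclasses import dataclass

from .bes import BESConfig
from .consolidate import consolidate_folds, evaluate_final
from .datasets import SyntheticConfig, generate_synthetic, make_folds
from .metrics import aggregate_folds
from .pipeline import FoldOptimizationResult, SearchSpace, optimize_fold, run_baseline
from .rotation_forest import RoFHyperparams

__all__ = ["RecoveryStudy", "run_recovery_study"]

# Ensemble sizes for the synthetic studies: recovery of a handful of planted
# features does not need the large ensembles used on real data, and small
# forests keep the wrapper search quick.
RECOVERY_N_ESTIMATORS_BOUNDS = (8, 16)


@dataclass
class RecoveryStudy:
    """Outcome of the planted-feature recovery + efficiency study."""

    per_seed_hits: list[int]            # informative features recovered per seed
    n_informative: int
    seeds_with_good_recovery: int       # seeds recovering >= n_informative - 1
    fold_results: list[FoldOptimizationResult]
    consolidated_features: list[int]
    consolidated_accuracy: float        # mean test accuracy, consolidated model
    baseline_accuracy: float            # mean test accuracy, all features
    consolidated_n_features: int
    p: int


def run_recovery_study(
    n_seeds: int = 10,
    base_seed: int = 0,
    synth: SyntheticConfig | None = None,
    bes_config: BESConfig | None = None,
    n_estimators_bounds: tuple[int, int] = RECOVERY_N_ESTIMATORS_BOUNDS,
    eval_folds: int = 10,
) -> RecoveryStudy:
    """Planted-feature recovery across seeds, then consolidation efficiency.

    For each seed s (base_seed + s), a synthetic dataset with planted
    informative features is generated, one 70/30 fold is drawn, and the BES
    wrapper optimizes that fold's training portion (inner-holdout fitness).
    The per-seed results are consolidated by majority vote and the
    consolidated configuration is scored over ``eval_folds`` folds of the
    base-seed dataset against an all-features baseline of comparable ensemble
    size.
    """
    if synth is None:
        synth = SyntheticConfig(n=319, p=38, n_informative=5, effect_size=2.0)
    if bes_config is None:
        bes_config = BESConfig(population=15, epochs=20)

    per_seed_hits: list[int] = []
    fold_results: list[FoldOptimizationResult] = []
    for s in range(n_seeds):
        seed = base_seed + s
        cfg = SyntheticConfig(
            n=synth.n, p=synth.p, n_informative=synth.n_informative,
            effect_size=synth.effect_size, block_corr=synth.block_corr,
            block_size=synth.block_size, class_balance=synth.class_balance,
            seed=seed,
        )
        data, informative = generate_synthetic(cfg)
        spec = make_folds(data.n, k=1, train_fraction=0.7, seed=seed)
        train = data.subset_rows(spec.folds[0][0])
        space = SearchSpace(p=data.p, n_estimators_bounds=n_estimators_bounds)
        result = optimize_fold(train, space=space, bes_config=bes_config,
                               seed=seed, mode="inner_holdout", fold_id=s)
        fold_results.append(result)
        per_seed_hits.append(
            len(set(result.selected_features) & set(informative)))

    consolidated = consolidate_folds(
        [r.selected_features for r in fold_results],
        [r.hyperparams for r in fold_results],
    )

    eval_cfg = SyntheticConfig(
        n=synth.n, p=synth.p, n_informative=synth.n_informative,
        effect_size=synth.effect_size, block_corr=synth.block_corr,
        block_size=synth.block_size, class_balance=synth.class_balance,
        seed=base_seed,
    )
    eval_data, _ = generate_synthetic(eval_cfg)
    eval_spec = make_folds(eval_data.n, k=eval_folds, train_fraction=0.7,
                           seed=base_seed)
    _, _, final_avg = evaluate_final(eval_data, eval_spec, consolidated,
                                     seed=base_seed)
    baseline_hp = RoFHyperparams(
        n_estimators=consolidated.hyperparams.n_estimators,
        min_group=consolidated.hyperparams.min_group,
        max_group=consolidated.hyperparams.max_group,
        remove_proportion=consolidated.hyperparams.remove_proportion,
    )
    _, baseline_test = run_baseline(eval_data, eval_spec, hp=baseline_hp,
                                    seed=base_seed)
    baseline_avg = aggregate_folds(baseline_test)

    good = synth.n_informative - 1
    return RecoveryStudy(
        per_seed_hits=per_seed_hits,
        n_informative=synth.n_informative,
        seeds_with_good_recovery=sum(h >= good for h in per_seed_hits),
        fold_results=fold_results,
        consolidated_features=consolidated.features,
        consolidated_accuracy=final_avg.accuracy,
        baseline_accuracy=baseline_avg.accuracy,
        consolidated_n_features=len(consolidated.features),
        p=synth.p,
    )
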