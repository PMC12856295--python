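"""Worked-example inputs: published fold-wise results from a gallstone study.

These constants reproduce the fold-wise outputs reported for a 10-fold
RoF-BES run on the UCI gallstone dataset (319 patients, 38 numeric features,
https://archive.ics.uci.edu/dataset/1150/gallstone-1): the per-fold selected
feature indices and hyperparameters, and the per-fold train/test metrics of
the baseline and optimized classifiers.  They serve as worked examples for
the consolidation and aggregation operations — published numbers in, exact
consolidated configuration and averages out — without needing the external
data download.
"""

from __future__ import annotations

from .rotation_forest import RoFHyperparams

__all__ = [
    "GALLSTONE_FOLD_FEATURES",
    "GALLSTONE_FOLD_HYPERPARAMS",
    "BASELINE_TEST_METRICS",
    "OPTIMIZED_TEST_METRICS",
]

# Fold-wise selected feature indices (0-based) from the published 10-fold run.
GALLSTONE_FOLD_FEATURES: list[tuple[int, ...]] = [
    (4, 8, 9, 15, 16, 17, 18, 20, 22, 26, 28, 29, 31, 33, 34, 35, 36, 37),
    (4, 8, 9, 15, 16, 17, 18, 20, 22, 26, 28, 29, 31, 33, 34, 35, 36, 37),
    (4, 8, 9, 15, 16, 17, 18, 20, 22, 26, 28, 31, 33, 34, 35, 36, 37),
    (4, 8, 9, 15, 16, 17, 18, 20, 22, 26, 28, 31, 33, 34, 35, 36, 37),
    (4, 8, 9, 15, 16, 17, 18, 19, 20, 22, 26, 28, 29, 31, 33, 34, 35, 36, 37),
    (4, 8, 9, 15, 16, 17, 18, 20, 22, 26, 28, 29, 31, 33, 34, 35, 36, 37),
    (4, 8, 9, 15, 16, 17, 18, 20, 22, 26, 28, 31, 33, 34, 35, 36, 37),
    (0, 1, 4, 5, 7, 8, 9, 15, 16, 17, 18, 19, 20, 22, 24, 25, 26, 27, 28, 29,
     30, 31, 32, 33, 34, 35, 36, 37),
    (4, 8, 9, 15, 16, 17, 18, 20, 22, 26, 28, 31, 33, 34, 35, 36, 37),
    (4, 8, 9, 15, 16, 17, 18, 20, 22, 26, 28, 31, 33, 34, 35, 36, 37),
]

# Fold-wise optimized hyperparameters from the same run.
GALLSTONE_FOLD_HYPERPARAMS: list[RoFHyperparams] = [
    RoFHyperparams(133, 4, 7, 0.486892852),
    RoFHyperparams(136, 4, 7, 0.494673715),
    RoFHyperparams(102, 3, 5, 0.484244168),
    RoFHyperparams(102, 3, 5, 0.484244168),
    RoFHyperparams(136, 4, 7, 0.494673715),
    RoFHyperparams(133, 4, 7, 0.486892852),
    RoFHyperparams(100, 3, 5, 0.485670606),
    RoFHyperparams(137, 4, 7, 0.494893893),
    RoFHyperparams(100, 2, 5, 0.419243714),
    RoFHyperparams(101, 4, 5, 0.500765242),
]

# Published per-fold TEST metrics (percent) of the unoptimized baseline:
# columns accuracy, F1, precision, recall.
BASELINE_TEST_METRICS: list[tuple[float, float, float, float]] = [
    (85.263, 84.782, 84.782, 84.782),
    (81.052, 79.069, 75.555, 82.926),
    (78.947, 78.260, 78.260, 78.260),
    (77.894, 77.419, 78.260, 76.595),
    (76.842, 76.595, 83.720, 70.588),
    (75.789, 71.604, 80.555, 64.444),
    (71.578, 69.662, 73.809, 65.957),
    (74.736, 75.0, 78.260, 72.0),
    (74.736, 77.777, 75.0, 80.769),
    (83.157, 83.333, 85.106, 81.632),
]

# Published per-fold TEST metrics (percent) of the optimized classifier.
OPTIMIZED_TEST_METRICS: list[tuple[float, float, float, float]] = [
    (77.894, 76.923, 76.086, 77.777),
    (76.842, 74.418, 78.048, 71.111),
    (72.631, 72.340, 73.913, 70.833),
    (76.842, 77.551, 80.851, 74.509),
    (69.473, 70.707, 68.627, 72.916),
    (74.736, 71.428, 66.666, 76.923),
    (75.789, 74.725, 72.340, 77.272),
    (77.894, 78.350, 76.0, 80.851),
    (75.789, 77.669, 76.923, 78.431),
    (80.0, 80.0, 77.551, 82.608),
]
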