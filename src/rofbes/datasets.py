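"""Tabular data handling: loading, fold construction, synthetic generation.

The fold scheme is repeated random subsampling (Monte Carlo cross-validation):
K independent shuffled train/test partitions of the *whole* dataset, each with
a fixed train fraction.  This is deliberately not rotating k-fold — with
n = 319 and a 70/30 split every fold has 224 training and 95 test rows, sizes
a disjoint-test-block scheme cannot produce.

The synthetic generator emulates the structure of a clinical gallstone-risk
table: n ≈ 319 patients, p ≈ 38 numeric features, a roughly balanced binary
outcome, a small planted set of informative features whose class-conditional
means differ, and optional correlated feature blocks among the noise features.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "FoldSpec",
    "SyntheticConfig",
    "read_tabular",
    "make_folds",
    "generate_synthetic",
]


@dataclass
class Dataset:
    """A numeric feature matrix with binary labels.

    Attributes
    ----------
    X : ndarray of shape (n, p)
        Real-valued features.
    y : ndarray of shape (n,)
        Binary labels in {0, 1}.
    feature_names : list of str
        Ordered column names; feature indices throughout the package are
        0-based positions into this list.
    provenance : str
        Free-text origin tag (file path or generator parameters).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n, p = self.X.shape
        # p == 1 arises for internal single-feature subsets; loaded/generated
        # datasets enforce p >= 2 at their construction sites
        if n < 2 or p < 1:
            raise ValueError(f"need at least 2 rows and 1 feature, got {n}x{p}")
        if len(self.y) != n:
            raise ValueError("X and y length mismatch")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary in {0, 1}")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, indices: Sequence[int]) -> "Dataset":
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            self.X[idx], self.y[idx], list(self.feature_names),
            provenance=f"{self.provenance}[rows]",
        )

    def subset_features(self, indices: Sequence[int]) -> "Dataset":
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            self.X[:, idx],
            self.y,
            [self.feature_names[i] for i in idx],
            provenance=f"{self.provenance}[cols]",
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_column] = self.y
        return df


@dataclass
class FoldSpec:
    """K independent shuffled train/test partitions of {0..n-1}."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    train_fraction: float

    @property
    def k(self) -> int:
        return len(self.folds)

    def validate(self, n: int) -> None:
        for train, test in self.folds:
            combined = np.concatenate([train, test])
            if len(np.unique(combined)) != n or len(combined) != n:
                raise ValueError("fold parts must partition {0..n-1} exactly")

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "seed": self.seed,
            "train_fraction": self.train_fraction,
            "folds": [
                {"train": [int(i) for i in tr], "test": [int(i) for i in te]}
                for tr, te in self.folds
            ],
        }
        text = json.dumps(obj)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FoldSpec":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)
        folds = [
            (np.asarray(f["train"], dtype=int), np.asarray(f["test"], dtype=int))
            for f in obj["folds"]
        ]
        return cls(folds=folds, seed=int(obj["seed"]),
                   train_fraction=float(obj["train_fraction"]))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic clinical-table generator.

    effect_size is the shift of the class-1 mean relative to class 0 on each
    informative feature, in units of the feature's noise standard deviation.
    block_corr is the common pairwise correlation within each declared block
    of (non-informative) features, realised through a shared latent factor.
    """

    n: int = 319
    p: int = 38
    n_informative: int = 5
    effect_size: float = 1.5
    block_corr: float = 0.0
    block_size: int = 4
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.p:
            raise ValueError("n_informative cannot exceed p")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0, 1)")
        if not (0.0 <= self.block_corr < 1.0):
            raise ValueError("block_corr must lie in [0, 1)")
        if self.n < 2 or self.p < 2:
            raise ValueError("need n >= 2 and p >= 2")


def read_tabular(
    path: str | Path,
    label_column: str,
    on_missing: str = "error",
) -> Dataset:
    """Load a CSV (header row, numeric features, binary label column).

    Non-numeric binary labels are mapped to {0, 1} in sorted order of their
    distinct values; the mapping is logged.  Rows with missing entries are
    rejected (``on_missing="error"``) or dropped with a logged count
    (``on_missing="drop"``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in header")

    labels_raw = df[label_column]
    features = df.drop(columns=[label_column])

    missing_mask = features.isna().any(axis=1) | labels_raw.isna()
    if missing_mask.any():
        if on_missing == "drop":
            n_dropped = int(missing_mask.sum())
            logger.info("dropped %d rows with missing values", n_dropped)
            features = features.loc[~missing_mask]
            labels_raw = labels_raw.loc[~missing_mask]
        else:
            rows = list(df.index[missing_mask][:5])
            raise ValueError(
                f"missing values in rows {rows}; pass on_missing='drop' to discard"
            )

    for col in features.columns:
        coerced = pd.to_numeric(features[col], errors="coerce")
        bad = coerced.isna() & features[col].notna()
        if bad.any():
            row = int(features.index[bad][0])
            raise ValueError(
                f"non-numeric value in column {col!r}, row {row}: "
                f"{features[col].loc[row]!r}"
            )
        features[col] = coerced

    distinct = sorted(pd.unique(labels_raw), key=lambda v: (str(type(v)), v))
    if len(distinct) != 2:
        raise ValueError(
            f"label column must have exactly 2 distinct values, got {len(distinct)}"
        )
    mapping = {distinct[0]: 0, distinct[1]: 1}
    if set(distinct) != {0, 1}:
        logger.info("label mapping: %r -> 0, %r -> 1", distinct[0], distinct[1])
    y = labels_raw.map(mapping).to_numpy(dtype=int)

    if features.shape[1] < 2:
        raise ValueError("need at least 2 feature columns besides the label")

    return Dataset(
        X=features.to_numpy(dtype=float),
        y=y,
        feature_names=[str(c) for c in features.columns],
        provenance=str(path),
    )


def make_folds(
    n: int,
    k: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_labels: np.ndarray | None = None,
) -> FoldSpec:
    """Build K independent shuffled 70/30-style partitions.

    Test size is floor((1 - train_fraction) * n); the remaining rows train.
    Each fold uses sub-seed ``seed + fold_index`` so folds are reproducible
    individually.  Optional stratification preserves the overall class mix in
    both parts (off by default: plain shuffling).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    if n < 4:
        raise ValueError("need at least 4 samples")
    n_test = int(math.floor((1.0 - train_fraction) * n))
    n_train = n - n_test
    if n_test == 0 or n_train == 0:
        raise ValueError("train or test part would be empty")

    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for fold_index in range(k):
        rng = np.random.default_rng(seed + fold_index)
        if stratify_labels is None:
            perm = rng.permutation(n)
            test = np.sort(perm[:n_test])
            train = np.sort(perm[n_test:])
        else:
            labels = np.asarray(stratify_labels)
            test_parts = []
            # proportional allocation per class, remainder to the larger class
            classes, counts = np.unique(labels, return_counts=True)
            quota = {c: int(math.floor(n_test * cnt / n)) for c, cnt in zip(classes, counts)}
            leftover = n_test - sum(quota.values())
            for c in classes[np.argsort(-counts)][:leftover]:
                quota[c] += 1
            for c in classes:
                members = np.flatnonzero(labels == c)
                perm = rng.permutation(members)
                test_parts.append(perm[: quota[c]])
            test = np.sort(np.concatenate(test_parts))
            train = np.sort(np.setdiff1d(np.arange(n), test))
            for part, name in ((train, "train"), (test, "test")):
                if len(np.unique(labels[part])) < 2:
                    raise ValueError(f"stratified {name} part lacks both classes")
        folds.append((train, test))

    spec = FoldSpec(folds=folds, seed=seed, train_fraction=train_fraction)
    spec.validate(n)
    return spec


def generate_synthetic(config: SyntheticConfig) -> tuple[Dataset, list[int]]:
    """Simulate a clinical-style numeric table with planted signal features.

    Returns the Dataset together with the ground-truth list of informative
    feature indices (the first ``n_informative`` columns).  Informative
    features are unit-variance Gaussians whose class-1 mean is shifted by
    ``effect_size``; the remaining features are noise, optionally grouped into
    consecutive blocks of ``block_size`` sharing pairwise correlation
    ``block_corr`` via a latent factor (x = sqrt(rho)*z_block +
    sqrt(1-rho)*eps, which gives corr(x_i, x_j) = rho exactly in expectation).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    y = (rng.random(cfg.n) < cfg.class_balance).astype(int)
    # guarantee both classes (invariant of any Dataset used for fitting)
    if y.sum() == 0:
        y[rng.integers(cfg.n)] = 1
    elif y.sum() == cfg.n:
        y[rng.integers(cfg.n)] = 0

    X = rng.standard_normal((cfg.n, cfg.p))
    informative = list(range(cfg.n_informative))
    for j in informative:
        X[:, j] += cfg.effect_size * y

    if cfg.block_corr > 0.0:
        noise_cols = list(range(cfg.n_informative, cfg.p))
        rho = cfg.block_corr
        for start in range(0, len(noise_cols), cfg.block_size):
            block = noise_cols[start : start + cfg.block_size]
            if len(block) < 2:
                continue
            z = rng.standard_normal(cfg.n)
            for j in block:
                X[:, j] = math.sqrt(rho) * z + math.sqrt(1.0 - rho) * rng.standard_normal(cfg.n)

    names = [f"feat_{j}" for j in range(cfg.p)]
    provenance = (
        f"synthetic(n={cfg.n},p={cfg.p},n_informative={cfg.n_informative},"
        f"effect_size={cfg.effect_size},block_corr={cfg.block_corr},"
        f"class_balance={cfg.class_balance},seed={cfg.seed})"
    )
    return Dataset(X=X, y=y, feature_names=names, provenance=provenance), informative
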