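"""Rotation Forest: CART trees on block-wise principal-component rotations.

Each tree in the ensemble sees the training data through its own random
rotation: the p features are split into random disjoint groups, a PCA is
fitted per group on an instance-subsampled copy of the training rows, and the
per-group loading blocks are assembled into a p x p rotation matrix.  All
principal components are retained, so the transform is a rotation of the
feature space, not a reduction.  Trees are grown to purity on the fully
rotated training set and predict by majority vote.

``remove_proportion`` is the fraction of training instances randomly excluded
before fitting each group's principal components (the trees themselves always
train on every row).  The classic random class-subset draw before PCA is not
performed here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .datasets import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "RoFHyperparams",
    "RotationTree",
    "RoFModel",
    "RotationForestClassifier",
    "partition_features",
    "fit_group_rotation",
    "fit_rof",
    "predict",
    "predict_proba",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RoFHyperparams:
    """Ensemble size, feature-group size bounds and PCA instance subsampling."""

    n_estimators: int = 100
    min_group: int = 3
    max_group: int = 3
    remove_proportion: float = 0.25

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not (1 <= self.min_group <= self.max_group):
            raise ValueError("need 1 <= min_group <= max_group")
        if not (0.0 <= self.remove_proportion < 1.0):
            raise ValueError("remove_proportion must lie in [0, 1)")

    def as_dict(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "min_group": self.min_group,
            "max_group": self.max_group,
            "remove_proportion": self.remove_proportion,
        }


def partition_features(
    p: int, min_group: int, max_group: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Split {0..p-1} into random disjoint groups.

    Group sizes are drawn uniformly from [min_group, max_group] until the
    shuffled feature pool is exhausted; at most one final remainder group may
    be smaller than min_group.
    """
    if not (1 <= min_group <= max_group <= p):
        raise ValueError("need 1 <= min_group <= max_group <= p")
    order = rng.permutation(p)
    groups: list[np.ndarray] = []
    start = 0
    while start < p:
        size = int(rng.integers(min_group, max_group + 1))
        groups.append(order[start : start + size])
        start += size
    return groups


def fit_group_rotation(
    X_train: np.ndarray,
    group: Sequence[int],
    remove_proportion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Principal-component loading block for one feature group.

    A uniformly random floor(remove_proportion * n) of the rows is discarded,
    then the loadings (eigenvectors of the sample covariance of the surviving
    rows restricted to the group's columns) are returned with all components
    kept.  Columns are orthonormal; each column's largest-magnitude entry is
    made positive to fix the eigenvector sign.
    """
    group = np.asarray(group, dtype=int)
    n = X_train.shape[0]
    n_remove = int(math.floor(remove_proportion * n))
    if n - n_remove < 2:
        raise ValueError("fewer than 2 rows survive removal")
    keep = rng.permutation(n)[n_remove:]
    sub = X_train[np.sort(keep)][:, group]

    centered = sub - sub.mean(axis=0)
    if not centered.any():
        logger.warning("zero-variance group %s: falling back to identity block", group)
        return np.eye(len(group))

    cov = centered.T @ centered / (sub.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    loadings = eigvecs[:, ::-1]  # descending eigenvalue order
    # sign convention: largest-|entry| of each loading positive
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return loadings


@dataclass
class RotationTree:
    """One ensemble member: feature groups, rotation matrix, fitted tree."""

    groups: list[np.ndarray]
    rotation: np.ndarray
    tree: DecisionTreeClassifier


class RoFModel:
    """A fitted Rotation Forest.

    Attributes
    ----------
    trees : list of RotationTree
    classes : ndarray
        Sorted class labels (binary: [0, 1]).
    hyperparams : RoFHyperparams
    seed : int
    """

    def __init__(
        self,
        trees: list[RotationTree],
        classes: np.ndarray,
        hyperparams: RoFHyperparams,
        seed: int,
        p: int,
    ) -> None:
        self.trees = trees
        self.classes = np.asarray(classes)
        self.hyperparams = hyperparams
        self.seed = seed
        self.p = p

    # -- prediction ---------------------------------------------------------

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.p:
            raise ValueError(f"expected {self.p} columns, got {X.shape}")
        return X

    def tree_votes(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, m) matrix of per-tree hard predictions."""
        X = self._check_width(X)
        return np.stack([
            rt.tree.predict((X @ rt.rotation).astype(np.float32),
                            check_input=False)
            for rt in self.trees
        ])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote across trees; ties go to the lower class label."""
        votes = self.tree_votes(X)
        counts = np.stack(
            [(votes == c).sum(axis=0) for c in self.classes]
        )  # (n_classes, m)
        # argmax over classes returns the first (lowest-label) maximum
        return self.classes[np.argmax(counts, axis=0)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean of per-tree leaf class-frequency estimates; rows sum to 1."""
        X = self._check_width(X)
        proba = np.zeros((X.shape[0], len(self.classes)))
        for rt in self.trees:
            tree_proba = rt.tree.predict_proba(
                (X @ rt.rotation).astype(np.float32), check_input=False)
            # map tree class order onto the model's class order
            for k, c in enumerate(rt.tree.classes_):
                col = int(np.flatnonzero(self.classes == c)[0])
                proba[:, col] += tree_proba[:, k]
        proba /= len(self.trees)
        return proba

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted ensemble (tree arrays + rotations) to JSON."""
        obj = {
            "format": "rofbes-model",
            "version": 1,
            "p": self.p,
            "seed": self.seed,
            "classes": [int(c) for c in self.classes],
            "hyperparams": self.hyperparams.as_dict(),
            "trees": [
                {
                    "groups": [[int(i) for i in g] for g in rt.groups],
                    "rotation": rt.rotation.tolist(),
                    "tree": _tree_to_dict(rt.tree),
                }
                for rt in self.trees
            ],
        }
        text = json.dumps(obj)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RoFModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)
        if obj.get("format") != "rofbes-model":
            raise ValueError("not a serialized rotation-forest model")
        trees = [
            RotationTree(
                groups=[np.asarray(g, dtype=int) for g in t["groups"]],
                rotation=np.asarray(t["rotation"], dtype=float),
                tree=_tree_from_dict(t["tree"]),
            )
            for t in obj["trees"]
        ]
        hp = RoFHyperparams(**obj["hyperparams"])
        return cls(
            trees=trees,
            classes=np.asarray(obj["classes"]),
            hyperparams=hp,
            seed=int(obj["seed"]),
            p=int(obj["p"]),
        )


class _FrozenTree:
    """Deserialized CART tree that predicts by explicit node traversal.

    Reproduces DecisionTreeClassifier.predict / predict_proba bit-for-bit from
    the stored node arrays (children, split feature, threshold, leaf counts).
    """

    def __init__(self, children_left, children_right, feature, threshold,
                 value, classes):
        self.children_left = np.asarray(children_left, dtype=int)
        self.children_right = np.asarray(children_right, dtype=int)
        self.feature = np.asarray(feature, dtype=int)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(value, dtype=float)  # (n_nodes, n_classes)
        self.classes_ = np.asarray(classes)

    def _leaf_indices(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)  # sklearn splits on float32 values
        out = np.zeros(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            node = 0
            while self.children_left[node] != -1:
                if row[self.feature[node]] <= self.threshold[node]:
                    node = self.children_left[node]
                else:
                    node = self.children_right[node]
            out[i] = node
        return out

    def predict_proba(self, X: np.ndarray, check_input: bool = True) -> np.ndarray:
        counts = self.value[self._leaf_indices(X)]
        return counts / counts.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray, check_input: bool = True) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _tree_to_dict(tree: DecisionTreeClassifier | _FrozenTree) -> dict:
    if isinstance(tree, _FrozenTree):
        t = tree
        value = t.value
        return {
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "value": value.tolist(),
            "classes": t.classes_.tolist(),
        }
    t = tree.tree_
    value = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": value.tolist(),
        "classes": [int(c) for c in tree.classes_],
    }


def _tree_from_dict(obj: dict) -> _FrozenTree:
    return _FrozenTree(
        obj["children_left"], obj["children_right"], obj["feature"],
        obj["threshold"], obj["value"], obj["classes"],
    )


def fit_rof(train: Dataset, hp: RoFHyperparams, seed: int = 0) -> RoFModel:
    """Fit a Rotation Forest on a Dataset.

    Every tree draws its own feature partition and per-group PCA rotations
    (fitted on instance-subsampled rows), then a CART tree with Gini impurity
    is grown to purity — no depth limit, no pruning — on the full rotated
    training set.  Deterministic given ``seed``.
    """
    classes = np.unique(train.y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    p = train.p
    if hp.max_group > p:
        hp = RoFHyperparams(
            n_estimators=hp.n_estimators,
            min_group=min(hp.min_group, p),
            max_group=p,
            remove_proportion=hp.remove_proportion,
        )
    rng = np.random.default_rng(seed)
    trees: list[RotationTree] = []
    for t in range(hp.n_estimators):
        groups = partition_features(p, hp.min_group, hp.max_group, rng)
        covered = np.sort(np.concatenate(groups))
        assert np.array_equal(covered, np.arange(p)), "groups must partition features"
        rotation = np.zeros((p, p))
        for group in groups:
            block = fit_group_rotation(train.X, group, hp.remove_proportion, rng)
            rotation[np.ix_(group, group)] = block
        tree = DecisionTreeClassifier(
            criterion="gini", random_state=int(rng.integers(2**31 - 1))
        )
        # sklearn casts inputs to float32 internally; doing it up front and
        # skipping re-validation leaves predictions unchanged but much faster
        tree.fit(np.ascontiguousarray((train.X @ rotation), dtype=np.float32),
                 train.y, check_input=False)
        trees.append(RotationTree(groups=groups, rotation=rotation, tree=tree))
    return RoFModel(trees=trees, classes=classes, hyperparams=hp, seed=seed, p=p)


def predict(model: RoFModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def predict_proba(model: RoFModel, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


class RotationForestClassifier:
    """sklearn-style estimator facade over :func:`fit_rof`.

    Parameters mirror :class:`RoFHyperparams`; ``fit`` accepts plain arrays.
    """

    def __init__(self, n_estimators: int = 100, min_group: int = 3,
                 max_group: int = 3, remove_proportion: float = 0.25,
                 random_state: int = 0) -> None:
        self.n_estimators = n_estimators
        self.min_group = min_group
        self.max_group = max_group
        self.remove_proportion = remove_proportion
        self.random_state = random_state
        self.model_: RoFModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RotationForestClassifier":
        X = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
        train = Dataset(X=X, y=np.asarray(y, dtype=int), feature_names=names,
                        provenance="array")
        hp = RoFHyperparams(
            n_estimators=self.n_estimators, min_group=self.min_group,
            max_group=self.max_group, remove_proportion=self.remove_proportion,
        )
        self.model_ = fit_rof(train, hp, seed=self.random_state)
        return self

    def _fitted(self) -> RoFModel:
        if self.model_ is None:
            raise RuntimeError("call fit first")
        return self.model_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._fitted().predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._fitted().predict_proba(X)
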