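"""Model-agnostic Shapley attributions for the rotation forest.

Because each tree splits on rotated (non-axis-aligned) features, tree-path
attribution methods do not apply in the original feature space; attributions
are therefore estimated by permutation sampling with background imputation:
for a random feature ordering, features are switched one at a time from a
background row's values to the explained row's values, and each feature is
credited with the change in the model's positive-class probability.  Averaged
over orderings and background rows this converges to the Shapley value, and
per sample the credits telescope, which yields the efficiency (local
accuracy) property up to Monte Carlo error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["AttributionMatrix", "shap_values", "importance_ranking"]


@dataclass
class AttributionMatrix:
    """Per-instance, per-feature Shapley estimates for the positive class.

    ``base_value`` is the mean positive-class score over the background set;
    for each explained row, base_value + sum(values[i]) approximates the
    model's score within Monte Carlo tolerance (exactly, under full
    permutation enumeration).
    """

    values: np.ndarray          # (m, p)
    base_value: float
    n_samples: int
    seed: int

    @property
    def signed_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


def _positive_score(model, Z: np.ndarray) -> np.ndarray:
    return model.predict_proba(Z)[:, 1]


def shap_values(
    model,
    X_explain: np.ndarray,
    background: np.ndarray,
    n_samples: int = 64,
    seed: int = 0,
    enumerate_permutations: bool = False,
) -> AttributionMatrix:
    """Estimate Shapley values of the positive-class probability.

    Parameters
    ----------
    model : object with ``predict_proba``
        Typically a fitted :class:`~rofbes.rotation_forest.RoFModel`.
    X_explain : (m, p) array
        Rows to explain.
    background : (b, p) array
        Reference rows used to impute "absent" features.
    n_samples : int
        Monte Carlo budget per explained row (one random permutation and one
        random background row each).
    enumerate_permutations : bool
        Evaluate all p! permutations against every background row instead of
        sampling — exact Shapley values, feasible only for small p.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    m, p = X_explain.shape
    if background.shape[1] != p:
        raise ValueError("background width must match X_explain")
    if background.shape[0] < 1 or n_samples < 1:
        raise ValueError("need at least one background row and one sample")

    rng = np.random.default_rng(seed)
    base_value = float(np.mean(_positive_score(model, background)))

    if enumerate_permutations:
        perms = list(itertools.permutations(range(p)))
        bg_idx = list(range(background.shape[0]))
        draws = [(np.asarray(perm), b) for perm in perms for b in bg_idx]
    else:
        draws = [
            (rng.permutation(p), int(rng.integers(background.shape[0])))
            for _ in range(n_samples)
        ]

    values = np.zeros((m, p))
    n_draws = len(draws)
    chain_len = p + 1
    for i in range(m):
        x = X_explain[i]
        # one big batch: all chains for this row evaluated in a single call
        Z = np.empty((n_draws * chain_len, p))
        for s, (perm, b) in enumerate(draws):
            block = Z[s * chain_len : (s + 1) * chain_len]
            block[:] = background[b]
            for t, j in enumerate(perm):
                block[t + 1 :, j] = x[j]
        scores = _positive_score(model, Z).reshape(n_draws, chain_len)
        deltas = np.diff(scores, axis=1)  # (n_draws, p) in permutation order
        for s, (perm, _) in enumerate(draws):
            values[i, perm] += deltas[s]
    values /= n_draws

    return AttributionMatrix(values=values, base_value=base_value,
                             n_samples=n_draws, seed=seed)


def importance_ranking(
    attr: AttributionMatrix, names: list[str]
) -> list[tuple[str, float]]:
    """Global ranking by mean |attribution|, descending; ties by feature index."""
    if len(names) != attr.values.shape[1]:
        raise ValueError("names length must match attribution width")
    scores = attr.mean_abs
    order = sorted(range(len(names)), key=lambda j: (-scores[j], j))
    return [(names[j], float(scores[j])) for j in order]


def ranking_to_csv(ranking: list[tuple[str, float]], path) -> None:
    """Write (rank, feature, mean_abs_value) rows as CSV."""
    from pathlib import Path

    lines = ["rank,feature,mean_abs_value"]
    lines += [f"{r + 1},{name},{val!r}" for r, (name, val) in enumerate(ranking)]
    Path(path).write_text("\n".join(lines) + "\n")
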