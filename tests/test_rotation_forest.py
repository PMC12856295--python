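"""Rotation-forest internals: grouping, rotations, voting, serialization."""

import numpy as np
import pytest

from rofbes import Dataset, RoFHyperparams, RoFModel, fit_rof
from rofbes.rotation_forest import (_FrozenTree, fit_group_rotation,
                                    partition_features)


def _leaf_tree(class_label: int) -> _FrozenTree:
    """Single-leaf stub tree that always predicts ``class_label``."""
    value = [[1.0, 0.0]] if class_label == 0 else [[0.0, 1.0]]
    return _FrozenTree([-1], [-1], [-2], [-2.0], value, [0, 1])


def _stub_model(leaf_labels: list[int], p: int = 3) -> RoFModel:
    from rofbes.rotation_forest import RotationTree

    trees = [
        RotationTree(groups=[np.arange(p)], rotation=np.eye(p),
                     tree=_leaf_tree(c))
        for c in leaf_labels
    ]
    hp = RoFHyperparams(n_estimators=len(leaf_labels), min_group=p, max_group=p)
    return RoFModel(trees, np.array([0, 1]), hp, seed=0, p=p)


class TestPartitionFeatures:
    def test_degenerate_single_group(self, rng):
        groups = partition_features(6, 6, 6, rng)
        assert len(groups) == 1 and sorted(groups[0]) == list(range(6))

    def test_sizes_within_bounds_over_many_seeds(self):
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            groups = partition_features(10, 2, 3, rng)
            sizes = [len(g) for g in groups]
            assert sum(sizes) == 10
            undersized = [s for s in sizes if s < 2]
            assert all(s in (2, 3) for s in sizes[:-1])
            assert len(undersized) <= 1

    def test_partition_covers_all_indices(self, rng):
        groups = partition_features(38, 4, 6, rng)
        flat = np.concatenate(groups)
        assert sorted(flat) == list(range(38))

    def test_invalid_bounds(self, rng):
        with pytest.raises(ValueError):
            partition_features(5, 3, 2, rng)
        with pytest.raises(ValueError):
            partition_features(5, 1, 6, rng)


class TestGroupRotation:
    def test_correlated_pair_gives_analytic_loadings(self, rng):
        z = rng.standard_normal(500)
        X = np.column_stack([z, z + 1e-6 * rng.standard_normal(500)])
        block = fit_group_rotation(X, [0, 1], 0.0, rng)
        target = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        assert np.allclose(np.abs(block), np.abs(target), atol=1e-3)

    def test_orthonormality(self, rng):
        X = rng.standard_normal((80, 6))
        block = fit_group_rotation(X, [0, 2, 3, 5], 0.0, rng)
        assert np.abs(block.T @ block - np.eye(4)).max() < 1e-8

    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((100, 4))
        block = fit_group_rotation(X, [0, 1, 2, 3], 0.0, np.random.default_rng(0))
        eigvals, eigvecs = np.linalg.eigh(np.cov(X, rowvar=False))
        oracle = eigvecs[:, ::-1]  # descending order
        for j in range(4):
            dot = abs(oracle[:, j] @ block[:, j])
            assert dot == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_falls_back_to_identity(self, rng):
        X = np.ones((30, 3))
        block = fit_group_rotation(X, [0, 1], 0.0, rng)
        np.testing.assert_array_equal(block, np.eye(2))

    def test_subsampling_removes_rows(self, rng):
        X = np.vstack([np.zeros((5, 2)), np.random.default_rng(0).normal(size=(5, 2))])
        with pytest.raises(ValueError):
            fit_group_rotation(X[:2], [0, 1], 0.9, rng)


class TestFitPredict:
    def test_perfect_training_fit(self, small_data):
        data, _ = small_data
        hp = RoFHyperparams(n_estimators=10, min_group=2, max_group=4,
                            remove_proportion=0.3)
        model = fit_rof(data, hp, seed=1)
        assert (model.predict(data.X) == data.y).mean() == 1.0

    def test_single_tree_matches_cart_on_rotated_data(self, small_data):
        from sklearn.tree import DecisionTreeClassifier

        data, _ = small_data
        hp = RoFHyperparams(n_estimators=1, min_group=data.p, max_group=data.p,
                            remove_proportion=0.0)
        model = fit_rof(data, hp, seed=3)
        rt = model.trees[0]
        oracle = DecisionTreeClassifier(
            random_state=rt.tree.random_state
        ).fit((data.X @ rt.rotation).astype(np.float32), data.y)
        probe = data.X[::3]
        np.testing.assert_array_equal(
            model.predict(probe),
            oracle.predict((probe @ rt.rotation).astype(np.float32)),
        )

    def test_seed_determinism(self, small_data):
        data, _ = small_data
        hp = RoFHyperparams(n_estimators=8, min_group=2, max_group=3,
                            remove_proportion=0.4)
        m1 = fit_rof(data, hp, seed=21)
        m2 = fit_rof(data, hp, seed=21)
        probe = data.X[::2] + 0.1
        np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))
        np.testing.assert_array_equal(m1.predict_proba(probe),
                                      m2.predict_proba(probe))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        data = Dataset(X, np.zeros(20, dtype=int) + 1, [f"x{i}" for i in range(4)])
        with pytest.raises(ValueError):
            fit_rof(data, RoFHyperparams(2, 2, 2), seed=0)

    def test_rotation_orthogonality_invariant(self, small_data):
        data, _ = small_data
        hp = RoFHyperparams(n_estimators=6, min_group=2, max_group=4,
                            remove_proportion=0.0)
        model = fit_rof(data, hp, seed=2)
        for rt in model.trees:
            R = rt.rotation
            assert np.abs(R.T @ R - np.eye(data.p)).max() < 1e-8

    def test_groups_partition_on_every_fit(self, small_model, small_data):
        data, _ = small_data
        for rt in small_model.trees:
            flat = np.concatenate(rt.groups)
            assert sorted(flat) == list(range(data.p))


class TestVoting:
    def test_majority_vote(self):
        model = _stub_model([1, 1, 0])
        X = np.zeros((4, 3))
        np.testing.assert_array_equal(model.predict(X), [1, 1, 1, 1])

    def test_tie_breaks_to_lower_label(self):
        model = _stub_model([0, 1])
        X = np.zeros((2, 3))
        np.testing.assert_array_equal(model.predict(X), [0, 0])

    def test_vote_against_brute_force_tally(self, small_model, small_data):
        data, _ = small_data
        probe = data.X[:50]
        votes = small_model.tree_votes(probe)
        expected = []
        for col in votes.T:
            counts = {c: int((col == c).sum()) for c in (0, 1)}
            best = max(sorted(counts), key=lambda c: counts[c])
            expected.append(best)
        np.testing.assert_array_equal(small_model.predict(probe), expected)

    def test_proba_rows_sum_to_one(self, small_model, small_data):
        data, _ = small_data
        proba = small_model.predict_proba(data.X[:30])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_proba_equals_hand_average_on_toy_ensemble(self):
        model = _stub_model([1, 1, 0])
        proba = model.predict_proba(np.zeros((2, 3)))
        np.testing.assert_allclose(proba, [[1 / 3, 2 / 3]] * 2, atol=1e-15)

    def test_proba_argmax_agrees_with_predict(self, small_model, small_data):
        data, _ = small_data
        probe = data.X[:40]
        proba = small_model.predict_proba(probe)
        # argmax with lowest-label tie-break
        agreed = np.where(proba[:, 0] >= proba[:, 1], 0, 1)
        np.testing.assert_array_equal(small_model.predict(probe), agreed)

    def test_width_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.predict(np.zeros((3, 99)))


class TestSerialization:
    def test_round_trip_preserves_predictions(self, small_model, small_data):
        data, _ = small_data
        restored = RoFModel.from_json(small_model.to_json())
        probe = data.X + 0.05
        np.testing.assert_array_equal(small_model.predict(probe),
                                      restored.predict(probe))
        np.testing.assert_array_equal(small_model.predict_proba(probe),
                                      restored.predict_proba(probe))

    def test_round_trip_via_file(self, small_model, tmp_path):
        path = tmp_path / "model.json"
        small_model.to_json(path)
        restored = RoFModel.from_json(path)
        assert restored.p == small_model.p
        assert restored.hyperparams == small_model.hyperparams

    def test_double_round_trip_is_stable(self, small_model, small_data):
        data, _ = small_data
        once = RoFModel.from_json(small_model.to_json())
        twice = RoFModel.from_json(once.to_json())
        np.testing.assert_array_equal(once.predict_proba(data.X),
                                      twice.predict_proba(data.X))


class TestHyperparams:
    def test_validation(self):
        with pytest.raises(ValueError):
            RoFHyperparams(0, 1, 2)
        with pytest.raises(ValueError):
            RoFHyperparams(5, 3, 2)
        with pytest.raises(ValueError):
            RoFHyperparams(5, 1, 2, remove_proportion=1.0)
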