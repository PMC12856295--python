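"""Loading, fold construction and the synthetic generator."""

import json

import numpy as np
import pytest
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from rofbes import (Dataset, FoldSpec, SyntheticConfig, generate_synthetic,
                    make_folds, read_tabular)


class TestReadTabular:
    def test_identity_load(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("a,b,label\n1,2,0\n3,4,1\n5,6,0\n7,8,1\n")
        data = read_tabular(f, "label")
        assert data.n == 4 and data.p == 2
        assert data.feature_names == ["a", "b"]
        np.testing.assert_array_equal(data.y, [0, 1, 0, 1])
        np.testing.assert_array_equal(data.X[:, 0], [1, 3, 5, 7])

    def test_string_labels_map_in_sorted_order(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("a,b,label\n1,2,no\n3,4,yes\n5,6,no\n7,8,yes\n")
        data = read_tabular(f, "label")
        np.testing.assert_array_equal(data.y, [0, 1, 0, 1])  # no->0, yes->1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_tabular(tmp_path / "absent.csv", "label")

    def test_non_numeric_cell_reported(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("a,b,label\n1,2,0\n3,oops,1\n5,6,0\n")
        with pytest.raises(ValueError, match="b"):
            read_tabular(f, "label")

    def test_label_cardinality(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("a,b,label\n1,2,0\n3,4,1\n5,6,2\n")
        with pytest.raises(ValueError, match="2 distinct"):
            read_tabular(f, "label")

    def test_missing_values_rejected_or_dropped(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("a,b,label\n1,2,0\n3,,1\n5,6,0\n7,8,1\n")
        with pytest.raises(ValueError, match="missing"):
            read_tabular(f, "label")
        data = read_tabular(f, "label", on_missing="drop")
        assert data.n == 3


class TestMakeFolds:
    def test_study_shape_224_95(self):
        spec = make_folds(319, k=10, train_fraction=0.7, seed=3)
        for train, test in spec.folds:
            assert len(train) == 224 and len(test) == 95

    def test_small_arithmetic_and_partition(self):
        spec = make_folds(10, k=2, train_fraction=0.7, seed=0)
        for train, test in spec.folds:
            assert len(train) == 7 and len(test) == 3
            assert set(train) & set(test) == set()
            assert sorted(np.concatenate([train, test])) == list(range(10))

    def test_determinism(self):
        a = make_folds(50, k=3, train_fraction=0.7, seed=9)
        b = make_folds(50, k=3, train_fraction=0.7, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    @pytest.mark.parametrize("n,k,frac", [(20, 5, 0.5), (101, 4, 0.8), (319, 10, 0.7)])
    def test_partition_property(self, n, k, frac):
        spec = make_folds(n, k=k, train_fraction=frac, seed=1)
        n_test = int(np.floor((1 - frac) * n))
        for train, test in spec.folds:
            assert len(test) == n_test and len(train) == n - n_test
            assert len(np.unique(np.concatenate([train, test]))) == n

    def test_folds_differ_across_fold_index(self):
        spec = make_folds(100, k=5, train_fraction=0.7, seed=2)
        tests = [tuple(te) for _, te in spec.folds]
        assert len(set(tests)) == 5  # independent shuffles

    def test_stratified_parts_keep_both_classes(self):
        y = np.array([0] * 45 + [1] * 5)
        spec = make_folds(50, k=4, train_fraction=0.7, seed=0, stratify_labels=y)
        for train, test in spec.folds:
            assert len(np.unique(y[train])) == 2
            assert len(np.unique(y[test])) == 2

    def test_json_round_trip(self, tmp_path):
        spec = make_folds(30, k=3, train_fraction=0.7, seed=4)
        path = tmp_path / "folds.json"
        spec.to_json(path)
        loaded = FoldSpec.from_json(path)
        assert loaded.seed == 4 and loaded.train_fraction == 0.7
        for (tr1, te1), (tr2, te2) in zip(spec.folds, loaded.folds):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)
        obj = json.loads(spec.to_json())
        assert set(obj) == {"seed", "train_fraction", "folds"}

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_folds(3, k=2, train_fraction=0.7, seed=0)
        with pytest.raises(ValueError):
            make_folds(10, k=2, train_fraction=1.2, seed=0)


class TestGenerateSynthetic:
    def test_null_generator_has_no_signal(self):
        data, informative = generate_synthetic(
            SyntheticConfig(n=2000, p=10, n_informative=5, effect_size=0.0, seed=1)
        )
        flagged = 0
        for j in informative:
            t, p_val = stats.ttest_ind(data.X[data.y == 1, j], data.X[data.y == 0, j])
            flagged += p_val < 0.001
        assert flagged == 0

    def test_planted_signal_is_separable_by_a_tree(self):
        data, _ = generate_synthetic(
            SyntheticConfig(n=319, p=38, n_informative=5, effect_size=1.5, seed=7)
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n)
        n_test = int(0.3 * data.n)
        test, train = perm[:n_test], perm[n_test:]
        tree = DecisionTreeClassifier(random_state=0).fit(data.X[train], data.y[train])
        assert tree.score(data.X[test], data.y[test]) > 0.7

    def test_block_correlation_matches_target(self):
        cfg = SyntheticConfig(n=5000, p=10, n_informative=2, effect_size=1.0,
                              block_corr=0.9, block_size=4, seed=3)
        data, informative = generate_synthetic(cfg)
        block = list(range(2, 6))  # first declared block after the informative cols
        corr = np.corrcoef(data.X[:, block], rowvar=False)
        off_diag = corr[~np.eye(len(block), dtype=bool)]
        assert off_diag.min() >= 0.85 and off_diag.max() <= 0.95

    def test_informative_features_have_univariate_auc(self):
        data, informative = generate_synthetic(
            SyntheticConfig(n=319, p=20, n_informative=4, effect_size=1.5, seed=5)
        )
        from rofbes import roc_auc
        for j in informative:
            _, auc = roc_auc(data.y, data.X[:, j])
            assert auc > 0.6

    def test_determinism_and_provenance(self):
        cfg = SyntheticConfig(n=100, p=6, n_informative=2, seed=9)
        d1, i1 = generate_synthetic(cfg)
        d2, i2 = generate_synthetic(cfg)
        np.testing.assert_array_equal(d1.X, d2.X)
        np.testing.assert_array_equal(d1.y, d2.y)
        assert i1 == i2
        assert "seed=9" in d1.provenance

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n=10, p=4, n_informative=5)
        with pytest.raises(ValueError):
            SyntheticConfig(class_balance=0.0)
        with pytest.raises(ValueError):
            SyntheticConfig(block_corr=1.0)


class TestDatasetInvariants:
    def test_rejects_non_finite(self):
        X = np.ones((4, 3))
        X[1, 1] = np.nan
        with pytest.raises(ValueError):
            Dataset(X, np.array([0, 1, 0, 1]), ["a", "b", "c"])

    def test_rejects_non_binary_labels(self):
        with pytest.raises(ValueError):
            Dataset(np.ones((3, 2)), np.array([0, 1, 2]), ["a", "b"])

    def test_subsetting_preserves_alignment(self, small_data):
        data, _ = small_data
        sub = data.subset_features([2, 0])
        assert sub.feature_names == [data.feature_names[2], data.feature_names[0]]
        np.testing.assert_array_equal(sub.X[:, 1], data.X[:, 0])
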