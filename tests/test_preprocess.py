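"""Filtering, normalization, correlation-based selection, renaming."""

import math

import numpy as np
import pytest

import molungn as m
from molungn.preprocess import cfs_scores


def _view(values, name="v", features=None):
    values = np.asarray(values, dtype=float)
    ids = [f"s{i}" for i in range(values.shape[0])]
    feats = features or [f"f{j}" for j in range(values.shape[1])]
    return m.OmicsView(name, ids, feats, values)


class TestFilter:
    def test_all_zero_column_dropped(self):
        v = _view(np.c_[np.zeros(10), np.arange(1, 11)])
        out = m.filter_low_quality(v, max_zero_fraction=0.5)
        assert out.feature_names == ["f1"]

    def test_clean_view_unchanged(self):
        v = _view(np.arange(1, 13).reshape(4, 3))
        out = m.filter_low_quality(v)
        np.testing.assert_array_equal(out.values, v.values)

    def test_zero_fraction_threshold_matches_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.5, 1.0, size=(20, 10))
        for j in range(10):  # feature j gets j zeros
            X[:j, j] = 0.0
        v = _view(X)
        out = m.filter_low_quality(v, max_zero_fraction=0.2,
                                   max_missing_fraction=1.0)
        expected = [f"f{j}" for j in range(10) if j / 20 <= 0.2]
        assert out.feature_names == expected

    def test_median_imputation(self):
        X = np.array([[1.0, 5.0], [np.nan, 6.0], [3.0, 7.0], [5.0, 8.0]])
        out = m.filter_low_quality(_view(X), max_missing_fraction=0.5)
        assert out.values[1, 0] == 3.0  # median of {1,3,5}
        assert not np.isnan(out.values).any()

    def test_all_dropped_raises(self):
        v = _view(np.zeros((5, 3)))
        with pytest.raises(ValueError, match="relax"):
            m.filter_low_quality(v, max_zero_fraction=0.1)


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        out = m.normalize_minmax(_view([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.values.ravel(), [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        out = m.normalize_minmax(_view([[5.0], [5.0], [5.0]]))
        np.testing.assert_array_equal(out.values.ravel(), [0, 0, 0])

    def test_out_of_range_test_value_clipped(self):
        train = _view([[0.0], [10.0]])
        test = m.OmicsView("v", ["t0"], ["f0"], [[12.0]])
        out = m.normalize_minmax(train, test)
        assert out.values[0, 0] == 1.0

    def test_idempotent_on_training_view(self):
        v = _view(np.random.default_rng(0).normal(size=(10, 4)))
        once = m.normalize_minmax(v)
        twice = m.normalize_minmax(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-15)

    def test_feature_mismatch_raises(self):
        with pytest.raises(ValueError, match="feature sets differ"):
            m.normalize_minmax(_view([[1.0]]),
                               _view([[1.0]], features=["other"]))


class TestCFS:
    def _labels(self, codes, C=2):
        return m.LabelSet([f"s{i}" for i in range(len(codes))],
                          codes, [f"c{i}" for i in range(C)])

    def test_indicator_feature_scores_one_and_ranks_first(self):
        codes = np.array([0, 1, 0, 1, 1, 0])
        X = np.c_[(codes == 0).astype(float),
                  np.random.default_rng(1).normal(size=6)]
        sel = m.cfs_select(_view(X), self._labels(codes), 0.5, 100)
        assert sel.kept_feature_names[0] == "f0"
        assert sel.scores["f0"] == pytest.approx(1.0)

    def test_constant_feature_scores_zero(self):
        codes = np.array([0, 1, 0, 1])
        X = np.c_[np.full(4, 7.0), (codes == 1).astype(float)]
        scores = cfs_scores(X, codes, 2)
        assert scores[0] == 0.0 and scores[1] == pytest.approx(1.0)

    def test_cap_rule(self):
        # k = min(ceil(fraction * p_clean), cap)
        codes = np.tile([0, 1], 20)
        X = np.random.default_rng(2).normal(size=(40, 40))
        sel = m.cfs_select(_view(X), self._labels(codes), 0.25, 5)
        assert sel.k == 5  # ceil(10) capped at 5
        sel = m.cfs_select(_view(X), self._labels(codes), 0.25, 5000)
        assert sel.k == math.ceil(0.25 * 40) == 10

    def test_ranking_matches_exhaustive_correlation(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=40)
        X = rng.normal(size=(40, 6)) + codes[:, None] * rng.normal(size=6)
        view = _view(X)
        sel = m.cfs_select(view, self._labels(codes, C=3), 1.0, 100)
        # brute force: per-feature max |pearson| against each one-vs-rest
        brute = []
        for j in range(6):
            best = max(abs(np.corrcoef(X[:, j],
                                       (codes == c).astype(float))[0, 1])
                       for c in range(3))
            brute.append((view.feature_names[j], best))
        expected = [f for f, _ in sorted(brute, key=lambda t: (-t[1], t[0]))]
        assert sel.kept_feature_names == expected
        for f, s in brute:
            assert sel.scores[f] == pytest.approx(s, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="n >= 3"):
            cfs_scores(np.zeros((2, 3)), np.array([0, 1]), 2)


class TestRename:
    def test_mapped_feature_renamed_unmapped_dropped(self):
        v = _view(np.arange(6.0).reshape(2, 3),
                  features=["cg0001", "cg0002", "cg0003"])
        out = m.rename_methylation_features(v, {"cg0001": "HMGN5"})
        assert out.feature_names == ["HMGN5"]
        np.testing.assert_array_equal(out.values, v.values[:, :1])

    def test_collision_resolved_by_variance(self):
        X = np.array([[0.0, 0.0], [1.0, 3.0]])  # second probe: larger var
        v = _view(X, features=["cgA", "cgB"])
        out = m.rename_methylation_features(v, {"cgA": "G", "cgB": "G"})
        assert out.feature_names == ["G"]
        np.testing.assert_array_equal(out.values.ravel(), X[:, 1])

    def test_empty_mapping_raises(self):
        v = _view(np.zeros((2, 1)), features=["cgA"])
        with pytest.raises(ValueError, match="empty"):
            m.rename_methylation_features(v, {})


class TestPipeline:
    def test_selection_blind_to_test_labels(self, tiny_data):
        """Permuting held-out labels never changes the selected feature set."""
        views, labels, _ = tiny_data
        train_ids, test_ids = m.split(labels, 0.7, seed=0)
        pre = m.Preprocessor(feature_fraction=0.25, feature_cap=5000)
        pre.fit_transform(views, labels, train_ids)
        baseline = {v: s.kept_feature_names for v, s in pre.selections_.items()}

        rng = np.random.default_rng(1)
        codes = labels.class_codes.copy()
        test_pos = [labels.sample_ids.index(s) for s in test_ids]
        codes[test_pos] = rng.permutation(codes[test_pos])
        permuted = m.LabelSet(labels.sample_ids, codes, labels.class_names)
        pre2 = m.Preprocessor(feature_fraction=0.25, feature_cap=5000)
        pre2.fit_transform(views, permuted, train_ids)
        assert baseline == {v: s.kept_feature_names
                            for v, s in pre2.selections_.items()}

    def test_normalized_output_in_unit_interval(self, tiny_data):
        views, labels, _ = tiny_data
        train_ids, _ = m.split(labels, 0.7, seed=0)
        pre = m.Preprocessor()
        for v in pre.fit_transform(views, labels, train_ids):
            assert v.values.min() >= 0.0 and v.values.max() <= 1.0

    def test_planted_feature_recovery(self):
        """cfs top-s recovers >= 80% of planted features (effect = 2 * noise,
        n >= 100, aggregated over 10 seeds)."""
        hits = total = 0
        for seed in range(10):
            spec = m.SyntheticSpec(
                n=120, C=3,
                views=(m.ViewSpec("mRNA", "expression", p=60, s=10),),
                effect=2.0, noise_sd=1.0, seed=seed)
            (view,), labels, truth = m.generate(spec)
            sel = m.cfs_select(view, labels, feature_fraction=10 / 60,
                               feature_cap=5000)
            hits += len(set(sel.kept_feature_names)
                        & set(truth["mRNA"]["informative"]))
            total += 10
        assert hits / total >= 0.8
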