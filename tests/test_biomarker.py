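"""Masking importance and stage-pair biomarker discovery."""

import numpy as np
import pytest

import molungn as m
from molungn.biomarker import top_biomarkers


@pytest.fixture(scope="module")
def dominant_feature_setup():
    """One planted feature per view with a very strong effect; everything
    else is pure noise."""
    spec = m.SyntheticSpec(
        n=90, C=2,
        views=(m.ViewSpec("mRNA", "expression", p=20, s=1),
               m.ViewSpec("miRNA", "mirna", p=16, s=1)),
        effect=5.0, noise_sd=1.0, seed=21)
    views, labels, truth = m.generate(spec)
    cfg = m.RunConfig(num_epochs=40, num_heads=2, hidden_dims=8,
                      fc_dims=(16, 8), vcdn_features=16, avg_degree=5)
    model = m.MultiOmicsGAT(views, labels, cfg)
    train_ids, _ = m.split(labels, 0.7, seed=3)
    res = model.fit(train_ids=train_ids, seed=3)
    return res, truth


class TestMaskingImportance:
    def test_dropped_features_score_exactly_zero(self, dominant_feature_setup):
        res, _ = dominant_feature_setup
        table = m.masking_importance(res)
        kept = {v: set(s.kept_feature_names)
                for v, s in res.preprocessor.selections_.items()}
        for _, row in table.frame.iterrows():
            if row.feature_name not in kept[row.view_name]:
                assert row.importance == 0.0

    def test_dominant_planted_feature_ranks_first(self,
                                                  dominant_feature_setup):
        res, truth = dominant_feature_setup
        table = m.masking_importance(res)
        top_mrna = table.view("mRNA").iloc[0].feature_name
        assert top_mrna == truth["mRNA"]["informative"][0]

    def test_ranks_are_dense_and_sorted(self, dominant_feature_setup):
        res, _ = dominant_feature_setup
        table = m.masking_importance(res)
        for vname in ("mRNA", "miRNA"):
            sub = table.view(vname)
            assert list(sub["rank"]) == list(range(1, len(sub) + 1))
            imp = sub.importance.to_numpy()
            assert (np.diff(imp) <= 1e-12).all()

    def test_whole_view_mask_consistency(self, dominant_feature_setup):
        """Masking every column of a view at once drops the score by
        baseline minus the all-masked evaluation, by definition."""
        res, _ = dominant_feature_setup
        from molungn.biomarker import _eval_f1
        node_pos = {s: i for i, s in enumerate(res.node_ids)}
        test_pos = np.array([node_pos[s] for s in res.test_ids])
        y_test = res.model.labels.subset(res.test_ids).class_codes
        base_probs = [res._branch_probs(i) for i in range(len(res.branches))]
        baseline = _eval_f1(res, base_probs, test_pos, y_test)
        X0 = np.zeros_like(res.processed[0].values)
        masked_probs = [res._branch_probs(0, X_override=X0), base_probs[1]]
        all_masked = _eval_f1(res, masked_probs, test_pos, y_test)
        assert baseline - all_masked >= 0.0  # the view carried signal
        assert baseline - all_masked <= 1.0

    def test_feature_order_invariance(self, dominant_feature_setup):
        """Permuting a view's columns leaves per-feature importance fixed."""
        res, _ = dominant_feature_setup
        views = res.model.views
        labels = res.model.labels
        rng = np.random.default_rng(0)
        perm = rng.permutation(views[0].n_features)
        shuffled = m.OmicsView(
            views[0].view_name, list(views[0].sample_ids),
            [views[0].feature_names[j] for j in perm],
            views[0].values[:, perm])
        model2 = m.MultiOmicsGAT([shuffled, views[1]], labels, res.config)
        res2 = model2.fit(train_ids=res.train_ids, seed=res.seed)
        t1 = m.masking_importance(res).frame.set_index(
            ["view_name", "feature_name"]).importance
        t2 = m.masking_importance(res2).frame.set_index(
            ["view_name", "feature_name"]).importance
        for key in t1.index:
            assert t1[key] == pytest.approx(t2[key], abs=1e-9)

    def test_gradient_input_alternative_scores_all_features(
            self, dominant_feature_setup):
        res, truth = dominant_feature_setup
        table = m.masking_importance(res, method="gradient_input")
        assert table.metadata["method"] == "gradient_input"
        assert (table.frame.importance >= 0).all()
        # the dominant feature is salient under this definition too
        sub = table.view("mRNA")
        assert truth["mRNA"]["informative"][0] in \
            set(sub.head(3).feature_name)

    def test_requires_test_set(self, tiny_data, fast_cfg):
        views, labels, _ = tiny_data
        res = m.MultiOmicsGAT(views, labels, fast_cfg.updated(
            num_epochs=1)).fit(seed=0)  # all samples train
        with pytest.raises(ValueError, match="test set"):
            m.masking_importance(res)


class TestTopBiomarkers:
    def _table(self, res):
        return m.masking_importance(res)

    def test_k_rows_per_view(self, dominant_feature_setup):
        res, _ = dominant_feature_setup
        top = top_biomarkers(self._table(res), 3)
        assert len(top) == 6  # 3 per view, 2 views
        assert set(top.view_name) == {"mRNA", "miRNA"}

    def test_k_zero_empty(self, dominant_feature_setup):
        res, _ = dominant_feature_setup
        assert len(top_biomarkers(self._table(res), 0)) == 0

    def test_k_beyond_p_clips_with_warning(self, dominant_feature_setup,
                                           caplog):
        res, _ = dominant_feature_setup
        import logging
        with caplog.at_level(logging.WARNING):
            top = top_biomarkers(self._table(res), 10_000)
        assert "clipping" in caplog.text
        assert len(top) == len(self._table(res).frame)

    def test_ties_resolved_by_name(self):
        from molungn.biomarker import _rank_frame
        rows = [{"view_name": "v", "feature_name": f, "importance": 0.0}
                for f in ["zeta", "alpha", "mid"]]
        frame = _rank_frame(rows)
        assert list(frame.sort_values("rank").feature_name) == \
            ["alpha", "mid", "zeta"]


class TestStagePairs:
    @pytest.fixture(scope="class")
    def pair_tables(self):
        spec = m.SyntheticSpec(
            n=120, C=3,
            views=(m.ViewSpec("mRNA", "expression", p=16, s=2),
                   m.ViewSpec("miRNA", "mirna", p=12, s=2)),
            effect=2.0, noise_sd=1.0, s_pair=1, pair_effect=5.0, seed=8)
        views, labels, truth = m.generate(spec)
        cfg = m.RunConfig(num_epochs=30, num_heads=2, hidden_dims=8,
                          fc_dims=(16, 8), vcdn_features=16, avg_degree=5)
        return m.stage_pair_biomarkers(views, labels, cfg, seed=8), truth

    def test_three_stages_two_tables(self, pair_tables):
        tables, _ = pair_tables
        assert [name for name, _ in tables] == \
            ["StageI-StageII", "StageII-StageIII"]

    def test_tables_cover_all_features(self, pair_tables):
        tables, _ = pair_tables
        for _, table in tables:
            counts = table.frame.groupby("view_name").size()
            assert counts["mRNA"] == 16 and counts["miRNA"] == 12

    def test_metadata_carries_pair_name(self, pair_tables):
        tables, _ = pair_tables
        assert tables[0][1].metadata["stage_pair"] == "StageI-StageII"

    def test_csv_export(self, pair_tables, tmp_path):
        tables, _ = pair_tables
        p = tmp_path / "t.csv"
        tables[0][1].to_csv(p)
        header = p.read_text().splitlines()[0]
        assert header == "view_name,feature_name,importance,rank"
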