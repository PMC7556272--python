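"""Two-layer random forest: ranking, nested CV, leakage control."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from mcinet import cohort as ch
from mcinet import rf_classifier as rf

FAST_CV = dict(
    n_estimators_grid=(50,),
    max_depth_grid=(3, None),
    ranking_n_estimators=50,
)


@pytest.fixture(scope="module")
def planted_table():
    feats, y, names = ch.simulate_feature_table(
        30,
        seed=2,
        informative={
            "ADAS13": 1.2, "CDRSB": 1.5, "MMSE": 1.2, "FAQ": 1.2, "L": 1.0,
            "bc_1": 0.8, "bc_10": 0.8, "bc_20": 0.8, "bc_30": 0.8, "bc_40": 0.8,
        },
    )
    return rf.FeatureTable(features=feats, labels=y, sparsity=0.16), names


@pytest.fixture(scope="module")
def null_table():
    feats, y, _ = ch.simulate_feature_table(30, seed=3)
    return rf.FeatureTable(features=feats, labels=y, sparsity=0.16)


class TestFeatureTable:
    def test_exact_column_contract(self):
        cols = rf.feature_columns()
        assert len(cols) == 124
        assert cols[:8] == ["ADAS13", "CDRSB", "MMSE", "FAQ", "C", "L", "GE", "SW"]
        assert cols[8] == "bc_1" and cols[-1] == "bc_116"

    def test_build_from_stage_tables(self):
        n = 24
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "group": ["NC"] * 12 + ["MCI"] * 12,
                **{s: rng.normal(size=n) for s in rf.SCORE_COLUMNS},
            }
        )
        gm = pd.DataFrame(
            {"subject_id": meta.subject_id, **{c: rng.normal(size=n) for c in rf.GLOBAL_COLUMNS}}
        )
        bc = pd.DataFrame(
            {"subject_id": meta.subject_id, **{f"bc_{i+1}": rng.random(n) for i in range(116)}}
        )
        table = rf.build_feature_table(meta, gm, bc, 0.16)
        assert table.features.shape == (n, 124)
        np.testing.assert_array_equal(table.labels, [0] * 12 + [1] * 12)
        np.testing.assert_allclose(table.features["C"], gm["C"])

    def test_missing_subject_metric_named(self):
        meta = pd.DataFrame(
            {
                "subject_id": ["A", "B"],
                "group": ["NC", "MCI"],
                **{s: [1.0, 2.0] for s in rf.SCORE_COLUMNS},
            }
        )
        gm = pd.DataFrame({"subject_id": ["A"], **{c: [1.0] for c in rf.GLOBAL_COLUMNS}})
        bc = pd.DataFrame({"subject_id": ["A", "B"], **{f"bc_{i+1}": [0.1, 0.2] for i in range(116)}})
        with pytest.raises(ValueError, match="B"):
            rf.build_feature_table(meta, gm, bc, 0.16)

    def test_round_trip_via_csv(self, tmp_path, null_table):
        path = tmp_path / "table.csv"
        null_table.features.to_csv(path, index=False)
        reloaded = rf.FeatureTable(
            features=pd.read_csv(path), labels=null_table.labels, sparsity=0.16
        )
        pd.testing.assert_frame_equal(reloaded.features, null_table.features)


class TestOOBImportance:
    def test_oob_indices_match_sklearn(self, null_table):
        """Our reconstruction of each tree's bootstrap must reproduce
        sklearn's own OOB votes exactly."""
        x = null_table.features.to_numpy()
        y = null_table.labels
        forest = RandomForestClassifier(n_estimators=30, random_state=0, oob_score=True)
        forest.fit(x, y)
        n = len(y)
        votes = np.zeros((n, 2))
        for tree in forest.estimators_:
            oob = rf._oob_indices(tree.random_state, n)
            votes[oob] += tree.predict_proba(x[oob])
        counts = votes.sum(axis=1, keepdims=True)
        ours = np.divide(votes, counts, out=np.zeros_like(votes), where=counts > 0)
        np.testing.assert_allclose(ours, forest.oob_decision_function_, atol=1e-12)

    def test_perfect_predictor_ranked_first(self):
        rng = np.random.default_rng(7)
        feats = pd.DataFrame(
            rng.standard_normal((40, 124)), columns=rf.feature_columns()
        )
        y = rng.integers(0, 2, 40)
        feats["GE"] = y.astype(float)  # feature identical to the label
        table = rf.FeatureTable(features=feats[rf.feature_columns()], labels=y)
        ranking = rf.rank_features_layer1(table, seed=0, n_estimators=100)
        assert ranking[0][0] == "GE"

    def test_ranking_deterministic(self, planted_table):
        table, _ = planted_table
        a = rf.rank_features_layer1(table, seed=5, n_estimators=50)
        b = rf.rank_features_layer1(table, seed=5, n_estimators=50)
        assert a == b

    def test_impurity_variant(self, planted_table):
        table, _ = planted_table
        ranking = rf.rank_features_layer1(table, seed=0, n_estimators=50, importance="impurity")
        assert len(ranking) == 124
        assert all(s >= 0 for _, s in ranking)

    def test_single_class_rejected(self):
        feats, y, _ = ch.simulate_feature_table(5, seed=0)
        table = rf.FeatureTable(features=feats, labels=y)
        with pytest.raises(ValueError):
            rf.rank_features_layer1(table, rows=np.flatnonzero(y == 0))


class TestNestedCV:
    def test_report_contract(self, planted_table):
        table, _ = planted_table
        rep = rf.nested_cv(table, top_n=10, seed=0, **FAST_CV)
        assert 0 <= rep.accuracy <= 1
        assert 0 <= rep.auc <= 1
        assert len(rep.folds) == 10
        assert len(rep.ranking) == 124
        assert all(len(f.selected_features) == 10 for f in rep.folds)

    def test_pooled_accuracy_is_size_weighted_fold_mean(self, planted_table):
        table, _ = planted_table
        rep = rf.nested_cv(table, top_n=10, seed=0, **FAST_CV)
        sizes = np.array([len(f.test_index) for f in rep.folds])
        accs = np.array([f.accuracy for f in rep.folds])
        assert rep.accuracy == pytest.approx(float((sizes * accs).sum() / sizes.sum()))

    def test_deterministic_under_seed(self, planted_table):
        table, _ = planted_table
        a = rf.nested_cv(table, top_n=8, seed=11, **FAST_CV)
        b = rf.nested_cv(table, top_n=8, seed=11, **FAST_CV)
        assert a.accuracy == b.accuracy
        assert a.auc == b.auc
        assert [f.selected_features for f in a.folds] == [f.selected_features for f in b.folds]
        assert [(f.n_estimators, f.max_depth) for f in a.folds] == [
            (f.n_estimators, f.max_depth) for f in b.folds
        ]

    def test_outer_test_labels_cannot_influence_selection(self, planted_table):
        """Flipping a held-out subject's label must not change the
        features selected for that subject's fold."""
        table, _ = planted_table
        rep = rf.nested_cv(table, top_n=10, seed=0, **FAST_CV)
        fold = rep.folds[0]
        splits = [
            (np.setdiff1d(np.arange(len(table.labels)), f.test_index), f.test_index)
            for f in rep.folds
        ]
        flipped = table.labels.copy()
        victim = fold.test_index[0]
        flipped[victim] = 1 - flipped[victim]
        table2 = rf.FeatureTable(features=table.features, labels=flipped, sparsity=0.16)
        rep2 = rf.nested_cv(table2, top_n=10, seed=0, outer_splits=splits, **FAST_CV)
        assert rep2.folds[0].selected_features == fold.selected_features

    def test_global_ranking_mode_shares_selection_across_folds(self, planted_table):
        table, _ = planted_table
        rep = rf.nested_cv(table, top_n=10, seed=0, global_ranking=True, **FAST_CV)
        first = set(rep.folds[0].selected_features)
        assert all(set(f.selected_features) == first for f in rep.folds)

    def test_too_few_subjects_rejected(self):
        feats, y, _ = ch.simulate_feature_table(8, seed=0)
        with pytest.raises(ValueError):
            rf.nested_cv(rf.FeatureTable(features=feats, labels=y), top_n=5, seed=0)


class TestSweepAndScoresOnly:
    def test_sweep_returns_one_report_per_n(self, planted_table):
        table, _ = planted_table
        reports, best = rf.sweep_top_n(table, n_values=[5, 10], seed=0, **FAST_CV)
        assert [r.top_n for r in reports] == [5, 10]
        assert best.accuracy == max(r.accuracy for r in reports)

    def test_scores_only_uses_four_features(self, planted_table):
        table, _ = planted_table
        rep = rf.compare_scores_only(table, seed=0, **FAST_CV)
        assert all(f.selected_features == list(rf.SCORE_COLUMNS) for f in rep.folds)
        assert rep.accuracy > 0.6  # scores carry planted signal
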