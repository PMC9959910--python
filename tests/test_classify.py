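"""Classifier cross-validation, feature importance, ordination, clustering."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import lfqcohort as lc
from lfqcohort.classify import fold_assignments, _roc_auc_filter
from lfqcohort.errors import ConfigError, DegenerateInputError, StratificationError

FAST = lc.ClassifierConfig(folds=5, repeats=2, ntree=100)


def _labeled_matrix(n1=10, n2=10, p=12, effect=4.0, noise=0.1, seed=0):
    """Two-class intensity matrix with a shift on every feature."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(4, 16, size=(p, 1))
    x = 2.0 ** (base + rng.normal(0, noise, size=(p, n1 + n2)))
    x[:, n1:] *= 2.0**effect
    ids = [f"F{i}" for i in range(p)]
    samples = [f"s{i}" for i in range(n1 + n2)]
    m = lc.IntensityMatrix(pd.DataFrame(x, index=ids, columns=samples))
    labels = np.array(["MGS1"] * n1 + ["MGS2"] * n2)
    return m, labels


class TestFolds:
    def test_pure_function_of_labels_and_seed(self):
        y = np.array(["a"] * 12 + ["b"] * 15)
        s1 = fold_assignments(y, 5, 2, seed=3)
        s2 = fold_assignments(y, 5, 2, seed=3)
        for (tr1, te1), (tr2, te2) in zip(s1, s2):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)
        assert len(s1) == 10

    def test_small_class_cannot_stratify(self):
        y = np.array(["a"] * 3 + ["b"] * 20)
        with pytest.raises(StratificationError):
            fold_assignments(y, 10, 3, seed=0)


class TestRunClassifiers:
    def test_separated_data_near_perfect(self):
        m, labels = _labeled_matrix(effect=4.0, noise=0.1)
        report = lc.run_classifiers(m, labels, FAST, seed=1)
        assert report.mean_accuracy["RF"] >= 0.95
        assert report.mean_accuracy["SVM"] >= 0.95

    def test_same_seed_reproduces_resample_vectors(self):
        m, labels = _labeled_matrix(effect=0.5, noise=0.5)
        r1 = lc.run_classifiers(m, labels, FAST, seed=9)
        r2 = lc.run_classifiers(m, labels, FAST, seed=9)
        for model in ("RF", "SVM"):
            np.testing.assert_array_equal(
                r1.resample_accuracies[model], r2.resample_accuracies[model]
            )
            pd.testing.assert_series_equal(r1.importance[model], r2.importance[model])

    def test_report_shape_and_ci(self):
        m, labels = _labeled_matrix(effect=1.0, noise=0.5)
        report = lc.run_classifiers(m, labels, FAST, seed=2)
        for model in ("RF", "SVM"):
            assert len(report.resample_accuracies[model]) == FAST.folds * FAST.repeats
            lo, hi = report.ci95[model]
            assert lo <= report.mean_accuracy[model] <= hi
            imp = report.importance[model]
            assert (imp >= 0).all() and imp.max() == pytest.approx(100.0)

    def test_mtry_cannot_exceed_feature_count(self):
        m, labels = _labeled_matrix(p=5)
        with pytest.raises(ConfigError):
            lc.run_classifiers(m, labels, replace(FAST, mtry=10), seed=0)

    def test_two_classes_required(self):
        m, labels = _labeled_matrix()
        with pytest.raises(ConfigError):
            lc.run_classifiers(m, np.array(["x"] * len(labels)), FAST, seed=0)


class TestImportance:
    def test_label_identical_feature_scores_100_for_svm(self):
        x = np.array([[1.0, 5.0], [2.0, 6.0], [1.5, 5.5], [9.0, 1.0], [8.0, 2.0], [9.5, 1.5]]).T
        y01 = np.array([0, 0, 0, 1, 1, 1])
        scores = _roc_auc_filter(x.T, y01)
        assert scores[0] == pytest.approx(1.0)  # AUC = 1 -> raw score 1

    def test_duplicated_features_get_equal_svm_importance(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=20)
        x = np.c_[col, col, rng.normal(size=20)]
        y01 = np.r_[np.zeros(10), np.ones(10)].astype(int)
        scores = _roc_auc_filter(x, y01)
        assert scores[0] == pytest.approx(scores[1])

    def test_constant_feature_scores_zero(self):
        x = np.c_[np.ones(10), np.arange(10.0)]
        y01 = np.r_[np.zeros(5), np.ones(5)].astype(int)
        scores = _roc_auc_filter(x, y01)
        assert scores[0] == 0.0

    def test_noise_feature_has_low_rf_importance(self):
        # informative features + one pure-noise feature: the noise feature's
        # permutation importance stays near zero
        rng = np.random.default_rng(7)
        m, labels = _labeled_matrix(p=6, effect=2.0, noise=0.3, seed=7)
        noise_row = pd.DataFrame(
            2.0 ** rng.normal(10, 1, size=(1, m.data.shape[1])),
            index=["NOISE"], columns=m.sample_ids,
        )
        m2 = lc.IntensityMatrix(pd.concat([m.data, noise_row]))
        report = lc.run_classifiers(m2, labels, FAST, seed=7)
        assert report.importance["RF"]["NOISE"] < 20


class TestTopOverlap:
    def test_identical_rankings_full_overlap(self):
        s = pd.Series(np.arange(40.0), index=[f"F{i}" for i in range(40)])
        assert len(lc.top_overlap(s, s, k=10)) == 10

    def test_disjoint_rankings_empty_overlap(self):
        ids = [f"F{i:02d}" for i in range(40)]
        a = pd.Series(np.r_[np.arange(1.0, 21.0), np.zeros(20)], index=ids)
        b = pd.Series(np.r_[np.zeros(20), np.arange(1.0, 21.0)], index=ids)
        assert lc.top_overlap(a, b, k=20) == []

    def test_ties_break_deterministically(self):
        ids = [f"F{i:02d}" for i in range(10)]
        s = pd.Series(np.ones(10), index=ids)
        got = lc.top_overlap(s, s, k=4)
        assert got == ["F00", "F01", "F02", "F03"]

    def test_requires_k_features(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ConfigError):
            lc.top_overlap(s, s, k=5)


class TestOrdination:
    def test_pca_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        m = lc.IntensityMatrix(
            pd.DataFrame(
                2.0 ** rng.uniform(2, 10, size=(4, 6)),
                index=list("ABCD"), columns=[f"s{i}" for i in range(6)],
            )
        )
        labels = ["g1"] * 3 + ["g2"] * 3
        res = lc.ordinate(m, labels, "pca")
        # oracle: eigendecomposition of the sample covariance of the same design
        from lfqcohort.classify import _standardized_design

        x = _standardized_design(m)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        want = xc @ evecs[:, :2]
        got = res.scores.to_numpy()
        for c in range(2):
            assert np.allclose(got[:, c], want[:, c], atol=1e-8) or np.allclose(
                got[:, c], -want[:, c], atol=1e-8
            )
        assert res.explained_variance[0] == pytest.approx(
            evals[0] / evals.sum(), abs=1e-10
        )

    def test_variance_on_single_feature_gives_unit_ev1(self):
        df = pd.DataFrame(
            {"s1": [1.0, 5, 5], "s2": [2.0, 5, 5], "s3": [4.0, 5, 5], "s4": [8.0, 5, 5]}
        ).T.T
        m = lc.IntensityMatrix(
            pd.DataFrame(df.to_numpy(), index=["V", "C1", "C2"], columns=df.columns)
        )
        res = lc.ordinate(m, ["a", "a", "b", "b"], "pca")
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(1)
        col = 2.0 ** rng.uniform(2, 8, 5)
        df = pd.DataFrame({"s1": col, "s2": col, "s3": col * 2, "s4": col * 3},
                          index=[f"P{i}" for i in range(5)])
        m = lc.IntensityMatrix(df)
        res = lc.ordinate(m, ["a", "a", "b", "b"], "pca")
        np.testing.assert_allclose(
            res.scores.loc["s1"], res.scores.loc["s2"], atol=1e-10
        )

    def test_plsda_scores_and_explained_variance(self):
        m, labels = _labeled_matrix(n1=6, n2=6, p=8, effect=1.0, noise=0.5, seed=5)
        res = lc.ordinate(m, labels, "plsda")
        assert res.scores.shape == (12, 2)
        ev = res.explained_variance
        assert 0 <= ev[0] <= 1 and 0 <= ev[1] <= 1

    def test_plsda_separates_better_than_pca_on_weak_effects(self):
        def separation(scores, labels):
            s = scores["comp1"].to_numpy()
            a, b = s[labels == "MGS1"], s[labels == "MGS2"]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / pooled

        wins = []
        for seed in range(10):
            m, labels = _labeled_matrix(n1=8, n2=8, p=20, effect=0.4, noise=1.0, seed=seed)
            pca = lc.ordinate(m, labels, "pca")
            pls = lc.ordinate(m, labels, "plsda")
            wins.append(
                separation(pls.scores, labels) - separation(pca.scores, labels)
            )
        assert np.median(wins) > 0

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 2], "s2": [3.0, 4]}, index=["A", "B"])
        with pytest.raises(DegenerateInputError):
            lc.ordinate(lc.IntensityMatrix(df), ["a", "b"], "pca")


class TestHeatmap:
    def test_identical_samples_are_adjacent_leaves(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(1, 100, 8)
        df = pd.DataFrame(
            {"s1": col, "s2": col * rng.uniform(0.9, 1.1, 8), "dupA": col * 2, "dupB": col * 2},
            index=[f"P{i}" for i in range(8)],
        )
        res = lc.cluster_heatmap(lc.IntensityMatrix(df))
        ia, ib = res.col_order.index("dupA"), res.col_order.index("dupB")
        assert abs(ia - ib) == 1

    def test_block_structure_recovered_by_two_cluster_cut(self):
        rng = np.random.default_rng(4)
        n1, n2, p = 6, 6, 30
        x = rng.normal(10, 0.3, size=(p, n1 + n2))
        x[:, n1:] += 3.0
        df = pd.DataFrame(
            2.0**x, index=[f"P{i}" for i in range(p)],
            columns=[f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)],
        )
        m = lc.IntensityMatrix(df)
        z = lc.cluster_heatmap(m)
        from scipy.spatial.distance import pdist

        link = hierarchy.ward(pdist(((m.values - m.values.mean(1, keepdims=True))
                                     / m.values.std(1, keepdims=True)).T))
        cut = hierarchy.fcluster(link, 2, criterion="maxclust")
        assert len(set(cut[:n1])) == 1 and len(set(cut[n1:])) == 1
        assert cut[0] != cut[-1]

    def test_leaf_order_deterministic(self, desk_cohort):
        matrix = desk_cohort[0]
        sub = matrix.subset_proteins(matrix.protein_ids[:25])
        r1 = lc.cluster_heatmap(sub)
        r2 = lc.cluster_heatmap(sub)
        assert r1.row_order == r2.row_order
        assert r1.col_order == r2.col_order

    def test_zero_variance_row_warns_and_zeroes(self):
        df = pd.DataFrame(
            {"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 4.0]}, index=["FLAT", "B"]
        )
        with pytest.warns(UserWarning):
            res = lc.cluster_heatmap(lc.IntensityMatrix(df))
        assert (res.grid.loc["FLAT"] == 0).all()
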