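"""Dataset assembly, LOSO machinery, classifiers, metrics, feature screen."""

import numpy as np
import pandas as pd
import pytest

from gazemotion.evaluation import (
    CLASSES,
    ConfusionMatrix,
    LabelledDataset,
    assemble_dataset,
    evaluate_loso,
    feature_screen,
    loso_splits,
    metrics_from_confusion,
    run_classifier,
)
from gazemotion.features import FEATURE_NAMES


def toy_features(n_participants=6, movies_per_class=2, rng=None, shift=None):
    """Feature table with one movie per class slot; optional class shift on f15."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for p in range(n_participants):
        for c in CLASSES:
            for m in range(movies_per_class):
                row = {
                    "participant_id": f"S{p:02d}",
                    "movie_id": f"{c}_m{m}",
                    "class_label": c,
                }
                row.update({name: float(rng.normal()) for name in FEATURE_NAMES})
                if shift:
                    row["f15_pupil_diameter_mean"] += shift.get(c, 0.0)
                rows.append(row)
    return pd.DataFrame(rows)


class TestAssembleAndSplits:
    def test_full_design_counts(self):
        df = toy_features(n_participants=25)
        ds = assemble_dataset(df)
        assert ds.n_examples == 150
        for pair in (("C1", "C2"), ("C1", "C3"), ("C2", "C3")):
            assert ds.subset(pair).n_examples == 100

    def test_tiny_design(self):
        df = toy_features(n_participants=2, movies_per_class=1)
        ds = assemble_dataset(df, classes=("C1", "C2"))
        assert ds.n_examples == 4

    def test_missing_class_movie_reported(self):
        df = toy_features(n_participants=3)
        df = df[~((df.participant_id == "S01") & (df.class_label == "C2"))]
        with pytest.raises(ValueError, match="S01"):
            assemble_dataset(df)

    def test_loso_folds_partition_dataset(self):
        ds = assemble_dataset(toy_features(n_participants=5))
        splits = loso_splits(ds)
        assert len(splits) == 5
        seen = np.concatenate([test for _, test in splits])
        assert sorted(seen) == list(range(ds.n_examples))
        for train, test in splits:
            assert set(ds.participants[train]).isdisjoint(ds.participants[test])


class TestClassifiers:
    def _blobs(self, rng, n=40, sep=8.0):
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(sep, 1, (n, 3))])
        y = np.array(["C1"] * n + ["C2"] * n)
        return X, y

    @pytest.mark.parametrize("model", ["qsvm", "lda", "knn11"])
    def test_separable_blobs_are_perfect(self, model):
        rng = np.random.default_rng(1)
        X, y = self._blobs(rng)
        idx = rng.permutation(len(y))
        train, test = idx[:60], idx[60:]
        pred = run_classifier(X[train], y[train], X[test], model=model)
        assert np.array_equal(pred, y[test])

    def test_knn_majority_rule(self):
        # 6 C1 neighbours at distance ~1, 5 C2 at distance ~0.5: majority wins
        X_train = np.vstack([np.full((6, 2), 1.0), np.full((5, 2), 0.5)])
        y_train = np.array(["C1"] * 6 + ["C2"] * 5)
        pred = run_classifier(X_train, y_train, np.zeros((1, 2)), model="knn11")
        assert pred[0] == "C1"

    def test_knn_tie_broken_by_summed_distance(self):
        # force a 5/5 vote tie at k=10: closer class must win
        X_train = np.vstack([np.full((5, 1), 0.4), np.full((5, 1), 1.0), [[50.0]]])
        y_train = np.array(["C2"] * 5 + ["C1"] * 5 + ["C3"])
        pred = run_classifier(X_train, y_train, np.zeros((1, 1)), model="knn11", k=10)
        assert pred[0] == "C2"

    def test_k_larger_than_training_set_rejected(self):
        with pytest.raises(ValueError):
            run_classifier(np.zeros((4, 2)), np.array(["C1", "C1", "C2", "C2"]),
                           np.zeros((1, 2)), model="knn11")

    def test_lda_matches_analytic_discriminant(self):
        # shared-covariance Gaussians: boundary is the closed-form LDA rule
        rng = np.random.default_rng(6)
        mu1, mu2 = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        cov = np.array([[1.0, 0.3], [0.3, 0.8]])
        n = 4000
        X = np.vstack([rng.multivariate_normal(mu1, cov, n),
                       rng.multivariate_normal(mu2, cov, n)])
        y = np.array(["C1"] * n + ["C2"] * n)
        X_test = rng.uniform(-2, 4, size=(400, 2))
        pred = run_classifier(X, y, X_test, model="lda")
        w = np.linalg.solve(cov, mu2 - mu1)
        c = 0.5 * (w @ (mu1 + mu2))
        analytic = np.where(X_test @ w > c, "C2", "C1")
        assert np.mean(pred == analytic) > 0.97


class TestMetrics:
    def test_identity_matrix_all_ones(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int) * 10, CLASSES)
        metrics = metrics_from_confusion(cm)
        assert metrics.accuracy == 1.0
        np.testing.assert_allclose(metrics.per_class.to_numpy(), 1.0)

    def test_hand_computed_two_class_matrix(self):
        # predicted rows / true columns: [[8, 2], [4, 6]]
        cm = ConfusionMatrix(np.array([[8, 2], [4, 6]]), ("A", "B"))
        m = metrics_from_confusion(cm)
        assert m.accuracy == pytest.approx(14 / 20)
        assert m.per_class.loc["A", "precision"] == pytest.approx(8 / 10)
        assert m.per_class.loc["A", "recall"] == pytest.approx(8 / 12)
        assert m.per_class.loc["A", "specificity"] == pytest.approx(6 / 8)
        assert m.per_class.loc["B", "f1"] == pytest.approx(2 * (6 / 10) * (6 / 8) / (6 / 10 + 6 / 8))

    def test_empty_predicted_row_warns_and_zeroes_precision(self):
        cm = ConfusionMatrix(np.array([[5, 5], [0, 0]]), ("A", "B"))
        with pytest.warns(UserWarning, match="no predictions"):
            m = metrics_from_confusion(cm)
        assert m.per_class.loc["B", "precision"] == 0.0
        assert m.per_class.loc["B", "f1"] == 0.0

    def test_column_sums_preserved_by_loso_pooling(self):
        ds = assemble_dataset(toy_features(n_participants=8))
        res = evaluate_loso(ds, model="lda")
        np.testing.assert_array_equal(res.confusion.counts.sum(axis=0), [16, 16, 16])

    def test_loso_invariant_to_participant_order(self):
        df = toy_features(n_participants=6, shift={"C1": 3.0, "C2": -3.0})
        ds = assemble_dataset(df)
        res1 = evaluate_loso(ds, model="qsvm")
        perm = np.random.default_rng(4).permutation(ds.n_examples)
        ds2 = LabelledDataset(ds.X[perm], ds.y[perm], ds.participants[perm])
        res2 = evaluate_loso(ds2, model="qsvm")
        np.testing.assert_array_equal(res1.confusion.counts, res2.confusion.counts)


class TestFeatureScreen:
    def test_flat_feature_not_significant(self):
        rng = np.random.default_rng(8)
        ds = assemble_dataset(toy_features(n_participants=20, rng=rng))
        screen = feature_screen(ds)
        # 18 null features at alpha=0.05: the vast majority must not flag
        assert screen["significant"].mean() < 0.25

    def test_planted_shift_flagged_in_the_right_pairs(self):
        rng = np.random.default_rng(9)
        df = toy_features(n_participants=20, rng=rng, shift={"C1": 2.0})
        screen = feature_screen(assemble_dataset(df))
        row = screen.loc["f15_pupil_diameter_mean"]
        assert row["anova_p"] < 0.001 and row["significant"]
        assert row["p_C1_vs_C2"] < 0.05 and row["p_C1_vs_C3"] < 0.05
        assert row["p_C2_vs_C3"] > 0.05

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(10)
        screen = feature_screen(assemble_dataset(toy_features(n_participants=15, rng=rng)))
        pair_cols = [c for c in screen.columns if c.startswith("p_")]
        assert (screen[pair_cols] <= 1.0).all().all()
        assert (screen[pair_cols] > 0.33).any().any()  # capping visibly active
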