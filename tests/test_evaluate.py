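import numpy as np
import pytest

from cleftgrade.evaluate import (
    ConfusionMatrix,
    confusion,
    f1_from_pr,
    per_class_metrics,
    roc_auc_ovr,
    row_normalize,
    split_dataset,
    weighted_totals,
    within_k_agreement,
)

COHORT = (62, 45, 45, 38)  # reference class supports, n = 190


def _cohort_labels():
    return np.repeat(np.arange(4), COHORT)


class TestSplitDataset:
    def test_five_test_folds_of_38(self):
        labels = _cohort_labels()
        folds = split_dataset(labels, seed=0)
        sizes = [int((folds.fold == f).sum()) for f in range(5)]
        assert sizes == [38] * 5

    def test_test_folds_partition_dataset(self):
        labels = _cohort_labels()
        folds = split_dataset(labels, seed=1)
        all_test = [np.nonzero(folds.roles[f] == "test")[0] for f in range(5)]
        cat = np.concatenate(all_test)
        assert len(cat) == len(labels)
        assert len(np.unique(cat)) == len(labels)

    def test_roles_approximate_70_10_20(self):
        labels = _cohort_labels()
        folds = split_dataset(labels, seed=2)
        for f in range(5):
            role = folds.roles[f]
            n = len(labels)
            assert abs((role == "train").sum() / n - 0.7) < 0.03
            assert abs((role == "val").sum() / n - 0.1) < 0.03
            assert abs((role == "test").sum() / n - 0.2) < 0.03

    def test_deterministic(self):
        labels = _cohort_labels()
        a, b = split_dataset(labels, seed=5), split_dataset(labels, seed=5)
        np.testing.assert_array_equal(a.fold, b.fold)

    def test_small_class_rejected_by_name(self):
        labels = np.array([0] * 10 + [1] * 10 + [2] * 10 + [3] * 3)
        with pytest.raises(ValueError, match="class 3"):
            split_dataset(labels)


class TestConfusion:
    def test_hand_enumerated_counts(self):
        cm = confusion([0, 0, 1], [0, 1, 1])
        np.testing.assert_array_equal(cm.counts[0], [1, 1, 0, 0])
        np.testing.assert_array_equal(cm.counts[1], [0, 1, 0, 0])
        assert cm.n == 3

    def test_perfect_predictions_are_diagonal(self):
        y = _cohort_labels()
        cm = confusion(y, y)
        assert np.all(cm.counts == np.diag(COHORT))
        np.testing.assert_array_equal(cm.supports, COHORT)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="y_pred"):
            confusion([0, 1], [0, 4])


class TestPerClassMetrics:
    def test_identity_matrix_scores_one(self):
        cm = ConfusionMatrix(np.eye(4, dtype=int) * 5)
        p, r, f1 = per_class_metrics(cm)
        assert np.all(p == 1) and np.all(r == 1) and np.all(f1 == 1)

    def test_degenerate_column_warns_and_zeroes(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 3  # class 0 never predicted as 0; nothing in class 1 row
        counts[2, 2] = counts[3, 3] = 1
        with pytest.warns(UserWarning, match="empty"):
            p, r, f1 = per_class_metrics(ConfusionMatrix(counts))
        assert p[0] == 0 and f1[0] == 0

    @pytest.mark.parametrize(
        "precision,recall,expected",
        [(0.914, 0.855, 0.883), (0.882, 0.789, 0.833), (0.739, 0.756, 0.747),
         (0.731, 0.844, 0.784)],
    )
    def test_f1_identities_of_reference_report(self, precision, recall, expected):
        """Per-class F1 is the harmonic mean of the published P/R values.

        P, R and F1 are each printed rounded to 3 decimals, so the harmonic
        mean of the printed P/R can differ from the printed F1 by up to about
        one unit in the last place.
        """
        assert abs(f1_from_pr(precision, recall) - expected) <= 1.5e-3


class TestWeightedTotals:
    def test_reference_report_totals(self):
        """Support-weighting reproduces the published pooled metrics."""
        assert round(weighted_totals([0.914, 0.739, 0.731, 0.882], COHORT), 3) == 0.823
        assert round(weighted_totals([0.855, 0.756, 0.844, 0.789], COHORT), 3) == 0.816
        assert round(weighted_totals([0.883, 0.747, 0.784, 0.833], COHORT), 3) == 0.817
        assert round(weighted_totals([0.96, 0.93, 0.94, 0.96], COHORT), 3) == 0.948

    def test_equal_supports_reduce_to_mean(self, rng):
        m = rng.random(4)
        assert np.isclose(weighted_totals(m, [7, 7, 7, 7]), m.mean())

    def test_single_support_returns_that_metric(self):
        assert weighted_totals([0.3, 0.9, 0.1, 0.5], [0, 4, 0, 0]) == 0.9

    def test_zero_support_rejected(self):
        with pytest.raises(ValueError):
            weighted_totals([1, 1, 1, 1], [0, 0, 0, 0])


class TestRocAucOvr:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        probs = np.zeros((8, 4))
        probs[np.arange(8), y] = 1.0
        aucs, _ = roc_auc_ovr(y, probs)
        np.testing.assert_allclose(aucs, 1.0)

    def test_uninformative_scores_near_half(self, rng):
        y = rng.integers(0, 4, size=4000)
        probs = rng.random((4000, 4))
        probs /= probs.sum(axis=1, keepdims=True)
        aucs, _ = roc_auc_ovr(y, probs)
        assert np.all(np.abs(aucs - 0.5) < 0.05)

    def test_matches_pair_counting_oracle(self, rng):
        """AUC equals concordant-pair fraction (ties counted half)."""
        y = np.array([0, 1, 0, 2, 0, 3])
        probs = rng.random((6, 4))
        probs /= probs.sum(axis=1, keepdims=True)
        aucs, _ = roc_auc_ovr(y, probs)
        s = probs[:, 0]
        pos, neg = s[y == 0], s[y != 0]
        pairs = [(p, n) for p in pos for n in neg]
        conc = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p, n in pairs)
        assert np.isclose(aucs[0], conc / len(pairs))

    def test_absent_class_flagged_nan(self):
        y = np.array([0, 0, 1, 1])
        probs = np.full((4, 4), 0.25)
        with pytest.warns(UserWarning, match="absent"):
            aucs, _ = roc_auc_ovr(y, probs)
        assert np.isnan(aucs[2]) and np.isnan(aucs[3])

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            roc_auc_ovr([0, 1], np.ones((2, 4)))


class TestRowNormalizeAndBand:
    def test_diagonal_equals_recall_on_random_matrices(self, rng):
        for _ in range(25):
            counts = rng.integers(1, 40, size=(4, 4))
            cm = ConfusionMatrix(counts)
            frac = row_normalize(cm)
            _, recall, _ = per_class_metrics(cm)
            np.testing.assert_allclose(np.diag(frac), recall)
            np.testing.assert_allclose(frac.sum(axis=1), 1.0)

    def test_hand_example_rows(self):
        cm = confusion([0, 0, 1], [0, 1, 1])
        frac = row_normalize(cm)
        np.testing.assert_allclose(frac[0], [0.5, 0.5, 0, 0])
        np.testing.assert_allclose(frac[1], [0, 1, 0, 0])

    def test_within_zero_equals_recall_and_accuracy(self, rng):
        counts = rng.integers(0, 30, size=(4, 4)) + np.eye(4, dtype=int)
        cm = ConfusionMatrix(counts)
        per_class, overall = within_k_agreement(cm, k=0)
        _, recall, _ = per_class_metrics(cm)
        np.testing.assert_allclose(per_class, recall)
        assert np.isclose(overall, cm.accuracy)

    def test_band_only_matrix_scores_one(self):
        counts = np.diag([5, 5, 5, 5]) + np.diag([2, 2, 2], k=1)
        _, overall = within_k_agreement(ConfusionMatrix(counts), k=1)
        assert overall == 1.0

    def test_two_off_prediction_fails_within_one(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 2] = 1
        counts[1, 1] = counts[2, 2] = counts[3, 3] = 1
        per_class, _ = within_k_agreement(ConfusionMatrix(counts), k=1)
        assert per_class[0] == 0.0

    def test_monotone_in_k_and_saturates(self, rng):
        counts = rng.integers(0, 20, size=(4, 4)) + 1
        cm = ConfusionMatrix(counts)
        overall = [within_k_agreement(cm, k)[1] for k in range(4)]
        assert all(np.diff(overall) >= 0)
        assert overall[3] == 1.0


class TestCrossValidate:
    def test_five_folds_pooled_report_structure(self, tmp_path):
        """5-fold CV trains per fold and pools test predictions into one
        report with per-fold metrics and across-fold SD."""
        from cleftgrade.evaluate import cross_validate
        from cleftgrade.model import ModelConfig, TrainConfig, render_mesh_views
        from cleftgrade.synthetic_shapes import build_arch, sample_params
        from cleftgrade.views import icosphere_cameras

        vs = icosphere_cameras(0, 3.0)
        views, labels = [], []
        for sev in range(4):
            for i in range(5):
                mesh, _ = build_arch(sample_params(sev, 300 + i))
                views.append(render_mesh_views(mesh, vs, 32))
                labels.append(sev)
        views = np.stack(views)
        labels = np.array(labels)
        folds = split_dataset(labels, seed=0)
        cfg = TrainConfig(
            epochs=2, batch_size=4, seed=0, patience=3,
            model=ModelConfig(resolution=32, conv_channels=(4, 8),
                              conv_strides=(2, 2), attn_dim=8),
        )
        report = cross_validate(views, labels, folds, cfg)
        assert len(report.fold_metrics) == 5
        for key in ("precision", "recall", "f1", "accuracy"):
            assert key in report.fold_sd
            for m in report.fold_metrics:
                assert 0.0 <= m[key] <= 1.0
        assert report.confusion.n == 20
        assert 0.0 <= report.totals["accuracy"] <= 1.0
        out = tmp_path / "metrics.json"
        report.to_json(out)
        assert out.stat().st_size > 0
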