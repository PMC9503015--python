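"""Training loop behavior and the ROC/AUC evaluation stack."""

import numpy as np
import pytest
from scipy import stats

from dbtmc import models, nn
from dbtmc.data import AugmentSpec
from dbtmc.train_eval import (
    TrainSpec,
    auc,
    average_roc,
    compare_auc_ttest,
    density_stratified_eval,
    evaluate_scores,
    metrics_at_threshold,
    predict_scores,
    roc_points,
    train_classifier,
)


def brute_force_auc(scores, labels):
    """Pairwise concordance oracle: P(pos > neg) with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_computed_example(self):
        # pos {0.9, 0.8}, neg {0.7, 0.85}: 3 of 4 pairs concordant
        assert np.isclose(auc([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0]), 0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_concordance_oracle(self, seed):
        """Trapezoidal ROC area == exhaustive pairwise concordance."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid provokes ties
        assert abs(auc(scores, labels) - brute_force_auc(scores, labels)) < 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(15)
        labels = (rng.random(15) > 0.5).astype(int)
        labels[:2] = [0, 1]
        assert np.isclose(auc(scores, labels), auc(np.exp(3 * scores), labels), atol=1e-12)

    def test_roc_endpoints(self):
        fpr, tpr = roc_points([0.2, 0.6, 0.4], [0, 1, 1])
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


class TestThresholdMetrics:
    def test_all_correct(self):
        sens, spec, acc = metrics_at_threshold([0.9, 0.1], [1, 0])
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        sens, spec, acc = metrics_at_threshold([0.9, 0.8], [1, 0], threshold=0.5)
        assert sens == 1.0 and spec == 0.0

    def test_counted_example(self):
        # 2 TP, 1 FN, 3 TN, 1 FP
        scores = [0.9, 0.8, 0.2, 0.1, 0.2, 0.3, 0.7]
        labels = [1, 1, 1, 0, 0, 0, 0]
        sens, spec, acc = metrics_at_threshold(scores, labels)
        assert np.isclose(sens, 2 / 3)
        assert np.isclose(spec, 3 / 4)
        assert np.isclose(acc, 5 / 7)


class TestAverageRoc:
    def test_single_curve_recovered(self):
        fpr = np.array([0.0, 0.5, 1.0])
        tpr = np.array([0.0, 0.8, 1.0])
        grid, mean_tpr = average_roc([(fpr, tpr)])
        assert np.allclose(mean_tpr, np.interp(grid, fpr, tpr))

    def test_two_identical_curves(self):
        c = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        grid, mean_tpr = average_roc([c, c])
        assert np.allclose(mean_tpr, grid)

    def test_perfect_plus_chance_vertical_average(self):
        perfect = (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]))
        chance = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        grid, mean_tpr = average_roc([perfect, chance])
        assert np.isclose(mean_tpr[np.searchsorted(grid, 0.5)], 0.75)


class TestTTest:
    def test_identical_groups_p_one(self):
        assert compare_auc_ttest([0.9, 0.9, 0.9], [0.9, 0.9, 0.9]) == 1.0

    def test_symmetry(self):
        a, b = [0.91, 0.88, 0.93], [0.85, 0.86, 0.84]
        assert np.isclose(compare_auc_ttest(a, b), compare_auc_ttest(b, a))

    def test_closed_form_three_plus_three(self):
        """Pooled-variance t with 4 df, computed by hand."""
        a = np.array([0.90, 0.91, 0.92])
        b = np.array([0.80, 0.81, 0.82])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t), 4)
        p = compare_auc_ttest(a, b)
        assert abs(p - p_hand) < 1e-9
        assert p < 0.05

    def test_too_few_folds(self):
        with pytest.raises(ValueError):
            compare_auc_ttest([0.9], [0.8, 0.7])


class TestDensityStratified:
    def test_four_entries_and_pooled_within_range(self):
        rng = np.random.default_rng(0)
        names = np.array(["fatty", "scattered", "heterogeneous", "dense"])
        densities = np.repeat(names, 40)
        labels = np.tile([0, 1], 80)
        scores = np.where(labels == 1, rng.normal(0.7, 0.15, 160), rng.normal(0.3, 0.15, 160))
        per = density_stratified_eval(scores, labels, densities)
        assert set(per) == set(names)
        aucs = [r.auc for r in per.values()]
        pooled = auc(scores, labels)
        assert min(aucs) - 1e-9 <= pooled <= max(aucs) + 1e-9

    def test_single_class_subset_reported_missing(self):
        densities = np.array(["fatty", "fatty", "dense", "dense"])
        per = density_stratified_eval([0.9, 0.8, 0.6, 0.2], [1, 1, 1, 0], densities)
        assert per["fatty"] is None
        assert per["dense"] is not None
        assert per["scattered"] is None  # absent from the test set


class _TinyCNN(nn.Module):
    """conv-bn-relu + global pooling head; enough to separate blobs."""

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.conv = nn.Conv2d(1, 8, 5, stride=2, rng=rng, name="conv")
        self.bn = nn.BatchNorm2d(8)
        self.fc = nn.Linear(8, 2, rng=rng)

    def __call__(self, x):
        return self.fc(nn.global_avg_pool(nn.relu(self.bn(self.conv(x)))))


def _toy_blob_set(n=24, size=32, seed=0):
    """Images separable by a bright square present/absent."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n):
        img = 0.3 + 0.05 * rng.standard_normal((size, size))
        y = i % 2
        if y:
            r, c = rng.integers(4, size - 8, 2)
            img[r : r + 4, c : c + 4] += 0.6
        images.append(np.clip(img, 0, 1))
        labels.append(y)
    return images, np.array(labels)


class TestTrainClassifier:
    def test_separable_toy_reaches_high_training_accuracy(self):
        """A small CNN fits a trivially separable image set."""
        images, labels = _toy_blob_set()
        model = _TinyCNN(seed=0)
        spec = TrainSpec(max_epochs=30, learning_rate=2e-2, batch_size=8,
                         l2_weight=1e-4, seed=1)
        model, history = train_classifier(model, images, labels, spec, augment_spec=None)
        assert len(history) <= spec.max_epochs
        scores = predict_scores(model, images)
        acc = ((scores >= 0.5).astype(int) == labels).mean()
        assert acc >= 0.9
        assert history[-1] < history[0]

    def test_single_class_rejected(self):
        images, labels = _toy_blob_set(8)
        model = models.build_reference("squeezenet", 32, seed=0)
        with pytest.raises(ValueError):
            train_classifier(model, images, np.ones_like(labels),
                             TrainSpec(max_epochs=1), None)

    def test_l2_penalty_reduces_weight_norm(self):
        images, labels = _toy_blob_set(12)

        def norm_after(l2):
            model = models.build_reference("squeezenet", 32, seed=3)
            spec = TrainSpec(max_epochs=5, learning_rate=1e-2, batch_size=6,
                             l2_weight=l2, seed=2)
            train_classifier(model, images, labels, spec, None)
            return float(sum((p.data ** 2).sum() for p in model.parameters()))

        assert norm_after(5e-2) < norm_after(0.0)

    def test_deterministic_given_seed(self):
        images, labels = _toy_blob_set(8)
        outs = []
        for _ in range(2):
            model = models.build_reference("squeezenet", 32, seed=5)
            spec = TrainSpec(max_epochs=2, learning_rate=1e-3, batch_size=4, seed=9)
            train_classifier(model, images, labels, spec, AugmentSpec(seed=1))
            outs.append(predict_scores(model, images))
        assert np.array_equal(outs[0], outs[1])


def test_evaluate_scores_consistency():
    scores = [0.9, 0.2, 0.7, 0.4]
    labels = [1, 0, 1, 0]
    res = evaluate_scores(scores, labels)
    assert res.auc == 1.0
    assert res.sensitivity == 1.0 and res.specificity == 1.0 and res.accuracy == 1.0
    assert np.isclose(np.trapezoid(res.tpr, res.fpr), res.auc)
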