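import numpy as np
import pytest

from bioradar import (CompressionStateNet, TrainConfig, augment_dataset,
                      metrics_from_confusion, train_and_evaluate)
from bioradar import nn


def toy_images(n_per_class=8, size=32, seed=0):
    """Five distinct constant images per class, trivially separable."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cls in range(5):
        base = np.zeros((3, size, size), np.float32)
        base[cls % 3] = (cls + 1) / 6
        for _ in range(n_per_class):
            images.append(base + rng.normal(0, 0.01, base.shape)
                          .astype(np.float32))
            labels.append(cls)
    return np.array(images), np.array(labels)


class TestNetwork:
    def test_forward_outputs_probabilities(self):
        net = CompressionStateNet(32, seed=0)
        x = np.random.default_rng(0).random((4, 3, 32, 32)).astype(
            np.float32)
        proba = net.predict_proba(x)
        assert proba.shape == (4, 5)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (proba >= 0).all()

    def test_multiscale_concat_is_64_channels(self):
        """The three branch outputs (16 + 32 + 16) feed a 64-channel
        attention stage whose gates are exposed."""
        net = CompressionStateNet(32, seed=0)
        x = np.random.default_rng(1).random((2, 3, 32, 32)).astype(
            np.float32)
        net.forward(x)
        assert net.se.last_gate.shape == (2, 64)
        assert net.a1.c_out + net.b3.c_out + net.c3.c_out == 64

    def test_residual_connection_is_live(self):
        net = CompressionStateNet(32, seed=0)
        x = np.random.default_rng(2).random((2, 3, 32, 32)).astype(
            np.float32)
        with_skip = net.forward(x)
        net.residual_scale = 0.0
        without_skip = net.forward(x)
        assert not np.allclose(with_skip, without_skip)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            CompressionStateNet(16)

    def test_gradients_match_numerical(self):
        """Spot-check backprop through the full network against a
        central finite difference on one weight and one input pixel."""
        net = CompressionStateNet(32, seed=3)
        rng = np.random.default_rng(3)
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        y = np.array([1, 4])

        logits = net.forward(x)
        _, grad = nn.softmax_cross_entropy(logits, y)
        net.backward(grad)
        w, gw = net.t1.params[0]
        idx = (1, 1, 3, 5)
        analytic = gw[idx]
        eps = 1e-2
        orig = w[idx]
        w[idx] = orig + eps
        lp, _ = nn.softmax_cross_entropy(net.forward(x), y)
        w[idx] = orig - eps
        lm, _ = nn.softmax_cross_entropy(net.forward(x), y)
        w[idx] = orig
        numeric = (lp - lm) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=0.05, abs=1e-4)


class TestAugmentation:
    def test_factor_one_is_identity(self):
        imgs, labels = toy_images(2)
        out_i, out_l = augment_dataset(imgs, labels, factor=1)
        assert np.array_equal(out_i, imgs)
        assert np.array_equal(out_l, labels)

    def test_factor_three_triples_the_set(self):
        imgs, labels = toy_images(4)
        out_i, out_l = augment_dataset(imgs, labels, factor=3,
                                       noise_sigma=0.05, seed=0)
        assert len(out_i) == 3 * len(imgs)
        assert np.array_equal(out_i[: len(imgs)], imgs)  # originals kept
        assert np.array_equal(out_l, np.tile(labels, 3))

    def test_zero_noise_duplicates_exactly(self):
        imgs, labels = toy_images(2)
        out_i, _ = augment_dataset(imgs, labels, factor=2, noise_sigma=0.0)
        assert np.array_equal(out_i[len(imgs):], imgs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_dataset(np.empty((0, 3, 8, 8)), np.empty(0), factor=2)


class TestMetrics:
    def test_confusion_derived_metrics(self):
        cm = np.array([[5, 1], [2, 4]])
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(9 / 12)
        assert m["recall"][0] == pytest.approx(5 / 6)
        assert m["precision"][1] == pytest.approx(4 / 5)

    def test_matches_sklearn(self):
        """Cross-check against the reference metric implementations."""
        from sklearn.metrics import (confusion_matrix, f1_score,
                                     precision_score, recall_score)

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        cm = confusion_matrix(y_true, y_pred, labels=range(5))
        m = metrics_from_confusion(cm)
        assert m["macro_f1"] == pytest.approx(
            f1_score(y_true, y_pred, average="macro"), abs=1e-12)
        assert m["recall"] == pytest.approx(
            recall_score(y_true, y_pred, average=None).tolist())
        assert m["precision"] == pytest.approx(
            precision_score(y_true, y_pred, average=None,
                            zero_division=0).tolist())


class TestTraining:
    def test_separable_toy_dataset_is_learned(self):
        images, labels = toy_images(8)
        cfg = TrainConfig(epochs=20, seed=0, patience=20, augment_factor=1,
                          val_fraction=0.0)
        result = train_and_evaluate(images, labels, cfg)
        assert result["accuracy"] == 1.0
        # loss decreases over the first epochs
        losses = result["history"]["train_loss"]
        assert losses[min(4, len(losses) - 1)] < losses[0]

    def test_confusion_rows_sum_to_class_counts(self):
        images, labels = toy_images(6)
        cfg = TrainConfig(epochs=3, seed=1, augment_factor=1,
                          val_fraction=0.0)
        result = train_and_evaluate(images, labels, cfg)
        cm = result["confusion"]
        assert cm.sum() == result["n_test"]
        # the stratified split leaves at least one test sample per class
        assert (cm.sum(axis=1) >= 1).all()
        assert result["accuracy"] == pytest.approx(
            np.trace(cm) / cm.sum())

    def test_missing_class_rejected(self):
        images, labels = toy_images(4)
        keep = labels != 2
        with pytest.raises(ValueError):
            train_and_evaluate(images[keep], labels[keep], TrainConfig())
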