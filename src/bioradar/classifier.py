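"""Compression-state recognition network and its training protocol.

The network fuses three parallel convolution branches of different
receptive fields (1x1 -> 16 channels; 3x3,5x5,1x1 -> 32; 5x5,3x3,1x1
-> 16), applies squeeze-and-excitation channel attention to the 64
concatenated feature channels, reduces them to 32 with a 1x1
convolution, passes them through an inception-style residual block
(parallel 1x1 / 1x1+3x3 / 1x1+5x5 / pool+1x1 branches, merged by a
linear 1x1 convolution and added to the block input), and finishes
with 3x3 convolutions to 128 and 256 channels, pooling, and a dense
softmax over the five compression states.  Stride-2 max pooling after
the attention stage, the residual block and the tail convolutions
shrinks the spatial grid.

Training follows the dataset protocol used for radar scalogram
classification: a stratified 8:2 train/test split, training-set-only
augmentation by adding pixel noise (tripling the training set), Adam
with cross-entropy, and early stopping on a validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import nn

__all__ = [
    "N_CLASSES", "TrainConfig", "CompressionStateNet",
    "augment_dataset", "metrics_from_confusion", "train_and_evaluate",
]

N_CLASSES = 5


@dataclass(frozen=True)
class TrainConfig:
    """Split, augmentation and optimizer settings."""

    test_fraction: float = 0.2  # the 8:2 protocol
    augment_factor: int = 3
    noise_sigma: float = 0.05  # fraction of the [0, 1] pixel range
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    val_fraction: float = 0.1  # carved from the training split
    patience: int = 5  # early stopping on validation loss
    seed: int = 0


class CompressionStateNet:
    """Multiscale + attention + inception-residual classifier."""

    def __init__(self, image_size: int = 64, seed: int = 0):
        if image_size < 32:
            raise ValueError("image_size must be >= 32")
        if image_size % 8 != 0:
            raise ValueError("image_size must be divisible by 8")
        rng = np.random.default_rng(seed)
        C = nn.Conv2d
        self.image_size = image_size
        # multiscale branches (input 3 channels)
        self.a1 = C(3, 16, 1, rng)
        self.b1, self.b2, self.b3 = C(3, 8, 3, rng), C(8, 16, 5, rng), \
            C(16, 32, 1, rng)
        self.c1, self.c2, self.c3 = C(3, 8, 5, rng), C(8, 8, 3, rng), \
            C(8, 16, 1, rng)
        self.se = nn.SEBlock(64, rng, reduction=4)
        self.pool1 = nn.MaxPool2d(3, 2, 1)
        self.reduce = C(64, 32, 1, rng)
        # inception-residual block (32 -> 32)
        self.ia = C(32, 32, 1, rng)
        self.ib1, self.ib2 = C(32, 16, 1, rng), C(16, 32, 3, rng)
        self.ic1, self.ic2 = C(32, 16, 1, rng), C(16, 32, 5, rng)
        self.id_pool = nn.MaxPool2d(3, 1, 1)
        self.id_conv = C(32, 32, 1, rng)
        self.merge = C(128, 32, 1, rng)  # linear, then residual add
        self.pool2 = nn.MaxPool2d(3, 2, 1)
        # tail
        self.t1 = C(32, 128, 3, rng)
        self.t2 = C(128, 256, 3, rng)
        self.pool3 = nn.MaxPool2d(3, 2, 1)
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Dense(256, N_CLASSES, rng)

        self._convs = [self.a1, self.b1, self.b2, self.b3, self.c1, self.c2,
                       self.c3, self.reduce, self.ia, self.ib1, self.ib2,
                       self.ic1, self.ic2, self.id_conv, self.merge,
                       self.t1, self.t2]
        self.params = sum((l.params for l in self._convs), []) \
            + self.se.params + self.fc.params
        self._relus = {}
        self.residual_scale = 1.0  # set to 0 to ablate the skip connection

    def n_parameters(self) -> int:
        return int(sum(w.size for w, _ in self.params))

    def _relu(self, name, x):
        mask = x > 0
        self._relus[name] = mask
        return x * mask

    def forward(self, x):
        """(B, 3, S, S) float32 -> logits (B, 5)."""
        x = np.ascontiguousarray(  # to NHWC for the conv layers
            np.transpose(np.asarray(x, dtype=np.float32), (0, 2, 3, 1)))
        a = self._relu("a1", self.a1.forward(x))
        b = self._relu("b1", self.b1.forward(x))
        b = self._relu("b2", self.b2.forward(b))
        b = self._relu("b3", self.b3.forward(b))
        c = self._relu("c1", self.c1.forward(x))
        c = self._relu("c2", self.c2.forward(c))
        c = self._relu("c3", self.c3.forward(c))
        cat = np.concatenate([a, b, c], axis=3)  # 16+32+16 = 64 channels
        att = self.se.forward(cat)
        p1 = self.pool1.forward(att)
        r = self._relu("reduce", self.reduce.forward(p1))
        self._res_in = r
        ba = self._relu("ia", self.ia.forward(r))
        bb = self._relu("ib1", self.ib1.forward(r))
        bb = self._relu("ib2", self.ib2.forward(bb))
        bc = self._relu("ic1", self.ic1.forward(r))
        bc = self._relu("ic2", self.ic2.forward(bc))
        bd = self.id_pool.forward(r)
        bd = self._relu("id", self.id_conv.forward(bd))
        icat = np.concatenate([ba, bb, bc, bd], axis=3)  # 128 channels
        res = self.merge.forward(icat) + self.residual_scale * r
        res = self._relu("res", res)
        p2 = self.pool2.forward(res)
        t = self._relu("t1", self.t1.forward(p2))
        t = self._relu("t2", self.t2.forward(t))
        p3 = self.pool3.forward(t)
        z = self.gap.forward(p3)
        return self.fc.forward(z)

    def backward(self, grad_logits):
        g = self.fc.backward(grad_logits)
        g = self.gap.backward(g)
        g = self.pool3.backward(g)
        g = self.t2.backward(g * self._relus["t2"])
        g = self.t1.backward(g * self._relus["t1"])
        g = self.pool2.backward(g)
        g = g * self._relus["res"]
        gi = self.merge.backward(g)
        g_res = self.residual_scale * g
        ga, gb, gc, gd = np.split(gi, [32, 64, 96], axis=3)
        g_r = self.ia.backward(ga * self._relus["ia"])
        t = self.ib2.backward(gb * self._relus["ib2"])
        g_r += self.ib1.backward(t * self._relus["ib1"])
        t = self.ic2.backward(gc * self._relus["ic2"])
        g_r += self.ic1.backward(t * self._relus["ic1"])
        t = self.id_conv.backward(gd * self._relus["id"])
        g_r += self.id_pool.backward(t)
        g_r += g_res
        g = self.reduce.backward(g_r * self._relus["reduce"])
        g = self.pool1.backward(g)
        g = self.se.backward(g)
        ga, gb, gc = np.split(g, [16, 48], axis=3)
        self.a1.backward(ga * self._relus["a1"])
        t = self.b3.backward(gb * self._relus["b3"])
        t = self.b2.backward(t * self._relus["b2"])
        self.b1.backward(t * self._relus["b1"])
        t = self.c3.backward(gc * self._relus["c3"])
        t = self.c2.backward(t * self._relus["c2"])
        self.c1.backward(t * self._relus["c1"])

    def predict_proba(self, images, batch_size=64):
        out = []
        for i in range(0, len(images), batch_size):
            out.append(nn.softmax(self.forward(images[i:i + batch_size])))
        return np.concatenate(out, axis=0)

    def predict(self, images, batch_size=64):
        return np.argmax(self.predict_proba(images, batch_size), axis=1)

    def state_dict(self):
        return [w.copy() for w, _ in self.params]

    def load_state_dict(self, state):
        for (w, _), saved in zip(self.params, state):
            w[...] = saved


def augment_dataset(images, labels, factor=3, noise_sigma=0.05, seed=0):
    """Expand a labelled image set ``factor`` times by adding noise.

    The originals are preserved; each extra copy gets i.i.d. Gaussian
    pixel noise of scale ``noise_sigma`` (fraction of the [0, 1] pixel
    range), clipped back to [0, 1].  Labels are carried over.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if images.shape[0] == 0:
        raise ValueError("empty dataset")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out_i, out_l = [images], [labels]
    for _ in range(factor - 1):
        if noise_sigma == 0:
            out_i.append(images.copy())
        else:
            noisy = images + rng.normal(
                0.0, noise_sigma, size=images.shape).astype(np.float32)
            out_i.append(np.clip(noisy, 0.0, 1.0))
        out_l.append(labels)
    return np.concatenate(out_i, axis=0), np.concatenate(out_l, axis=0)


def metrics_from_confusion(confusion) -> dict:
    """Accuracy, per-class recall/precision, macro-F1 from a confusion
    matrix whose rows are true classes and columns predictions."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom,
                   out=np.zeros_like(denom), where=denom > 0)
    return {
        "accuracy": float(diag.sum() / total),
        "recall": recall.tolist(),
        "precision": precision.tolist(),
        "macro_f1": float(f1.mean()),
    }


def _train(model, x_tr, y_tr, x_val, y_val, cfg):
    opt = nn.Adam(model.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    history = {"train_loss": [], "val_loss": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(x_tr[idx])
            loss, grad = nn.softmax_cross_entropy(logits, y_tr[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if len(x_val):
            logits = np.concatenate(
                [model.forward(x_val[j:j + 64])
                 for j in range(0, len(x_val), 64)])
            val_loss, _ = nn.softmax_cross_entropy(logits, y_val)
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return history


def train_and_evaluate(images, labels, cfg: TrainConfig = TrainConfig(),
                       model: CompressionStateNet | None = None) -> dict:
    """Stratified 8:2 split, train with augmentation, report test metrics.

    Returns a dict with the confusion matrix, accuracy, per-class
    recall/precision, macro-F1, the loss history and the trained model.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=N_CLASSES)
    if (counts < 2).any():
        raise ValueError(
            "every one of the five states needs >= 2 samples; got "
            f"counts {counts.tolist()}")
    x_tr, x_te, y_tr, y_te = train_test_split(
        images, labels, test_size=cfg.test_fraction,
        stratify=labels, random_state=cfg.seed)
    if cfg.val_fraction > 0 and len(x_tr) >= 20:
        x_tr, x_val, y_tr, y_val = train_test_split(
            x_tr, y_tr, test_size=cfg.val_fraction,
            stratify=y_tr, random_state=cfg.seed)
    else:
        x_val = x_tr[:0]
        y_val = y_tr[:0]
    x_tr, y_tr = augment_dataset(
        x_tr, y_tr, cfg.augment_factor, cfg.noise_sigma, cfg.seed)

    if model is None:
        model = CompressionStateNet(image_size=images.shape[-1],
                                    seed=cfg.seed)
    history = _train(model, x_tr, y_tr, x_val, y_val, cfg)

    pred = model.predict(x_te)
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (y_te, pred), 1)
    metrics = metrics_from_confusion(cm)
    metrics.update(confusion=cm, history=history, model=model,
                   n_test=len(y_te), n_train=len(y_tr))
    return metrics
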