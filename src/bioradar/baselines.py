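"""Comparison methods: an SVM on hand-crafted respiratory features and
a 1-D CNN operating directly on the reconstructed life signal.

The SVM sees a 10-dimensional respiratory feature vector computed from
breath peaks and troughs of the band-limited respiration waveform.
Five of the features follow the established radar-respiration set
(mean respiratory amplitude, linear peak deviation, mean expiration
and inspiration velocities, mean breath interval); the other five are
supplementary features defined here (respiratory rate, amplitude
variance, expiration/inspiration asymmetry, respiration-band spectral
centroid, heart/respiration band-power ratio) and are not canonical.

The 1-D CNN has four convolution layers, four pooling layers and a
flattened dense softmax head over the five states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import nn
from .classifier import N_CLASSES, metrics_from_confusion
from .preprocessing import SlowTimeSignal
from .timefrequency import HEART_BAND, RESP_BAND, bandpass, dominant_frequency

__all__ = [
    "FEATURE_NAMES", "extract_respiratory_features",
    "Cnn1d", "run_baselines", "cross_dataset_protocol",
]

FEATURE_NAMES = (
    "mean_resp_amplitude",
    "linear_peak_deviation",
    "mean_expiration_velocity",
    "mean_inspiration_velocity",
    "mean_breath_interval",
    # supplementary, non-canonical:
    "respiratory_rate_hz",
    "amplitude_variance",
    "exp_insp_asymmetry",
    "resp_band_spectral_centroid",
    "heart_resp_power_ratio",
)


def _band_power(x, fs, band):
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].sum()), freqs[sel], spec[sel]


def extract_respiratory_features(signal: SlowTimeSignal) -> np.ndarray:
    """10 breath-morphology features from the respiration-band signal.

    Raises ``ValueError`` when no breath cycle can be detected.
    """
    fs = signal.slow_rate
    if signal.values.size / fs < 10:
        raise ValueError("need at least 10 s of signal")
    resp = bandpass(signal, RESP_BAND).values
    scale = np.std(resp)
    swing = np.max(np.abs(signal.values - signal.values.mean()))
    if swing == 0 or scale <= 1e-9 * swing:
        raise ValueError("no detectable breaths: respiration band is silent")
    # breaths cannot be closer than 1/f_hi of the respiration band
    min_dist = max(int(fs / RESP_BAND[1]), 1)
    peaks, _ = find_peaks(resp, distance=min_dist, prominence=0.5 * scale)
    troughs, _ = find_peaks(-resp, distance=min_dist, prominence=0.5 * scale)
    if peaks.size < 2 or troughs.size < 1:
        raise ValueError(
            f"no detectable breaths ({peaks.size} peaks, "
            f"{troughs.size} troughs)")

    # pair each peak with the nearest following trough (expiration) and
    # the nearest preceding trough (end of the previous inspiration)
    exp_vel, insp_vel, amps = [], [], []
    for p in peaks:
        nxt = troughs[troughs > p]
        prv = troughs[troughs < p]
        if nxt.size:
            t = nxt[0]
            amps.append(resp[p] - resp[t])
            exp_vel.append((resp[p] - resp[t]) / ((t - p) / fs))
        if prv.size:
            t = prv[-1]
            insp_vel.append((resp[p] - resp[t]) / ((p - t) / fs))
    if not amps:
        amps = [resp[peaks].mean() - resp[troughs].mean()]
    peak_times = peaks / fs
    intervals = np.diff(peak_times)

    # linear peak deviation: scatter of peak heights about a linear trend
    coef = np.polyfit(peak_times, resp[peaks], 1)
    peak_resid = resp[peaks] - np.polyval(coef, peak_times)

    p_resp, f_sel, s_sel = _band_power(signal.values, fs, RESP_BAND)
    p_heart, _, _ = _band_power(signal.values, fs, HEART_BAND)
    centroid = float((f_sel * s_sel).sum() / s_sel.sum()) if p_resp > 0 \
        else 0.0

    feats = np.array([
        float(np.mean(amps)),
        float(np.std(peak_resid)),
        float(np.mean(exp_vel)) if exp_vel else 0.0,
        float(np.mean(insp_vel)) if insp_vel else 0.0,
        float(np.mean(intervals)),
        dominant_frequency(signal, RESP_BAND),
        float(np.var(amps)),
        float(np.mean(exp_vel) / np.mean(insp_vel))
        if exp_vel and insp_vel and np.mean(insp_vel) != 0 else 1.0,
        centroid,
        float(p_heart / p_resp) if p_resp > 0 else 0.0,
    ])
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite respiratory feature")
    return feats


class Cnn1d:
    """Four conv + four pool layers, flatten, dense softmax over 5."""

    def __init__(self, n_samples: int, seed: int = 0,
                 channels=(16, 32, 64, 128), kernel: int = 7):
        rng = np.random.default_rng(seed)
        self.layers = []
        c_prev = 1
        n = n_samples
        for c in channels:
            self.layers.append(nn.Conv1d(c_prev, c, kernel, rng))
            self.layers.append(nn.ReLU())
            self.layers.append(nn.MaxPool1d(2))
            c_prev = c
            n = n // 2
        self.flat_dim = c_prev * n
        self.fc = nn.Dense(self.flat_dim, N_CLASSES, rng)
        self.params = sum((l.params for l in self.layers), []) + \
            self.fc.params

    def forward(self, x):
        h = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h)
        self._h_shape = h.shape
        return self.fc.forward(h.reshape(h.shape[0], -1))

    def backward(self, grad):
        g = self.fc.backward(grad).reshape(self._h_shape)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict(self, x, batch_size=128):
        out = []
        for i in range(0, len(x), batch_size):
            out.append(np.argmax(self.forward(x[i:i + batch_size]), axis=1))
        return np.concatenate(out)


def _confusion(y_true, y_pred):
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
    return cm


def _fit_svm(features_tr, y_tr, seed):
    clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0))
    clf.fit(features_tr, y_tr)
    return clf


def _fit_cnn1d(x_tr, y_tr, seed, epochs=30, batch_size=32, lr=1e-3):
    x_tr = np.asarray(x_tr, dtype=np.float32)
    # per-signal standardization
    x = (x_tr - x_tr.mean(axis=1, keepdims=True)) / (
        x_tr.std(axis=1, keepdims=True) + 1e-8)
    x = x[:, None, :]
    net = Cnn1d(x.shape[-1], seed=seed)
    opt = nn.Adam(net.params, lr=lr)
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            logits = net.forward(x[idx])
            _, grad = nn.softmax_cross_entropy(logits, np.asarray(y_tr)[idx])
            net.backward(grad)
            opt.step()
    return net


def _cnn1d_predict(net, signals):
    x = np.asarray(signals, dtype=np.float32)
    x = (x - x.mean(axis=1, keepdims=True)) / (
        x.std(axis=1, keepdims=True) + 1e-8)
    return net.predict(x[:, None, :])


def run_baselines(signals, labels, slow_rate: float, seed: int = 0,
                  test_fraction: float = 0.2,
                  cnn_epochs: int = 30) -> dict:
    """Train and evaluate both baselines with the stratified 8:2 split.

    ``signals`` is an (N, T) array of reconstructed life signals.
    Returns ``{"svm": metrics, "cnn1d": metrics}`` with confusion
    matrices and the derived accuracy/recall/precision/macro-F1.
    """
    signals = np.asarray(signals, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes")
    x_tr, x_te, y_tr, y_te = train_test_split(
        signals, labels, test_size=test_fraction, stratify=labels,
        random_state=seed)

    feats_tr = np.array([
        extract_respiratory_features(SlowTimeSignal(s, slow_rate))
        for s in x_tr])
    feats_te = np.array([
        extract_respiratory_features(SlowTimeSignal(s, slow_rate))
        for s in x_te])
    svm = _fit_svm(feats_tr, y_tr, seed)
    svm_metrics = metrics_from_confusion(
        _confusion(y_te, svm.predict(feats_te)))

    net = _fit_cnn1d(x_tr, y_tr, seed, epochs=cnn_epochs)
    cnn_metrics = metrics_from_confusion(
        _confusion(y_te, _cnn1d_predict(net, x_te)))
    return {"svm": svm_metrics, "cnn1d": cnn_metrics}


def cross_dataset_protocol(signals, labels, slow_rate: float,
                           seed: int = 0, cnn_epochs: int = 30) -> dict:
    """A/B/C protocol: split into three parts, train on A, test on B, C.

    Returns ``{"svm": {"A-B": acc, "A-C": acc}, "cnn1d": {...}}``.
    """
    signals = np.asarray(signals, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rest, part_a, y_rest, y_a = train_test_split(
        signals, labels, test_size=1 / 3, stratify=labels, random_state=seed)
    part_b, part_c, y_b, y_c = train_test_split(
        rest, y_rest, test_size=0.5, stratify=y_rest, random_state=seed)

    fa = np.array([extract_respiratory_features(SlowTimeSignal(s, slow_rate))
                   for s in part_a])
    svm = _fit_svm(fa, y_a, seed)
    net = _fit_cnn1d(part_a, y_a, seed, epochs=cnn_epochs)

    out = {"svm": {}, "cnn1d": {}}
    for name, xs, ys in (("A-B", part_b, y_b), ("A-C", part_c, y_c)):
        fx = np.array([
            extract_respiratory_features(SlowTimeSignal(s, slow_rate))
            for s in xs])
        out["svm"][name] = metrics_from_confusion(
            _confusion(ys, svm.predict(fx)))["accuracy"]
        out["cnn1d"][name] = metrics_from_confusion(
            _confusion(ys, _cnn1d_predict(net, xs)))["accuracy"]
    return out
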