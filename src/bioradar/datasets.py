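"""Labelled synthetic datasets for training and evaluating the
compression-state classifiers.

Each sample draws one subject's ground truth for a state, synthesizes
the chest-motion slow-time signal (the quantity the radar's target-bin
trace is proportional to after preprocessing), adds white noise at the
requested SNR, and renders the Morlet scalogram image.  The same
signals feed the 1-D CNN and SVM baselines so that all three methods
see identical data.  An optional full-chain mode instead pushes a
complete simulated echo matrix through preprocessing, VMD and
permutation-entropy reconstruction before the scalogram — closer to
the deployed pipeline but considerably slower, so the direct path is
the default for dataset-scale generation.
"""

from __future__ import annotations

import numpy as np

from .mode_selection import PEConfig, reconstruct_life_signal
from .preprocessing import SlowTimeSignal, preprocess
from .simulate import RadarConfig, StateLabel, sample_truth, \
    simulate_displacement, simulate_echo_matrix
from .timefrequency import cwt_scalogram, render_image
from .vmd import VMDParams, vmd_decompose

__all__ = ["CLASS_ORDER", "make_signal_dataset", "make_scalogram_dataset"]

#: Fixed label order: index in this tuple is the integer class id.
CLASS_ORDER = (
    StateLabel.SUPINE_NO_COMPRESSION,
    StateLabel.SUPINE_COMPRESSION,
    StateLabel.PRONE_NO_COMPRESSION,
    StateLabel.PRONE_COMPRESSION,
    StateLabel.NO_TARGET,
)


def _noisy_vitals_signal(truth, cfg, snr_db, rng):
    if truth.state_label is StateLabel.NO_TARGET:
        # noise floor matched to the average vitals power of the other
        # classes so "empty scene" is not trivially quieter
        ref = 1e-3 / np.sqrt(2)
        return rng.normal(0.0, ref, size=cfg.n_slow)
    d = simulate_displacement(truth, cfg, seed=rng)
    x = d - d.mean()
    sigma = np.sqrt(np.var(x) * 10 ** (-snr_db / 10))
    return x + rng.normal(0.0, sigma, size=x.size)


def _full_chain_signal(truth, cfg, snr_db, rng, vmd_params, pe_cfg):
    echo = simulate_echo_matrix(
        truth, cfg, clutter_spec=[(0.6, 0.8)], snr_db=snr_db,
        seed=int(rng.integers(2**31)))
    _, _, raw_sig = preprocess(echo)
    if truth.state_label is StateLabel.NO_TARGET:
        return raw_sig.values
    imfs = vmd_decompose(raw_sig, vmd_params)
    life, _ = reconstruct_life_signal(imfs, pe_cfg)
    return life.values


def make_signal_dataset(
    n_per_class: int,
    cfg: RadarConfig | None = None,
    snr_db: float = 0.0,
    seed: int = 0,
    full_chain: bool = False,
    vmd_params: VMDParams = VMDParams(K=4, alpha=1053.0),
    pe_cfg: PEConfig = PEConfig(),
):
    """(signals (N, T), labels (N,)) with ``n_per_class`` per state."""
    cfg = cfg or RadarConfig()
    rng = np.random.default_rng(seed)
    signals, labels = [], []
    for class_id, state in enumerate(CLASS_ORDER):
        for _ in range(n_per_class):
            truth = sample_truth(state, cfg, rng)
            if full_chain:
                sig = _full_chain_signal(truth, cfg, snr_db, rng,
                                         vmd_params, pe_cfg)
            else:
                sig = _noisy_vitals_signal(truth, cfg, snr_db, rng)
            signals.append(sig)
            labels.append(class_id)
    return np.asarray(signals), np.asarray(labels)


def make_scalogram_dataset(
    n_per_class: int,
    image_size: int = 32,
    cfg: RadarConfig | None = None,
    snr_db: float = 0.0,
    seed: int = 0,
    full_chain: bool = False,
    return_signals: bool = False,
):
    """Scalogram images (N, 3, S, S) plus integer labels.

    ``return_signals=True`` additionally returns the underlying
    slow-time signals, so the baselines can be trained on exactly the
    same draws.
    """
    cfg = cfg or RadarConfig()
    signals, labels = make_signal_dataset(
        n_per_class, cfg, snr_db=snr_db, seed=seed, full_chain=full_chain)
    images = np.empty((len(signals), 3, image_size, image_size),
                      dtype=np.float32)
    for i, sig in enumerate(signals):
        scal = cwt_scalogram(SlowTimeSignal(sig, cfg.slow_rate))
        images[i] = render_image(scal, size=image_size)
    if return_signals:
        return images, labels, signals
    return images, labels
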