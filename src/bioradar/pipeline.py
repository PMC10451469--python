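"""End-to-end composition: preprocess -> (PSO) -> VMD -> permutation
entropy reconstruction -> time-frequency analysis -> classification.

``run_pipeline`` consumes a raw echo matrix, persists every
intermediate artifact to a run directory when one is given, and
returns a JSON-serializable report: located range, chosen (alpha, K),
kept-mode mask, respiration/heart rates, and — when a trained model is
supplied — class probabilities for the five compression states.

Long recordings are analysed in 30 s windows with 50 % overlap and the
per-window rate estimates are reduced to their medians.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import CLASS_ORDER
from .mode_selection import PEConfig, reconstruct_life_signal
from .preprocessing import EchoMatrix, SlowTimeSignal, preprocess
from .pso import PSOConfig, pso_optimize
from .timefrequency import (HEART_BAND, RESP_BAND, cwt_scalogram,
                            dominant_frequency, render_image)
from .vmd import VMDParams, vmd_decompose

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a run, serialized alongside it.

    ``alpha``/``K`` are used when ``use_pso`` is off; 1053 and 4 are
    the optimum reported for the instrument this package emulates and
    are a starting point, not a universal constant.
    """

    use_pso: bool = False
    alpha: float = 1053.0
    K: int = 4
    vmd: VMDParams = VMDParams()
    pso: PSOConfig = PSOConfig()
    pe: PEConfig = PEConfig()
    compensation: bool = True
    window_seconds: float = 30.0
    window_overlap: float = 0.5
    image_size: int = 64
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _windows(n: int, w: int, overlap: float):
    if n <= w:
        return [(0, n)]
    step = max(int(w * (1 - overlap)), 1)
    spans = [(s, s + w) for s in range(0, n - w + 1, step)]
    if spans[-1][1] < n:
        spans.append((n - w, n))
    return spans


def run_pipeline(
    echo: EchoMatrix,
    cfg: RunConfig = RunConfig(),
    model=None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full recognition chain on one raw acquisition."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(cfg.to_dict(), indent=2, default=str))

    report: dict = {"stages": []}
    try:
        d2, curve, raw_signal = preprocess(echo, cfg.compensation)
        report["stages"].append("preprocess")
        report["target_bin"] = int(curve.argmax_bin)
        report["radial_distance_m"] = float(curve.radial_distance)
        if out is not None:
            np.savetxt(out / "energy.csv", curve.values, delimiter=",")
            raw_signal.to_csv(out / "signal_raw.csv")

        w = int(round(cfg.window_seconds * raw_signal.slow_rate))
        spans = _windows(raw_signal.values.size, w, cfg.window_overlap)

        alpha, K = cfg.alpha, cfg.K
        if cfg.use_pso:
            first = SlowTimeSignal(raw_signal.values[spans[0][0]:spans[0][1]],
                                   raw_signal.slow_rate)
            alpha, K, fit_report, trace = pso_optimize(
                first, cfg.pso, cfg.vmd)
            report["pso"] = {"fitness": fit_report.fitness,
                             "trace": [float(t) for t in trace]}
            report["stages"].append("pso")
        report["alpha"] = float(alpha)
        report["K"] = int(K)

        params = dataclasses.replace(cfg.vmd, alpha=float(alpha), K=int(K))
        resp_hz, heart_hz, masks = [], [], []
        life_full = np.zeros_like(raw_signal.values)
        weight = np.zeros_like(raw_signal.values)
        for s0, s1 in spans:
            win_sig = SlowTimeSignal(raw_signal.values[s0:s1],
                                     raw_signal.slow_rate)
            imfs = vmd_decompose(win_sig, params)
            life, kept = reconstruct_life_signal(imfs, cfg.pe)
            masks.append([bool(k) for k in kept])
            life_full[s0:s1] += life.values
            weight[s0:s1] += 1.0
            resp_hz.append(dominant_frequency(life, RESP_BAND))
            heart_hz.append(dominant_frequency(life, HEART_BAND))
        life_full /= np.maximum(weight, 1.0)
        life_signal = SlowTimeSignal(life_full, raw_signal.slow_rate)
        report["stages"] += ["vmd", "mode_selection"]
        report["kept_mode_masks"] = masks
        report["resp_hz"] = float(np.median(resp_hz))
        report["heart_hz"] = float(np.median(heart_hz))
        report["resp_rate_bpm"] = report["resp_hz"] * 60.0
        report["heart_rate_bpm"] = report["heart_hz"] * 60.0
        if out is not None:
            life_signal.to_csv(out / "life_signal.csv")

        scal = cwt_scalogram(life_signal)
        image = render_image(scal, size=cfg.image_size)
        report["stages"].append("timefrequency")
        if out is not None:
            np.save(out / "scalogram_image.npy", image)

        if model is not None:
            proba = model.predict_proba(image[None])[0]
            pred = int(np.argmax(proba))
            report["class_probabilities"] = {
                CLASS_ORDER[i].value: float(p) for i, p in enumerate(proba)}
            report["predicted_state"] = CLASS_ORDER[pred].value
            report["stages"].append("classify")
    except Exception as err:  # surface the failing stage, keep artifacts
        report["error"] = f"after {report['stages']}: {err}"
        if out is not None:
            (out / "report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True))
        raise

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    report["life_signal"] = life_signal
    report["scalogram_image"] = image
    return report
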