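# bioradar

Non-contact vital-sign extraction and compression-state recognition
from ultra-wideband (UWB) bio-radar echoes.

After a building collapse, people trapped under rubble are at risk of
crush syndrome: releasing a compressed casualty without preparation
can trigger reperfusion injury, rhabdomyolysis and organ failure.
A through-obstacle bio-radar can find casualties by their breathing
and heartbeat and — from the shape of the recovered breathing signal —
indicate *how* they are trapped (supine/prone, compressed or not), so
rescue and medical teams can plan extraction.  `bioradar` implements
that processing chain end-to-end and bundles a synthetic echo
simulator with known ground truth, so everything is testable without
human-subject data.

## The method

Starting from a raw fast-time × slow-time echo matrix `D` (93 range
bins × N frames at 17 Hz):

1. **Preprocessing** — static clutter removal
   `D1[m,n] = D[m,n] − mean_n D[m,·]`, per-bin min–max attenuation
   compensation, and target localization at the argmax of the per-bin
   slow-time energy `E_m = Σ_n D[m,n]²`; the slow-time signal `s(t)`
   is read at the located bin.
2. **Variational mode decomposition (VMD)** — `s(t)` is split into K
   narrow-band modes `c_i(t)` with centre frequencies `ω_i` by ADMM:
   Wiener-filter mode updates
   `ĉ_i = (f̂ − Σ_{j≠i} ĉ_j + λ̂/2)/(1 + 2α(ω−ω_i)²)`, spectral-centroid
   frequency updates, and dual ascent.
3. **PSO** — a particle swarm tunes `(α, K)` over [200, 2000] × [2, 8]
   by maximizing the MCC fitness `F = mean(R_i)/std(R_i)`, where `R_i`
   is each mode's Pearson correlation with `s(t)`.
4. **Permutation-entropy screening** — modes whose normalized
   permutation entropy exceeds 0.8 are treated as noise and dropped;
   the rest sum to the reconstructed life signal, from which
   respiration and heart rates are read as band-limited FFT peaks.
5. **Classification** — the Morlet scalogram of the life signal is
   fed to a multiscale CNN (parallel 1×1/3×3–5×5/5×5–3×3 branches,
   squeeze-and-excitation channel attention, an inception-style
   residual block, softmax over five states: supine/prone ×
   compressed/uncompressed + no target).  An SVM on hand-crafted
   respiratory features and a 1-D CNN on the raw life signal serve as
   baselines.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from bioradar import (RadarConfig, StateLabel, VMDParams, sample_truth,
                      simulate_echo_matrix, preprocess, vmd_decompose,
                      reconstruct_life_signal, dominant_frequency,
                      RESP_BAND, HEART_BAND)

cfg = RadarConfig()                      # 93 bins / 5 m / 17 Hz / 30 s
truth = sample_truth(StateLabel.SUPINE_COMPRESSION, cfg, rng=2)
echo = simulate_echo_matrix(truth, cfg, snr_db=0.0, seed=2)

d2, curve, sig = preprocess(echo)
imfs = vmd_decompose(sig, VMDParams(K=8, alpha=2000.0))
life, kept = reconstruct_life_signal(imfs)

print(f"target at {curve.radial_distance:.2f} m "
      f"(truth {truth.base_range:.2f} m)")
print(f"kept modes: {kept.astype(int)}, centres {np.round(imfs.omegas, 2)} Hz")
print(f"respiration {dominant_frequency(life, RESP_BAND):.3f} Hz "
      f"(truth {truth.resp_freq:.3f})")
print(f"heartbeat   {dominant_frequency(life, HEART_BAND):.3f} Hz "
      f"(truth {truth.heart_freq:.3f})")
```

Output:

```
target at 1.85 m (truth 1.80 m)
kept modes: [1 1 1 1 1 1 1 1], centres [0.31 0.62 1.49 3.03 3.71 5.1  6.05 7.59] Hz
respiration 0.309 Hz (truth 0.311)
heartbeat   1.405 Hz (truth 1.407)
```

The compression state raises the breathing rate, halves its depth and
adds the "M-shaped" second harmonic — visible here as the 0.62 Hz mode
locked at twice the breathing rate.  Even at 0 dB SNR the located
range is within one bin and both rates are recovered to a fraction of
a percent for this draw (median errors over many draws are reported by
`scripts/acceptance.py`).

A command-line interface mirrors the library
(`bioradar simulate|preprocess|optimize|vmd|denoise|tf|train|predict|baselines|run-all`),
e.g.:

```sh
bioradar simulate --state prone_compression --snr-db 0 --seed 3 --out echo.h5
bioradar run-all --in echo.h5 --out run/
```

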