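"""Continuous-wavelet scalograms and spectral rate estimation.

The reconstructed life signal is mapped to a time-frequency magnitude
image by a continuous wavelet transform; the complex Morlet wavelet is
the default because of its time-frequency resolution on quasi-periodic
biosignals.  Scalograms are rendered to fixed-size 3-channel images
(log-scaled magnitude through a perceptual colormap) for the
compression-state classifier.  Respiration and heart rates are read
from the FFT peak inside the corresponding physiological band, refined
by parabolic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from matplotlib import colormaps
from skimage.transform import resize

from .preprocessing import SlowTimeSignal

__all__ = [
    "Scalogram", "cwt_scalogram", "render_image",
    "dominant_frequency", "rate_error",
    "RESP_BAND", "HEART_BAND", "bandpass",
]

#: Default physiological bands (Hz): eupnoea to mild tachypnoea, and
#: resting to elevated heart rates.
RESP_BAND = (0.1, 0.7)
HEART_BAND = (0.8, 2.0)

#: Complex Morlet used by default: bandwidth 1.5, centre frequency 1.0.
MORLET = "cmor1.5-1.0"

_WAVELETS = {
    "morlet": MORLET,
    "haar": "haar",
    "db4": "db4",
    "sym4": "sym4",
}


@dataclass
class Scalogram:
    """|CWT| magnitude over an ascending frequency grid."""

    magnitude: np.ndarray  # (n_freqs, n_times), row 0 = lowest frequency
    freqs: np.ndarray  # Hz, ascending
    times: np.ndarray  # seconds

    def ridge(self) -> np.ndarray:
        """Per-time frequency of maximum magnitude (Hz)."""
        return self.freqs[np.argmax(self.magnitude, axis=0)]


def _generic_cwt(x, scales, wavelet, dt):
    """CWT by direct convolution with a sampled, rescaled wavelet.

    Used for the discrete-family bases (haar, db4, sym4) that the
    standard continuous-transform routine does not accept; retained for
    qualitative comparison of wavelet families.
    """
    w = pywt.Wavelet(wavelet)
    _, psi, grid = w.wavefun(level=10)
    psi = np.asarray(psi, dtype=float)
    grid = np.asarray(grid, dtype=float)
    d_grid = grid[1] - grid[0]
    out = np.empty((len(scales), x.size))
    for i, a in enumerate(scales):
        # psi(t/a) sampled on the signal grid: the support spans
        # (grid span) * a samples
        n_tap = max(int(np.ceil((grid[-1] - grid[0]) * a)), 2)
        tt = np.linspace(grid[0], grid[-1], n_tap)
        kernel = np.interp(tt, grid, psi) / np.sqrt(a)
        full = np.convolve(x, kernel[::-1]) * dt
        start = (kernel.size - 1) // 2  # crop "same" w.r.t. the signal
        out[i] = np.abs(full[start:start + x.size])
    return out


def cwt_scalogram(
    signal: SlowTimeSignal,
    wavelet_name: str = "morlet",
    freq_range: tuple[float, float] = (0.1, 2.5),
    n_scales: int = 64,
) -> Scalogram:
    """Scalogram of the signal over ``freq_range`` (Hz).

    ``wavelet_name`` is one of ``morlet`` (default), ``haar``, ``db4``
    or ``sym4``.
    """
    if wavelet_name not in _WAVELETS:
        raise ValueError(
            f"unsupported wavelet {wavelet_name!r}; "
            f"choose from {sorted(_WAVELETS)}")
    x = np.asarray(signal.values, dtype=float)
    if x.size < 32:
        raise ValueError("signal too short for a scalogram (need >= 32)")
    fs = signal.slow_rate
    f_lo, f_hi = freq_range
    if not (0 < f_lo < f_hi <= fs / 2):
        raise ValueError("freq_range must lie within (0, Nyquist]")

    freqs = np.linspace(f_lo, f_hi, n_scales)
    name = _WAVELETS[wavelet_name]
    dt = 1.0 / fs
    fc = pywt.central_frequency(name)
    scales = fc / (freqs * dt)

    if wavelet_name == "morlet":
        coef, _ = pywt.cwt(x, scales, name, sampling_period=dt)
        mag = np.abs(coef)
    else:
        mag = _generic_cwt(x, scales, name, dt)

    # scales descend as freqs ascend; pywt returns rows in scale order
    return Scalogram(magnitude=mag, freqs=freqs, times=signal.times)


def render_image(
    scalogram: Scalogram,
    size: int = 64,
    cmap: str = "viridis",
    log_scale: bool = True,
) -> np.ndarray:
    """Render a scalogram to a (3, size, size) float image in [0, 1].

    Magnitude is log-compressed, min-max normalized, passed through a
    perceptual colormap, and resized to a square.
    """
    mag = scalogram.magnitude
    if log_scale:
        mag = np.log1p(mag / (mag.max() + np.finfo(float).tiny) * 1e3)
    lo, hi = mag.min(), mag.max()
    norm = (mag - lo) / (hi - lo) if hi > lo else np.zeros_like(mag)
    rgb = colormaps[cmap](norm)[..., :3]
    img = resize(rgb, (size, size, 3), order=1, mode="reflect",
                 anti_aliasing=True, preserve_range=True)
    return np.ascontiguousarray(img.transpose(2, 0, 1), dtype=np.float32)


def bandpass(signal: SlowTimeSignal, band, order: int = 4) -> SlowTimeSignal:
    """Zero-phase Butterworth band-pass view of the signal."""
    from scipy.signal import butter, sosfiltfilt

    nyq = signal.slow_rate / 2
    lo, hi = band
    sos = butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return SlowTimeSignal(sosfiltfilt(sos, signal.values),
                          slow_rate=signal.slow_rate)


def dominant_frequency(signal: SlowTimeSignal, band) -> float:
    """Frequency (Hz) of the strongest FFT peak within ``band``.

    The peak bin is refined by parabolic interpolation of the spectrum
    magnitude at the bin and its two neighbours.
    """
    f_lo, f_hi = band
    nyq = signal.slow_rate / 2
    if not (0 < f_lo < f_hi <= nyq):
        raise ValueError("band must lie within (0, Nyquist]")
    x = signal.values - signal.values.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / signal.slow_rate)
    sel = np.flatnonzero((freqs >= f_lo) & (freqs <= f_hi))
    if sel.size == 0:
        raise ValueError("band contains no FFT bins at this record length")
    k = sel[np.argmax(spec[sel])]
    if 0 < k < spec.size - 1:
        a, b, c = spec[k - 1], spec[k], spec[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = freqs[1] - freqs[0]
    return float(freqs[k] + delta * df)


def rate_error(estimate: float, reference: float) -> float:
    """Relative rate measurement error, in percent."""
    if reference <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * abs(estimate - reference) / reference
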