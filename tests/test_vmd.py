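import numpy as np
import pytest

from bioradar import SlowTimeSignal, VMDParams, vmd_decompose
from bioradar.vmd import spectral_centroid, wiener_mode_update

from conftest import tone


class TestDecomposition:
    def test_two_tone_centre_frequencies(self, two_tone):
        imfs = vmd_decompose(two_tone, VMDParams(K=2, alpha=2000))
        assert imfs.omegas[0] == pytest.approx(0.3, rel=0.05)
        assert imfs.omegas[1] == pytest.approx(1.2, rel=0.05)

    def test_two_tone_reconstruction(self, two_tone):
        imfs = vmd_decompose(two_tone, VMDParams(K=2, alpha=2000,
                                                 tau_admm=0.0))
        err = np.linalg.norm(imfs.reconstruction() - two_tone.values)
        assert err / np.linalg.norm(two_tone.values) <= 0.1

    def test_single_tone_dominant_mode(self):
        """A lone 0.3 Hz tone: the strongest mode's spectral centroid
        sits on the tone and the mode sum reconstructs the input.
        (With K=2 both filters settle on the tone and share its energy;
        the tone's identity lives in the centroids, not the split.)"""
        sig = tone([0.3], [1.0])
        imfs = vmd_decompose(sig, VMDParams(K=2, alpha=2000))
        dominant = np.argmax((imfs.modes ** 2).sum(axis=1))
        mode = imfs.modes[dominant]
        spec = np.abs(np.fft.rfft(mode)) ** 2
        freqs = np.fft.rfftfreq(mode.size, 1 / sig.slow_rate)
        assert freqs[np.argmax(spec)] == pytest.approx(0.3, abs=0.05)
        assert imfs.omegas[dominant] == pytest.approx(0.3, abs=0.05)
        err = np.linalg.norm(imfs.reconstruction() - sig.values)
        assert err / np.linalg.norm(sig.values) <= 0.1

    def test_modes_sorted_by_frequency(self, two_tone):
        imfs = vmd_decompose(two_tone, VMDParams(K=4, alpha=1000))
        assert np.all(np.diff(imfs.omegas) >= 0)
        assert np.all(imfs.omegas < two_tone.slow_rate / 2)
        assert imfs.modes.shape == (4, two_tone.values.size)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            vmd_decompose(SlowTimeSignal(np.ones(100), 17.0), VMDParams())

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            vmd_decompose(SlowTimeSignal(np.sin(np.arange(6.0)), 17.0),
                          VMDParams(K=4))

    def test_amplitude_scale_equivariance(self, two_tone):
        """Scaling the input scales every mode by the same factor."""
        p = VMDParams(K=2, alpha=2000)
        a = vmd_decompose(two_tone, p)
        scaled = SlowTimeSignal(5.0 * two_tone.values, two_tone.slow_rate)
        b = vmd_decompose(scaled, p)
        assert np.allclose(b.modes, 5.0 * a.modes, rtol=1e-6, atol=1e-9)


class TestClosedFormUpdates:
    def test_wiener_update_matches_scalar_evaluation(self):
        """Element-wise oracle: the vectorized Wiener mode update equals
        the per-frequency closed form on random spectra."""
        rng = np.random.default_rng(42)
        n = 257
        omega = np.linspace(0, 0.5, n)
        f_hat = rng.normal(size=n) + 1j * rng.normal(size=n)
        others = rng.normal(size=n) + 1j * rng.normal(size=n)
        lam = rng.normal(size=n) + 1j * rng.normal(size=n)
        alpha, w_i = 1234.5, 0.21
        got = wiener_mode_update(f_hat, others, lam, alpha, omega, w_i)
        for idx in rng.integers(0, n, size=40):
            expected = (f_hat[idx] - others[idx] + lam[idx] / 2) / (
                1 + 2 * alpha * (omega[idx] - w_i) ** 2)
            assert abs(got[idx] - expected) <= 1e-8 * max(abs(expected), 1)

    def test_centroid_matches_direct_sum(self):
        rng = np.random.default_rng(43)
        n = 513
        omega = np.linspace(0, 0.5, n)
        u = rng.normal(size=n) + 1j * rng.normal(size=n)
        got = spectral_centroid(u, omega)
        p = np.abs(u) ** 2
        expected = float(np.sum(omega * p) / np.sum(p))
        assert got == pytest.approx(expected, rel=1e-8)


def mode_bandwidth_3db(mode, fs):
    spec = np.abs(np.fft.rfft(mode))
    freqs = np.fft.rfftfreq(mode.size, 1 / fs)
    above = freqs[spec >= spec.max() / np.sqrt(2)]
    return above.max() - above.min()


def test_alpha_narrows_bandwidth(two_tone):
    """Doubling alpha never widens any mode's -3 dB bandwidth."""
    widths = []
    for alpha in (250, 500, 1000, 2000):
        imfs = vmd_decompose(two_tone, VMDParams(K=2, alpha=alpha))
        widths.append([mode_bandwidth_3db(m, two_tone.slow_rate)
                       for m in imfs.modes])
    widths = np.array(widths)
    assert np.all(np.diff(widths, axis=0) <= 1e-9)
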