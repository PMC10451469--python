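import numpy as np
import pytest

from bioradar import (RadarConfig, StateLabel, VitalsTruth, sample_truth,
                      simulate_displacement, simulate_echo_matrix)
from bioradar.simulate import STATE_MODELS, load_echo_h5, save_echo_h5


def make_truth(**kw):
    base = dict(resp_freq=0.3, resp_amp=3e-3, heart_freq=1.2,
                heart_amp=4e-4, base_range=1.75, drift_sigma=0.0)
    base.update(kw)
    return VitalsTruth(**base)


class TestDisplacement:
    def test_all_motion_off_gives_constant(self, radar_cfg):
        truth = make_truth(resp_amp=0.0, heart_amp=0.0)
        d = simulate_displacement(truth, radar_cfg, seed=3)
        assert np.allclose(d, truth.base_range)

    def test_fft_peak_at_respiration_frequency(self, radar_cfg):
        """FFT oracle: with the heart off, the spectrum of d(t) peaks at
        the generating respiration frequency (0.41 Hz)."""
        truth = make_truth(resp_freq=0.41, heart_amp=0.0)
        d = simulate_displacement(truth, radar_cfg, seed=1)
        spec = np.abs(np.fft.rfft(d - d.mean()))
        freqs = np.fft.rfftfreq(d.size, 1 / radar_cfg.slow_rate)
        assert abs(freqs[np.argmax(spec)] - 0.41) < freqs[1]

    def test_deterministic_for_fixed_seed(self, radar_cfg):
        truth = make_truth(drift_sigma=1e-5)
        d1 = simulate_displacement(truth, radar_cfg, seed=7)
        d2 = simulate_displacement(truth, radar_cfg, seed=7)
        d3 = simulate_displacement(truth, radar_cfg, seed=8)
        assert np.array_equal(d1, d2)
        assert not np.array_equal(d1, d3)

    @pytest.mark.parametrize("bad", [
        dict(resp_freq=0.0), dict(resp_freq=np.nan),
        dict(heart_freq=0.2),                 # below resp_freq
        dict(heart_amp=5e-3),                 # above resp_amp
        dict(base_range=6.0), dict(base_range=-1.0),
    ])
    def test_invalid_parameters_rejected(self, radar_cfg, bad):
        with pytest.raises(ValueError):
            simulate_displacement(make_truth(**bad), radar_cfg, seed=0)


class TestEchoMatrix:
    def test_no_target_no_clutter_noise_free_is_zero(self, radar_cfg):
        truth = make_truth(state_label=StateLabel.NO_TARGET)
        echo = simulate_echo_matrix(truth, radar_cfg, snr_db=np.inf, seed=0)
        assert np.all(echo.data == 0)

    def test_static_scene_has_identical_columns(self, radar_cfg):
        truth = make_truth(resp_amp=0.0, heart_amp=0.0)
        echo = simulate_echo_matrix(
            truth, radar_cfg, clutter_spec=[(3.0, 0.5)],
            snr_db=np.inf, seed=0)
        assert np.allclose(echo.data, echo.data[:, :1])

    def test_echo_peak_tracks_displacement(self, radar_cfg):
        """Independent oracle: re-simulate d(t) and check the per-frame
        argmax bin equals round(d(t) / bin_spacing)."""
        truth = make_truth(resp_amp=4e-3)
        echo = simulate_echo_matrix(truth, radar_cfg, snr_db=np.inf, seed=9)
        d = simulate_displacement(truth, radar_cfg,
                                  seed=np.random.default_rng(9))
        expected = np.round(d / radar_cfg.bin_spacing).astype(int)
        assert np.array_equal(np.argmax(echo.data, axis=0), expected)

    def test_realized_snr_within_1db(self, radar_cfg):
        """Averaged over draws, noise power matches the request."""
        truth = make_truth()
        ratios = []
        for s in range(100):
            echo = simulate_echo_matrix(truth, radar_cfg, snr_db=3.0, seed=s)
            clean = simulate_echo_matrix(truth, radar_cfg, snr_db=np.inf,
                                         seed=s)
            noise = echo.data - clean.data
            sig_power = clean.data.var(axis=1).max()
            ratios.append(10 * np.log10(sig_power / noise.var()))
        assert abs(np.mean(ratios) - 3.0) < 1.0

    def test_out_of_window_target_rejected(self, radar_cfg):
        truth = make_truth(base_range=4.99, resp_amp=4e-2, heart_amp=1e-3)
        with pytest.raises(ValueError):
            simulate_echo_matrix(truth, radar_cfg, snr_db=10, seed=0)


class TestStateModel:
    def test_states_have_distinct_generative_parameters(self):
        """The four body states modify (amplitude, rate, waveform shape)
        in pairwise distinct ways."""
        body = [s for s in StateLabel if s is not StateLabel.NO_TARGET]
        combos = {(STATE_MODELS[s].amp_scale, STATE_MODELS[s].freq_scale,
                   STATE_MODELS[s].m_shape_ratio) for s in body}
        assert len(combos) == len(body)

    def test_sampled_truths_reflect_state_model(self, radar_cfg):
        rng = np.random.default_rng(0)
        amps = {}
        freqs = {}
        for state in (StateLabel.SUPINE_NO_COMPRESSION,
                      StateLabel.SUPINE_COMPRESSION):
            t = [sample_truth(state, radar_cfg, rng) for _ in range(200)]
            amps[state] = np.mean([x.resp_amp for x in t])
            freqs[state] = np.mean([x.resp_freq for x in t])
        assert amps[StateLabel.SUPINE_COMPRESSION] < \
            0.6 * amps[StateLabel.SUPINE_NO_COMPRESSION]
        assert freqs[StateLabel.SUPINE_COMPRESSION] > \
            1.2 * freqs[StateLabel.SUPINE_NO_COMPRESSION]


def test_h5_round_trip(tmp_path, radar_cfg):
    truth = make_truth()
    echo = simulate_echo_matrix(truth, radar_cfg, snr_db=5.0, seed=2)
    path = tmp_path / "echo.h5"
    save_echo_h5(path, echo)
    back = load_echo_h5(path)
    assert np.allclose(back.data, echo.data)
    assert back.truth.resp_freq == truth.resp_freq
    assert back.truth.state_label is truth.state_label
    assert back.config.n_fast_bins == radar_cfg.n_fast_bins
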