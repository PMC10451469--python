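import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioradar import PEConfig, VMDParams, permutation_entropy, \
    reconstruct_life_signal
from bioradar.vmd import IMFSet

from conftest import tone


def brute_force_pe(x, m, tau):
    """Literal ordinal-pattern tally: enumerate delay vectors, sort each
    (stable), count patterns, Shannon entropy over ln(m!)."""
    n_vec = len(x) - (m - 1) * tau
    counts = {}
    for j in range(n_vec):
        vec = [x[j + i * tau] for i in range(m)]
        pattern = tuple(sorted(range(m), key=lambda i: vec[i]))
        counts[pattern] = counts.get(pattern, 0) + 1
    h = -sum((c / n_vec) * math.log(c / n_vec) for c in counts.values())
    return h / math.log(math.factorial(m))


class TestPermutationEntropy:
    def test_monotone_series_has_zero_entropy(self):
        x = np.arange(1, 101, dtype=float)
        assert permutation_entropy(x, PEConfig(3, 1)) == 0.0

    def test_alternating_series_saturates(self):
        # 9 samples -> 8 delay vectors, two patterns with equal counts:
        # -2*(1/2)ln(1/2)/ln(2!) = 1 exactly
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1], float)
        assert permutation_entropy(x, PEConfig(2, 1)) == pytest.approx(1.0)
        # 8 samples -> 7 vectors with counts 4 and 3
        expected = -(4 / 7 * np.log(4 / 7) + 3 / 7 * np.log(3 / 7)) \
            / np.log(2)
        assert permutation_entropy(x[:-1], PEConfig(2, 1)) == \
            pytest.approx(expected)

    def test_white_noise_near_maximum(self):
        x = np.random.default_rng(0).normal(size=10_000)
        assert permutation_entropy(x, PEConfig(5, 1)) > 0.95

    @pytest.mark.parametrize("m,tau", [(3, 1), (4, 1), (5, 1), (3, 2)])
    def test_matches_brute_force(self, m, tau):
        rng = np.random.default_rng(m * 10 + tau)
        for _ in range(25):
            x = rng.normal(size=rng.integers(50, 400))
            got = permutation_entropy(x, PEConfig(m, tau))
            assert got == pytest.approx(brute_force_pe(x, m, tau),
                                        abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        """PE depends only on ordinal structure: strictly monotone maps
        (affine, exp) leave it unchanged."""
        x = np.random.default_rng(seed).normal(size=150)
        cfg = PEConfig(4, 1)
        base = permutation_entropy(x, cfg)
        assert permutation_entropy(3.7 * x + 11, cfg) == base
        assert permutation_entropy(np.exp(x), cfg) == base

    def test_noise_raises_entropy_of_a_tone(self):
        rng = np.random.default_rng(7)
        t = np.arange(510) / 17.0
        clean = np.sin(2 * np.pi * 0.3 * t)
        cfg = PEConfig(5, 1)
        levels = [0.0, 0.05, 0.2, 0.8, 3.0]
        pes = [np.mean([permutation_entropy(
            clean + a * rng.normal(size=t.size), cfg) for _ in range(5)])
            for a in levels]
        # non-decreasing up to estimator noise at the saturated end
        assert all(a <= b + 0.01 for a, b in zip(pes, pes[1:]))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            permutation_entropy(np.arange(5.0), PEConfig(5, 2))


class TestReconstruction:
    def fake_imfs(self, modes):
        modes = np.asarray(modes, float)
        return IMFSet(modes=modes, omegas=np.arange(len(modes), dtype=float),
                      slow_rate=17.0, n_iters=1, converged=True,
                      params=VMDParams())

    def test_noise_mode_dropped_sinusoid_kept(self):
        clean = tone([0.3], [1.0]).values
        noise = np.random.default_rng(1).normal(size=clean.size)
        life, kept = reconstruct_life_signal(self.fake_imfs([clean, noise]))
        assert list(kept) == [True, False]
        assert np.array_equal(life.values, clean)

    def test_all_clean_modes_summed(self):
        m1 = tone([0.3], [1.0]).values
        m2 = tone([1.2], [0.3]).values
        life, kept = reconstruct_life_signal(self.fake_imfs([m1, m2]))
        assert kept.all()
        assert np.allclose(life.values, m1 + m2)

    def test_all_noisy_keeps_least_random_with_warning(self):
        rng = np.random.default_rng(2)
        n1 = rng.normal(size=510)
        n2 = rng.normal(size=510)
        with pytest.warns(UserWarning):
            life, kept = reconstruct_life_signal(self.fake_imfs([n1, n2]))
        assert kept.sum() == 1

    def test_default_threshold(self):
        assert PEConfig().threshold == 0.8
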