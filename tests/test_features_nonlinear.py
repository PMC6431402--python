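"""Nonlinear estimators against independent brute-force and analytic
oracles: entropy orderings, the logistic map's known Lyapunov exponent,
limit-cycle dimension, LZ76 hand traces, scaling invariance."""

import numpy as np
import pytest

from emoeeg import features_nonlinear as fnl
from emoeeg.features import FEATURE_NAMES
from emoeeg.synthetic import logistic_map

from .oracles import apen_brute, lz76_brute, sampen_brute

FS = 256.0


class TestRegularityEntropies:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_equality(self, seed):
        x = np.random.default_rng(seed).normal(size=100)
        assert fnl.approximate_entropy(x) == pytest.approx(apen_brute(x), abs=1e-10)
        assert fnl.sample_entropy(x) == pytest.approx(sampen_brute(x), abs=1e-10)

    def test_constant_sequences_zero(self):
        c = np.full(200, 3.7)
        assert fnl.approximate_entropy(c) == 0.0
        assert fnl.sample_entropy(c) == 0.0

    def test_noise_more_entropic_than_sine(self):
        """Ordering must hold in >= 95% of seeds (it holds in all here)."""
        t = np.arange(1024) / FS
        sine = np.sin(2 * np.pi * 10 * t)
        apen_ok = sampen_ok = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).uniform(-1, 1, 1024)
            apen_ok += fnl.approximate_entropy(noise) > fnl.approximate_entropy(sine)
            sampen_ok += fnl.sample_entropy(noise) > fnl.sample_entropy(sine)
        assert apen_ok >= 19
        assert sampen_ok >= 19

    def test_short_input_rejected(self):
        with pytest.raises(fnl.NonlinearError):
            fnl.approximate_entropy(np.ones(10))


class TestLyapunov:
    def test_logistic_map_matches_ln2(self):
        vals = [fnl.max_lyapunov(logistic_map(2000, seed=s), m=2, tau=1)
                for s in range(5)]
        assert np.mean(vals) == pytest.approx(np.log(2), abs=0.1)

    def test_sine_not_chaotic(self, sine):
        assert fnl.max_lyapunov(sine, m=5) <= 0.05

    def test_noise_flagged(self, white_noise):
        val, det = fnl.max_lyapunov(white_noise[:2000], m=5, return_details=True)
        assert val > 0
        assert det["flags"].get("no_divergence_region")


class TestCorrelationDimension:
    def test_limit_cycle_dimension_one(self, sine):
        assert fnl.correlation_dimension(sine) == pytest.approx(1.0, abs=0.3)

    def test_logistic_map_stable_across_seeds(self):
        vals = [fnl.correlation_dimension(logistic_map(2000, seed=s), tau=1)
                for s in range(10)]
        assert np.std(vals) < 0.15
        assert 0.5 <= np.mean(vals) <= 1.1

    def test_noise_never_saturates(self, white_noise):
        _, det = fnl.correlation_dimension(white_noise[:2000], return_details=True)
        assert det["flags"].get("no_saturation")


class TestKEntropy:
    def test_periodic_signal_near_zero(self, sine):
        assert abs(fnl.k_entropy(sine)) < 0.05

    def test_logistic_map_positive(self):
        vals = [fnl.k_entropy(logistic_map(2000, seed=s), tau=1) for s in range(3)]
        assert min(vals) > 0.3

    def test_constant_degenerate_via_extract(self):
        block = fnl.extract_nonlinear(np.zeros(1024))
        assert block.values_by_name["k_entropy"] == 0.0


class TestC0Complexity:
    def test_pure_tone_regular(self):
        t = np.arange(1024) / FS
        assert fnl.c0_complexity(np.sin(2 * np.pi * 16 * t)) < 0.05

    def test_white_noise_irregular(self, white_noise):
        assert fnl.c0_complexity(white_noise) > 0.6

    def test_regular_part_idempotent(self, white_noise):
        x = white_noise[:1024]
        # rebuild the regular part the same way the estimator defines it
        F = np.fft.fft(x)
        power = np.abs(F) ** 2
        regular = np.real(np.fft.ifft(np.where(power > 5.0 * power.mean(), F, 0)))
        if np.sum(regular ** 2) > 0:
            assert fnl.c0_complexity(regular) < 0.05

    def test_zero_energy_rejected(self):
        with pytest.raises(fnl.NonlinearError, match="degenerate"):
            fnl.c0_complexity(np.zeros(128))


class TestSpectralEntropies:
    def test_singular_spectrum_of_sine_is_two_component(self, sine):
        assert fnl.singular_spectral_entropy(sine, 64) == pytest.approx(
            np.log(2) / np.log(64), abs=0.05)

    def test_singular_spectrum_ordering(self, sine, white_noise):
        assert fnl.singular_spectral_entropy(white_noise) > \
            fnl.singular_spectral_entropy(sine)

    def test_rank_one_signal_near_zero(self):
        x = 0.995 ** np.arange(512)  # geometric: rank-1 trajectory matrix
        assert fnl.singular_spectral_entropy(x, 64) < 0.02

    def test_spectral_entropy_tone_vs_noise(self):
        t = np.arange(4096) / FS
        tone = np.sin(2 * np.pi * 16 * t)
        assert fnl.spectral_entropy(tone) < 0.2
        vals = [fnl.spectral_entropy(np.random.default_rng(s).normal(size=4096))
                for s in range(10)]
        assert np.mean(vals) > 0.85

    def test_two_tones_add_about_ln2(self):
        t = np.arange(4096) / FS
        one = np.sin(2 * np.pi * 16 * t)
        two = one + np.sin(2 * np.pi * 24 * t)
        n_bins = 2048
        gap = fnl.spectral_entropy(two) - fnl.spectral_entropy(one)
        assert gap == pytest.approx(np.log(2) / np.log(n_bins), abs=0.02)


class TestLempelZiv:
    def test_hand_traced_pattern_count(self):
        bits = [int(c) for c in "0001101001000101"]
        assert fnl.lz76_pattern_count(bits) == 6
        assert lz76_brute(bits) == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_pattern_count_matches_brute_force(self, seed):
        bits = np.random.default_rng(seed).integers(0, 2, 200)
        assert fnl.lz76_pattern_count(bits) == lz76_brute(bits)

    def test_alternating_sequence_minimal(self):
        saw = np.tile([0.0, 1.0], 2048)
        assert fnl.lz_complexity(saw) < 0.2

    def test_coin_flip_normalization_near_one(self):
        x = np.random.default_rng(11).normal(size=4096)
        assert 0.8 <= fnl.lz_complexity(x) <= 1.2

    def test_constant_input_flagged(self):
        val, det = fnl.lz_complexity(np.zeros(128), return_details=True)
        assert det["flags"].get("constant_binarization")
        assert det["pattern_count"] <= 2


class TestExtractNonlinear:
    def test_constant_epoch_all_flagged_zero(self):
        block = fnl.extract_nonlinear(np.full(1024, 2.0))
        assert np.all(block.values() == 0.0)
        assert len(block.flags) == 9

    def test_chaotic_epoch_more_complex_than_tone(self):
        t = np.arange(1024) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        chaos = logistic_map(1024, seed=3)
        b_tone = fnl.extract_nonlinear(tone)
        b_chaos = fnl.extract_nonlinear(chaos)
        for name in ("approximate_entropy", "sample_entropy",
                     "spectral_entropy", "lz_complexity"):
            assert b_chaos.values_by_name[name] > b_tone.values_by_name[name]

    def test_canonical_index_22_is_lyapunov(self):
        assert FEATURE_NAMES[22] == "Maximum Lyapunov exponent"
        assert fnl.NONLINEAR_ORDER[22 - 19] == "max_lyapunov"

    @pytest.mark.parametrize("scale", [0.5, 2.0, 10.0])
    def test_amplitude_scaling_invariance(self, scale):
        rng = np.random.default_rng(21)
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 9 * t) + 0.4 * logistic_map(1024, seed=5) \
            + 0.2 * rng.normal(size=1024)
        b1 = fnl.extract_nonlinear(x)
        b2 = fnl.extract_nonlinear(scale * x)
        tight = {"lz_complexity", "c0_complexity", "spectral_entropy"}
        for name in fnl.NONLINEAR_ORDER:
            tol = 1e-6 if name in tight else 1e-3
            assert b2.values_by_name[name] == pytest.approx(
                b1.values_by_name[name], abs=tol), name
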