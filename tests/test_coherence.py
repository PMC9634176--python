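import numpy as np
import pytest

from rattlekit.coherence import (
    CoherenceResult,
    band_average,
    cwt,
    group_null_test,
    single_hand_spectrum,
    surrogate_null,
    wavelet_coherence,
)
from rattlekit.containers import ValidationError


def _noise(n, seed, fs=60.0, factory=None):
    rng = np.random.default_rng(seed)
    return factory(9.81 + rng.normal(0, 0.5, n), fs=fs)


class TestCWT:
    def test_pure_tone_peak_frequency(self, magnitude_factory):
        t = np.arange(3600) / 60.0
        m = magnitude_factory(np.sin(2 * np.pi * 1.0 * t))
        res = cwt(m)
        power = (np.abs(res.coeffs) ** 2).mean(axis=1)
        f_peak = res.freqs[np.argmax(power)]
        step = 2 ** (1 / 12)
        assert 1.0 / step <= f_peak <= 1.0 * step

    def test_peak_frequency_matches_pywavelets_oracle(self, magnitude_factory):
        # independent implementation: PyWavelets complex-Morlet CWT
        import pywt

        t = np.arange(2400) / 60.0
        sig = np.sin(2 * np.pi * 1.7 * t)
        m = magnitude_factory(sig)
        res = cwt(m)
        ours = res.freqs[np.argmax((np.abs(res.coeffs) ** 2).mean(axis=1))]
        freqs = np.linspace(0.5, 4.0, 36)
        scales = pywt.frequency2scale("cmor1.5-1.0", freqs / 60.0)
        coeffs, f_out = pywt.cwt(sig, scales, "cmor1.5-1.0", sampling_period=1 / 60.0)
        theirs = f_out[np.argmax((np.abs(coeffs) ** 2).mean(axis=1))]
        assert abs(np.log2(ours / theirs)) < 0.15

    def test_constant_input_near_zero_power(self, magnitude_factory):
        m = magnitude_factory(np.full(1200, 9.81))
        res = cwt(m)
        assert np.max(np.abs(res.coeffs)) < 1e-9

    def test_white_noise_seeds_differ_but_grid_fixed(self, magnitude_factory):
        a = cwt(_noise(1200, 0, factory=magnitude_factory))
        b = cwt(_noise(1200, 1, factory=magnitude_factory))
        assert np.array_equal(a.freqs, b.freqs)
        assert not np.allclose(np.abs(a.coeffs), np.abs(b.coeffs))

    def test_grid_spans_band_with_margin(self, magnitude_factory):
        res = cwt(_noise(1200, 0, factory=magnitude_factory))
        assert res.freqs.max() >= 5.0 - 1e-9
        assert res.freqs.min() <= 0.25 + 1e-9
        assert np.all(np.diff(res.freqs) < 0)

    def test_short_input_flagged(self, magnitude_factory):
        with pytest.warns(UserWarning, match="shorter"):
            res = cwt(_noise(100, 0, factory=magnitude_factory))
        assert res.short_input


class TestWaveletCoherence:
    def test_self_coherence_is_one_everywhere(self, magnitude_factory):
        x = _noise(1800, 3, factory=magnitude_factory)
        y = magnitude_factory(x.acc.copy())
        res = wavelet_coherence(x, y)
        assert np.allclose(res.wc, 1.0, atol=1e-9)
        assert res.band_mean == pytest.approx(1.0, abs=1e-12)

    def test_constant_phase_shift_keeps_full_band_coherence(self, magnitude_factory):
        t = np.arange(3600) / 60.0
        x = magnitude_factory(np.sin(2 * np.pi * t))
        y = magnitude_factory(np.cos(2 * np.pi * t))  # 90 deg shift
        res = wavelet_coherence(x, y)
        row = np.argmin(np.abs(res.freqs - 1.0))
        interior = slice(300, 3300)
        assert res.wc[row, interior].mean() > 0.99

    def test_independent_noise_band_mean_low(self, magnitude_factory):
        x = _noise(3600, 10, factory=magnitude_factory)
        y = _noise(3600, 11, factory=magnitude_factory)
        res = wavelet_coherence(x, y)
        assert res.band_mean < 0.5

    def test_symmetry_in_arguments(self, magnitude_factory):
        x = _noise(900, 20, factory=magnitude_factory)
        y = _noise(900, 21, factory=magnitude_factory)
        a = wavelet_coherence(x, y)
        b = wavelet_coherence(y, x)
        assert np.allclose(a.wc, b.wc, atol=1e-9)

    def test_scale_invariance(self, magnitude_factory):
        x = _noise(900, 30, factory=magnitude_factory)
        y = _noise(900, 31, factory=magnitude_factory)
        xs = magnitude_factory(3.0 * x.acc)
        ys = magnitude_factory(0.2 * y.acc)
        a = wavelet_coherence(x, y)
        b = wavelet_coherence(xs, ys)
        assert np.allclose(a.wc, b.wc, atol=1e-9)

    def test_boundedness_on_random_pairs(self, magnitude_factory):
        for seed in range(25):
            x = _noise(600, 100 + seed, factory=magnitude_factory)
            y = _noise(600, 200 + seed, factory=magnitude_factory)
            res = wavelet_coherence(x, y)
            assert res.raw_min >= -1e-9
            assert res.raw_max <= 1.0 + 1e-9

    def test_disabled_smoothing_degenerates_to_one(self, magnitude_factory):
        # negative control: with S = identity, WC is algebraically 1
        x = _noise(1200, 40, factory=magnitude_factory)
        y = _noise(1200, 41, factory=magnitude_factory)
        res = wavelet_coherence(x, y, smoothing=False)
        assert np.allclose(res.wc, 1.0, atol=1e-6)

    def test_length_mismatch_and_constant_rejected(self, magnitude_factory):
        x = _noise(600, 50, factory=magnitude_factory)
        with pytest.raises(ValidationError, match="length"):
            wavelet_coherence(x, _noise(500, 51, factory=magnitude_factory))
        with pytest.raises(ValidationError, match="constant"):
            wavelet_coherence(x, magnitude_factory(np.ones(600)))


class TestBandAverage:
    def _result(self, wc, freqs):
        return CoherenceResult(
            wc=np.asarray(wc, dtype=float),
            freqs=np.asarray(freqs, dtype=float),
            scales=1.0 / np.asarray(freqs, dtype=float),
            coi=np.full(np.asarray(wc).shape[1], 0.01),
            band_mean=float("nan"),
            raw_min=0.0,
            raw_max=1.0,
        )

    def test_all_ones_gives_one(self):
        res = self._result(np.ones((4, 10)), [2.0, 1.5, 1.0, 0.6])
        assert band_average(res) == 1.0

    def test_all_zeros_gives_zero(self):
        res = self._result(np.zeros((4, 10)), [2.0, 1.5, 1.0, 0.6])
        assert band_average(res) == 0.0

    def test_half_ones_rows_give_half(self):
        wc = np.vstack([np.ones((2, 10)), np.zeros((2, 10))])
        res = self._result(wc, [2.0, 1.5, 1.0, 0.6])
        assert band_average(res) == 0.5

    def test_rows_outside_band_ignored(self):
        wc = np.vstack([np.ones((1, 10)), np.zeros((2, 10))])
        res = self._result(wc, [4.0, 1.0, 0.6])
        assert band_average(res) == 0.0

    def test_empty_band_rejected(self):
        res = self._result(np.ones((2, 10)), [4.0, 3.5])
        with pytest.raises(ValidationError, match="band|rows"):
            band_average(res)


class TestSurrogates:
    def test_identical_series_exceed_every_null_draw(self, magnitude_factory):
        x = _noise(1200, 60, factory=magnitude_factory)
        y = magnitude_factory(x.acc.copy())
        null = surrogate_null(x, y, n_iter=100, seed=0)
        assert null.observed == pytest.approx(1.0, abs=1e-9)
        assert np.all(null.null_values < null.observed)

    def test_independent_noise_within_null(self, magnitude_factory):
        hits = 0
        for seed in range(10):
            x = _noise(1200, 300 + seed, factory=magnitude_factory)
            y = _noise(1200, 400 + seed, factory=magnitude_factory)
            null = surrogate_null(x, y, n_iter=100, seed=seed)
            if null.percentile(2.5) <= null.observed <= null.percentile(97.5):
                hits += 1
        assert hits >= 8

    def test_band_mean_matches_full_grid_computation(self, magnitude_factory):
        x = _noise(900, 70, factory=magnitude_factory)
        y = _noise(900, 71, factory=magnitude_factory)
        null = surrogate_null(x, y, n_iter=1, seed=0)
        full = wavelet_coherence(x, y)
        assert null.observed == pytest.approx(full.band_mean, abs=1e-9)

    def test_phase_surrogates_preserve_spectrum(self, magnitude_factory):
        t = np.arange(2400) / 60.0
        rng = np.random.default_rng(5)
        x = magnitude_factory(np.sin(2 * np.pi * 1.2 * t) + rng.normal(0, 0.3, 2400))
        y = magnitude_factory(np.sin(2 * np.pi * 1.2 * t) + rng.normal(0, 0.3, 2400))
        perm = surrogate_null(x, y, n_iter=60, seed=1, method="permutation")
        phase = surrogate_null(x, y, n_iter=60, seed=1, method="phase")
        # spectrum-preserving surrogates keep the narrowband coherence bias,
        # so their null sits above the whitened permutation null
        assert phase.null_values.mean() > perm.null_values.mean()

    def test_zero_iterations_rejected(self, magnitude_factory):
        x = _noise(600, 80, factory=magnitude_factory)
        with pytest.raises(ValidationError):
            surrogate_null(x, x, n_iter=0, seed=0)


class TestGroupNullTest:
    def test_identical_vectors_t_zero(self):
        t, p = group_null_test([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        assert t == 0.0 and p == 1.0

    def test_constant_offset_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = group_null_test([1.4, 1.5, 1.6], [0.4, 0.5, 0.6])
        assert np.isinf(t) and p == 0.0

    def test_matches_scipy_on_generic_data(self, rng):
        obs = rng.uniform(0.3, 0.8, 12)
        nul = rng.uniform(0.2, 0.5, 12)
        from scipy.stats import ttest_rel

        t, p = group_null_test(obs, nul)
        t_ref, p_ref = ttest_rel(obs, nul)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            group_null_test([0.5], [0.4])


class TestSingleHandSpectrum:
    def test_burst_train_peaks_in_2_3_hz_band(self, magnitude_factory):
        # 2.5 Hz packet train (one Hann-windowed cycle per movement)
        t = np.arange(3600) / 60.0
        f = 2.5
        sig = np.zeros_like(t)
        for c in np.arange(5.0, 55.0, 1.0 / f):
            u = t - c
            w = np.abs(u) < 0.625 / f
            sig[w] += 0.5 * (1 + np.cos(np.pi * u[w] / (0.625 / f))) * np.cos(
                2 * np.pi * f * u[w]
            )
        freqs, power = single_hand_spectrum(magnitude_factory(9.81 + sig))
        f_peak = freqs[np.argmax(power)]
        assert 2.0 <= f_peak <= 3.0

    def test_amplitude_doubling_quadruples_power(self, magnitude_factory):
        x = _noise(1200, 90, factory=magnitude_factory)
        f1, p1 = single_hand_spectrum(x)
        _, p2 = single_hand_spectrum(magnitude_factory(2.0 * x.acc))
        assert np.allclose(p2, 4.0 * p1, rtol=1e-9)

    def test_constant_flat_near_zero(self, magnitude_factory):
        _, p = single_hand_spectrum(magnitude_factory(np.full(1200, 3.0)))
        assert np.max(p) < 1e-12
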