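from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from htdspeech.htd_core import (
    analytic_signal,
    compute_htd,
    inst_autocorrelation,
    kernel_norm,
    kernel_weights,
    render_tf_image,
    wvd_reference,
)
from htdspeech.signal_io import RunConfig, Waveform

RATE = 8000


class TestKernelNorm:
    def test_closed_form_values(self):
        assert kernel_norm(1.0) == pytest.approx(0.5, abs=1e-12)
        assert kernel_norm(0.5) == pytest.approx(1.0 / np.pi, abs=1e-12)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0, 5.0])
    def test_reciprocal_of_sech_integral(self, sigma):
        integral, _ = quad(lambda t: np.cosh(t) ** (-2.0 * sigma), -60, 60)
        assert kernel_norm(sigma) * integral == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kernel_norm(0.0)
        with pytest.raises(ValueError):
            kernel_norm(-1.0)


class TestKernelWeights:
    def _grid(self, n=801, span=10.0):
        return np.linspace(-span, span, n)

    def test_symmetric_and_positive(self):
        k = kernel_weights(1.0, self._grid())
        np.testing.assert_allclose(k.weights, k.weights[::-1], rtol=1e-12)
        assert np.all(k.weights > 0)

    def test_unit_discrete_mass(self):
        g = self._grid()
        k = kernel_weights(2.0, g)
        dt = g[1] - g[0]
        assert k.weights.sum() * dt == pytest.approx(1.0, abs=1e-6)

    def test_peak_matches_closed_form_before_renormalization(self):
        g = self._grid(n=4001, span=20.0)
        k = kernel_weights(1.0, g, truncation_eps=1e-12)
        # fine grid: discrete renormalization is a tiny correction
        assert k.weights.max() == pytest.approx(k.k_sigma, rel=1e-3)

    def test_hwhm_decreases_with_sigma(self):
        hwhms = []
        g = self._grid(n=8001, span=12.0)
        for sigma in (0.5, 1.0, 2.0, 5.0):
            k = kernel_weights(sigma, g, truncation_eps=1e-10)
            half = k.weights.max() / 2.0
            hwhms.append(np.abs(k.times[k.weights >= half]).max())
        assert all(a > b for a, b in zip(hwhms, hwhms[1:]))

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            kernel_weights(1.0, np.array([-1.0, 0.0]))


class TestAnalyticSignal:
    def test_zero_signal(self):
        z = analytic_signal(Waveform(np.zeros(128), RATE))
        np.testing.assert_array_equal(z.values, np.zeros(128, complex))

    def test_cosine_closed_form(self):
        rate, n, f0 = 48000, 4096, 1000.0
        t = np.arange(n) / rate
        z = analytic_signal(Waveform(np.cos(2 * np.pi * f0 * t), rate))
        expected = np.exp(1j * 2 * np.pi * f0 * t)
        core = slice(n // 8, -n // 8)
        np.testing.assert_allclose(z.values[core], expected[core], atol=5e-3)
        np.testing.assert_allclose(np.abs(z.values[core]), 1.0, atol=5e-3)

    def test_real_part_is_input(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        z = analytic_signal(Waveform(x, RATE))
        np.testing.assert_allclose(z.values.real, x, atol=1e-9)

    def test_negative_frequencies_suppressed(self):
        rng = np.random.default_rng(1)
        z = analytic_signal(Waveform(rng.standard_normal(512), RATE))
        spec = np.fft.fft(z.values)
        neg = spec[512 // 2 + 1 :]
        assert np.abs(neg).max() <= 1e-9 * np.abs(spec).max()


class TestInstAutocorrelation:
    def test_pure_tone_closed_form(self):
        n, f0 = 2048, 1000.0
        t = np.arange(n) / RATE
        z = analytic_signal(Waveform(np.cos(2 * np.pi * f0 * t), RATE))
        k = inst_autocorrelation(z, 65)
        m = np.arange(33)
        expected = np.exp(1j * 2 * np.pi * f0 * 2 * m / RATE)
        mid = n // 2
        np.testing.assert_allclose(k[mid], expected, atol=2e-2)
        np.testing.assert_allclose(np.abs(k[mid]), 1.0, atol=2e-2)

    def test_zero_lag_is_magnitude_squared(self):
        rng = np.random.default_rng(2)
        z = analytic_signal(Waveform(rng.standard_normal(256), RATE))
        k = inst_autocorrelation(z, 31)
        np.testing.assert_allclose(k[:, 0], np.abs(z.values) ** 2, rtol=1e-12)

    def test_hermitian_symmetry(self):
        # K[n, -m] = conj(K[n, m]) realized as z[n-m] z*[n+m]
        rng = np.random.default_rng(3)
        z = analytic_signal(Waveform(rng.standard_normal(128), RATE))
        v = np.concatenate([np.zeros(5, complex), z.values, np.zeros(5, complex)])
        for n in (20, 64, 100):
            for m in range(1, 6):
                kp = v[n + 5 + m] * np.conj(v[n + 5 - m])
                km = v[n + 5 - m] * np.conj(v[n + 5 + m])
                assert km == pytest.approx(np.conj(kp), abs=1e-12)


class TestComputeHTD:
    def test_tone_localized_at_1khz(self, tone, cfg):
        g = compute_htd(tone, cfg)
        interior = slice(3, g.times.size - 3)
        peaks = g.values[interior].argmax(axis=1)
        expected = np.argmin(np.abs(g.freqs - 1000.0))
        assert np.all(peaks == expected)

    def test_zero_signal_zero_grid(self, cfg):
        g = compute_htd(Waveform(np.zeros(4000), RATE), cfg)
        np.testing.assert_array_equal(g.values, np.zeros_like(g.values))

    def test_chirp_tracks_instantaneous_frequency(self, chirp, cfg):
        g = compute_htd(chirp, cfg)
        interior = slice(4, g.times.size - 4)
        est = g.freqs[g.values[interior].argmax(axis=1)]
        true_if = 500.0 + 3000.0 * g.times[interior]
        bin_width = RATE / (2.0 * cfg.nfft_effective)
        rmse = np.sqrt(np.mean((est - true_if) ** 2)) / bin_width
        assert rmse <= 2.0

    def test_short_waveform_rejected(self, cfg):
        with pytest.raises(ValueError, match="shorter"):
            compute_htd(Waveform(np.zeros(cfg.lag_window - 2), RATE), cfg)


class TestWVDReference:
    def test_chirp_peak_on_if_bin(self, chirp, cfg):
        g = wvd_reference(chirp, cfg)
        interior = slice(4, g.times.size - 4)
        est = g.freqs[g.values[interior].argmax(axis=1)]
        true_if = 500.0 + 3000.0 * g.times[interior]
        bin_width = RATE / (2.0 * cfg.nfft_effective)
        assert np.abs(est - true_if).max() <= bin_width

    def test_tone_peak(self, tone, cfg):
        g = wvd_reference(tone, cfg)
        expected = np.argmin(np.abs(g.freqs - 1000.0))
        assert np.all(g.values[5:-5].argmax(axis=1) == expected)

    def test_same_grid_shape_as_htd(self, tone, cfg):
        assert wvd_reference(tone, cfg).values.shape == compute_htd(tone, cfg).values.shape


class TestTFDInvariants:
    def test_frequency_marginal_matches_wvd(self, tone, cfg):
        h = compute_htd(tone, cfg)
        w = wvd_reference(tone, cfg)
        mh, mw = h.values.sum(axis=0), w.values.sum(axis=0)
        assert np.linalg.norm(mh - mw) / np.linalg.norm(mw) <= 0.02

    @pytest.mark.parametrize("sig", ["tone", "chirp"])
    def test_energy_preserved(self, sig, tone, chirp, cfg):
        w = {"tone": tone, "chirp": chirp}[sig]
        g = compute_htd(w, cfg)
        z = analytic_signal(w)
        df = RATE / (2.0 * cfg.nfft_effective)
        dt = cfg.hop / RATE
        assert g.values.sum() * dt * df == pytest.approx(z.energy, rel=0.02)

    def test_sigma_convergence_to_wvd_monotone(self, chirp, cfg):
        ref = wvd_reference(chirp, cfg)
        dists = []
        for sigma in (0.5, 1.0, 2.0, 5.0, 10.0):
            g = compute_htd(chirp, replace(cfg, sigma=sigma))
            dists.append(np.linalg.norm(g.values - ref.values) / np.linalg.norm(ref.values))
        assert all(a > b for a, b in zip(dists, dists[1:]))

    def test_cross_term_suppression_two_tones(self, time_axis, cfg):
        x = 0.4 * np.cos(2 * np.pi * 800 * time_axis) + 0.4 * np.cos(2 * np.pi * 1200 * time_axis)
        w = Waveform(x, RATE)
        h, v = compute_htd(w, cfg), wvd_reference(w, cfg)
        mid = np.argmin(np.abs(h.freqs - 1000.0))
        interior = slice(4, h.times.size - 4)
        ratio = np.abs(h.values[interior, mid]).sum() / np.abs(v.values[interior, mid]).sum()
        assert ratio < 1.0

    def test_time_shift_covariance(self, time_axis, cfg):
        d = 3  # frames
        x = 0.5 * np.cos(2 * np.pi * 1000 * time_axis) * np.exp(-(((time_axis - 0.25) / 0.05) ** 2))
        g1 = compute_htd(Waveform(x, RATE), cfg)
        g2 = compute_htd(Waveform(np.roll(x, d * cfg.hop), RATE), cfg)
        n = g1.values.shape[0]
        a, b = g1.values[5 : n - 5 - d], g2.values[5 + d : n - 5]
        assert np.abs(a - b).max() <= 1e-6 * np.abs(g1.values).max()


class TestRenderTFImage:
    def test_deterministic(self, tone, cfg):
        g = compute_htd(tone, cfg)
        a = render_tf_image(g, size=64)
        b = render_tf_image(g, size=64)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_all_zero_grid_uniform(self, cfg):
        g = compute_htd(Waveform(np.zeros(4000), RATE), cfg)
        img = render_tf_image(g, size=32)
        assert np.all(img.pixels == img.pixels[0, 0])

    def test_output_shape_and_dtype(self, tone, cfg):
        img = render_tf_image(compute_htd(tone, cfg), size=224)
        assert img.pixels.shape == (224, 224, 3) and img.pixels.dtype == np.uint8

    def test_brightest_row_maps_to_tone_bin(self, tone, cfg):
        g = compute_htd(tone, cfg)
        size = 224
        img = render_tf_image(g, size=size)
        gray = img.pixels.astype(float).sum(axis=2)
        row = np.unravel_index(gray.argmax(), gray.shape)[0]
        # rows run from high frequency (top) to low; invert the resize
        nbins = g.freqs.size
        bin_est = (1.0 - (row + 0.5) / size) * nbins
        bin_true = np.argmin(np.abs(g.freqs - 1000.0))
        assert abs(bin_est - bin_true) <= nbins / size + 1.5
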