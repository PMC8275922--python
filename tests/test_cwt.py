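"""Complex Morlet CWT: closed forms, oracle equivalence, invariances."""

import numpy as np
import pytest

from swdetect import (
    FrequencyGrid,
    MorletSpec,
    TimeSeries,
    cwt,
    cwt_direct,
    morlet_fourier,
    morlet_time,
    normalized_power,
)
from swdetect.cwt import power_at

FS = 250.0
SPEC = MorletSpec(fc=1.0)


def mixed_signal(duration=4.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    x = (
        np.sin(2 * np.pi * 2.7 * t)
        + 0.5 * np.sin(2 * np.pi * 3.3 * t + 0.4)
        + 0.3 * np.sin(2 * np.pi * 15.3 * t + 1.1)
    )
    return TimeSeries(x, fs, "mix")


class TestMotherWavelet:
    def test_value_at_origin(self):
        psi0 = morlet_time(0.0, SPEC)
        assert psi0.imag == 0.0
        assert psi0.real == pytest.approx(np.pi**-0.25)
        assert psi0.real == pytest.approx(0.7511, abs=1e-4)

    def test_envelope_even(self, rng):
        for t in rng.uniform(-4, 4, size=20):
            assert abs(morlet_time(t, SPEC)) == pytest.approx(abs(morlet_time(-t, SPEC)))

    def test_gaussian_decay_ratio(self):
        assert abs(morlet_time(5.0, SPEC)) / abs(morlet_time(0.0, SPEC)) == pytest.approx(
            np.exp(-12.5)
        )

    def test_fourier_peak_value_at_fc(self):
        assert morlet_fourier(1.0, SPEC) == pytest.approx(np.sqrt(2) * np.pi**0.25)
        assert morlet_fourier(1.0, SPEC) == pytest.approx(1.8828, abs=1e-4)

    def test_fourier_symmetric_about_fc(self, rng):
        for d in rng.uniform(0, 2, size=10):
            assert morlet_fourier(1.0 + d, SPEC) == pytest.approx(morlet_fourier(1.0 - d, SPEC))

    def test_fourier_negligible_far_from_fc(self):
        assert morlet_fourier(11.0, SPEC) < 1e-8
        assert morlet_fourier(-9.0, SPEC) < 1e-8

    def test_sampled_transform_matches_closed_form(self):
        """FFT of the sampled mother wavelet reproduces the analytic Gaussian."""
        dt = 1 / 64.0
        t = np.arange(-16.0, 16.0, dt)
        psi = morlet_time(t, SPEC)
        freqs = np.fft.fftfreq(t.size, dt)
        # integral FT with the phase referenced to t=0
        numeric = np.fft.fft(np.fft.ifftshift(psi)) * dt
        assert np.max(np.abs(numeric - morlet_fourier(freqs, SPEC))) < 1e-6


class TestTransform:
    def test_fft_path_matches_direct_integration(self):
        x = mixed_signal()
        grid = FrequencyGrid.from_frequencies([2.7, 3.3, 15.3], SPEC)
        fast = cwt(x, grid, SPEC)
        slow = cwt_direct(x, grid, SPEC)
        for i in range(len(grid)):
            m = fast.valid_mask[i]
            scale = np.max(np.abs(slow.coefficients[i, m]))
            err = np.max(np.abs(fast.coefficients[i, m] - slow.coefficients[i, m])) / scale
            assert err < 1e-6

    def test_time_shift_covariance(self):
        x = mixed_signal(duration=8.0)
        grid = FrequencyGrid.from_frequencies([3.0], SPEC)
        k = 100
        n = len(x)
        shifted = TimeSeries(
            np.concatenate([np.zeros(k), x.samples[: n - k]]), x.fs, "shifted"
        )
        a = cwt(x, grid, SPEC)
        b = cwt(shifted, grid, SPEC)
        # 7 wavelet SDs: the Gaussian tail must be below the 1e-9 comparison
        margin = int(7 * grid.scales[0] * x.fs) + 1
        idx = np.arange(margin, n - k - margin)
        ref = a.coefficients[0, idx]
        got = b.coefficients[0, idx + k]
        assert np.max(np.abs(got - ref)) / np.max(np.abs(ref)) < 1e-9

    def test_zero_signal_zero_coefficients(self):
        x = TimeSeries(np.zeros(500), FS, "zero")
        grid = FrequencyGrid.from_frequencies([3.0], SPEC)
        assert np.all(cwt(x, grid, SPEC).coefficients == 0)

    def test_linearity(self, rng):
        grid = FrequencyGrid.from_frequencies([2.7, 15.3], SPEC)
        a = TimeSeries(rng.normal(size=1000), FS, "a")
        b = TimeSeries(rng.normal(size=1000), FS, "b")
        combo = TimeSeries(2.0 * a.samples - 0.5 * b.samples, FS, "c")
        ca, cb, cc = (cwt(s, grid, SPEC).coefficients for s in (a, b, combo))
        assert np.allclose(cc, 2.0 * ca - 0.5 * cb, atol=1e-9)

    def test_nyquist_frequency_rejected(self):
        x = mixed_signal()
        grid = FrequencyGrid.from_frequencies([FS / 2], SPEC)
        with pytest.raises(ValueError, match="Nyquist"):
            cwt(x, grid, SPEC)

    def test_grid_requires_increasing_frequencies(self):
        with pytest.raises(ValueError):
            FrequencyGrid.from_frequencies([3.3, 2.7], SPEC)


class TestNormalizedPower:
    @pytest.mark.parametrize("c", [0.1, 1.0, 1000.0])
    def test_amplitude_invariance(self, c):
        x = mixed_signal()
        grid = FrequencyGrid.from_frequencies([2.7, 3.3, 15.3], SPEC)
        base = normalized_power(cwt(x, grid, SPEC), x).values
        xs = TimeSeries(c * x.samples, x.fs, "scaled")
        scaled = normalized_power(cwt(xs, grid, SPEC), xs).values
        assert np.max(np.abs(scaled - base)) < 1e-12 * max(1.0, base.max())

    def test_zero_variance_degenerate(self):
        x = TimeSeries(np.zeros(500), FS, "flat")
        grid = FrequencyGrid.from_frequencies([3.0], SPEC)
        with pytest.warns(UserWarning, match="zero-variance"):
            pm = normalized_power(cwt(x, grid, SPEC), x)
        assert pm.degenerate
        assert np.all(pm.values == 0.0)

    def test_sinusoid_power_peaks_at_own_frequency(self):
        t = np.arange(int(8 * FS)) / FS
        x = TimeSeries(np.sin(2 * np.pi * 3.0 * t), FS, "s3")
        freqs = [2.4, 2.7, 3.0, 3.3, 3.6]
        pm = power_at(x, freqs, SPEC)
        medians = [
            np.median(pm.values[i][pm.valid_mask[i]]) for i in range(len(freqs))
        ]
        assert freqs[int(np.argmax(medians))] == 3.0

    @pytest.mark.parametrize("f0", [2.7, 3.3, 15.3])
    def test_frequency_localization_of_detector_rows(self, f0):
        """Among the detector's rows, a pure tone excites its own row most."""
        t = np.arange(int(8 * FS)) / FS
        x = TimeSeries(np.sin(2 * np.pi * f0 * t), FS, "tone")
        freqs = [2.7, 3.3, 15.3]
        pm = power_at(x, freqs, SPEC)
        medians = [np.median(pm.values[i][pm.valid_mask[i]]) for i in range(3)]
        assert freqs[int(np.argmax(medians))] == f0

    def test_analytic_sinusoid_level(self):
        """A unit sinusoid's normalized power equals a*sqrt(pi) at its own row."""
        t = np.arange(int(12 * FS)) / FS
        x = TimeSeries(np.sin(2 * np.pi * 3.0 * t), FS, "s3")
        pm = power_at(x, [3.0], SPEC)
        level = np.median(pm.values[0][pm.valid_mask[0]])
        assert level == pytest.approx((1.0 / 3.0) * np.sqrt(np.pi), rel=5e-3)


class TestDiagnosticExports:
    def test_scalogram_csv_matrix(self, tmp_path):
        import pandas as pd

        t = np.arange(int(2 * FS)) / FS
        x = TimeSeries(np.sin(2 * np.pi * 3 * t), FS, "s")
        pm = power_at(x, [2.5, 3.0, 3.5], SPEC)
        out = tmp_path / "scalogram.csv"
        from swdetect.cwt import export_scalogram_csv

        export_scalogram_csv(pm, out)
        back = pd.read_csv(out, index_col=0)
        assert back.shape == (3, len(x))
        assert list(back.index) == [2.5, 3.0, 3.5]

    def test_scalogram_png_density_map(self, tmp_path):
        t = np.arange(int(2 * FS)) / FS
        x = TimeSeries(np.sin(2 * np.pi * 3 * t), FS, "s")
        pm = power_at(x, [2.5, 3.0, 3.5], SPEC)
        out = tmp_path / "scalogram.png"
        from swdetect.cwt import export_scalogram_png

        export_scalogram_png(pm, out, title="demo")
        assert out.stat().st_size > 1000
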