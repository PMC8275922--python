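"""Complex Morlet continuous wavelet transform via the Fourier-domain product.

The transform of a signal :math:`s(t)` at scale :math:`a` and time
:math:`t_0` is

.. math:: T[s](a, t_0) = \\frac{1}{\\sqrt{a}}
          \\int s(t)\\, \\psi^*\\!\\left(\\frac{t - t_0}{a}\\right) dt,

with the complex Morlet mother wavelet
:math:`\\psi(t) = \\pi^{-1/4} e^{2\\pi i f_c t} e^{-t^2/2}` whose Fourier
transform is the real Gaussian
:math:`\\hat\\psi(f) = \\sqrt{2}\\,\\pi^{1/4} e^{-2\\pi^2 (f - f_c)^2}`.
The center frequency :math:`f_c` is the peak of the wavelet's Fourier power
spectrum, and scale :math:`a` maps to the pseudofrequency
:math:`f_a = f_c / a`.

By the convolution theorem the transform over a whole buffer is computed as
one FFT of the signal followed, per scale, by a pointwise product with the
analytically sampled :math:`\\hat\\psi(a f)` and an inverse FFT — no signal
partitioning. Detection uses the instantaneous wavelet power normalized by
the signal variance, :math:`w^{(n)}(f_a, t_0) = |T[s](a, t_0)|^2 / \\sigma^2`.

A slow direct-integration evaluation of the defining integral
(:func:`cwt_direct`) is included as an independent test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signals import TimeSeries

__all__ = [
    "MorletSpec",
    "FrequencyGrid",
    "Scalogram",
    "PowerMap",
    "morlet_time",
    "morlet_fourier",
    "cwt",
    "cwt_direct",
    "normalized_power",
]

#: samples closer than this many wavelet time-constants (a seconds each) to a
#: buffer edge are flagged as edge-contaminated
_EDGE_STDS = 3.0


@dataclass(frozen=True)
class MorletSpec:
    """Complex Morlet mother wavelet with center frequency ``fc`` (Hz).

    The Gaussian envelope width is fixed (``exp(-t^2/2)``); ``fc`` is the
    single free parameter and controls the time/frequency trade-off: at
    pseudofrequency ``f`` the wavelet's time constant is ``a = fc / f``
    seconds and its spectral standard deviation is ``f / (2*pi*fc)`` Hz.
    """

    fc: float = 1.0

    def __post_init__(self) -> None:
        if not self.fc > 0:
            raise ValueError(f"center frequency must be positive, got {self.fc}")


def morlet_time(t: np.ndarray | float, spec: MorletSpec = MorletSpec()) -> np.ndarray | complex:
    """Mother wavelet in the time domain, ``pi**-0.25 * exp(2j pi fc t) * exp(-t^2/2)``."""
    t = np.asarray(t, dtype=np.float64)
    out = np.pi ** -0.25 * np.exp(2j * np.pi * spec.fc * t) * np.exp(-(t**2) / 2.0)
    return complex(out) if out.ndim == 0 else out


def morlet_fourier(f: np.ndarray | float, spec: MorletSpec = MorletSpec()) -> np.ndarray | float:
    """Fourier transform of the mother wavelet, a real Gaussian peaked at ``fc``."""
    f = np.asarray(f, dtype=np.float64)
    out = np.sqrt(2.0) * np.pi**0.25 * np.exp(-2.0 * np.pi**2 * (f - spec.fc) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing pseudofrequencies with their wavelet scales.

    Scales satisfy ``a = fc / f_a``, so the grid depends on the mother
    wavelet's center frequency.
    """

    frequencies: tuple[float, ...]
    scales: tuple[float, ...] = field(default=())

    @classmethod
    def from_frequencies(cls, freqs: Sequence[float], spec: MorletSpec = MorletSpec()) -> "FrequencyGrid":
        freqs = tuple(float(f) for f in freqs)
        if not freqs or any(f <= 0 for f in freqs):
            raise ValueError("pseudofrequencies must be positive")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("pseudofrequencies must be strictly increasing")
        return cls(frequencies=freqs, scales=tuple(spec.fc / f for f in freqs))

    def __len__(self) -> int:
        return len(self.frequencies)

    def index_of(self, f: float) -> int:
        """Row index of the grid frequency nearest ``f``."""
        return int(np.argmin(np.abs(np.asarray(self.frequencies) - f)))


@dataclass
class Scalogram:
    """Complex CWT coefficients on a (pseudofrequency x time) grid.

    ``valid_mask`` is False where a sample lies within three wavelet time
    constants (``3 a`` seconds) of either buffer end and is therefore
    contaminated by the zero-padded edges.
    """

    coefficients: np.ndarray  # (n_freqs, n_samples) complex
    grid: FrequencyGrid
    fs: float
    valid_mask: np.ndarray  # (n_freqs, n_samples) bool

    def row(self, f: float) -> np.ndarray:
        return self.coefficients[self.grid.index_of(f)]


@dataclass
class PowerMap:
    """Variance-normalized instantaneous wavelet power ``|T|^2 / sigma^2``."""

    values: np.ndarray  # (n_freqs, n_samples) real, >= 0
    variance: float
    grid: FrequencyGrid
    fs: float
    valid_mask: np.ndarray
    degenerate: bool = False

    def row(self, f: float) -> np.ndarray:
        return self.values[self.grid.index_of(f)]


def _next_pow2(n: int) -> int:
    return 1 << (max(n, 1) - 1).bit_length()


def cwt(x: TimeSeries, grid: FrequencyGrid, spec: MorletSpec = MorletSpec()) -> Scalogram:
    """Complex Morlet CWT of a whole buffer via the FFT product.

    The buffer is zero-padded to the next power of two at least twice its
    length before the frequency-domain product, so the implicit circular
    convolution never wraps wavelet tails around the buffer; the result is
    truncated back to the input length.

    Raises
    ------
    ValueError
        If any grid pseudofrequency reaches the Nyquist frequency.
    """
    n = len(x)
    if n < 2:
        raise ValueError("buffer must contain at least 2 samples")
    if max(grid.frequencies) >= x.fs / 2:
        raise ValueError(
            f"grid frequency {max(grid.frequencies)} Hz >= Nyquist ({x.fs / 2} Hz)"
        )
    nfft = _next_pow2(2 * n)
    X = np.fft.fft(x.samples, nfft)
    f = np.fft.fftfreq(nfft, d=1.0 / x.fs)
    coeffs = np.empty((len(grid), n), dtype=np.complex128)
    mask = np.empty((len(grid), n), dtype=bool)
    t = np.arange(n) / x.fs
    t_end = (n - 1) / x.fs
    for i, a in enumerate(grid.scales):
        psi_hat = morlet_fourier(a * f, spec)
        coeffs[i] = np.sqrt(a) * np.fft.ifft(X * psi_hat)[:n]
        margin = _EDGE_STDS * a
        mask[i] = (t >= margin) & (t <= t_end - margin)
    return Scalogram(coefficients=coeffs, grid=grid, fs=x.fs, valid_mask=mask)


def cwt_direct(x: TimeSeries, grid: FrequencyGrid, spec: MorletSpec = MorletSpec()) -> Scalogram:
    """Riemann-sum evaluation of the defining CWT integral (test oracle).

    Quadratic in the buffer length; intended for short fixtures only. Kept
    deliberately independent of the FFT path: it sums the time-domain
    product of the signal with the conjugated, scaled mother wavelet.
    """
    n = len(x)
    t = np.arange(n) / x.fs
    dt = 1.0 / x.fs
    coeffs = np.empty((len(grid), n), dtype=np.complex128)
    mask = np.empty((len(grid), n), dtype=bool)
    for i, a in enumerate(grid.scales):
        lag = (t[None, :] - t[:, None]) / a  # rows: t0, columns: t
        coeffs[i] = np.conj(morlet_time(lag, spec)) @ x.samples * (dt / np.sqrt(a))
        margin = _EDGE_STDS * a
        mask[i] = (t >= margin) & (t <= t[-1] - margin)
    return Scalogram(coefficients=coeffs, grid=grid, fs=x.fs, valid_mask=mask)


def normalized_power(scalogram: Scalogram, x: TimeSeries) -> PowerMap:
    """Instantaneous wavelet power normalized by the buffer variance.

    ``sigma^2`` is the unbiased sample variance of the buffer that was
    transformed (the streaming buffer, or the whole record in batch mode).
    Normalization makes the power dimensionless and invariant under
    amplitude scaling of the input. A zero-variance buffer is flagged
    degenerate and yields an all-zero map instead of dividing by zero.
    """
    sigma2 = float(np.var(x.samples, ddof=1)) if len(x) > 1 else 0.0
    if sigma2 <= 0.0:
        warnings.warn("zero-variance buffer: normalized power set to zero", stacklevel=2)
        return PowerMap(
            values=np.zeros_like(scalogram.coefficients, dtype=np.float64),
            variance=0.0,
            grid=scalogram.grid,
            fs=scalogram.fs,
            valid_mask=scalogram.valid_mask,
            degenerate=True,
        )
    values = np.abs(scalogram.coefficients) ** 2 / sigma2
    return PowerMap(
        values=values,
        variance=sigma2,
        grid=scalogram.grid,
        fs=scalogram.fs,
        valid_mask=scalogram.valid_mask,
    )


def power_at(x: TimeSeries, freqs: Sequence[float], spec: MorletSpec = MorletSpec()) -> PowerMap:
    """Convenience: normalized wavelet power of ``x`` at the given frequencies.

    Frequencies need not be sorted; rows are returned in the order given.
    """
    order = np.argsort(freqs)
    grid = FrequencyGrid.from_frequencies([freqs[i] for i in order], spec)
    pm = normalized_power(cwt(x, grid, spec), x)
    inverse = np.argsort(order)
    return PowerMap(
        values=pm.values[inverse],
        variance=pm.variance,
        grid=FrequencyGrid(tuple(float(f) for f in freqs), tuple(spec.fc / f for f in freqs)),
        fs=pm.fs,
        valid_mask=pm.valid_mask[inverse],
        degenerate=pm.degenerate,
    )


def export_scalogram_csv(pm: PowerMap, path: str) -> None:
    """Write a power map as a CSV matrix (first column = pseudofrequency)."""
    import pandas as pd

    n = pm.values.shape[1]
    df = pd.DataFrame(pm.values, index=list(pm.grid.frequencies), columns=np.arange(n) / pm.fs)
    df.index.name = "frequency_hz"
    df.to_csv(path, float_format="%.6g")


def export_scalogram_png(pm: PowerMap, path: str, title: str = "") -> None:
    """Render a power map as a (time x frequency) density image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = pm.values.shape[1]
    fig, ax = plt.subplots(figsize=(10, 4))
    extent = (0.0, n / pm.fs, pm.grid.frequencies[0], pm.grid.frequencies[-1])
    im = ax.imshow(pm.values, aspect="auto", origin="lower", extent=extent, cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pseudofrequency (Hz)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized wavelet power")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
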