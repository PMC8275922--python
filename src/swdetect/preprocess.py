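"""Three-filter EEG preprocessing cascade.

A power-line notch (second-order IIR biquad), a 6th-order high-pass
Butterworth at 0.5 Hz (baseline drift) and a 6th-order low-pass Butterworth
at 25 Hz (muscle activity) are applied in that order. Filtering is causal
(single pass) by default because the detector is meant to run in real time;
a zero-phase option exists for offline analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .signals import TimeSeries

__all__ = ["FilterSpec", "design_cascade", "preprocess", "cascade_response"]


@dataclass(frozen=True)
class FilterSpec:
    """Parameters of the preprocessing cascade.

    The notch realizes the "second-order IIR" power-line filter as a biquad
    at ``powerline_hz`` with quality factor ``notch_q`` (Q = 30 gives a
    −3 dB width of about 1.7 Hz at 50 Hz); 60 Hz is selectable for other
    mains regions.
    """

    powerline_hz: float = 50.0
    notch_q: float = 30.0
    hp_order: int = 6
    hp_cutoff: float = 0.5
    lp_order: int = 6
    lp_cutoff: float = 25.0
    zero_phase: bool = False

    def validate(self, fs: float) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff < fs / 2:
            raise ValueError(
                f"need 0 < hp_cutoff < lp_cutoff < fs/2, got "
                f"({self.hp_cutoff}, {self.lp_cutoff}) at fs={fs}"
            )
        if not 0 < self.powerline_hz < fs / 2:
            raise ValueError(f"powerline frequency {self.powerline_hz} outside (0, fs/2)")


def design_cascade(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the cascade as second-order sections (notch, then HP, then LP).

    Second-order sections keep the 0.5 Hz high-pass numerically stable at
    200–250 Hz sampling rates.
    """
    spec.validate(fs)
    b, a = sps.iirnotch(spec.powerline_hz, spec.notch_q, fs=fs)
    sections = [sps.tf2sos(b, a)]
    sections.append(sps.butter(spec.hp_order, spec.hp_cutoff, "highpass", fs=fs, output="sos"))
    sections.append(sps.butter(spec.lp_order, spec.lp_cutoff, "lowpass", fs=fs, output="sos"))
    sos = np.vstack(sections)
    # stability: all poles strictly inside the unit circle
    poles = np.concatenate([np.roots(sec[3:]) for sec in sos])
    assert np.all(np.abs(poles) < 1.0), "unstable preprocessing filter design"
    return sos


def preprocess(x: TimeSeries, spec: FilterSpec | None = None) -> TimeSeries:
    """Apply the notch → high-pass → low-pass cascade to one channel.

    Output has the same length and sampling rate; the label is preserved.
    """
    spec = spec or FilterSpec()
    sos = design_cascade(spec, x.fs)
    if spec.zero_phase:
        y = sps.sosfiltfilt(sos, x.samples)
    else:
        y = sps.sosfilt(sos, x.samples)
    return x.copy(samples=np.asarray(y, dtype=np.float64))


def cascade_response(spec: FilterSpec, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Complex frequency response of the designed cascade at ``freqs`` (Hz)."""
    sos = design_cascade(spec, fs)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    return h


def with_zero_phase(spec: FilterSpec, zero_phase: bool = True) -> FilterSpec:
    return replace(spec, zero_phase=zero_phase)
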