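"""Seeded generator of annotated synthetic absence-EEG records.

Emulates the statistical structure the detector assumes: two bipolar
channels (Fp1-T3, Fp2-T4) of band-limited 1/f ("pink") background noise
with, superimposed, bilateral ~3 Hz spike-and-wave trains — a slow
sinusoid with one sharp negative Gaussian transient phase-locked near each
wave trough — and, optionally, high-amplitude blink, muscle and motion
artifacts. The seizure waveform is shared between the channels (absence
discharges are bilateral, synchronous and symmetrical) while the background
noise is drawn independently per channel. Seizure onset and offset are
tapered with a 0.25 s cosine ramp: clinical onsets are abrupt, but abrupt
still spans tens of milliseconds, and a hard step would be a synthetic
discontinuity no real EEG contains.

Everything is deterministic given the configuration seed: identical
configurations produce bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signals import AnnotatedRecord, TimeSeries

__all__ = [
    "SynthConfig",
    "ArtifactSpec",
    "PlacementError",
    "gen_background",
    "gen_swd",
    "gen_record",
]

#: background band limits (Hz); clinical preprocessing keeps 0.5–25 Hz, the
#: raw surrogate is a little wider so the filters have work to do
_BG_BAND = (0.5, 70.0)

_TAPER_S = 0.25  # cosine onset/offset ramp


class PlacementError(RuntimeError):
    """Requested seizures/artifacts cannot be placed disjointly."""


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact class: kind, occurrence rate and peak amplitude.

    ``kind``: ``blink`` (0.3 s raised-cosine pulse), ``muscle`` (0.5–2 s
    burst of 25–70 Hz noise) or ``motion`` (1–3 s low-frequency excursion).
    ``rate_per_hour`` is the expected count per hour; ``amplitude_uv`` the
    peak amplitude in μV.
    """

    kind: str
    rate_per_hour: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.kind not in ("blink", "muscle", "motion"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.rate_per_hour < 0 or self.amplitude_uv < 0:
            raise ValueError("artifact rate and amplitude must be non-negative")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic record.

    Defaults mirror the clinical material the detector was built for:
    250 Hz sampling, ~3 Hz SWDs with seizure durations of 12 ± 4 s
    (truncated at the 2 s seizure definition), slow waves of 100 μV and
    spikes of 300 μV (differential-montage spikes reach hundreds of μV)
    over a 30 μV RMS background. ``spike_width`` is the full width at half
    maximum of the Gaussian transient; 40 ms lies in the canonical
    20–70 ms epileptic-spike range. ``end_drift`` > 0 lowers the
    instantaneous SWD frequency linearly over the final third of each
    seizure, emulating the end-of-seizure slowing that fragments slow-wave
    envelopes.
    """

    duration: float = 600.0
    fs: float = 250.0
    swd_frequency: float = 3.0
    end_drift: float = 0.0
    wave_amplitude: float = 100.0
    spike_amplitude: float = 300.0
    spike_width: float = 0.040
    spike_sign: int = -1
    background_rms: float = 30.0
    n_seizures: int = 4
    seizure_duration_mean: float = 12.0
    seizure_duration_sd: float = 4.0
    artifact_spec: tuple[ArtifactSpec, ...] = ()
    seed: int = 0
    channel_labels: tuple[str, str] = ("Fp1-T3", "Fp2-T4")

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.fs not in (200.0, 250.0) and not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.swd_frequency <= 0:
            raise ValueError("swd_frequency must be positive")
        if self.spike_sign not in (-1, 1):
            raise ValueError("spike_sign must be -1 (trough-locked, conventional) or +1")


def gen_background(duration: float, fs: float, rms: float, seed: int) -> TimeSeries:
    """Zero-mean pink-noise EEG surrogate scaled to the requested RMS.

    Spectral density falls as 1/f within 0.5–70 Hz and is zero outside the
    band. Synthesis is done in the frequency domain with independent
    Gaussian coefficients, so the trace is stationary and Gaussian.
    """
    if duration <= 0 or fs <= 0 or rms <= 0:
        raise ValueError("duration, fs and rms must all be positive")
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration*fs must be at least 1 sample")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    band = (freqs >= _BG_BAND[0]) & (freqs <= _BG_BAND[1])
    amp[band] = 1.0 / np.sqrt(freqs[band])
    spectrum = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n)
    x -= x.mean()
    x *= rms / np.sqrt(np.mean(x**2))
    return TimeSeries(samples=x, fs=fs, label="background")


def gen_swd(duration: float, fs: float, cfg: SynthConfig) -> TimeSeries:
    """Noise-free spike-and-wave train of the given duration.

    A sinusoid at ``swd_frequency`` plus one Gaussian transient per cycle,
    phase-locked to each wave trough (negative polarity by default,
    matching conventional SWD morphology). With ``end_drift`` > 0 the
    instantaneous frequency decreases linearly by ``end_drift`` Hz over the
    final third of the segment. Deterministic: no randomness enters.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if cfg.spike_width >= 0.5 / cfg.swd_frequency:
        raise ValueError(
            f"spike_width {cfg.spike_width}s must be below half the wave period "
            f"({0.5 / cfg.swd_frequency:.3f}s)"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    f_inst = np.full(n, cfg.swd_frequency)
    if cfg.end_drift > 0:
        t_drift = 2.0 * duration / 3.0
        ramp = np.clip((t - t_drift) / (duration - t_drift), 0.0, 1.0)
        f_inst = cfg.swd_frequency - cfg.end_drift * ramp
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    x = cfg.wave_amplitude * np.sin(phase)

    if cfg.spike_amplitude != 0:
        sigma = cfg.spike_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> SD
        # wave troughs: phase = 3*pi/2 (mod 2*pi); find the crossings
        trough_phases = np.arange(1.5 * np.pi, phase[-1], 2.0 * np.pi)
        trough_times = np.interp(trough_phases, phase, t)
        for tk in trough_times:
            x += cfg.spike_sign * cfg.spike_amplitude * np.exp(-((t - tk) ** 2) / (2 * sigma**2))

    # cosine onset/offset ramps
    ramp_n = min(int(round(_TAPER_S * fs)), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        x[:ramp_n] *= ramp
        x[-ramp_n:] *= ramp[::-1]
    return TimeSeries(samples=x, fs=fs, label="swd")


def _draw_intervals(
    rng: np.random.Generator,
    cfg: SynthConfig,
    margin: float = 5.0,
    gap: float = 2.0,
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    """Disjoint seizure intervals: uniform starts, truncated-normal durations."""
    intervals: list[tuple[float, float]] = []
    tries = 0
    while len(intervals) < cfg.n_seizures:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {cfg.n_seizures} disjoint seizures in "
                f"{cfg.duration}s after {max_tries} attempts"
            )
        tries += 1
        d = rng.normal(cfg.seizure_duration_mean, cfg.seizure_duration_sd)
        if d < 2.0:  # a seizure is an SWD lasting more than 2 s
            continue
        lo, hi = margin, cfg.duration - margin - d
        if hi <= lo:
            continue
        start = rng.uniform(lo, hi)
        cand = (start, start + d)
        if all(cand[1] + gap <= s or e + gap <= cand[0] for s, e in intervals):
            intervals.append(cand)
    return sorted(intervals)


def _artifact_waveform(
    kind: str, amplitude: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    if kind == "blink":
        n = int(round(0.3 * fs))
        return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
    if kind == "muscle":
        dur = rng.uniform(0.5, 2.0)
        n = int(round(dur * fs))
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        amp = ((freqs >= 25.0) & (freqs <= 70.0)).astype(float)
        spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
        burst = np.fft.irfft(spec, n)
        peak = np.max(np.abs(burst))
        burst *= amplitude / peak if peak > 0 else 0.0
        window = np.hanning(n)
        return burst * window
    if kind == "motion":
        dur = rng.uniform(1.0, 3.0)
        n = int(round(dur * fs))
        # smooth low-frequency excursion: single raised-cosine lobe with a
        # random sign, like an electrode-cable pull
        sign = rng.choice((-1.0, 1.0))
        return sign * amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
    raise ValueError(f"unknown artifact kind {kind!r}")


def gen_record(cfg: SynthConfig) -> AnnotatedRecord:
    """Generate one annotated two-channel record under the given conditions.

    Background noise is drawn independently per channel; the SWD waveform
    and the artifacts are shared (bilateral). Artifacts are placed outside
    the seizure intervals. ``reference_events`` are exactly the inserted
    SWD intervals (taper included).
    """
    root = np.random.SeedSequence(cfg.seed)
    s_bg1, s_bg2, s_place, s_artifacts = root.spawn(4)
    n = int(round(cfg.duration * cfg.fs))

    bg1 = gen_background(cfg.duration, cfg.fs, cfg.background_rms, seed=s_bg1)
    bg2 = gen_background(cfg.duration, cfg.fs, cfg.background_rms, seed=s_bg2)

    swd_track = np.zeros(n)
    rng_place = np.random.default_rng(s_place)
    intervals = _draw_intervals(rng_place, cfg) if cfg.n_seizures > 0 else []
    for start, end in intervals:
        seg = gen_swd(end - start, cfg.fs, cfg)
        i0 = int(round(start * cfg.fs))
        i1 = min(n, i0 + len(seg))
        swd_track[i0:i1] += seg.samples[: i1 - i0]

    artifact_track = np.zeros(n)
    rng_art = np.random.default_rng(s_artifacts)
    for spec in cfg.artifact_spec:
        count = rng_art.poisson(spec.rate_per_hour * cfg.duration / 3600.0)
        for _ in range(count):
            wav = _artifact_waveform(spec.kind, spec.amplitude_uv, cfg.fs, rng_art)
            placed = False
            for _attempt in range(200):
                start = rng_art.uniform(0.0, cfg.duration - wav.size / cfg.fs)
                end = start + wav.size / cfg.fs
                if all(end + 1.0 <= s or e + 1.0 <= start for s, e in intervals):
                    i0 = int(round(start * cfg.fs))
                    artifact_track[i0 : i0 + wav.size] += wav
                    placed = True
                    break
            if not placed:
                raise PlacementError("could not place an artifact outside the seizures")

    ch1 = TimeSeries(bg1.samples + swd_track + artifact_track, cfg.fs, cfg.channel_labels[0])
    ch2 = TimeSeries(bg2.samples + swd_track + artifact_track, cfg.fs, cfg.channel_labels[1])
    return AnnotatedRecord(channels=[ch1, ch2], reference_events=intervals)


def gen_corpus(
    n_records: int,
    base_seed: int,
    cfg: SynthConfig | None = None,
    **overrides,
) -> list[AnnotatedRecord]:
    """Generate ``n_records`` records with per-record seeds derived from
    ``base_seed`` (record i uses ``base_seed + i``)."""
    cfg = cfg or SynthConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    return [gen_record(replace(cfg, seed=base_seed + i)) for i in range(n_records)]
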