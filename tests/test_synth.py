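"""Synthetic absence-EEG generator: determinism, spectra, morphology, placement."""

import numpy as np
import pytest
from scipy import signal as sps

from swdetect import ArtifactSpec, SynthConfig, gen_background, gen_record, gen_swd
from swdetect.synth import PlacementError


class TestBackground:
    def test_rms_scaling_and_zero_mean(self):
        bg = gen_background(60.0, 250.0, rms=30.0, seed=1)
        rms = np.sqrt(np.mean(bg.samples**2))
        assert abs(rms - 30.0) / 30.0 < 0.01
        assert abs(bg.samples.mean()) < 1e-9 * 30.0

    def test_seed_determinism(self):
        a = gen_background(60.0, 250.0, 30.0, seed=1)
        b = gen_background(60.0, 250.0, 30.0, seed=1)
        assert np.array_equal(a.samples, b.samples)
        c = gen_background(60.0, 250.0, 30.0, seed=2)
        assert not np.array_equal(a.samples, c.samples)

    def test_pink_spectral_slope(self):
        """log-log periodogram slope over [1, 40] Hz is about -1 (pink noise)."""
        bg = gen_background(60.0, 250.0, 30.0, seed=1)
        f, p = sps.welch(bg.samples, fs=250.0, nperseg=4096)
        band = (f >= 1.0) & (f <= 40.0)
        slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
        assert -1.3 < slope < -0.7

    @pytest.mark.parametrize("bad", [dict(duration=0), dict(fs=-1), dict(rms=0)])
    def test_invalid_arguments(self, bad):
        kwargs = dict(duration=10.0, fs=250.0, rms=30.0, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            gen_background(kwargs["duration"], kwargs["fs"], kwargs["rms"], kwargs["seed"])


class TestSwd:
    def test_dominant_frequency_without_spikes(self):
        cfg = SynthConfig(spike_amplitude=0.0)
        seg = gen_swd(10.0, 250.0, cfg)
        f, p = sps.periodogram(seg.samples, fs=250.0)
        assert abs(f[np.argmax(p)] - 3.0) <= 0.1

    def test_one_spike_per_cycle(self):
        """10 s at 3 Hz: exactly 30 spike transients (one per wave trough).

        The onset/offset cosine ramps attenuate the outermost transients, so
        peaks are counted on the noise-free trace at a low height bound while
        the interior ones must reach the full 300 uV amplitude.
        """
        cfg = SynthConfig(wave_amplitude=0.0, spike_amplitude=300.0, spike_width=0.04, spike_sign=+1)
        seg = gen_swd(10.0, 250.0, cfg)
        peaks, props = sps.find_peaks(seg.samples, height=10.0)
        assert len(peaks) == int(10.0 * 3.0)
        assert np.sum(props["peak_heights"] > 290.0) >= 28

    def test_spikes_negative_by_default_at_troughs(self):
        cfg = SynthConfig(wave_amplitude=0.0)
        seg = gen_swd(5.0, 250.0, cfg)
        assert seg.samples.min() < -250.0
        assert seg.samples.max() < 50.0

    def test_zero_amplitudes_give_zero_trace(self):
        cfg = SynthConfig(wave_amplitude=0.0, spike_amplitude=0.0)
        seg = gen_swd(5.0, 250.0, cfg)
        assert np.all(seg.samples == 0.0)

    def test_end_drift_lowers_final_frequency(self):
        cfg = SynthConfig(spike_amplitude=0.0, end_drift=1.0)
        seg = gen_swd(12.0, 250.0, cfg)
        f, p = sps.periodogram(seg.samples[-2 * 250 :], fs=250.0)
        assert f[np.argmax(p)] < 2.7

    def test_wide_spike_rejected(self):
        cfg = SynthConfig(spike_width=0.2)  # half wave period at 3 Hz is 1/6 s
        with pytest.raises(ValueError):
            gen_swd(5.0, 250.0, cfg)


class TestRecord:
    def test_reference_event_count(self):
        rec = gen_record(SynthConfig(duration=300.0, n_seizures=4, seed=3))
        assert len(rec.reference_events) == 4

    def test_no_seizures_is_pure_background(self):
        rec = gen_record(SynthConfig(duration=60.0, n_seizures=0, seed=3))
        assert rec.reference_events == []
        assert np.max(np.abs(rec.channels[0].samples)) < 6.5 * 30.0

    def test_record_determinism_is_bitwise(self):
        cfg = SynthConfig(duration=120.0, seed=9, n_seizures=2)
        a, b = gen_record(cfg), gen_record(cfg)
        assert np.array_equal(a.channels[0].samples, b.channels[0].samples)
        assert np.array_equal(a.channels[1].samples, b.channels[1].samples)
        assert a.reference_events == b.reference_events

    def test_events_disjoint_inside_record_and_long_enough(self):
        rec = gen_record(SynthConfig(duration=300.0, n_seizures=5, seed=21))
        prev_end = 0.0
        for s, e in rec.reference_events:
            assert 0.0 <= s < e <= 300.0
            assert e - s >= 2.0
            assert s >= prev_end
            prev_end = e

    def test_channels_share_seizure_not_noise(self):
        rec = gen_record(SynthConfig(duration=120.0, n_seizures=1, seed=5,
                                     seizure_duration_mean=10.0, seizure_duration_sd=1.0))
        s, e = rec.reference_events[0]
        fs = rec.fs
        sl = slice(int(s * fs), int(e * fs))
        a, b = rec.channels[0].samples, rec.channels[1].samples
        r_seiz = np.corrcoef(a[sl], b[sl])[0, 1]
        quiet = slice(0, int(5 * fs))
        r_quiet = np.corrcoef(a[quiet], b[quiet])[0, 1]
        assert r_seiz > 0.9  # bilateral, synchronous, symmetrical
        assert abs(r_quiet) < 0.3  # independent background

    def test_motion_artifacts_exceed_1000uv_outside_events(self):
        spec = (ArtifactSpec("motion", rate_per_hour=120.0, amplitude_uv=2000.0),)
        rec = gen_record(SynthConfig(duration=300.0, n_seizures=0, artifact_spec=spec, seed=4))
        assert np.max(np.abs(rec.channels[0].samples)) > 1000.0

    def test_background_bounded_without_artifacts(self):
        """No spurious SWD-like amplitude in pure background (<= 6x RMS)."""
        rec = gen_record(SynthConfig(duration=600.0, n_seizures=0, seed=17))
        for ch in rec.channels:
            assert np.max(np.abs(ch.samples)) <= 6.0 * 30.0

    def test_impossible_placement_raises(self):
        cfg = SynthConfig(duration=30.0, n_seizures=10, seizure_duration_mean=12.0,
                          seizure_duration_sd=0.5, seed=0)
        with pytest.raises(PlacementError):
            gen_record(cfg)
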