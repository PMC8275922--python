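"""Detector checks and end-to-end detection behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swdetect import (
    DetectorParams,
    SynthConfig,
    TimeSeries,
    amplitude_check,
    band_envelope,
    detect_channel,
    detect_record,
    merge_envelopes,
    run_detection,
    spike_check,
    variance_check,
)
from swdetect.detector import Envelope
from swdetect.synth import ArtifactSpec, gen_record

FS = 250.0


class TestEnvelope:
    def test_thresholding(self):
        env = band_envelope(np.array([0.01, 0.06, 0.07, 0.02]), 0.05, FS)
        assert env.mask.tolist() == [False, True, True, False]
        assert env.intervals() == [(1, 3)]

    def test_all_below_gives_empty(self):
        env = band_envelope(np.full(100, 0.01), 0.05, FS)
        assert env.intervals() == []

    def test_all_above_gives_full_run(self):
        env = band_envelope(np.full(100, 0.99), 0.05, FS)
        assert env.intervals() == [(0, 100)]

    def test_merge_is_pointwise_or(self):
        e1 = Envelope(np.array([True, True, False, False]), FS)
        e2 = Envelope(np.array([False, True, True, False]), FS)
        assert merge_envelopes(e1, e2).mask.tolist() == [True, True, True, False]

    def test_merge_identity_with_empty(self):
        e = Envelope(np.array([True, False, True]), FS)
        empty = Envelope(np.zeros(3, dtype=bool), FS)
        assert merge_envelopes(e, empty).mask.tolist() == e.mask.tolist()

    @given(st.lists(st.booleans(), min_size=1, max_size=64))
    @settings(derandomize=True, max_examples=25)
    def test_merge_commutative(self, bits):
        a = Envelope(np.array(bits), FS)
        b = Envelope(np.array(bits[::-1]), FS)
        assert np.array_equal(merge_envelopes(a, b).mask, merge_envelopes(b, a).mask)

    @given(st.floats(min_value=0.01, max_value=0.5), st.floats(min_value=0.0, max_value=0.5))
    @settings(derandomize=True, max_examples=25)
    def test_envelope_shrinks_as_threshold_rises(self, t_low, bump):
        """Raising T_E can only turn mask samples off, never on."""
        rng = np.random.default_rng(42)
        w = rng.exponential(0.1, size=500)
        lo = band_envelope(w, t_low, FS).mask
        hi = band_envelope(w, t_low + bump, FS).mask
        assert not np.any(hi & ~lo)


class TestSpikeCheck:
    def test_boundary_fraction_passes_at_pt(self):
        w = np.zeros(100)
        w[:12] = 1.0  # 12% of samples above threshold
        ok, frac = spike_check(w, (0, 100), t_spike=0.012, pt_fraction=0.12)
        assert ok and frac == pytest.approx(0.12)

    def test_just_below_fails(self):
        w = np.zeros(100)
        w[:11] = 1.0
        ok, frac = spike_check(w, (0, 100), 0.012, 0.12)
        assert not ok and frac == pytest.approx(0.11)

    def test_zero_power_fails(self):
        ok, frac = spike_check(np.zeros(50), (0, 50), 0.012, 0.12)
        assert not ok and frac == 0.0

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            spike_check(np.zeros(10), (5, 5), 0.012, 0.12)

    @given(st.floats(min_value=0.0, max_value=0.5))
    @settings(derandomize=True, max_examples=25)
    def test_raising_threshold_never_rescues_a_failure(self, bump):
        rng = np.random.default_rng(7)
        w = rng.exponential(0.05, size=200)
        ok_low, _ = spike_check(w, (0, 200), 0.02, 0.12)
        ok_high, _ = spike_check(w, (0, 200), 0.02 + bump, 0.12)
        assert ok_low or not ok_high


class TestAmplitudeCheck:
    def test_soft_limit_fraction(self):
        seg = np.zeros(100)
        seg[:11] = 600.0  # 11% beyond +-500 uV
        assert not amplitude_check(seg)
        seg[:10] = 600.0
        seg[10] = 0.0  # exactly 10% is tolerated
        assert amplitude_check(seg)

    def test_hard_limit_single_sample(self):
        seg = np.zeros(1000)
        seg[500] = 1100.0
        assert not amplitude_check(seg)

    def test_physiological_amplitudes_pass(self):
        rng = np.random.default_rng(0)
        assert amplitude_check(rng.uniform(-400, 400, size=1000))


class TestVarianceCheck:
    def test_pulsatile_short_interval_passes(self):
        fs = FS
        n = int(4 * fs)
        w = np.zeros(n)
        # spike-rate pulses of realistic ~0.07 s width and 0.35 peak power
        for start in range(0, n, int(fs / 3)):
            w[start : start + 17] = 0.35
        assert np.var(w) > 0.008
        assert variance_check(w, (0, n), fs, t_variance=0.008)

    def test_constant_power_fails(self):
        n = int(4 * FS)
        assert not variance_check(np.full(n, 0.5), (0, n), FS, 0.008)

    def test_long_interval_exempt(self):
        n = int(6 * FS)
        assert variance_check(np.full(n, 0.5), (0, n), FS, 0.008)


class TestEndToEnd:
    def test_single_swd_detected_once(self, swd_record_factory, default_params):
        rec = swd_record_factory(10.0)
        events = run_detection(rec, default_params)
        assert len(events) == 1
        (s, e), ev = rec.reference_events[0], events[0]
        assert ev.start < e and s < ev.end  # overlaps the true interval
        assert ev.flags >= {"duration", "amplitude", "spike", "variance"}

    def test_subsecond_swd_not_detected(self, swd_record_factory, default_params):
        rec = swd_record_factory(1.5)
        assert len(run_detection(rec, default_params)) == 0

    def test_pure_background_has_no_pulsatile_events(self, default_params):
        """Background never shows spike-band pulsatility: with the variance
        check applied to every candidate (no 5 s exemption), ten minutes of
        artifact-free background yields nothing."""
        import dataclasses

        rec = gen_record(SynthConfig(duration=600.0, n_seizures=0, seed=201))
        p = dataclasses.replace(default_params, variance_check_max_duration=1e9)
        assert len(run_detection(rec, p)) == 0

    def test_motion_artifact_record_yields_nothing(self, default_params):
        """+-2000 uV motion artifacts and no seizures: amplitude check wins."""
        import dataclasses

        spec = (ArtifactSpec("motion", rate_per_hour=60.0, amplitude_uv=2000.0),)
        rec = gen_record(SynthConfig(duration=600.0, n_seizures=0, artifact_spec=spec, seed=31))
        p = dataclasses.replace(default_params, variance_check_max_duration=1e9)
        events = run_detection(rec, p)
        assert len(events) == 0

    def test_bilateral_swd_gives_one_merged_event(self, swd_record_factory, default_params):
        rec = swd_record_factory(10.0)
        events = run_detection(rec, default_params)
        assert len(events) == 1
        assert set(events[0].channels) == {"Fp1-T3", "Fp2-T4"}

    def test_unilateral_swd_names_its_channel(self, default_params):
        from swdetect import gen_swd

        cfg = SynthConfig(duration=60.0, n_seizures=0, seed=7)
        rec = gen_record(cfg)
        seg = gen_swd(10.0, rec.fs, cfg)
        i0 = int(25.0 * rec.fs)
        rec.channels[0].samples[i0 : i0 + len(seg)] += seg.samples
        events = run_detection(rec, default_params)
        assert len(events) == 1
        assert events[0].channels == ("Fp1-T3",)

    def test_determinism(self, swd_record_factory, default_params):
        rec = swd_record_factory(10.0)
        a = run_detection(rec, default_params)
        b = run_detection(rec, default_params)
        assert a == b

    def test_empty_record_empty_list(self, default_params):
        from swdetect.detector import detect_record

        assert len(detect_record([], default_params)) == 0

    def test_superpose_mode_detects_bilateral_swd(self, swd_record_factory):
        p = DetectorParams(channel_mode="superpose")
        rec = swd_record_factory(10.0)
        events = run_detection(rec, p)
        assert len(events) == 1
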