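import numpy as np
import pytest

from swdetect import (
    AnnotatedRecord,
    DetectorParams,
    SynthConfig,
    TimeSeries,
    gen_record,
    gen_swd,
)


@pytest.fixture(scope="session")
def default_params() -> DetectorParams:
    return DetectorParams()


@pytest.fixture(scope="session")
def easy_record() -> AnnotatedRecord:
    """120 s record with one ~10 s seizure: comfortably detectable."""
    return gen_record(
        SynthConfig(
            duration=120.0,
            n_seizures=1,
            seizure_duration_mean=10.0,
            seizure_duration_sd=1.0,
            seed=11,
        )
    )


def inject_swd(record: AnnotatedRecord, start: float, duration: float, cfg: SynthConfig) -> AnnotatedRecord:
    """Add an exact-duration SWD to both channels of a record (bilateral)."""
    seg = gen_swd(duration, record.fs, cfg)
    i0 = int(round(start * record.fs))
    channels = []
    for ch in record.channels:
        samples = ch.samples.copy()
        samples[i0 : i0 + len(seg)] += seg.samples[: len(samples) - i0]
        channels.append(TimeSeries(samples, ch.fs, ch.label))
    events = sorted(record.reference_events + [(start, start + duration)])
    return AnnotatedRecord(channels=channels, reference_events=events)


@pytest.fixture()
def swd_record_factory():
    """Build a 60 s two-channel record with one SWD of exact duration."""

    def build(duration: float, seed: int = 7, record_duration: float = 60.0, **cfg_overrides):
        cfg = SynthConfig(
            duration=record_duration, n_seizures=0, seed=seed, **cfg_overrides
        )
        base = gen_record(cfg)
        start = record_duration / 2.0 - duration / 2.0
        return inject_swd(base, start, duration, cfg)

    return build


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
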