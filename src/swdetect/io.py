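"""Reading and writing EEG records and seizure-event files.

Supported record formats: EDF/EDF+ (read via MNE, written by a minimal
16-bit EDF+ writer with reference events stored as EDF+ annotations) and
plain CSV (one column per channel, values in microvolts, with a ``time_s``
column carrying the sampling grid). Event files are CSV or JSON with columns
``start_s``, ``end_s``, ``channels``, ``flags``.

Channel-label matching is case-insensitive and ignores whitespace; EDF
labels such as ``"EEG Fp1-REF"`` are matched by their electrode token, so
``"FP1"``, ``"Fp1"`` and ``"EEG Fp1-REF"`` all name the same electrode.
"""

from __future__ import annotations

import csv
import json
import math
import re
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .signals import AnnotatedRecord, EventList, SeizureEvent, TimeSeries

__all__ = [
    "MissingChannelError",
    "InconsistentRecordError",
    "EventParseError",
    "read_record",
    "read_edf_annotations",
    "make_bipolar",
    "write_record",
    "write_events",
    "read_events",
]

#: Sampling rates used by the clinical hardware the detector targets.
_EXPECTED_RATES = (200.0, 250.0)


class MissingChannelError(ValueError):
    """A requested electrode is absent from the record."""

    def __init__(self, channel: str, available: Sequence[str]) -> None:
        self.channel = channel
        super().__init__(
            f"channel {channel!r} not found; available channels: {sorted(available)}"
        )


class InconsistentRecordError(ValueError):
    """Channels that must be combined disagree in length or sampling rate."""


class EventParseError(ValueError):
    """An event file could not be parsed; carries the offending line number."""

    def __init__(self, path: str | Path, line: int, message: str) -> None:
        self.line = line
        super().__init__(f"{path}: line {line}: {message}")


def _electrode_token(label: str) -> str:
    """Normalize a channel label to its electrode token ("EEG Fp1-REF" -> "FP1")."""
    s = re.sub(r"\s+", "", label).upper()
    s = re.sub(r"^EEG", "", s)
    s = re.sub(r"-(REF|LE|AVG|A1|A2)$", "", s)
    return s


def find_channel(channels: Mapping[str, TimeSeries], name: str) -> TimeSeries:
    """Look up a channel by label, tolerant to case/whitespace/EDF decoration."""
    want = _electrode_token(name)
    for label, ts in channels.items():
        if _electrode_token(label) == want:
            return ts
    raise MissingChannelError(name, list(channels))


# ---------------------------------------------------------------------------
# record reading


def read_record(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
) -> dict[str, TimeSeries]:
    """Read a multichannel EEG record into a label -> :class:`TimeSeries` map.

    Parameters
    ----------
    path : path
        EDF/EDF+ or CSV file.
    format : {"edf", "csv"}, optional
        Inferred from the file extension when omitted.
    fs : float, optional
        Sampling rate for CSV files lacking a ``time_s`` column.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() in {".edf", ".bdf"} else "csv"
    if format == "edf":
        channels = _read_edf(path)
    elif format == "csv":
        channels = _read_csv(path, fs=fs)
    else:
        raise ValueError(f"unsupported record format {format!r}")
    rates = {ts.fs for ts in channels.values()}
    if len(rates) > 1:
        raise InconsistentRecordError(f"mixed sampling rates in {path}: {sorted(rates)}")
    rate = rates.pop()
    if rate not in _EXPECTED_RATES:
        warnings.warn(
            f"sampling rate {rate} Hz differs from the 200/250 Hz clinical hardware; "
            "the detector is rate-agnostic and proceeds",
            stacklevel=2,
        )
    return channels


def _read_edf(path: Path) -> dict[str, TimeSeries]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts; EEG work is in microvolts
    return {
        name: TimeSeries(samples=row, fs=float(raw.info["sfreq"]), label=name)
        for name, row in zip(raw.ch_names, data)
    }


def read_edf_annotations(path: str | Path) -> EventList:
    """Read EDF+ annotations as an event list (onset/duration in seconds)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    events = [
        SeizureEvent(float(on), float(on) + float(dur))
        for on, dur in zip(raw.annotations.onset, raw.annotations.duration)
        if dur > 0
    ]
    return EventList(events)


def _read_csv(path: Path, fs: float | None = None) -> dict[str, TimeSeries]:
    import pandas as pd

    df = pd.read_csv(path)
    time_col = next((c for c in df.columns if c.lower() in {"time_s", "time", "t"}), None)
    if time_col is not None:
        t = df[time_col].to_numpy(dtype=float)
        if t.size < 2:
            raise InconsistentRecordError(f"{path}: time column too short to infer fs")
        fs = round(1.0 / float(np.median(np.diff(t))), 6)
        df = df.drop(columns=[time_col])
    if fs is None:
        raise ValueError(f"{path}: CSV has no time column; pass fs explicitly")
    return {
        str(col): TimeSeries(samples=df[col].to_numpy(dtype=float), fs=float(fs), label=str(col))
        for col in df.columns
    }


# ---------------------------------------------------------------------------
# montage


def make_bipolar(
    channels: Mapping[str, TimeSeries],
    pairs: Sequence[tuple[str, str]],
) -> list[TimeSeries]:
    """Build bipolar derivations (anode minus cathode) such as Fp1-T3.

    The longitudinal bipolar montage augments both the spikes and the slow
    waves of an SWD relative to referential channels, which is why the
    detector operates on Fp1-T3 and Fp2-T4.
    """
    out: list[TimeSeries] = []
    for anode, cathode in pairs:
        a = find_channel(channels, anode)
        c = find_channel(channels, cathode)
        if len(a) != len(c) or a.fs != c.fs:
            raise InconsistentRecordError(
                f"channels {anode!r} and {cathode!r} disagree in length or sampling rate"
            )
        out.append(TimeSeries(samples=a.samples - c.samples, fs=a.fs, label=f"{anode}-{cathode}"))
    return out


# ---------------------------------------------------------------------------
# record writing


def write_record(
    record: AnnotatedRecord,
    path: str | Path,
    format: str | None = None,
    events_path: str | Path | None = None,
) -> None:
    """Write an annotated record as EDF+ (annotations embedded) or CSV.

    For CSV output the reference events go to ``events_path`` (default:
    ``<path stem>_events.csv``) as a two-column ``start_s,end_s`` sidecar.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        _write_edf(record, path)
    elif format == "csv":
        import pandas as pd

        n = len(record.channels[0])
        data = {"time_s": np.arange(n) / record.fs}
        for ch in record.channels:
            data[ch.label] = ch.samples
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")
        if events_path is None:
            events_path = path.with_name(path.stem + "_events.csv")
        pd.DataFrame(record.reference_events, columns=["start_s", "end_s"]).to_csv(
            events_path, index=False, float_format="%.6f"
        )
    else:
        raise ValueError(f"unsupported record format {format!r}")


def _ascii_field(value: object, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        # shorten floats that overflow their fixed-width header field
        s = f"{float(s):.{max(width - 6, 1)}g}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _write_edf(record: AnnotatedRecord, path: Path) -> None:
    """Minimal EDF+C writer: 16-bit samples, 1 s data records, one annotation signal."""
    fs = record.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n = len(record.channels[0])
    n_records = math.ceil(n / spr)

    # annotation stream: one time-keeping TAL per record; all events in record 0
    tals = []
    for i in range(n_records):
        tal = f"+{i}\x14\x14\x00".encode("ascii")
        if i == 0:
            for s, e in record.reference_events:
                tal += f"+{s:.6f}\x15{e - s:.6f}\x14seizure\x14\x00".encode("ascii")
        tals.append(tal)
    ann_bytes = 2 * math.ceil(max(len(t) for t in tals) / 2)
    ann_spr = ann_bytes // 2

    phys_max = [max(1.0, float(np.max(np.abs(ch.samples)))) for ch in record.channels]
    ns = len(record.channels) + 1

    labels = [ch.label for ch in record.channels] + ["EDF Annotations"]
    header = b""
    header += _ascii_field("0", 8)
    header += _ascii_field("X X X X", 80)
    header += _ascii_field("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (ns + 1), 8)
    header += _ascii_field("EDF+C", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)
    header += _ascii_field(ns, 4)

    def sig_fields(values: list[object], width: int) -> bytes:
        return b"".join(_ascii_field(v, width) for v in values)

    header += sig_fields(labels, 16)
    header += sig_fields([""] * ns, 80)  # transducer
    header += sig_fields(["uV"] * (ns - 1) + [""], 8)
    # asymmetric physical minimum makes the digital->physical scale exactly
    # pm/32767 with zero offset, so round-tripping loses only quantization
    header += sig_fields([f"{-pm * 32768.0 / 32767.0:.6g}" for pm in phys_max] + ["-1"], 8)
    header += sig_fields([f"{pm:.6g}" for pm in phys_max] + ["1"], 8)
    header += sig_fields(["-32768"] * ns, 8)
    header += sig_fields(["32767"] * ns, 8)
    header += sig_fields([""] * ns, 80)  # prefiltering
    header += sig_fields([spr] * (ns - 1) + [ann_spr], 8)
    header += sig_fields([""] * ns, 32)

    digital = []
    for ch, pm in zip(record.channels, phys_max):
        padded = np.zeros(n_records * spr)
        padded[:n] = ch.samples
        digital.append(np.round(padded / pm * 32767.0).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for i in range(n_records):
            for d in digital:
                fh.write(d[i * spr : (i + 1) * spr].tobytes())
            fh.write(tals[i].ljust(ann_bytes, b"\x00"))


# ---------------------------------------------------------------------------
# event files


def write_events(events: EventList, path: str | Path, format: str | None = None) -> None:
    """Write an event list as CSV or JSON (lossless to microsecond precision)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    rows = [
        {
            "start_s": f"{e.start:.6f}",
            "end_s": f"{e.end:.6f}",
            "channels": ";".join(e.channels),
            "flags": ";".join(sorted(e.flags)),
        }
        for e in events
    ]
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["start_s", "end_s", "channels", "flags"])
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        payload = [
            {
                "start_s": float(r["start_s"]),
                "end_s": float(r["end_s"]),
                "channels": r["channels"].split(";") if r["channels"] else [],
                "flags": sorted(r["flags"].split(";")) if r["flags"] else [],
            }
            for r in rows
        ]
        Path(path).write_text(json.dumps({"events": payload}, indent=2) + "\n")
    else:
        raise ValueError(f"unsupported event format {format!r}")


def read_events(path: str | Path, format: str | None = None) -> EventList:
    """Read an event file written by :func:`write_events` (or a bare
    ``start_s,end_s`` sidecar)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    events: list[SeizureEvent] = []
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "start_s" not in reader.fieldnames:
                raise EventParseError(path, 1, "missing start_s/end_s header")
            for i, row in enumerate(reader, start=2):
                try:
                    start = float(row["start_s"])
                    end = float(row["end_s"])
                except (TypeError, KeyError, ValueError) as exc:
                    raise EventParseError(path, i, f"bad interval: {exc}") from exc
                channels = tuple(c for c in (row.get("channels") or "").split(";") if c)
                flags = frozenset(f for f in (row.get("flags") or "").split(";") if f)
                try:
                    events.append(SeizureEvent(start, end, channels, flags))
                except ValueError as exc:
                    raise EventParseError(path, i, str(exc)) from exc
    elif format == "json":
        payload = json.loads(Path(path).read_text())
        for i, row in enumerate(payload.get("events", []), start=1):
            try:
                events.append(
                    SeizureEvent(
                        float(row["start_s"]),
                        float(row["end_s"]),
                        tuple(row.get("channels", [])),
                        frozenset(row.get("flags", [])),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise EventParseError(path, i, f"bad event object: {exc}") from exc
    else:
        raise ValueError(f"unsupported event format {format!r}")
    return EventList(events)
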