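"""Event matching against reference annotations and evaluation quantities.

Reference seizures were marked by a neurologist with 1 s accuracy, so a
detected event counts a reference as found (TP) whenever it overlaps the
reference dilated by ±1 s; one detected event may cover several references
(each counts). Detected events overlapping no dilated reference are false
detections (FP). Reported quantities:

- sensitivity: TP / (TP + FN), in percent;
- false-detection rate: FP per hour of recording (plus the raw count);
- OVR: per reference seizure, the fraction of the seizure covered by the
  union of its matched detections, in percent (mean ± SD over seizures;
  unmatched seizures contribute 0);
- PERR: percentage of the record's samples flagged as seizure outside all
  dilated references — it accounts both for false positives and for
  erroneously extended slow-wave envelopes;
- the training objective O = OVR_f − PERR − 0.5·FDET − FDET_C, where FDET
  and FDET_C count false detections in patients and controls and the 1:2
  weighting reflects that patient false positives are usually subclinical
  epileptiform discharges rather than plain errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import EventList

__all__ = [
    "EvalMetrics",
    "match_events",
    "sensitivity",
    "fdet_rate",
    "ovr",
    "perr",
    "objective",
    "evaluate",
]


@dataclass
class EvalMetrics:
    """Summary of a detector run against reference annotations."""

    tp: int
    fn: int
    fp: int
    sensitivity_pct: float | None
    fdet_count: int
    fdet_per_hour: float
    ovr_mean_pct: float | None
    ovr_sd_pct: float | None
    perr_pct: float
    total_hours: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def match_events(
    detected: EventList,
    reference: EventList,
    tolerance: float = 1.0,
) -> tuple[int, int, int, dict[int, list[int]]]:
    """Match detected events to reference seizures by dilated overlap.

    Returns ``(tp, fn, fp, pairing)`` where ``pairing[r]`` lists the indices
    of detected events overlapping reference ``r`` after dilating it by
    ±``tolerance`` seconds (the annotation accuracy).
    """
    pairing: dict[int, list[int]] = {}
    matched_det: set[int] = set()
    for r, ref in enumerate(reference):
        dil = (ref.start - tolerance, ref.end + tolerance)
        hits = [d for d, det in enumerate(detected) if _overlap(dil, (det.start, det.end)) > 0]
        if hits:
            pairing[r] = hits
            matched_det.update(hits)
    tp = len(pairing)
    fn = len(reference) - tp
    fp = len(detected) - len(matched_det)
    return tp, fn, fp, pairing


def sensitivity(tp: int, fn: int) -> float:
    """Detection sensitivity in percent; undefined (raises) when no references exist."""
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no reference seizures (tp + fn == 0)")
    return 100.0 * tp / (tp + fn)


def fdet_rate(fp: int, total_hours: float) -> float:
    """False detections per hour of recording."""
    if not total_hours > 0:
        raise ValueError("total_hours must be positive")
    return fp / total_hours


def ovr(
    detected: EventList,
    reference: EventList,
    pairing: dict[int, list[int]] | None = None,
    tolerance: float = 1.0,
) -> tuple[float, float]:
    """Percentage overlap of detections with each reference seizure.

    Per reference: |union of matched detections ∩ seizure| / |seizure| × 100;
    unmatched seizures contribute 0. Returns (mean, sd) over seizures.
    """
    if len(reference) == 0:
        raise ValueError("ovr undefined without reference seizures")
    if pairing is None:
        _, _, _, pairing = match_events(detected, reference, tolerance)
    per_seizure = []
    for r, ref in enumerate(reference):
        hits = pairing.get(r, [])
        covered = 0.0
        cursor = ref.start
        # events are sorted, so sweep to measure the union of intersections
        for d in hits:
            det = detected[d]
            lo, hi = max(det.start, cursor), min(det.end, ref.end)
            if hi > lo:
                covered += hi - lo
                cursor = hi
        per_seizure.append(100.0 * covered / ref.duration)
    arr = np.asarray(per_seizure)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def perr(
    detected: EventList,
    reference: EventList,
    n_samples_total: int,
    fs: float,
    tolerance: float = 1.0,
) -> float:
    """Percentage of samples flagged seizure outside all dilated references."""
    if n_samples_total <= 0:
        raise ValueError("n_samples_total must be positive")
    flagged = np.zeros(n_samples_total, dtype=bool)
    for det in detected:
        i0 = max(0, int(np.floor(det.start * fs)))
        i1 = min(n_samples_total, int(np.ceil(det.end * fs)))
        flagged[i0:i1] = True
    for ref in reference:
        i0 = max(0, int(np.floor((ref.start - tolerance) * fs)))
        i1 = min(n_samples_total, int(np.ceil((ref.end + tolerance) * fs)))
        flagged[i0:i1] = False
    return 100.0 * np.count_nonzero(flagged) / n_samples_total


def objective(ovr_f: float, perr_pct: float, fdet: int, fdet_c: int, fdet_weight: float = 0.5) -> float:
    """Grid-search objective O = OVR_f − PERR − 0.5·FDET − FDET_C.

    The patients' false-detection weight (default 0.5) is half the controls'
    because patient false positives are typically epileptiform discharges
    without clinical manifestation; the 1:2 ratio is a convention, exposed
    as ``fdet_weight``.
    """
    return ovr_f - perr_pct - fdet_weight * fdet - fdet_c


def evaluate(
    detected: EventList,
    reference: EventList,
    n_samples_total: int,
    fs: float,
    tolerance: float = 1.0,
) -> EvalMetrics:
    """All evaluation quantities for one record (or a pooled corpus)."""
    tp, fn, fp, pairing = match_events(detected, reference, tolerance)
    total_hours = n_samples_total / fs / 3600.0
    if len(reference) > 0:
        sens = sensitivity(tp, fn)
        ovr_mean, ovr_sd = ovr(detected, reference, pairing)
    else:
        sens, ovr_mean, ovr_sd = None, None, None
    return EvalMetrics(
        tp=tp,
        fn=fn,
        fp=fp,
        sensitivity_pct=sens,
        fdet_count=fp,
        fdet_per_hour=fdet_rate(fp, total_hours),
        ovr_mean_pct=ovr_mean,
        ovr_sd_pct=ovr_sd,
        perr_pct=perr(detected, reference, n_samples_total, fs, tolerance),
        total_hours=total_hours,
    )
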