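"""Two-stage exhaustive grid search for the detector parameters.

Stage one chooses the slow-wave parameters (``f_low``, ``f_high``, ``T_E``)
by maximizing the overlap of slow-wave envelopes with the annotated
seizures of a training corpus, deliberately ignoring false detections.
Stage two, with the envelope parameters frozen, chooses the spike
parameters (``f_spike``, ``T_S``, ``PT``) by maximizing

    O(f_spike, T_S, PT) = OVR_f − PERR − 0.5·FDET − FDET_C

over the patients (OVR_f, PERR, FDET) and controls (FDET_C). Finally the
wavelet-variance threshold ``T_V`` is estimated from the controls as the
mean plus three standard deviations of the spike-band power variance over
envelope-free windows.

Both stages precompute the needed normalized-power rows once per record and
reuse them across the grid, so exhaustive search stays cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .cwt import MorletSpec, power_at
from .detector import DetectorParams, band_envelope, merge_envelopes
from .preprocess import FilterSpec, preprocess
from .signals import AnnotatedRecord, TimeSeries

__all__ = [
    "GridSpec",
    "TrainingCorpus",
    "fit_envelope_params",
    "fit_spike_params",
    "estimate_tv",
    "tv_from_variances",
    "fit",
]


def _grid_axis(lo: float, hi: float, step: float) -> tuple[float, ...]:
    if step <= 0:
        raise ValueError("grid step must be positive")
    if hi < lo:
        raise ValueError("grid min must not exceed max")
    n = int(round((hi - lo) / step)) + 1
    return tuple(round(lo + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class GridSpec:
    """Per-parameter (min, max, step) ranges for the exhaustive search.

    Defaults bracket the clinical operating point: the slow-wave bands span
    the canonical 3 Hz SWD rate and the spike band covers the beta range
    where SWD spikes concentrate their wavelet power.
    """

    f_low: tuple[float, float, float] = (2.0, 3.0, 0.1)
    f_high: tuple[float, float, float] = (3.0, 4.5, 0.1)
    t_envelope: tuple[float, float, float] = (0.01, 0.10, 0.01)
    f_spike: tuple[float, float, float] = (10.0, 20.0, 0.1)
    t_spike: tuple[float, float, float] = (0.004, 0.04, 0.004)
    pt_fraction: tuple[float, float, float] = (0.04, 0.40, 0.04)

    def axis(self, name: str) -> tuple[float, ...]:
        return _grid_axis(*getattr(self, name))

    def validate(self) -> None:
        for name in ("f_low", "f_high", "t_envelope", "f_spike", "t_spike", "pt_fraction"):
            self.axis(name)
        if max(self.axis("f_low")) > min(self.axis("f_high")):
            # overlapping axes are allowed only where f_low < f_high pointwise;
            # pairs violating that are skipped during the search
            pass


@dataclass
class TrainingCorpus:
    """Annotated patient records plus (unannotated) control records."""

    patients: list[AnnotatedRecord]
    controls: list[AnnotatedRecord] = field(default_factory=list)

    def validate(self) -> None:
        if not self.patients or not any(r.reference_events for r in self.patients):
            raise ValueError("stage-1 training needs at least one patient record with a seizure")


def _preprocessed_channels(rec: AnnotatedRecord, filter_spec: FilterSpec | None) -> list[TimeSeries]:
    return [preprocess(ch, filter_spec) for ch in rec.channels]


def _seizure_mask(rec: AnnotatedRecord, n: int, fs: float, dilate: float = 0.0) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in rec.reference_events:
        i0 = max(0, int(np.floor((s - dilate) * fs)))
        i1 = min(n, int(np.ceil((e + dilate) * fs)))
        mask[i0:i1] = True
    return mask


def fit_envelope_params(
    corpus: TrainingCorpus,
    grid: GridSpec | None = None,
    fc: float = 1.0,
    filter_spec: FilterSpec | None = None,
) -> tuple[float, float, float, float]:
    """Stage 1: maximize mean envelope/seizure overlap over the grid.

    Returns ``(f_low, f_high, t_envelope, best_overlap_pct)``. Overlap is
    the per-seizure fraction of reference samples covered by the merged
    slow-wave envelope (pooled over channels with OR), averaged over all
    seizures in the corpus; false detections are ignored at this stage.
    Ties are broken toward smaller ``T_E``, then smaller band width.
    """
    grid = grid or GridSpec()
    grid.validate()
    corpus.validate()
    spec = MorletSpec(fc=fc)
    lows = grid.axis("f_low")
    highs = grid.axis("f_high")
    tes = grid.axis("t_envelope")
    all_freqs = sorted(set(lows) | set(highs))

    # per record: power rows for every candidate frequency, computed once
    rows_per_record: list[tuple[dict[float, np.ndarray], np.ndarray, float]] = []
    for rec in corpus.patients:
        if not rec.reference_events:
            continue
        chans = _preprocessed_channels(rec, filter_spec)
        maps = [power_at(ch, all_freqs, spec) for ch in chans]
        per_freq = {
            f: np.stack([pm.row(f) for pm in maps]) for f in all_freqs
        }  # (n_channels, n_samples)
        seiz = _seizure_mask(rec, len(chans[0]), rec.fs)
        rows_per_record.append((per_freq, seiz, rec.fs))

    best = None  # (overlap, -t_e, -(width)) maximized lexicographically
    best_params = None
    for f_lo, f_hi in itertools.product(lows, highs):
        if f_lo >= f_hi:
            continue
        for t_e in tes:
            covered = 0
            total = 0
            for per_freq, seiz, _fs in rows_per_record:
                env = (per_freq[f_lo] > t_e) | (per_freq[f_hi] > t_e)
                env_any = env.any(axis=0)
                covered += int(np.count_nonzero(env_any & seiz))
                total += int(np.count_nonzero(seiz))
            overlap = 100.0 * covered / total if total else 0.0
            key = (overlap, -t_e, -(f_hi - f_lo))
            if best is None or key > best:
                best = key
                best_params = (f_lo, f_hi, t_e, overlap)
    assert best_params is not None
    return best_params


@dataclass
class _Stage2Cache:
    """Per-candidate-interval quantities reused across the stage-2 grid."""

    sorted_w: list[np.ndarray]  # spike-band power samples per interval, sorted
    seiz_overlap: np.ndarray  # samples of each interval inside a reference seizure
    out_samples: np.ndarray  # samples outside all dilated references
    is_false: np.ndarray  # True if the interval overlaps no dilated reference
    is_control: np.ndarray
    amp_ok: np.ndarray


def _stage2_cache(
    corpus: TrainingCorpus,
    f_low: float,
    f_high: float,
    t_envelope: float,
    f_spikes: tuple[float, ...],
    p_template: DetectorParams,
    filter_spec: FilterSpec | None,
    tolerance: float = 1.0,
) -> tuple[dict[float, _Stage2Cache], int, int]:
    """Collect candidate envelope intervals and their per-f_spike statistics.

    Candidates are the merged-envelope intervals (per channel) that survive
    the duration rule; the amplitude check is precomputed since it does not
    depend on the spike parameters. Returns the cache keyed by f_spike, the
    total seizure sample count and the total sample count of the corpus.
    """
    from .detector import amplitude_check

    spec = p_template.morlet
    caches = {f: _Stage2Cache([], [], [], [], [], []) for f in f_spikes}  # type: ignore[arg-type]
    total_seiz = 0
    total_samples = 0
    records = [(rec, False) for rec in corpus.patients] + [(rec, True) for rec in corpus.controls]
    for rec, is_control in records:
        chans = _preprocessed_channels(rec, filter_spec)
        n = len(chans[0])
        fs = rec.fs
        if not is_control:
            # pooled sample-level denominator: seizure samples of every channel
            total_seiz += int(np.count_nonzero(_seizure_mask(rec, n, fs))) * len(chans)
        total_samples += n * len(chans)
        seiz = _seizure_mask(rec, n, fs)
        seiz_dil = _seizure_mask(rec, n, fs, dilate=tolerance)
        freqs = sorted({f_low, f_high, *f_spikes})
        for ch in chans:
            pm = power_at(ch, freqs, spec)
            env = merge_envelopes(
                band_envelope(pm.row(f_low), t_envelope, fs),
                band_envelope(pm.row(f_high), t_envelope, fs),
            )
            intervals = [
                (i0, i1)
                for i0, i1 in env.intervals()
                if (i1 - i0) / fs > p_template.min_duration
            ]
            for i0, i1 in intervals:
                amp = amplitude_check(
                    ch.samples[i0:i1],
                    p_template.amp_soft_limit,
                    p_template.amp_soft_fraction,
                    p_template.amp_hard_limit,
                )
                overlap = int(np.count_nonzero(seiz[i0:i1]))
                outside = int(np.count_nonzero(~seiz_dil[i0:i1]))
                false_det = not np.any(seiz_dil[i0:i1])
                for f in f_spikes:
                    c = caches[f]
                    c.sorted_w.append(np.sort(pm.row(f)[i0:i1]))
                    c.seiz_overlap.append(overlap)  # type: ignore[attr-defined]
                    c.out_samples.append(outside)  # type: ignore[attr-defined]
                    c.is_false.append(false_det)  # type: ignore[attr-defined]
                    c.is_control.append(is_control)  # type: ignore[attr-defined]
                    c.amp_ok.append(amp)  # type: ignore[attr-defined]
    for f in f_spikes:
        c = caches[f]
        c.seiz_overlap = np.asarray(c.seiz_overlap, dtype=float)
        c.out_samples = np.asarray(c.out_samples, dtype=float)
        c.is_false = np.asarray(c.is_false, dtype=bool)
        c.is_control = np.asarray(c.is_control, dtype=bool)
        c.amp_ok = np.asarray(c.amp_ok, dtype=bool)
    return caches, total_seiz, total_samples


def fit_spike_params(
    corpus: TrainingCorpus,
    grid: GridSpec | None = None,
    envelope_params: tuple[float, float, float] | None = None,
    fc: float = 1.0,
    filter_spec: FilterSpec | None = None,
    fdet_weight: float = 0.5,
    log: list[dict] | None = None,
) -> tuple[float, float, float, float]:
    """Stage 2: maximize O = OVR_f − PERR − 0.5·FDET − FDET_C over the grid.

    ``envelope_params`` are the stage-1 ``(f_low, f_high, t_envelope)``;
    when omitted, stage 1 is run first with the same grid. An interval
    counts as detected when it passes the amplitude check and its spike
    fraction reaches PT; the variance check is not part of this stage (its
    threshold is estimated afterwards). OVR_f and PERR are pooled
    sample-level quantities over the corpus. Returns
    ``(f_spike, t_spike, pt_fraction, best_objective)``; ties break toward
    larger ``T_S`` (more conservative), then larger PT.

    Pass ``log`` (a list) to receive one dict per grid point with the
    objective components.
    """
    grid = grid or GridSpec()
    grid.validate()
    corpus.validate()
    if envelope_params is None:
        f_low, f_high, t_env, _ = fit_envelope_params(corpus, grid, fc, filter_spec)
    else:
        f_low, f_high, t_env = envelope_params
    p_template = DetectorParams(f_low=f_low, f_high=f_high, t_envelope=t_env, fc=fc)
    f_spikes = grid.axis("f_spike")
    t_spikes = grid.axis("t_spike")
    pts = grid.axis("pt_fraction")

    caches, total_seiz, total_samples = _stage2_cache(
        corpus, f_low, f_high, t_env, f_spikes, p_template, filter_spec
    )

    best = None
    best_params = None
    for f_sp in f_spikes:
        c = caches[f_sp]
        n_int = len(c.sorted_w)
        sizes = np.asarray([w.size for w in c.sorted_w], dtype=float)
        # fraction of interval samples above each T_S: (n_ts, n_intervals)
        frac = np.empty((len(t_spikes), n_int))
        for j, w in enumerate(c.sorted_w):
            idx = np.searchsorted(w, t_spikes, side="right")
            frac[:, j] = (w.size - idx) / w.size if w.size else 0.0
        true_int = ~c.is_false & ~c.is_control
        for i_ts, t_s in enumerate(t_spikes):
            for pt in pts:
                accept = (frac[i_ts] >= pt) & c.amp_ok
                ovr_f = (
                    100.0 * float(c.seiz_overlap[accept].sum()) / total_seiz
                    if total_seiz
                    else 0.0
                )
                perr_pct = 100.0 * float(c.out_samples[accept].sum()) / total_samples
                fdet = int(np.count_nonzero(accept & c.is_false & ~c.is_control))
                fdet_c = int(np.count_nonzero(accept & c.is_false & c.is_control))
                obj = ovr_f - perr_pct - fdet_weight * fdet - fdet_c
                # the objective is piecewise constant, so plateaus of equal O are
                # common; break ties toward larger T_S (more conservative), larger
                # PT, then the point deepest inside its accepting region (largest
                # minimum spike-fraction margin over accepted true intervals)
                hit = accept & true_int
                margin = float(np.min(frac[i_ts][hit] - pt)) if np.any(hit) else -np.inf
                if log is not None:
                    log.append(
                        dict(
                            f_spike=f_sp, t_spike=t_s, pt_fraction=pt,
                            ovr_f=ovr_f, perr=perr_pct, fdet=fdet, fdet_c=fdet_c,
                            objective=obj,
                        )
                    )
                key = (obj, t_s, pt, margin)
                if best is None or key > best:
                    best = key
                    best_params = (f_sp, t_s, pt, obj)
        del sizes
    assert best_params is not None
    return best_params


def tv_from_variances(variances: np.ndarray) -> float:
    """T_V rule: mean of the variance distribution plus three sample SDs."""
    v = np.asarray(variances, dtype=float)
    if v.size == 0:
        raise ValueError("empty variance distribution")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)) + 3.0 * sd


def estimate_tv(
    controls: list[AnnotatedRecord],
    f_spike: float,
    envelope_params: tuple[float, float, float] | None = None,
    fc: float = 1.0,
    filter_spec: FilterSpec | None = None,
    window: float = 5.0,
) -> float:
    """Estimate T_V from the controls' spike-band power variance.

    The spike-band normalized power of every control channel is cut into
    non-overlapping ``window``-second windows (5 s — the duration below
    which the variance check applies); windows intersecting a slow-wave
    envelope (when envelope parameters are given) or the edge-contaminated
    buffer ends are excluded. T_V is the mean plus three standard
    deviations of the per-window variance distribution.
    """
    if not controls:
        raise ValueError("estimate_tv needs at least one control record")
    spec = MorletSpec(fc=fc)
    variances: list[float] = []
    for rec in controls:
        for ch in _preprocessed_channels(rec, filter_spec):
            freqs = [f_spike] if envelope_params is None else sorted(
                {envelope_params[0], envelope_params[1], f_spike}
            )
            pm = power_at(ch, freqs, spec)
            w = pm.row(f_spike)
            valid = pm.valid_mask[pm.grid.index_of(f_spike)]
            env = np.zeros_like(valid)
            if envelope_params is not None:
                # exclude only seizure-candidate envelopes (sustained runs longer
                # than the 2 s seizure definition); momentary background
                # threshold crossings are part of what T_V must characterize
                f_low, f_high, t_env = envelope_params
                from .detector import Envelope

                mask = (pm.row(f_low) > t_env) | (pm.row(f_high) > t_env)
                for i0, i1 in Envelope(mask, ch.fs).intervals():
                    if (i1 - i0) / ch.fs > 2.0:
                        env[i0:i1] = True
            win = int(round(window * ch.fs))
            for i0 in range(0, len(w) - win + 1, win):
                sl = slice(i0, i0 + win)
                if env[sl].any() or not valid[sl].all():
                    continue
                variances.append(float(np.var(w[sl], ddof=1)))
    if not variances:
        raise ValueError("no envelope-free windows available for T_V estimation")
    return tv_from_variances(np.asarray(variances))


def fit(
    corpus: TrainingCorpus,
    grid: GridSpec | None = None,
    fc: float = 1.0,
    filter_spec: FilterSpec | None = None,
    log: list[dict] | None = None,
) -> DetectorParams:
    """Run both stages plus the T_V rule and return fitted DetectorParams."""
    grid = grid or GridSpec()
    f_low, f_high, t_env, _ = fit_envelope_params(corpus, grid, fc, filter_spec)
    f_spike, t_spike, pt, _ = fit_spike_params(
        corpus, grid, (f_low, f_high, t_env), fc, filter_spec, log=log
    )
    if corpus.controls:
        t_v = estimate_tv(corpus.controls, f_spike, (f_low, f_high, t_env), fc, filter_spec)
    else:
        t_v = DetectorParams().t_variance
    return DetectorParams(
        f_low=f_low,
        f_high=f_high,
        t_envelope=t_env,
        f_spike=f_spike,
        t_spike=t_spike,
        pt_fraction=pt,
        t_variance=t_v,
        fc=fc,
    )
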