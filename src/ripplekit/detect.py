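"""Envelope-threshold detection of ripples, spindles and delta waves.

All three detectors share one rule template: band-pass the source LFP,
take the Hilbert envelope, threshold at baseline mean + k*SD (baseline
over NREM samples), merge supra-threshold windows closer than a merge
gap, then discard windows outside the duration bounds.  Merging runs
before duration filtering so that brief envelope dips cannot fragment a
genuine long event into rejected pieces.

Profile defaults follow the standard criteria for each event class
(ripple: 100-250 Hz, k=3, 50 ms merge; spindle: 12-15 Hz, k=2,
200-2000 ms, 100 ms merge; delta: 1-4 Hz, k=1.5, 150-500 ms, 100 ms
merge).  A short envelope smoothing and, for ripples, a minimum
duration are applied on top: a bare k*SD threshold on a continuous
envelope marks a fixed fraction of background time regardless of scale,
so some run-length discrimination is required for usable precision (see
docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .core import (
    NREM,
    ACC_LFP,
    CA1_LFP,
    DegenerateSignalError,
    DetectionParams,
    EventSet,
    Hypnogram,
    InsufficientDataError,
    OscEvent,
    ParameterError,
    Recording,
    StateInterval,
)
from .spectral import bandpass_filter, hilbert_envelope, moving_average

#: Detection profiles. Thresholds, bands, merge gaps and duration bounds
#: are the standard criteria; smoothing (and the ripple minimum duration)
#: are this package's additions for background-noise rejection.
RIPPLE_PARAMS = DetectionParams(
    band_low_hz=100.0, band_high_hz=250.0, threshold_sd=3.0,
    merge_gap_ms=50.0, min_dur_ms=20.0, max_dur_ms=None, smooth_ms=10.0,
)
SPINDLE_PARAMS = DetectionParams(
    band_low_hz=12.0, band_high_hz=15.0, threshold_sd=2.0,
    merge_gap_ms=100.0, min_dur_ms=200.0, max_dur_ms=2000.0, smooth_ms=300.0,
)
DELTA_PARAMS = DetectionParams(
    band_low_hz=1.0, band_high_hz=4.0, threshold_sd=1.5,
    merge_gap_ms=100.0, min_dur_ms=150.0, max_dur_ms=500.0, smooth_ms=20.0,
)

PROFILES = {"ripple": RIPPLE_PARAMS, "spindle": SPINDLE_PARAMS, "delta": DELTA_PARAMS}


def _interval_mask(intervals: list[StateInterval], fs: float, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        a = max(int(round(iv.start_s * fs)), 0)
        b = min(int(round(iv.end_s * fs)), n)
        mask[a:b] = True
    return mask


def _runs(mask: np.ndarray) -> np.ndarray:
    """(start, end) index pairs of maximal True runs (end exclusive)."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.column_stack([starts, ends])


def detect_threshold_events(
    envelope: np.ndarray,
    fs: float,
    params: DetectionParams,
    nrem: list[StateInterval],
    kind: str = "event",
    source_role: str | None = None,
) -> EventSet:
    """Threshold -> merge -> duration-filter on a Hilbert envelope.

    The baseline mean/SD is estimated over NREM samples (or the whole
    recording if ``params.baseline_scope`` says so); candidate windows
    are maximal supra-threshold runs inside NREM, so a candidate
    straddling an NREM edge is truncated before duration filtering.
    ``peak_amp``/``peak_time_s`` come from the unsmoothed envelope.
    """
    envelope = np.asarray(envelope, dtype=np.float64)
    if np.any(envelope < 0):
        raise ParameterError("envelope must be nonnegative")
    if not nrem:
        raise ParameterError("NREM interval list is empty")
    n = envelope.size
    mask = _interval_mask(nrem, fs, n)
    if not mask.any():
        raise InsufficientDataError("NREM intervals cover no samples")

    smoothed = envelope
    if params.smooth_ms > 0:
        smoothed = moving_average(envelope, int(round(params.smooth_ms * 1e-3 * fs)))

    baseline = smoothed[mask] if params.baseline_scope == "NREM" else smoothed
    mu, sd = float(np.mean(baseline)), float(np.std(baseline))
    if sd == 0:
        raise DegenerateSignalError("envelope is constant over the baseline")
    thr = mu + params.threshold_sd * sd if params.threshold_rule == "mean_plus_k_sd" \
        else params.threshold_sd * sd

    above = (smoothed > thr) & mask
    if not above.any():
        return EventSet(kind=kind, events=[], params=params,
                        source_role=source_role, restricted_to=list(nrem))
    windows = _runs(above)

    # merge windows separated by less than the merge gap
    gap = params.merge_gap_ms * 1e-3 * fs
    merged = [windows[0].tolist()]
    for s, e in windows[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: list[OscEvent] = []
    for s, e in merged:
        dur_ms = (e - s) / fs * 1e3
        if params.min_dur_ms is not None and dur_ms < params.min_dur_ms:
            continue
        if params.max_dur_ms is not None and dur_ms > params.max_dur_ms:
            continue
        seg = envelope[s:e]
        ipk = int(np.argmax(seg))
        events.append(
            OscEvent(kind=kind, start_s=s / fs, end_s=e / fs,
                     peak_amp=float(seg[ipk]), peak_time_s=(s + ipk) / fs)
        )
    return EventSet(kind=kind, events=events, params=params,
                    source_role=source_role, restricted_to=list(nrem))


def _detect(
    rec: Recording, hypnogram: Hypnogram, role: str, kind: str,
    params: DetectionParams,
) -> EventSet:
    nrem = hypnogram.intervals_for(NREM)
    if not nrem:
        raise InsufficientDataError("hypnogram contains no NREM")
    x = rec.channel(role)
    env = hilbert_envelope(bandpass_filter(x, rec.fs, params.band_low_hz,
                                           params.band_high_hz))
    return detect_threshold_events(env, rec.fs, params, nrem, kind=kind,
                                   source_role=role)


def detect_ripples(
    rec: Recording, hypnogram: Hypnogram, params: DetectionParams = RIPPLE_PARAMS
) -> EventSet:
    """Hippocampal ripples: CA1 LFP, 100-250 Hz, mean + 3 SD."""
    return _detect(rec, hypnogram, CA1_LFP, "ripple", params)


def detect_spindles(
    rec: Recording, hypnogram: Hypnogram, params: DetectionParams = SPINDLE_PARAMS
) -> EventSet:
    """Sleep spindles: ACC LFP, 12-15 Hz, mean + 2 SD, 200-2000 ms."""
    return _detect(rec, hypnogram, ACC_LFP, "spindle", params)


def detect_deltas(
    rec: Recording, hypnogram: Hypnogram, params: DetectionParams = DELTA_PARAMS
) -> EventSet:
    """Delta waves: ACC LFP, 1-4 Hz, mean + 1.5 SD, 150-500 ms."""
    return _detect(rec, hypnogram, ACC_LFP, "delta", params)


def event_incidence(es: EventSet, hypnogram: Hypnogram) -> float:
    """Events per minute of NREM."""
    t_nrem = hypnogram.total_s(NREM)
    if t_nrem <= 0:
        raise InsufficientDataError("hypnogram has zero NREM time")
    return len(es) / (t_nrem / 60.0)


def event_amplitude_summary(es: EventSet) -> float:
    """Mean peak envelope amplitude across events."""
    if len(es) == 0:
        raise InsufficientDataError("event set is empty")
    return float(np.mean(es.peak_amps()))
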