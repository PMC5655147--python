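"""EMG/theta-delta sleep staging and sleep-architecture summaries.

Staging proceeds in two steps.  Immobility is detected from the smoothed
EMG envelope with an adaptive threshold of 3x the envelope's mode
(sustained for at least 10 s); everything else is WAKE.  Immobile time
is then tiled into 2 s epochs and each epoch's theta(4-12 Hz) /
delta(1-4 Hz) power ratio is compared against an adaptive threshold of
3.5x the mode of the ratio over all immobile epochs: low ratio means
NREM, high ratio means REM.  Mode-relative thresholds make the scorer
invariant to overall signal scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CA1_LFP,
    EMG,
    NREM,
    REM,
    WAKE,
    DegenerateSignalError,
    Hypnogram,
    InsufficientDataError,
    Recording,
    StateInterval,
)
from .spectral import hilbert_envelope, moving_average, welch_psd

EMG_SMOOTH_S = 0.5
EMG_MODE_MULT = 3.0
MIN_IMMOBILE_S = 10.0
EPOCH_S = 2.0
RATIO_MODE_MULT = 3.5
MIN_EPOCH_S = 1.0


def estimate_mode(values: np.ndarray, min_n: int = 100) -> float:
    """Mode of a continuous sample: centre of the fullest histogram bin.

    Freedman-Diaconis binning; ties break toward the lower bin.  With a
    degenerate spread (IQR and range both ~0) the common value itself is
    returned.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size < min_n:
        raise InsufficientDataError(
            f"mode estimation needs >= {min_n} finite values, got {v.size}"
        )
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    span = float(v.max() - v.min())
    if span == 0:
        return float(v[0])
    width = 2 * iqr * v.size ** (-1 / 3)
    if width <= 0:
        width = span / np.sqrt(v.size)  # IQR degenerate; fall back
    n_bins = max(int(np.ceil(span / width)), 1)
    counts, edges = np.histogram(v, bins=n_bins)
    i = int(np.argmax(counts))  # argmax takes the first (lower) max bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def detect_immobility(emg: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Maximal intervals with smoothed EMG envelope < 3x its mode for
    at least 10 s."""
    emg = np.asarray(emg, dtype=np.float64)
    if emg.size < 60 * fs:
        raise InsufficientDataError("EMG must be at least 60 s long")
    env = moving_average(hilbert_envelope(emg), int(round(EMG_SMOOTH_S * fs)))
    mode = estimate_mode(env)
    if mode <= 0:
        raise DegenerateSignalError("EMG envelope mode is zero")
    quiet = env < EMG_MODE_MULT * mode
    out: list[tuple[float, float]] = []
    d = np.diff(quiet.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if quiet[0]:
        starts = np.r_[0, starts]
    if quiet[-1]:
        ends = np.r_[ends, quiet.size]
    for a, b in zip(starts, ends):
        if (b - a) / fs >= MIN_IMMOBILE_S:
            out.append((a / fs, b / fs))
    return out


def _epoch_ratio(x: np.ndarray, fs: float) -> float:
    """Theta/delta power ratio of one epoch (inf when delta power ~ 0)."""
    window_s = min(EPOCH_S, x.size / fs)
    psd = welch_psd(x, fs, window_s=window_s)
    theta = psd.band_power(4.0, 12.0)
    delta = psd.band_power(1.0, 4.0)
    if delta <= 0:
        return np.inf
    return theta / delta


def score_sleep(rec: Recording, lfp_role: str = CA1_LFP) -> Hypnogram:
    """Score WAKE/NREM/REM for a recording.

    Non-immobile time is WAKE.  Immobile time is tiled into 2 s epochs
    (boundary epochs truncated; fragments shorter than 1 s dropped into
    WAKE); each epoch is NREM when its theta/delta ratio is below 3.5x
    the mode of the ratio across all immobile epochs, REM otherwise.
    Needs enough immobility (>= 100 epochs) to estimate the ratio mode;
    with no immobility at all the whole recording is returned as WAKE
    with a ``"warning"`` entry in ``Hypnogram.meta``.
    """
    rec.require_min_duration(60.0)
    emg = rec.channel(EMG)
    lfp = rec.channel(lfp_role)
    fs = rec.fs
    immobile = detect_immobility(emg, fs)
    if not immobile:
        hyp = Hypnogram(
            [StateInterval(0.0, rec.duration_s, WAKE)], rec.duration_s
        )
        hyp.meta["warning"] = "no immobile epochs; scored all WAKE"
        return hyp

    groups: list[list[tuple[float, float]]] = []
    ratios: list[list[float]] = []
    for a, b in immobile:
        eps: list[tuple[float, float]] = []
        rs: list[float] = []
        t = a
        while t < b - MIN_EPOCH_S:
            e = min(t + EPOCH_S, b)
            seg = lfp[int(round(t * fs)) : int(round(e * fs))]
            eps.append((t, e))
            rs.append(_epoch_ratio(seg, fs))
            t = e
        groups.append(eps)
        ratios.append(rs)
    finite = [r for rs in ratios for r in rs if np.isfinite(r)]
    thr = RATIO_MODE_MULT * estimate_mode(np.array(finite))

    intervals: list[StateInterval] = []
    cursor = 0.0
    for eps, rs in zip(groups, ratios):
        states = [NREM if r < thr else REM for r in rs]
        states = _majority_smooth(states)
        for (t, e), st in zip(eps, states):
            if t > cursor:
                intervals.append(StateInterval(cursor, t, WAKE))
            intervals.append(StateInterval(t, e, st))
            cursor = e
    if cursor < rec.duration_s:
        intervals.append(StateInterval(cursor, rec.duration_s, WAKE))
    return Hypnogram(intervals, rec.duration_s)


def _majority_smooth(states: list[str]) -> list[str]:
    """3-epoch majority vote within one immobile stretch: an epoch whose
    two neighbours agree takes their label, suppressing isolated
    misclassifications from noisy 2 s power ratios."""
    if len(states) < 3:
        return states
    out = list(states)
    for i in range(1, len(states) - 1):
        if states[i - 1] == states[i + 1] != states[i]:
            out[i] = states[i - 1]
    return out


@dataclass
class ArchitectureSummary:
    """Sleep-architecture totals of a scored session."""

    total_nrem_s: float
    mean_nrem_epoch_s: float
    n_nrem_epochs: int
    total_rem_s: float
    total_wake_s: float


def sleep_architecture(hyp: Hypnogram) -> ArchitectureSummary:
    """Totals per state and NREM bout statistics (a bout = one maximal
    NREM interval of the canonical hypnogram)."""
    nrem = hyp.intervals_for(NREM)
    total_nrem = float(sum(iv.duration_s for iv in nrem))
    return ArchitectureSummary(
        total_nrem_s=total_nrem,
        mean_nrem_epoch_s=total_nrem / len(nrem) if nrem else 0.0,
        n_nrem_epochs=len(nrem),
        total_rem_s=hyp.total_s(REM),
        total_wake_s=hyp.total_s(WAKE),
    )
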