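"""Ripple-spindle (and ripple-delta) coupling statistics.

Three complementary measures:

* **Amplitude cross-correlogram** -- around each anchor (spindle centre
  or delta onset), the anchor-band envelope over a fixed window is
  Pearson-correlated with the ripple-band envelope shifted by each lag
  on a grid; coefficients are averaged across anchors.  Negative peak
  lag = ripple leads the anchor.
* **Timestamp cross-correlogram** -- event centre times binarized on a
  coarse grid over concatenated NREM and correlated at integer-bin lags.
* **Joint occurrence rate** -- ripples within a fixed window of any
  spindle centre, normalized by the spindle count.

Significance of the amplitude correlogram peak is assessed against a
surrogate null: the ripple envelope is circularly time-shifted within
concatenated NREM (by at least 4 s; by default anywhere on the
concatenated-trace circle) and the peak recomputed, 100 times; the
observed peak is significant when it exceeds the nearest-rank 99th
percentile of the surrogate peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DegenerateSignalError,
    EventSet,
    InsufficientDataError,
    ParameterError,
    StateInterval,
)

DEFAULT_HALF_WINDOW_S = 4.0
DEFAULT_STEP_S = 0.01
DELTA_HALF_WINDOW_S = 0.5
TS_BIN_S = 0.1
JOINT_WINDOW_S = 0.25
# minimum surrogate shift 4 s; upper bound None = span the whole trace
SHIFT_RANGE_S: tuple[float, float | None] = (4.0, None)
N_SHUFFLES = 100
DEFAULT_PEAK_SEARCH_S = 0.5  # peak extraction window (coupling-relevant lags)
REFINE_HALF_S = 0.15  # quadratic peak-refinement neighbourhood


@dataclass
class CrossCorrelogram:
    """Lag grid and mean correlation coefficients.

    ``peak_lag_s`` follows the convention that a negative lag means the
    ripple leads the anchor event.
    """

    lags_s: np.ndarray
    coefs: np.ndarray
    n_windows: int
    peak_coef: float
    peak_lag_s: float
    method: str
    anchor: str
    half_window_s: float
    n_skipped: int = 0
    peak_search_s: float | None = None


@dataclass
class ShuffleNull:
    """Surrogate distribution of correlogram peaks under time-shifting."""

    n_shuffles: int
    shift_range_s: tuple[float, float | None]
    null_peaks: np.ndarray
    pct99: float
    observed_peak: float
    is_significant: bool
    seed: int


@dataclass
class CouplingReport:
    """All coupling measures of one session."""

    amp_xcorr: CrossCorrelogram
    amp_null: ShuffleNull | None
    ts_xcorr: CrossCorrelogram | None
    joint_rate: float
    ripple_delta_xcorr: CrossCorrelogram | None = None
    normalized_peak: float | None = None


# ---------------------------------------------------------------------------
# concatenated-NREM representation


def nrem_concat_envelope(
    env: np.ndarray, fs: float, nrem: list[StateInterval], step_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin-average an envelope to the lag-grid resolution over NREM.

    Returns ``(concat, bounds, starts_s)``: the concatenated decimated
    envelope, the decimated index at which each NREM segment starts
    (length n_seg + 1), and each segment's start time in recording
    seconds.  Each segment is trimmed to a whole number of bins before
    concatenation so segment boundaries are exact.
    """
    d = step_s * fs
    if abs(d - round(d)) > 1e-6:
        raise ParameterError(f"step_s * fs must be an integer, got {d}")
    d = int(round(d))
    pieces: list[np.ndarray] = []
    bounds = [0]
    starts = []
    for iv in nrem:
        i0, i1 = int(round(iv.start_s * fs)), int(round(iv.end_s * fs))
        m = (min(i1, env.size) - i0) // d
        if m <= 0:
            continue
        pieces.append(env[i0 : i0 + m * d].reshape(m, d).mean(axis=1))
        bounds.append(bounds[-1] + m)
        starts.append(iv.start_s)
    if not pieces:
        raise InsufficientDataError("NREM intervals contain no whole bins")
    return np.concatenate(pieces), np.array(bounds), np.array(starts)


def _anchors_to_bins(
    anchors_s: np.ndarray,
    nrem: list[StateInterval],
    bounds: np.ndarray,
    starts_s: np.ndarray,
    step_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Map anchor times to concatenated-bin indices; returns (bin index,
    segment index); anchors outside NREM are dropped."""
    out_j, out_seg = [], []
    kept = [iv for iv in nrem]
    seg_of_start = {s: k for k, s in enumerate(starts_s)}
    for t in np.atleast_1d(anchors_s):
        for iv in kept:
            if iv.start_s <= t < iv.end_s and iv.start_s in seg_of_start:
                k = seg_of_start[iv.start_s]
                j = bounds[k] + int((t - iv.start_s) / step_s)
                if j < bounds[k + 1]:
                    out_j.append(j)
                    out_seg.append(k)
                break
    return np.array(out_j, dtype=np.int64), np.array(out_seg, dtype=np.int64)


class _AmplitudeEngine:
    """Shared machinery for the observed amplitude correlogram and its
    circular-shift surrogates.

    Per anchor, raw dot products between the (fixed) anchor window and
    every needed circular placement of the ripple trace are precomputed,
    so each surrogate correlogram reduces to indexed gathers.
    """

    def __init__(
        self,
        rip_c: np.ndarray,
        anc_c: np.ndarray,
        bounds: np.ndarray,
        anchors_j: np.ndarray,
        anchors_seg: np.ndarray,
        w: int,
        step_s: float,
        max_shift_bins: int,
    ) -> None:
        L = rip_c.size
        self.L, self.w, self.ms, self.step_s = L, w, max_shift_bins, step_s
        n = 2 * w + 1
        self.n = n
        rp = np.concatenate([rip_c, rip_c])
        cs = np.concatenate([[0.0], np.cumsum(rp)])
        cq = np.concatenate([[0.0], np.cumsum(rp * rp)])
        self.S = cs[n : L + n] - cs[:L]  # circular sliding window sums
        self.Q = cq[n : L + n] - cq[:L]
        self.n_skipped = 0
        self.anchors: list[dict] = []
        m = 2 * w + 2 * max_shift_bins + 1  # offsets j-2w-ms .. j+ms
        # full circular dot tables (via FFT) once the shift span approaches
        # the trace length; windowed direct correlation otherwise
        self.full = m + n - 1 >= L
        if not self.full and L < m + n:
            raise InsufficientDataError(
                f"concatenated NREM ({L * step_s:.0f} s) shorter than the "
                f"window + shift span ({(m + n) * step_s:.0f} s)"
            )
        rip_fft = np.fft.rfft(rip_c) if self.full else None
        for j, seg in zip(anchors_j, anchors_seg):
            lo, hi = bounds[seg], bounds[seg + 1]
            if j - 2 * w < lo or j + 2 * w + 1 > hi:
                continue  # lagged window would exit the NREM segment
            a = anc_c[j - w : j + w + 1]
            am = float(a.mean())
            denom_a = float(np.sqrt(np.sum((a - am) ** 2)))
            if denom_a == 0:
                self.n_skipped += 1
                continue
            if self.full:
                # dots[p] = sum_i a[i] * rip[(p + i) mod L] for all p
                dots = np.fft.irfft(rip_fft * np.conj(np.fft.rfft(a, n=L)),
                                    n=L)
                q0 = 0
            else:
                q0 = (j - 2 * w - max_shift_bins) % L
                dots = np.correlate(rp[q0 : q0 + m + n - 1], a, mode="valid")
            self.anchors.append(
                {"j": int(j), "a_mean": am, "a_denom": denom_a, "dots": dots}
            )
        self.lag_bins = np.arange(-w, w + 1)

    @property
    def n_windows(self) -> int:
        return len(self.anchors)

    def coefs(self, shift_bins: int = 0) -> np.ndarray:
        """Mean Pearson coefficient per lag with the ripple trace
        circularly shifted by ``shift_bins``."""
        w, ms, L, n = self.w, self.ms, self.L, self.n
        if abs(shift_bins) > ms:
            raise ParameterError("shift exceeds precomputed range")
        rows = np.full((len(self.anchors), 2 * w + 1), np.nan)
        for i, anc in enumerate(self.anchors):
            p = (anc["j"] - w + self.lag_bins - shift_bins) % L
            if self.full:
                dots = anc["dots"][p]
            else:
                dots = anc["dots"][self.lag_bins + w + ms - shift_bins]
            S, Q = self.S[p], self.Q[p]
            var_t = Q - S * S / n
            with np.errstate(invalid="ignore", divide="ignore"):
                coef = (dots - anc["a_mean"] * S) / (
                    anc["a_denom"] * np.sqrt(var_t)
                )
            coef[var_t <= 0] = np.nan
            rows[i] = coef
        with np.errstate(invalid="ignore"):
            return np.nanmean(rows, axis=0)


def _peak(
    lags_s: np.ndarray,
    coefs: np.ndarray,
    search_s: float | None = None,
    refine: bool = True,
) -> tuple[float, float]:
    """Correlogram peak and its lag.

    The maximum is searched within ``|lag| <= search_s`` (full grid when
    None); lag ties break toward the smallest |lag|, then the negative
    lag.  When ``refine`` is set, the reported lag is the vertex of a
    quadratic fitted to the coefficients within +-0.15 s of the argmax,
    snapped back to the lag grid -- a lower-variance location estimate
    for broad correlogram peaks (the peak coefficient itself stays the
    grid maximum).
    """
    ok = np.isfinite(coefs)
    if search_s is not None:
        ok &= np.abs(lags_s) <= search_s + 1e-12
    if not ok.any():
        raise DegenerateSignalError("all correlogram coefficients undefined")
    best = np.max(coefs[ok])
    cand = np.flatnonzero(ok & (coefs == best))
    order = sorted(cand, key=lambda i: (abs(lags_s[i]), lags_s[i]))
    i = order[0]
    lag = float(lags_s[i])
    if refine:
        sel = ok & (np.abs(lags_s - lag) <= REFINE_HALF_S + 1e-12)
        if sel.sum() >= 5:
            a, b, _ = np.polyfit(lags_s[sel], coefs[sel], 2)
            if a < 0:
                v = -b / (2 * a)
                if abs(v - lag) <= REFINE_HALF_S:
                    j = int(np.argmin(np.abs(lags_s[ok] - v)))
                    lag = float(lags_s[ok][j])
    return float(best), lag


def _build_engine(
    ripple_env: np.ndarray,
    anchor_env: np.ndarray,
    anchors_s: np.ndarray,
    fs: float,
    half_window_s: float,
    step_s: float,
    nrem: list[StateInterval],
    max_shift_s: float,
) -> tuple[_AmplitudeEngine, np.ndarray]:
    ripple_env = np.asarray(ripple_env, dtype=np.float64)
    anchor_env = np.asarray(anchor_env, dtype=np.float64)
    if ripple_env.shape != anchor_env.shape:
        raise ParameterError("envelopes must have equal length")
    if not nrem:
        raise InsufficientDataError("no NREM intervals")
    rip_c, bounds, starts = nrem_concat_envelope(ripple_env, fs, nrem, step_s)
    anc_c, _, _ = nrem_concat_envelope(anchor_env, fs, nrem, step_s)
    j, seg = _anchors_to_bins(np.asarray(anchors_s, float), nrem, bounds,
                              starts, step_s)
    if j.size == 0:
        raise InsufficientDataError("no anchors inside NREM")
    w = int(round(half_window_s / step_s))
    ms = min(int(np.ceil(max_shift_s / step_s)), rip_c.size)
    engine = _AmplitudeEngine(rip_c, anc_c, bounds, j, seg, w, step_s, ms)
    if engine.n_windows == 0:
        raise InsufficientDataError(
            "all anchors dropped (windows exit their NREM segments)"
        )
    lags = engine.lag_bins * step_s
    return engine, lags


def amplitude_xcorr(
    ripple_env: np.ndarray,
    anchor_env: np.ndarray,
    anchors_s: np.ndarray,
    fs: float,
    half_window_s: float = DEFAULT_HALF_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    nrem: list[StateInterval] | None = None,
    anchor_label: str = "spindle_center",
    peak_search_s: float | None = DEFAULT_PEAK_SEARCH_S,
) -> CrossCorrelogram:
    """Anchor-averaged Pearson correlogram of two envelopes.

    For each anchor time c and each lag tau on the grid, the anchor
    envelope over [c-W, c+W] is correlated with the ripple envelope over
    [c-W+tau, c+W+tau]; coefficients are averaged across anchors.
    Anchors whose shifted windows would exit their containing NREM
    segment are dropped.  Envelopes are bin-averaged to the lag-grid
    resolution first.  The full correlogram is returned; the peak is
    extracted within ``peak_search_s`` of zero lag (None = full grid).
    """
    if peak_search_s is not None and peak_search_s >= half_window_s:
        peak_search_s = None
    engine, lags = _build_engine(
        ripple_env, anchor_env, anchors_s, fs, half_window_s, step_s,
        nrem, max_shift_s=0.0,
    )
    coefs = engine.coefs(0)
    peak, lag = _peak(lags, coefs, peak_search_s)
    return CrossCorrelogram(
        lags_s=lags, coefs=coefs, n_windows=engine.n_windows,
        peak_coef=peak, peak_lag_s=lag, method="amplitude",
        anchor=anchor_label, half_window_s=half_window_s,
        n_skipped=engine.n_skipped, peak_search_s=peak_search_s,
    )


def shuffle_null_test(
    ripple_env: np.ndarray,
    anchor_env: np.ndarray,
    anchors_s: np.ndarray,
    fs: float,
    half_window_s: float = DEFAULT_HALF_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    nrem: list[StateInterval] | None = None,
    n_shuffles: int = N_SHUFFLES,
    shift_range_s: tuple[float, float | None] = SHIFT_RANGE_S,
    seed: int = 0,
    shuffle_mode: str = "global",
    anchor_label: str = "spindle_center",
    peak_search_s: float | None = DEFAULT_PEAK_SEARCH_S,
) -> tuple[CrossCorrelogram, ShuffleNull]:
    """Observed amplitude correlogram plus its circular-shift null.

    Each surrogate circularly shifts the ripple envelope within
    concatenated NREM by at least ``shift_range_s[0]`` seconds (sign
    equiprobable); with the default upper bound ``None`` the shift is
    drawn uniformly over the whole concatenated trace.  Surrogate peaks
    sample one underlying cross-correlogram at shifted positions, so the
    shifts must spread over a span much longer than the correlogram's
    decorrelation time for the 100 surrogate peaks to be effectively
    independent -- with a narrow range such as the classical 4-10 s the
    null's 99th percentile is under-sampled and the test becomes
    anti-conservative (see docs/methods.md).  ``shuffle_mode`` 'global'
    shifts the whole trace once per surrogate (preserving ripple
    autocorrelation); 'per_window' draws an independent shift per anchor
    window.  Significance: observed peak strictly above the nearest-rank
    99th percentile of surrogate peaks.
    """
    if shuffle_mode not in ("global", "per_window"):
        raise ParameterError(f"unknown shuffle_mode {shuffle_mode!r}")
    if peak_search_s is not None and peak_search_s >= half_window_s:
        peak_search_s = None
    lo, hi = shift_range_s
    if not nrem:
        raise InsufficientDataError("no NREM intervals")
    total_nrem = sum(iv.duration_s for iv in nrem)
    if total_nrem < 20.0:
        raise InsufficientDataError(
            f"concatenated NREM is {total_nrem:.0f} s; shifting needs >= 20 s"
        )
    if hi is None:
        hi = max(total_nrem - lo, 2 * lo)
    if not 0 < lo < hi:
        raise ParameterError(f"bad shift range ({lo}, {hi})")
    engine, lags = _build_engine(
        ripple_env, anchor_env, anchors_s, fs, half_window_s, step_s,
        nrem, max_shift_s=hi,
    )
    coefs = engine.coefs(0)
    observed, lag = _peak(lags, coefs, peak_search_s)
    xcg = CrossCorrelogram(
        lags_s=lags, coefs=coefs, n_windows=engine.n_windows,
        peak_coef=observed, peak_lag_s=lag, method="amplitude",
        anchor=anchor_label, half_window_s=half_window_s,
        n_skipped=engine.n_skipped, peak_search_s=peak_search_s,
    )
    rng = np.random.default_rng(seed)
    null_peaks = np.empty(n_shuffles)
    for i in range(n_shuffles):
        if shuffle_mode == "global":
            delta = rng.uniform(lo, hi)
            sign = 1 if rng.random() < 0.5 else -1
            c = engine.coefs(sign * int(round(delta / step_s)))
        else:
            rows = []
            for k in range(engine.n_windows):
                delta = rng.uniform(lo, hi)
                sign = 1 if rng.random() < 0.5 else -1
                rows.append((k, sign * int(round(delta / step_s))))
            c = _per_window_coefs(engine, rows)
        null_peaks[i], _ = _peak(lags, c, peak_search_s, refine=False)
    srt = np.sort(null_peaks)
    rank = int(np.ceil(0.99 * n_shuffles))  # nearest-rank percentile
    pct99 = float(srt[rank - 1])
    null = ShuffleNull(
        n_shuffles=n_shuffles, shift_range_s=(lo, hi),
        null_peaks=null_peaks, pct99=pct99, observed_peak=observed,
        is_significant=bool(observed > pct99), seed=seed,
    )
    return xcg, null


def _per_window_coefs(engine: _AmplitudeEngine, shifts: list[tuple[int, int]]):
    """Correlogram with an independent circular shift per anchor."""
    w, ms, L, n = engine.w, engine.ms, engine.L, engine.n
    rows = np.full((len(shifts), 2 * w + 1), np.nan)
    for r, (k, sh) in enumerate(shifts):
        anc = engine.anchors[k]
        p = (anc["j"] - w + engine.lag_bins - sh) % L
        if engine.full:
            dots = anc["dots"][p]
        else:
            dots = anc["dots"][engine.lag_bins + w + ms - sh]
        S, Q = engine.S[p], engine.Q[p]
        var_t = Q - S * S / n
        with np.errstate(invalid="ignore", divide="ignore"):
            coef = (dots - anc["a_mean"] * S) / (anc["a_denom"] * np.sqrt(var_t))
        coef[var_t <= 0] = np.nan
        rows[r] = coef
    with np.errstate(invalid="ignore"):
        return np.nanmean(rows, axis=0)


# ---------------------------------------------------------------------------
# timestamp method


def _event_times(events) -> np.ndarray:
    if isinstance(events, EventSet):
        return events.centers()
    return np.asarray(events, dtype=np.float64)


def timestamp_xcorr(
    ripple_events,
    spindle_events,
    half_window_s: float = DEFAULT_HALF_WINDOW_S,
    bin_s: float = TS_BIN_S,
    nrem: list[StateInterval] | None = None,
) -> CrossCorrelogram:
    """Pearson correlogram of binarized event trains.

    Event centres are mapped onto concatenated NREM time, binarized at
    ``bin_s`` resolution and correlated at every integer-bin lag within
    +-half_window_s over the overlapping stretch.  Sign convention
    matches the amplitude method (negative lag = ripple leads).
    """
    rip_t = _event_times(ripple_events)
    spi_t = _event_times(spindle_events)
    if rip_t.size == 0 or spi_t.size == 0:
        raise InsufficientDataError("both event sets must be non-empty")
    if not nrem:
        raise InsufficientDataError("no NREM intervals")

    # map recording times to concatenated NREM time
    def to_concat(ts: np.ndarray) -> np.ndarray:
        out = []
        offset = 0.0
        for iv in nrem:
            sel = (ts >= iv.start_s) & (ts < iv.end_s)
            out.extend(offset + ts[sel] - iv.start_s)
            offset += iv.duration_s
        return np.asarray(out)

    total = sum(iv.duration_s for iv in nrem)
    L = int(np.floor(total / bin_s))
    if L < 2:
        raise InsufficientDataError("NREM too short for the bin grid")

    def train(ts: np.ndarray) -> np.ndarray:
        tr = np.zeros(L, dtype=np.float64)
        idx = np.floor(to_concat(ts) / bin_s).astype(int)
        idx = idx[(idx >= 0) & (idx < L)]
        tr[idx] = 1.0
        return tr

    x = train(spi_t)  # anchor train
    y = train(rip_t)  # ripple train
    for name, tr in (("spindle", x), ("ripple", y)):
        if tr.sum() == 0 or tr.sum() == L:
            raise DegenerateSignalError(f"{name} train is constant")

    K = int(round(half_window_s / bin_s))
    lags = np.arange(-K, K + 1) * bin_s
    coefs = np.full(2 * K + 1, np.nan)
    for i, k in enumerate(range(-K, K + 1)):
        if k >= 0:
            xa, ya = x[: L - k], y[k:]
        else:
            xa, ya = x[-k:], y[: L + k]
        if xa.size < 2 or xa.std() == 0 or ya.std() == 0:
            continue
        coefs[i] = float(np.corrcoef(xa, ya)[0, 1])
    peak, lag = _peak(lags, coefs)
    return CrossCorrelogram(
        lags_s=lags, coefs=coefs, n_windows=int(spi_t.size),
        peak_coef=peak, peak_lag_s=lag, method="timestamp",
        anchor="spindle_center", half_window_s=half_window_s,
    )


# ---------------------------------------------------------------------------
# joint occurrence and normalization


def joint_occurrence_rate(
    ripple_events, spindle_events, window_s: float = JOINT_WINDOW_S
) -> float:
    """Ripples whose centre lies within +-window_s of at least one
    spindle centre (each ripple counted once), per spindle."""
    rip_t = _event_times(ripple_events)
    spi_t = _event_times(spindle_events)
    if spi_t.size == 0:
        raise InsufficientDataError("spindle count is zero")
    if rip_t.size == 0:
        return 0.0
    spi_sorted = np.sort(spi_t)
    idx = np.searchsorted(spi_sorted, rip_t)
    near = np.full(rip_t.size, np.inf)
    left = idx > 0
    near[left] = np.abs(rip_t[left] - spi_sorted[idx[left] - 1])
    right = idx < spi_sorted.size
    near[right] = np.minimum(
        near[right], np.abs(rip_t[right] - spi_sorted[idx[right]])
    )
    return float(np.sum(near <= window_s) / spi_t.size)


def ripple_delta_xcorr(
    ripple_env: np.ndarray,
    delta_env: np.ndarray,
    delta_events,
    fs: float,
    nrem: list[StateInterval],
    half_window_s: float = DELTA_HALF_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
) -> CrossCorrelogram:
    """Ripple-delta amplitude correlogram anchored at delta onsets
    (+-0.5 s window; negative lag = ripple lead, positive = delta lead)."""
    onsets = (
        delta_events.onsets()
        if isinstance(delta_events, EventSet)
        else np.asarray(delta_events, dtype=np.float64)
    )
    return amplitude_xcorr(
        ripple_env, delta_env, onsets, fs, half_window_s=half_window_s,
        step_s=step_s, nrem=nrem, anchor_label="delta_onset",
    )


def normalize_to_baseline(post_value: float, pre_value: float) -> float:
    """Post/pre ratio (session value normalized to its baseline)."""
    if pre_value == 0:
        raise ParameterError("baseline value is zero")
    return post_value / pre_value
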