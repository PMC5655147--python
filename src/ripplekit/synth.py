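"""Synthetic dual-site LFP/EMG generator with ground truth.

Emulates a 2 kHz three-channel recording (CA1 LFP, ACC LFP, EMG) of a
mouse resting in a recording chamber: wake/NREM/REM blocks, 1/f
background, hippocampal ripples (100-250 Hz bursts), neocortical
spindles (12-15 Hz bursts) and delta waves (1-4 Hz deflections) during
NREM, tonic theta during REM, and EMG whose movement bursts mark wake.
A controllable fraction of ripples is placed at a fixed (jittered) lag
from spindle centres so downstream coupling statistics have an exact
ground truth.

Amplitude calibration: the LFP backgrounds are scaled so the 100-250 Hz
Hilbert-envelope SD equals 1, and each event template's amplitude is set
so the detection-band envelope at the event peak sits ``event_snr``
background-envelope SDs above the background-envelope mean -- the same
z-score scale on which the detectors threshold.  Phase-aligned bursts
(spindles, delta waves) subtract the background envelope mean from the
target amplitude (constructive addition); random-phase ripples use a
quadrature correction for the background's envelope power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import hilbert as sps_hilbert
from scipy.signal.windows import tukey

from .core import (
    DEFAULT_FS,
    NREM,
    REM,
    WAKE,
    ACC_LFP,
    CA1_LFP,
    EMG,
    Hypnogram,
    ParameterError,
    Recording,
    StateInterval,
)
from .spectral import bandpass_filter, hilbert_envelope

RIPPLE_BAND = (100.0, 250.0)
SPINDLE_BAND = (12.0, 15.0)
DELTA_BAND = (1.0, 4.0)
THETA_BAND = (4.0, 12.0)


@dataclass
class SynthConfig:
    """Generator settings.

    Event rates are per second of NREM; conventional rodent values are
    used as defaults (ripples ~15/min, spindles ~9/min, delta waves
    ~18/min of NREM).  ``p_couple`` is the probability that a ripple is
    placed relative to a spindle centre at ``couple_lag_s`` (negative =
    ripple leads) with Gaussian jitter; remaining ripples fall uniformly
    over NREM.  ``event_snr`` is the z-score of the detection-band
    envelope at an event peak relative to the background envelope
    (mean + snr * SD) in that band.
    """

    duration_s: float = 1800.0
    fs: float = DEFAULT_FS
    state_block_s: dict = field(
        default_factory=lambda: {WAKE: 60.0, NREM: 240.0, REM: 30.0}
    )
    state_sequence_mode: str = "fixed_blocks"  # or "markov"
    ripple_rate_hz: float = 0.25
    spindle_rate_hz: float = 0.15
    delta_rate_hz: float = 0.30
    p_couple: float = 0.5
    couple_lag_s: float = -0.07
    couple_jitter_sd_s: float = 0.03
    event_snr: float = 5.0
    emg_wake_gain: float = 8.0
    emg_sleep_gain: float = 1.0
    noise_exponent: float = 1.0
    seed: int = 0
    # waveform templates
    ripple_freq_hz: float = 150.0
    ripple_dur_s: float = 0.08
    ripple_taper: float = 0.3
    spindle_freq_hz: float = 13.0
    spindle_dur_s: float = 0.7
    spindle_shape_exp: float = 0.5
    delta_dur_s: float = 0.25
    theta_freq_hz: float = 7.0
    rem_theta_gain: float = 6.0
    nrem_delta_gain: float = 2.0
    max_ripples_per_spindle: int = 1

    def __post_init__(self) -> None:
        if self.fs / 2 <= RIPPLE_BAND[1]:
            raise ParameterError(
                f"fs={self.fs}: Nyquist must exceed {RIPPLE_BAND[1]} Hz"
            )
        for name in ("ripple_rate_hz", "spindle_rate_hz", "delta_rate_hz"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.p_couple <= 1.0:
            raise ParameterError("p_couple must lie in [0, 1]")
        if self.p_couple > 0 and self.spindle_rate_hz == 0:
            raise ParameterError("p_couple > 0 requires spindle_rate_hz > 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")


@dataclass
class GroundTruth:
    """Generator-side truth, consumed only by validation code."""

    hypnogram: Hypnogram
    ripple_times: np.ndarray
    spindle_times: np.ndarray
    delta_times: np.ndarray
    coupled_flags: np.ndarray
    config: SynthConfig
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# state sequence


def generate_state_sequence(cfg: SynthConfig, seed: int | None = None) -> Hypnogram:
    """Wake/NREM/REM hypnogram with full coverage.

    ``fixed_blocks`` cycles WAKE -> NREM -> REM with the configured
    block lengths (states with zero length are skipped); ``markov``
    draws exponential block durations with those means and alternates
    via a simple transition rule.  REM is kept a minor fraction by the
    default block lengths, matching short rest recordings in which
    substantial REM is rare.
    """
    if cfg.duration_s < 120:
        raise ParameterError("state sequence needs duration_s >= 120")
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed).spawn(1)[0]
    )
    intervals: list[StateInterval] = []
    t = 0.0
    if cfg.state_sequence_mode == "fixed_blocks":
        cycle = [s for s in (WAKE, NREM, REM) if cfg.state_block_s.get(s, 0) > 0]
        i = 0
        while t < cfg.duration_s:
            state = cycle[i % len(cycle)]
            end = min(t + cfg.state_block_s[state], cfg.duration_s)
            intervals.append(StateInterval(t, end, state))
            t = end
            i += 1
    elif cfg.state_sequence_mode == "markov":
        state = WAKE
        while t < cfg.duration_s:
            mean = cfg.state_block_s.get(state, 0.0)
            dur = max(rng.exponential(mean), 2.0) if mean > 0 else 2.0
            end = min(t + dur, cfg.duration_s)
            intervals.append(StateInterval(t, end, state))
            t = end
            if state == WAKE:
                state = NREM
            elif state == NREM:
                state = REM if (
                    cfg.state_block_s.get(REM, 0) > 0 and rng.random() < 0.3
                ) else WAKE
            else:
                state = WAKE
    else:
        raise ParameterError(f"unknown mode {cfg.state_sequence_mode!r}")
    hyp = Hypnogram(intervals, cfg.duration_s)
    if hyp.total_s(NREM) <= 0:
        raise ParameterError("generated hypnogram contains no NREM")
    return hyp


# ---------------------------------------------------------------------------
# helpers


def _pink_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """1/f^alpha background via spectral shaping of white noise.

    Below 1 Hz the gain rolls off toward DC and above 400 Hz it falls as
    1/f^2, mimicking the 1-400 Hz acquisition band.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(f)
    mid = f >= 1.0
    gain[mid] = f[mid] ** (-alpha / 2.0)
    low = (f > 0) & (f < 1.0)
    gain[low] = f[low] ** 2  # gentle roll-off to DC
    gain[0] = 0.0
    high = f > 400.0
    gain[high] = (400.0 ** (-alpha / 2.0)) * (400.0 / f[high]) ** 2
    return np.fft.irfft(spec * gain, n=n)


def _band_stats(x: np.ndarray, fs: float, band: tuple[float, float]):
    """(envelope SD, mean envelope^2, envelope mean) in a band."""
    xf = bandpass_filter(x, fs, *band)
    env = hilbert_envelope(xf)
    return float(np.std(env)), float(np.mean(env**2)), float(np.mean(env))


def _template_amp(
    snr: float,
    env_sd: float,
    env_sq: float,
    env_mean: float,
    template: np.ndarray,
    fs: float,
    band: tuple[float, float],
    aligned: bool,
) -> float:
    """Scale factor so the detection-band envelope at the event peak sits
    ``snr`` background-envelope SDs above the background-envelope mean
    (the same z-score scale the detectors threshold on).

    The unit template's own in-band envelope response is measured
    directly (a half-wave delta deflection, for instance, loses part of
    its energy outside 1-4 Hz).  For bursts phase-aligned to the ongoing
    band activity the background adds constructively at the peak, so its
    envelope mean is subtracted; for random-phase bursts the background
    contributes envelope power ``env_sq`` in quadrature.  At low snr the
    corrections are clamped to keep amplitudes positive.
    """
    pad = np.zeros(int(round(4.0 * fs)))
    probe = np.concatenate([pad, template, pad])
    h = float(np.max(hilbert_envelope(bandpass_filter(probe, fs, *band))))
    target = env_mean + snr * env_sd
    if aligned:
        a = max(target - env_mean, 0.5 * target)
    else:
        a = np.sqrt(max(target**2 - env_sq, (0.5 * target) ** 2))
    return float(a / h)


def _burst(fs: float, dur_s: float, freq: float, taper: float, phase: float) -> np.ndarray:
    """Tukey-tapered oscillatory burst; ``phase`` is the carrier phase at
    the burst centre (so it can be aligned to ongoing band activity)."""
    n = max(int(round(dur_s * fs)), 4)
    t = (np.arange(n) - (n - 1) / 2) / fs
    return tukey(n, taper) * np.cos(2 * np.pi * freq * t + phase)


def _waxwane_burst(
    fs: float, dur_s: float, freq: float, shape_exp: float, phase: float
) -> np.ndarray:
    """Waxing-waning burst with a cos^gamma envelope: strictly unimodal
    (the envelope maximum pins the event centre, which lag statistics
    rely on) yet broad-shouldered for small gamma, so the suprathreshold
    extent stays close to the nominal duration."""
    n = max(int(round(dur_s * fs)), 4)
    t = (np.arange(n) - (n - 1) / 2) / fs
    env = np.cos(np.pi * t / dur_s) ** shape_exp
    return env * np.cos(2 * np.pi * freq * t + phase)


def _half_wave(fs: float, dur_s: float) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 4)
    t = np.arange(n) / fs
    return -np.sin(np.pi * t / dur_s)


def _add_at(signal: np.ndarray, template: np.ndarray, center_idx: int) -> None:
    n = template.size
    a = center_idx - n // 2
    b = a + n
    lo, hi = max(a, 0), min(b, signal.size)
    if lo < hi:
        signal[lo:hi] += template[lo - a : hi - a]


def _state_weight(
    hyp: Hypnogram, state: str, fs: float, n: int, ramp_s: float = 1.0
) -> np.ndarray:
    """Per-sample 0..1 weight for a state with half-cosine edge ramps."""
    w = np.zeros(n)
    nramp = int(round(ramp_s * fs))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nramp) / nramp))
    for iv in hyp.intervals_for(state):
        a, b = int(round(iv.start_s * fs)), min(int(round(iv.end_s * fs)), n)
        w[a:b] = 1.0
        if nramp and a > 0:
            seg = ramp[: min(nramp, b - a)]
            w[a : a + seg.size] = np.maximum(w[a : a + seg.size] * 0, seg)
        if nramp and b < n:
            seg = ramp[::-1][: min(nramp, b - a)]
            w[b - seg.size : b] = seg
    return w


def _sample_times(
    rng: np.random.Generator,
    intervals: list[StateInterval],
    n: int,
    margin_s: float,
    min_sep_s: float,
    avoid: np.ndarray | None = None,
    avoid_sep_s: float = 0.0,
) -> np.ndarray:
    """Uniform times inside intervals with edge margins and separation."""
    lens = np.array([max(iv.duration_s - 2 * margin_s, 0.0) for iv in intervals])
    if lens.sum() <= 0 or n == 0:
        return np.empty(0)
    probs = lens / lens.sum()
    placed: list[float] = []
    tries = 0
    while len(placed) < n and tries < 400 * max(n, 1):
        tries += 1
        i = rng.choice(len(intervals), p=probs)
        iv = intervals[i]
        t = rng.uniform(iv.start_s + margin_s, iv.end_s - margin_s)
        if placed and np.min(np.abs(np.array(placed) - t)) < min_sep_s:
            continue
        if avoid is not None and avoid.size and np.min(np.abs(avoid - t)) < avoid_sep_s:
            continue
        placed.append(t)
    return np.sort(np.array(placed))


def _time_in_nrem(t: float, intervals: list[StateInterval], margin_s: float) -> bool:
    return any(iv.start_s + margin_s <= t <= iv.end_s - margin_s for iv in intervals)


# ---------------------------------------------------------------------------
# main generator


def generate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Build a three-channel recording plus its ground truth.

    Independent seeded sub-streams drive the state sequence, the noise
    backgrounds, event placement and the EMG, so changing one component
    leaves the others bit-identical.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_state, s_noise, s_events, s_emg, s_tonic = ss.spawn(5)
    rng_noise = np.random.default_rng(s_noise)
    rng_events = np.random.default_rng(s_events)
    rng_emg = np.random.default_rng(s_emg)
    rng_tonic = np.random.default_rng(s_tonic)

    hyp = generate_state_sequence(cfg, seed=None)  # uses cfg.seed via its own stream
    warnings: list[str] = []

    n = int(round(cfg.duration_s * cfg.fs))
    fs = cfg.fs
    nrem = hyp.intervals_for(NREM)
    t_nrem = hyp.total_s(NREM)

    # --- backgrounds, normalized to unit ripple-band envelope SD
    ca1 = _pink_noise(rng_noise, n, fs, cfg.noise_exponent)
    acc = _pink_noise(rng_noise, n, fs, cfg.noise_exponent)
    sd_r, _, _ = _band_stats(ca1, fs, RIPPLE_BAND)
    ca1 /= sd_r
    sd_r_acc, _, _ = _band_stats(acc, fs, RIPPLE_BAND)
    acc /= sd_r_acc

    # band calibration on the normalized backgrounds
    u_rip, q_rip, m_rip = _band_stats(ca1, fs, RIPPLE_BAND)
    # spindle band: keep the analytic signal, its phase aligns the bursts
    acc_sigma_analytic = sps_hilbert(bandpass_filter(acc, fs, *SPINDLE_BAND))
    sigma_env = np.abs(acc_sigma_analytic)
    u_spi = float(np.std(sigma_env))
    q_spi = float(np.mean(sigma_env**2))
    m_spi = float(np.mean(sigma_env))
    sigma_phase = np.angle(acc_sigma_analytic)
    del acc_sigma_analytic, sigma_env
    # delta band: keep the filtered trace, its polarity aligns deflections
    acc_delta_f = bandpass_filter(acc, fs, *DELTA_BAND)
    delta_env = hilbert_envelope(acc_delta_f)
    u_del = float(np.std(delta_env))
    q_del = float(np.mean(delta_env**2))
    m_del = float(np.mean(delta_env))
    del delta_env
    u_del_ca1, _, _ = _band_stats(ca1, fs, DELTA_BAND)
    u_the_ca1, _, _ = _band_stats(ca1, fs, THETA_BAND)
    u_the_acc, _, _ = _band_stats(acc, fs, THETA_BAND)

    # --- event times
    exp_counts = {
        "ripple": cfg.ripple_rate_hz * t_nrem,
        "spindle": cfg.spindle_rate_hz * t_nrem,
        "delta": cfg.delta_rate_hz * t_nrem,
    }
    for kind, ec in exp_counts.items():
        if 0 < ec < 1:
            warnings.append(f"expected {kind} count {ec:.2f} < 1")

    n_spindles = rng_events.poisson(exp_counts["spindle"])
    spindle_times = _sample_times(
        rng_events, nrem, n_spindles, margin_s=cfg.spindle_dur_s / 2 + 0.3,
        min_sep_s=2.0,
    )
    n_deltas = rng_events.poisson(exp_counts["delta"])
    delta_times = _sample_times(
        rng_events, nrem, n_deltas, margin_s=cfg.delta_dur_s / 2 + 0.2,
        min_sep_s=0.8, avoid=spindle_times, avoid_sep_s=1.0,
    )

    n_ripples = rng_events.poisson(exp_counts["ripple"])
    rip_margin = cfg.ripple_dur_s / 2 + 0.1
    free_spindles = list(rng_events.permutation(len(spindle_times)))
    ripple_times: list[float] = []
    coupled: list[bool] = []
    for _ in range(n_ripples):
        t = None
        is_coupled = False
        if rng_events.random() < cfg.p_couple and free_spindles:
            for _ in range(100):
                z = rng_events.standard_normal()
                if abs(z) <= 4.0:  # keep within the documented jitter bound
                    break
            # scan for a pairable spindle: one unplaceable candidate (NREM
            # margin or ripple separation) must not block the whole queue
            for pos, sp_idx in enumerate(free_spindles):
                cand = (spindle_times[sp_idx] + cfg.couple_lag_s
                        + z * cfg.couple_jitter_sd_s)
                if _time_in_nrem(cand, nrem, rip_margin) and (
                    not ripple_times
                    or np.min(np.abs(np.array(ripple_times) - cand)) >= 0.3
                ):
                    t = cand
                    is_coupled = True
                    free_spindles.pop(pos)
                    break
        if t is None:
            got = _sample_times(
                rng_events, nrem, 1, margin_s=rip_margin, min_sep_s=0.0,
                avoid=np.array(ripple_times), avoid_sep_s=0.3,
            )
            if got.size == 0:
                continue
            t = float(got[0])
        ripple_times.append(float(t))
        coupled.append(is_coupled)
    order = np.argsort(ripple_times)
    ripple_times_arr = np.array(ripple_times)[order]
    coupled_arr = np.array(coupled, dtype=bool)[order]

    # --- implant templates
    a_rip = _template_amp(
        cfg.event_snr, u_rip, q_rip, m_rip,
        _burst(fs, cfg.ripple_dur_s, cfg.ripple_freq_hz, cfg.ripple_taper, 0.0),
        fs, RIPPLE_BAND, aligned=False,
    )
    a_spi = _template_amp(
        cfg.event_snr, u_spi, q_spi, m_spi,
        _waxwane_burst(fs, cfg.spindle_dur_s, cfg.spindle_freq_hz,
                       cfg.spindle_shape_exp, 0.0),
        fs, SPINDLE_BAND, aligned=True,
    )
    a_del = _template_amp(
        cfg.event_snr, u_del, q_del, m_del, _half_wave(fs, cfg.delta_dur_s),
        fs, DELTA_BAND, aligned=True,
    )
    for t in ripple_times_arr:
        phase = rng_events.uniform(0, 2 * np.pi)
        _add_at(ca1, a_rip * _burst(fs, cfg.ripple_dur_s, cfg.ripple_freq_hz,
                                    cfg.ripple_taper, phase),
                int(round(t * fs)))
    for t in spindle_times:
        # align the carrier to the ongoing sigma-band phase at the centre:
        # additive bursts with independent phase suffer Rician fading that
        # can cancel an entire event against the narrowband background
        idx = int(round(t * fs))
        phase = float(sigma_phase[idx])
        _add_at(acc, a_spi * _waxwane_burst(fs, cfg.spindle_dur_s,
                                            cfg.spindle_freq_hz,
                                            cfg.spindle_shape_exp, phase), idx)
    for t in delta_times:
        # sign-match the deflection to the ongoing delta-band polarity so
        # additive synthesis does not cancel the event against background
        idx = int(round(t * fs))
        sign = 1.0 if acc_delta_f[idx] <= 0 else -1.0
        _add_at(acc, sign * a_del * _half_wave(fs, cfg.delta_dur_s), idx)

    # --- tonic state-dependent components
    w_nrem = _state_weight(hyp, NREM, fs, n)
    w_rem = _state_weight(hyp, REM, fs, n)
    if np.any(w_nrem > 0):
        delta_noise = bandpass_filter(rng_tonic.standard_normal(n), fs, 1.0, 4.0)
        delta_noise *= cfg.nrem_delta_gain * u_del_ca1 / np.std(hilbert_envelope(delta_noise))
        ca1 += w_nrem * delta_noise
    if np.any(w_rem > 0):
        theta_noise = bandpass_filter(
            rng_tonic.standard_normal(n), fs,
            cfg.theta_freq_hz - 1.0, cfg.theta_freq_hz + 1.0,
        )
        theta_env_sd = np.std(hilbert_envelope(theta_noise))
        ca1 += w_rem * theta_noise * (cfg.rem_theta_gain * u_the_ca1 / theta_env_sd)
        acc += w_rem * theta_noise * (0.5 * cfg.rem_theta_gain * u_the_acc / theta_env_sd)

    # --- EMG: broadband noise; movement bursts mark wake
    emg_env = np.full(n, cfg.emg_sleep_gain)
    burst_amp = cfg.emg_wake_gain - cfg.emg_sleep_gain
    for iv in hyp.intervals_for(WAKE):
        t = iv.start_s + rng_emg.uniform(0.0, 0.5)
        while t < iv.end_s:
            dur = rng_emg.uniform(0.3, 1.5)
            amp = burst_amp * rng_emg.uniform(0.6, 1.0)
            a = int(round(t * fs))
            b = min(int(round((t + dur) * fs)), int(round(iv.end_s * fs)), n)
            if b > a:
                bump = np.sin(np.pi * np.arange(b - a) / (b - a)) ** 2
                emg_env[a:b] += amp * bump
            t += dur + rng_emg.uniform(0.3, 2.5)
    emg = rng_emg.standard_normal(n) * emg_env

    rec = Recording(
        channels={CA1_LFP: ca1, ACC_LFP: acc, EMG: emg},
        fs=fs,
        meta={"generator": "ripplekit.synth", "seed": cfg.seed},
    )
    gt = GroundTruth(
        hypnogram=hyp,
        ripple_times=ripple_times_arr,
        spindle_times=spindle_times,
        delta_times=delta_times,
        coupled_flags=coupled_arr,
        config=cfg,
        warnings=warnings,
    )
    return rec, gt
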