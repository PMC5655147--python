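"""Coupling statistics against brute-force oracles and sign conventions."""

import numpy as np
import pytest

from ripplekit.core import (
    DegenerateSignalError,
    InsufficientDataError,
    ParameterError,
    StateInterval,
)
from ripplekit.coupling import (
    amplitude_xcorr,
    joint_occurrence_rate,
    normalize_to_baseline,
    ripple_delta_xcorr,
    shuffle_null_test,
    timestamp_xcorr,
)

FS = 2000.0


def _smooth_env(seed, duration_s=30.0, tau=0.1):
    rng = np.random.default_rng(seed)
    n = int(duration_s * FS)
    k = int(tau * FS)
    return np.abs(np.convolve(rng.standard_normal(n), np.ones(k) / k, "same"))


NREM_30 = [StateInterval(0.0, 30.0, "NREM")]
ANCHORS = np.array([12.0, 15.0, 18.0])


def _naive_xcorr(rip, anc, anchors, half_window_s, step_s):
    """Brute-force per-lag Pearson on bin-averaged envelopes."""
    d = int(step_s * FS)
    dec_r = rip[: rip.size // d * d].reshape(-1, d).mean(axis=1)
    dec_a = anc[: anc.size // d * d].reshape(-1, d).mean(axis=1)
    w = int(half_window_s / step_s)
    rows = []
    for c in anchors:
        j = int(c / step_s)
        a = dec_a[j - w : j + w + 1]
        rows.append([
            np.corrcoef(a, dec_r[j - w + k : j + w + 1 + k])[0, 1]
            for k in range(-w, w + 1)
        ])
    return np.mean(rows, axis=0)


class TestAmplitudeXcorr:
    def test_matches_naive_pearson_oracle(self):
        rip, anc = _smooth_env(0), _smooth_env(1)
        xc = amplitude_xcorr(rip, anc, ANCHORS, FS, half_window_s=2.0,
                             nrem=NREM_30)
        oracle = _naive_xcorr(rip, anc, ANCHORS, 2.0, 0.01)
        assert np.max(np.abs(xc.coefs - oracle)) < 1e-10

    def test_identical_envelopes_peak_one_at_zero(self):
        env = _smooth_env(2)
        xc = amplitude_xcorr(env, env, ANCHORS, FS, half_window_s=2.0,
                             nrem=NREM_30)
        assert xc.peak_coef == pytest.approx(1.0, abs=1e-9)
        assert xc.peak_lag_s == 0.0

    def test_advanced_ripple_gives_negative_lag(self):
        """Ripple activity 0.07 s before the anchor -> peak lag -0.07."""
        anc = _smooth_env(3)
        rip = np.roll(anc, -int(0.07 * FS))
        xc = amplitude_xcorr(rip, anc, ANCHORS, FS, half_window_s=2.0,
                             nrem=NREM_30)
        assert xc.peak_lag_s == pytest.approx(-0.07, abs=0.0101)
        assert xc.peak_coef > 0.99

    def test_swap_negates_lag(self):
        anc = _smooth_env(4)
        rip = np.roll(anc, -int(0.1 * FS))
        x1 = amplitude_xcorr(rip, anc, ANCHORS, FS, half_window_s=2.0,
                             nrem=NREM_30)
        x2 = amplitude_xcorr(anc, rip, ANCHORS, FS, half_window_s=2.0,
                             nrem=NREM_30)
        assert x1.peak_lag_s == pytest.approx(-x2.peak_lag_s, abs=0.0201)

    def test_anchors_near_segment_edge_dropped(self):
        env = _smooth_env(5)
        xc = amplitude_xcorr(env, env, np.array([2.0, 15.0]), FS,
                             half_window_s=2.0, nrem=NREM_30)
        assert xc.n_windows == 1  # the 2.0 s anchor needs data before 0

    def test_all_anchors_dropped_raises(self):
        env = _smooth_env(6)
        with pytest.raises(InsufficientDataError):
            amplitude_xcorr(env, env, np.array([1.0]), FS, half_window_s=2.0,
                            nrem=NREM_30)

    def test_coefficients_bounded(self):
        xc = amplitude_xcorr(_smooth_env(7), _smooth_env(8), ANCHORS, FS,
                             half_window_s=2.0, nrem=NREM_30)
        ok = np.isfinite(xc.coefs)
        assert np.all(xc.coefs[ok] <= 1.0 + 1e-12)
        assert np.all(xc.coefs[ok] >= -1.0 - 1e-12)


class TestShuffleNull:
    def test_seed_reproducibility(self):
        rip, anc = _smooth_env(10, 120.0), _smooth_env(11, 120.0)
        nrem = [StateInterval(0.0, 120.0, "NREM")]
        anchors = np.arange(20.0, 100.0, 10.0)
        _, n1 = shuffle_null_test(rip, anc, anchors, FS, half_window_s=2.0,
                                  nrem=nrem, seed=7)
        _, n2 = shuffle_null_test(rip, anc, anchors, FS, half_window_s=2.0,
                                  nrem=nrem, seed=7)
        assert np.array_equal(n1.null_peaks, n2.null_peaks)
        _, n3 = shuffle_null_test(rip, anc, anchors, FS, half_window_s=2.0,
                                  nrem=nrem, seed=8)
        assert not np.array_equal(n1.null_peaks, n3.null_peaks)
        assert n3.observed_peak == n1.observed_peak

    def test_nearest_rank_pct99_is_max_of_lowest_99(self):
        rip, anc = _smooth_env(12, 120.0), _smooth_env(13, 120.0)
        nrem = [StateInterval(0.0, 120.0, "NREM")]
        anchors = np.arange(20.0, 100.0, 10.0)
        _, null = shuffle_null_test(rip, anc, anchors, FS, half_window_s=2.0,
                                    nrem=nrem, seed=9)
        assert null.pct99 == np.sort(null.null_peaks)[98]
        assert null.is_significant == (null.observed_peak > null.pct99)

    def test_short_nrem_rejected(self):
        rip, anc = _smooth_env(14, 15.0), _smooth_env(15, 15.0)
        with pytest.raises(InsufficientDataError):
            shuffle_null_test(rip, anc, np.array([7.0]), FS, half_window_s=2.0,
                              nrem=[StateInterval(0.0, 15.0, "NREM")], seed=0)

    def test_per_window_mode_runs(self):
        rip, anc = _smooth_env(16, 120.0), _smooth_env(17, 120.0)
        nrem = [StateInterval(0.0, 120.0, "NREM")]
        anchors = np.arange(20.0, 100.0, 10.0)
        _, null = shuffle_null_test(rip, anc, anchors, FS, half_window_s=2.0,
                                    nrem=nrem, seed=1, shuffle_mode="per_window")
        assert len(null.null_peaks) == 100

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            shuffle_null_test(_smooth_env(18, 60.0), _smooth_env(19, 60.0),
                              np.array([30.0]), FS,
                              nrem=[StateInterval(0.0, 60.0, "NREM")],
                              shuffle_mode="bogus")


class TestTimestampXcorr:
    NREM_600 = [StateInterval(0.0, 600.0, "NREM")]

    def test_identical_trains_peak_at_zero(self):
        t = np.arange(20.0, 580.0, 7.0)
        xc = timestamp_xcorr(t, t, nrem=self.NREM_600)
        assert xc.peak_lag_s == 0.0
        assert xc.peak_coef == pytest.approx(1.0)

    def test_half_second_offset_recovered(self):
        spi = np.arange(20.0, 580.0, 7.0)
        rip = spi + 0.5  # ripples after spindles -> spindle leads -> +0.5
        xc = timestamp_xcorr(rip, spi, nrem=self.NREM_600)
        assert xc.peak_lag_s == pytest.approx(0.5)

    def test_independent_poisson_trains_not_significant(self):
        """Independent trains stay below the 99th percentile of their own
        circular-shift null in most seeds."""
        wins = 0
        n_seeds = 10
        dur = 1200.0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rip = np.sort(rng.uniform(0, dur, rng.poisson(0.1 * dur)))
            spi = np.sort(rng.uniform(0, dur, rng.poisson(0.1 * dur)))
            nrem = [StateInterval(0.0, dur, "NREM")]
            xc = timestamp_xcorr(rip, spi, nrem=nrem)
            # circular-shift surrogate of the ripple train
            peaks = []
            for k in range(100):
                shift = rng.uniform(30, dur - 30)
                xs = timestamp_xcorr((rip + shift) % dur, spi, nrem=nrem)
                peaks.append(xs.peak_coef)
            if xc.peak_coef <= np.sort(peaks)[98]:
                wins += 1
        assert wins >= 9

    def test_empty_train_rejected(self):
        with pytest.raises(InsufficientDataError):
            timestamp_xcorr(np.array([]), np.array([10.0]), nrem=self.NREM_600)


class TestJointRate:
    def test_worked_example(self):
        rate = joint_occurrence_rate(
            np.array([10.1, 19.0, 30.2]), np.array([10.0, 20.0, 30.0])
        )
        assert rate == pytest.approx(2.0 / 3.0)

    def test_no_ripples_gives_zero(self):
        assert joint_occurrence_rate(np.array([]), np.array([10.0])) == 0.0

    def test_zero_spindles_rejected(self):
        with pytest.raises(InsufficientDataError):
            joint_occurrence_rate(np.array([10.0]), np.array([]))

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            rip = rng.uniform(0, 600, 50)
            spi = rng.uniform(0, 600, 50)
            fast = joint_occurrence_rate(rip, spi)
            brute = sum(
                1 for r in rip if any(abs(r - s) <= 0.25 for s in spi)
            ) / len(spi)
            assert fast == brute


class TestRippleDelta:
    def test_identical_envelopes(self):
        env = _smooth_env(20)
        xc = ripple_delta_xcorr(env, env, np.array([12.0, 15.0]), FS, NREM_30)
        assert xc.peak_coef == pytest.approx(1.0, abs=1e-9)
        assert xc.peak_lag_s == 0.0
        assert xc.half_window_s == 0.5
        assert xc.anchor == "delta_onset"

    def test_ripple_after_delta_positive_lag(self):
        """Ripple bumps 0.1 s after delta onsets -> delta leads -> +0.1."""
        rng = np.random.default_rng(21)
        n = int(120 * FS)
        onsets = np.arange(10.0, 110.0, 5.0)
        bump = np.exp(-0.5 * ((np.arange(-400, 401) / 100.0) ** 2))
        delta_env = 0.1 * np.abs(rng.standard_normal(n))
        rip_env = 0.1 * np.abs(rng.standard_normal(n))
        for c in onsets:
            i = int(c * FS)
            delta_env[i - 400 : i + 401] += bump
            j = int((c + 0.1) * FS)
            rip_env[j - 400 : j + 401] += bump
        xc = ripple_delta_xcorr(rip_env, delta_env, onsets, FS,
                                [StateInterval(0.0, 120.0, "NREM")])
        assert xc.peak_lag_s == pytest.approx(0.1, abs=0.0101)


class TestNormalize:
    def test_examples(self):
        assert normalize_to_baseline(0.04, 0.02) == pytest.approx(2.0)
        assert normalize_to_baseline(0.02, 0.02) == pytest.approx(1.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ParameterError):
            normalize_to_baseline(0.04, 0.0)
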