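"""Filtering, instantaneous amplitude and power-spectral summaries.

The detectors and coupling statistics all run on zero-phase band-passed
signals and their Hilbert envelopes; zero phase matters because event
timing feeds the lag statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import DegenerateSignalError, IntegrityError, ParameterError

#: Canonical frequency bands (Hz), half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 12.0),
    "alpha": (12.0, 20.0),
    "beta": (20.0, 40.0),
    "gamma": (40.0, 100.0),
}
TOTAL_BAND = (1.0, 100.0)

FILTER_ORDER = 4  # Butterworth, applied forward-backward


def bandpass_filter(
    x: np.ndarray, fs: float, low_hz: float, high_hz: float
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    A 4th-order Butterworth is applied forward and backward
    (``filtfilt``), giving zero group delay and a squared magnitude
    response; the passband gain at band centre stays within a few
    percent of unity.
    """
    if not (0 < low_hz < high_hz < fs / 2):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    x = np.asarray(x, dtype=np.float64)
    sos = sps.butter(FILTER_ORDER, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: modulus of the analytic signal."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise IntegrityError("signal contains NaN/inf")
    return np.abs(sps.hilbert(x))


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centred moving average over ``n`` samples (edge-padded)."""
    if n <= 1:
        return np.asarray(x, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + x.size]
    return out


@dataclass
class PSD:
    """Welch power spectral density from short fixed-length bins."""

    freqs_hz: np.ndarray
    power: np.ndarray
    window_s: float
    n_segments: int

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise IntegrityError("PSD has negative power")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise IntegrityError("frequency grid must be increasing")

    def band_power(self, low_hz: float, high_hz: float) -> float:
        """Integrated power over the half-open band [low, high)."""
        sel = (self.freqs_hz >= low_hz) & (self.freqs_hz < high_hz)
        df = self.freqs_hz[1] - self.freqs_hz[0]
        return float(np.sum(self.power[sel]) * df)

    def to_csv(self, path) -> None:
        """Write the spectrum as a two-column (freq_hz, power) CSV."""
        with open(path, "w") as fh:
            fh.write("freq_hz,power\n")
            for f, p in zip(self.freqs_hz, self.power):
                fh.write(f"{f:.17g},{p:.17g}\n")


@dataclass
class BandPowerSummary:
    """Fraction of total 1-100 Hz power in each canonical band."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise IntegrityError(f"band fractions sum to {total}, not 1")


def welch_psd(x: np.ndarray, fs: float, window_s: float = 2.0) -> PSD:
    """Welch PSD over ``window_s``-long Hann-tapered bins (50% overlap).

    The grid resolution is 1/window_s; density scaling.
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ParameterError(
            f"signal of {x.size} samples shorter than one {window_s} s window"
        )
    freqs, power = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        scaling="density",
    )
    n_segments = 1 + (x.size - nperseg) // (nperseg - nperseg // 2)
    return PSD(freqs_hz=freqs, power=power, window_s=window_s, n_segments=n_segments)


def band_power_fractions(psd: PSD) -> BandPowerSummary:
    """Share of 1-100 Hz power per band.

    Each grid frequency is assigned to exactly one band by half-open
    binning, so the five fractions sum to one; the denominator is total
    power over 1-100 Hz.
    """
    if psd.freqs_hz[0] > TOTAL_BAND[0] or psd.freqs_hz[-1] < TOTAL_BAND[1]:
        raise ParameterError("PSD must cover 1-100 Hz")
    total = psd.band_power(*TOTAL_BAND)
    if total <= 0:
        raise DegenerateSignalError("total 1-100 Hz power is zero")
    fractions = {
        name: psd.band_power(lo, hi) / total for name, (lo, hi) in BANDS.items()
    }
    return BandPowerSummary(fractions=fractions)
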