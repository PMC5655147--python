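"""Core data types: recordings, hypnograms, oscillatory events.

All times are seconds from recording start (float64); intervals are
half-open ``[start, end)`` so that tiling a recording into states or
epochs never double-counts a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

# Channel roles
CA1_LFP = "CA1_LFP"
ACC_LFP = "ACC_LFP"
EMG = "EMG"
ROLES = (CA1_LFP, ACC_LFP, EMG)

# Behavioural states
WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
STATES = (WAKE, NREM, REM)

DEFAULT_FS = 2000.0  # Hz


class RippleKitError(Exception):
    """Base class for all package errors."""


class FormatError(RippleKitError):
    """A file or sidecar does not conform to the expected format."""


class IntegrityError(RippleKitError):
    """Data violates a structural invariant (lengths, NaNs, ordering)."""


class ParameterError(RippleKitError):
    """Invalid parameter value (bad band, non-positive threshold, ...)."""


class InsufficientDataError(RippleKitError):
    """Not enough data to compute the requested quantity."""


class DegenerateSignalError(RippleKitError):
    """Signal is constant/zero where variability is required."""


@dataclass
class Recording:
    """Multichannel continuous recording.

    Parameters
    ----------
    channels
        Map from channel role (``CA1_LFP``, ``ACC_LFP``, ``EMG``) to a
        1-D float array of samples. All channels must share one length.
    fs
        Sampling rate in Hz (default 2000).
    start_offset_s
        Offset of the first sample relative to an external clock; all
        analysis times are relative to the first sample regardless.
    meta
        Free-form provenance (subject id, session label, ...).
    """

    channels: dict[str, np.ndarray]
    fs: float = DEFAULT_FS
    start_offset_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            raise IntegrityError("recording has no channels")
        self.channels = {
            k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()
        }
        lengths = {k: v.shape for k, v in self.channels.items()}
        shapes = set(lengths.values())
        if len(shapes) != 1:
            raise IntegrityError(f"channel length mismatch: {lengths}")
        (shape,) = shapes
        if len(shape) != 1:
            raise IntegrityError("channels must be 1-D arrays")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise FormatError(
                f"recording lacks required channel role {role!r}; "
                f"has {sorted(self.channels)}"
            ) from None

    def require_min_duration(self, min_s: float = 60.0) -> None:
        if self.duration_s < min_s:
            raise InsufficientDataError(
                f"recording is {self.duration_s:.1f} s; need >= {min_s:.0f} s"
            )


@dataclass(frozen=True)
class StateInterval:
    start_s: float
    end_s: float
    state: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise IntegrityError(
                f"interval start {self.start_s} must precede end {self.end_s}"
            )
        if self.state not in STATES:
            raise IntegrityError(f"unknown state {self.state!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Hypnogram:
    """Full-coverage, gap-free sequence of behavioural-state intervals."""

    intervals: list[StateInterval]
    recording_duration_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = canonicalize_intervals(self.intervals)
        if not self.intervals:
            raise IntegrityError("hypnogram has no intervals")
        if abs(self.intervals[0].start_s) > 1e-9:
            raise IntegrityError("hypnogram must start at 0")
        if abs(self.intervals[-1].end_s - self.recording_duration_s) > 1e-6:
            raise IntegrityError(
                f"hypnogram ends at {self.intervals[-1].end_s}, expected "
                f"{self.recording_duration_s}"
            )
        for a, b in zip(self.intervals, self.intervals[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise IntegrityError(f"gap/overlap between {a} and {b}")

    def intervals_for(self, state: str) -> list[StateInterval]:
        return [iv for iv in self.intervals if iv.state == state]

    def total_s(self, state: str) -> float:
        return float(sum(iv.duration_s for iv in self.intervals_for(state)))

    def state_at(self, t: float) -> str:
        for iv in self.intervals:
            if iv.start_s <= t < iv.end_s:
                return iv.state
        return self.intervals[-1].state

    def sample_states(self, step_s: float = 1.0) -> np.ndarray:
        """States sampled at the midpoints of a regular grid (for agreement
        scoring between hypnograms)."""
        t = np.arange(0.0, self.recording_duration_s, step_s) + step_s / 2
        t = t[t < self.recording_duration_s]
        out = np.empty(t.shape, dtype=object)
        for iv in self.intervals:
            sel = (t >= iv.start_s) & (t < iv.end_s)
            out[sel] = iv.state
        return out


def canonicalize_intervals(intervals: Iterable[StateInterval]) -> list[StateInterval]:
    """Sort by start and merge adjacent intervals that share a state."""
    ivs = sorted(intervals, key=lambda iv: iv.start_s)
    merged: list[StateInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].state == iv.state
            and abs(merged[-1].end_s - iv.start_s) <= 1e-9
        ):
            merged[-1] = StateInterval(merged[-1].start_s, iv.end_s, iv.state)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True)
class DetectionParams:
    """Envelope-threshold detector settings.

    ``threshold_rule`` selects how the amplitude criterion "k times the
    standard deviation" is anchored: ``mean_plus_k_sd`` thresholds at
    baseline mean + k*SD of the envelope (default; the envelope of a
    band-limited signal is strictly positive so a bare k*SD can fall
    below its own mean), ``k_sd`` thresholds at k*SD.
    ``smooth_ms`` applies a centred moving average to the envelope
    before thresholding (0 disables).  ``baseline_scope`` restricts the
    mean/SD estimate to NREM samples or uses the whole recording.
    """

    band_low_hz: float
    band_high_hz: float
    threshold_sd: float
    merge_gap_ms: float
    min_dur_ms: float | None = None
    max_dur_ms: float | None = None
    baseline_scope: str = "NREM"  # or "whole_recording"
    threshold_rule: str = "mean_plus_k_sd"  # or "k_sd"
    smooth_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ParameterError(
                f"need 0 < band_low < band_high, got "
                f"({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.threshold_sd <= 0:
            raise ParameterError("threshold_sd must be positive")
        if (
            self.min_dur_ms is not None
            and self.max_dur_ms is not None
            and self.min_dur_ms > self.max_dur_ms
        ):
            raise ParameterError("min_dur_ms must not exceed max_dur_ms")
        if self.baseline_scope not in ("NREM", "whole_recording"):
            raise ParameterError(f"bad baseline_scope {self.baseline_scope!r}")
        if self.threshold_rule not in ("mean_plus_k_sd", "k_sd"):
            raise ParameterError(f"bad threshold_rule {self.threshold_rule!r}")


@dataclass(frozen=True)
class OscEvent:
    """A detected oscillatory event (ripple, spindle or delta wave).

    ``center_s`` is the midpoint of the detection window; ``peak_time_s``
    is where the envelope is maximal; ``onset_s`` aliases ``start_s``
    (delta-wave coupling is anchored at onsets).
    """

    kind: str
    start_s: float
    end_s: float
    peak_amp: float
    peak_time_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise IntegrityError("event start must precede end")
        if not (self.start_s <= self.peak_time_s < self.end_s):
            raise IntegrityError("peak_time_s must lie inside [start_s, end_s)")

    @property
    def center_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def onset_s(self) -> float:
        return self.start_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventSet:
    """Detected events of one kind plus the parameters that produced them."""

    kind: str
    events: list[OscEvent]
    params: DetectionParams | None = None
    source_role: str | None = None
    restricted_to: list[StateInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start_s)
        for a, b in zip(self.events, self.events[1:]):
            if b.start_s < a.end_s - 1e-12:
                raise IntegrityError(f"events overlap: {a} / {b}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def centers(self) -> np.ndarray:
        return np.array([e.center_s for e in self.events], dtype=np.float64)

    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=np.float64)

    def peak_amps(self) -> np.ndarray:
        return np.array([e.peak_amp for e in self.events], dtype=np.float64)
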