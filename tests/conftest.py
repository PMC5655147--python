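"""Shared fixtures: synthetic sessions are expensive, so the ones reused
across modules are generated once per test run."""

from __future__ import annotations

import numpy as np
import pytest

from ripplekit import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def default_session():
    """A 14-minute default-condition session (~10 min NREM)."""
    cfg = SynthConfig(duration_s=840.0, seed=11)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def long_session():
    """A 30-minute default-condition session for recovery/staging checks."""
    cfg = SynthConfig(duration_s=1800.0, seed=42)
    return generate_recording(cfg)


def window_match(es, truth, template_dur_s, slack_s=0.05):
    """Ground-truth matching for window detectors.

    Recall counts an implanted centre as found when it falls inside a
    detected window (+- slack); precision counts a detected window as
    correct when it overlaps an implanted template span.
    """
    wins = [(e.start_s, e.end_s) for e in es]
    truth = np.atleast_1d(truth)
    hit = sum(
        any(a - slack_s <= t <= b + slack_s for a, b in wins) for t in truth
    )
    ok = sum(
        any(a <= t + template_dur_s / 2 and b >= t - template_dur_s / 2
            for t in truth)
        for a, b in wins
    )
    recall = hit / max(len(truth), 1)
    precision = ok / max(len(wins), 1)
    return recall, precision


def staging_agreement(truth_hyp, scored_hyp, exclude_s=4.0, step_s=0.5):
    """Per-sample state agreement, excluding samples within ``exclude_s``
    of a ground-truth state transition (boundary epochs)."""
    a = truth_hyp.sample_states(step_s)
    b = scored_hyp.sample_states(step_s)
    t = np.arange(len(a)) * step_s + step_s / 2
    keep = np.ones(len(a), bool)
    for tr in [iv.start_s for iv in truth_hyp.intervals[1:]]:
        keep &= np.abs(t - tr) > exclude_s
    return float((a[keep] == b[keep]).mean())
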