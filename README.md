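# ripplekit

Analysis pipeline for dual-site rodent LFP recordings that quantifies the
temporal coupling between hippocampal sharp-wave ripples and neocortical
sleep spindles — the hippocampo-cortical dialogue thought to support
memory consolidation.

Given a three-channel recording (hippocampal CA1 LFP, anterior-cingulate
LFP, neck EMG, nominally 2 kHz), the library

* scores **WAKE / NREM / REM** from EMG immobility (envelope < 3× its mode
  for ≥ 10 s) and an adaptive theta/delta-ratio threshold (3.5× the ratio's
  mode over immobile 2 s epochs);
* detects **ripples** (CA1, 100–250 Hz, envelope > mean + 3 SD, merge
  < 50 ms), **spindles** (ACC, 12–15 Hz, mean + 2 SD, 200–2000 ms, merge
  < 100 ms) and **delta waves** (ACC, 1–4 Hz, mean + 1.5 SD, 150–500 ms)
  from zero-phase band-passed Hilbert envelopes during NREM;
* quantifies **ripple–spindle coupling** three ways: the anchor-averaged
  amplitude cross-correlogram `r(τ)` over ±4 s around spindle centres at
  0.01 s lag steps (negative peak lag ⇒ ripple leads), a binarized
  timestamp cross-correlogram at 0.1 s resolution, and the joint occurrence
  rate (ripples within ±0.25 s of a spindle centre, per spindle) — plus a
  ripple–delta correlogram anchored at delta onsets;
* tests the correlogram peak against **100 circular-time-shift surrogates**
  (≥ 4 s shifts within concatenated NREM; significant when the observed
  peak exceeds the nearest-rank 99th percentile of surrogate peaks);
* summarizes **band power** (δ 1–4, θ 4–12, α 12–20, β 20–40, γ 40–100 Hz
  as fractions of total 1–100 Hz power, Welch, 2 s Hann bins) and sleep
  architecture, and normalizes post-training sessions to a pre-training
  baseline.

Because public recordings of this kind are scarce, the package ships a
first-class **synthetic-data generator** (`ripplekit.synth`): 1/f
background, state-dependent EMG, implanted ripple/spindle/delta templates
with calibrated signal-to-noise, and a controllable probability and lag of
ripple–spindle coupling — so every stage can be validated against exact
ground truth.

## Worked example

```python
from ripplekit import (SynthConfig, generate_recording, bandpass_filter,
                       hilbert_envelope, shuffle_null_test,
                       joint_occurrence_rate, NREM)

cfg = SynthConfig(duration_s=900.0, seed=5, p_couple=0.8)   # strong coupling
rec, gt = generate_recording(cfg)
nrem = gt.hypnogram.intervals_for(NREM)

rip = hilbert_envelope(bandpass_filter(rec.channel("CA1_LFP"), rec.fs, 100, 250))
spi = hilbert_envelope(bandpass_filter(rec.channel("ACC_LFP"), rec.fs, 12, 15))
xcg, null = shuffle_null_test(rip, spi, gt.spindle_times, rec.fs,
                              nrem=nrem, seed=5)
```

Running `python examples/04_coupling_analysis.py` (exactly this analysis)
prints:

```
amplitude correlogram: peak r = 0.169 at -70 ms over 100 spindle windows
surrogate 99th percentile = 0.029 -> significant: True
timestamp correlogram: peak r = 0.435 at -100 ms
joint occurrence rate: 1.00 ripples within 0.25 s per spindle
```

The peak correlation (r = 0.169) far exceeds the chance level estimated
from time-shifted surrogates (0.029), so the session shows significant
ripple–spindle coupling; the −70 ms peak lag recovers the implanted
ripple lead exactly, and on average every spindle has a ripple within
±0.25 s of its centre.

The other scripts in `examples/` demonstrate the generator, sleep scoring,
event detection and the full pre/post pipeline (`run_session` /
`compare_sessions`, which emit schema-validated JSON reports). A thin CLI
mirrors them:

```bash
ripplekit simulate --seed 3 --duration 600 --out session.bin --truth-out truth.json
ripplekit score-sleep --recording session.bin --out hypnogram.csv
ripplekit detect --recording session.bin --hypnogram hypnogram.csv \
        --profile ripple --out ripples.csv
ripplekit report --recording session.bin --seed 3 --out-dir out/
```

Recordings are read and written as raw float32 + JSON sidecar or plain
EDF; events and hypnograms as CSV; reports as JSON.

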