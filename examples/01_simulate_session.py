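"""Generate a synthetic dual-site recording with ground truth.

Builds a 10-minute three-channel session (CA1 LFP, ACC LFP, EMG) with
wake/NREM/REM blocks and implanted ripples, spindles and delta waves,
then prints what was implanted.  The ground truth is what every other
example validates against.
"""

from ripplekit import NREM, SynthConfig, generate_recording

cfg = SynthConfig(duration_s=600.0, seed=42)
rec, gt = generate_recording(cfg)

print(f"recording: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz, "
      f"channels {sorted(rec.channels)}")
print(f"NREM time: {gt.hypnogram.total_s(NREM):.0f} s "
      f"({len(gt.hypnogram.intervals)} state intervals)")
print(f"implanted: {len(gt.ripple_times)} ripples, "
      f"{len(gt.spindle_times)} spindles, {len(gt.delta_times)} delta waves")
print(f"coupled ripples (placed {abs(cfg.couple_lag_s)*1e3:.0f} ms before "
      f"a spindle centre): {int(gt.coupled_flags.sum())}")
# Event counts are Poisson in the NREM time at the configured rates;
# roughly half the ripples ride a spindle because p_couple defaults to 0.5.
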