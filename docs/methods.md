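# Methods

This note documents the models and procedures implemented in `ripplekit`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic validations show.

## Signal path

All detectors and coupling statistics run on band-limited Hilbert
envelopes. Band-passing uses a 4th-order Butterworth applied forward and
backward (`sosfiltfilt`): zero phase is mandatory because event timing
feeds the lag statistics, and the squared magnitude response keeps the
passband within a few percent of unity. The instantaneous amplitude is
the modulus of the analytic signal, with no implicit smoothing.

Power spectra use Welch's method on 2 s Hann-tapered bins with 50%
overlap and density scaling. Band-power summaries assign each grid
frequency to exactly one of the five canonical bands by half-open binning
(δ 1–4, θ 4–12, α 12–20, β 20–40, γ 40–100 Hz), so the five fractions of
total 1–100 Hz power sum to one. Whether power above 100 Hz should enter
the denominator is a convention; it is fixed to 1–100 Hz here.

## Sleep scoring

Two adaptive, scale-invariant thresholds:

* **Immobility** — the EMG envelope is smoothed with a 0.5 s moving
  average; maximal runs below 3× the envelope's mode lasting ≥ 10 s are
  immobile. The mode of a continuous quantity is estimated as the centre
  of the fullest histogram bin under Freedman–Diaconis binning (ties
  toward the lower bin). Mode-relative thresholds make scoring invariant
  to amplifier gain.
* **NREM vs REM** — immobile time is tiled into 2 s epochs (matching the
  spectral bin length; boundary epochs truncated, fragments < 1 s
  dropped). Each epoch's theta(4–12)/delta(1–4) power ratio is compared
  with 3.5× the mode of the ratio over all immobile epochs: below ⇒ NREM,
  above ⇒ REM. The threshold is re-estimated per session ("adaptive" is
  read as per-session, not sliding-window). A 3-epoch majority vote
  suppresses isolated misclassifications, which otherwise arise from the
  high variance of 2 s band-power ratios (~5–10% of NREM epochs). Mode
  estimation needs ≥ 100 immobile epochs (~4 min of immobility); a
  session with no immobility at all is returned as pure WAKE with a
  warning.

Non-immobile time is WAKE. Everything downstream that says "during NREM"
uses the scored (or supplied) hypnogram's NREM intervals.

## Event detection

One rule template serves all three detectors: estimate the envelope's
mean and SD over NREM samples, threshold at mean + k·SD, take maximal
supra-threshold runs inside NREM, merge runs closer than the merge gap,
then discard runs outside the duration bounds. Merging **precedes**
duration filtering so a brief envelope dip cannot fragment a long event
into two rejected halves. Candidates straddling an NREM edge are
truncated at the edge before duration filtering. Peak amplitude and peak
time are read from the unsmoothed envelope.

Profiles: ripple (CA1, 100–250 Hz, k=3, merge 50 ms), spindle (ACC,
12–15 Hz, k=2, 200–2000 ms, merge 100 ms), delta (ACC, 1–4 Hz, k=1.5,
150–500 ms, merge 100 ms).

Two additions condition the envelope, both exposed in `DetectionParams`:

* **Envelope smoothing** (moving average; 10 ms ripple, 300 ms spindle,
  20 ms delta) and a **20 ms ripple minimum duration**. These are needed
  because a bare mean+k·SD threshold on a stationary envelope marks a
  fixed *fraction of time* regardless of scale (the envelope of Gaussian
  band noise is Rayleigh; mean+3SD sits at its ~99.4th percentile), which
  a detector without any run-length discrimination turns into tens of
  false events per minute. Smoothing plus the duration rules restores
  usable precision while leaving the printed criteria intact.
* The threshold anchor is mean + k·SD (`mean_plus_k_sd`); a bare k·SD
  variant exists but can fall below the envelope's own mean. Baseline
  scope is NREM by default (whole-recording by option). Which scope the
  original criteria assumed is not determinable; both are provided.

Two properties of adaptive SD thresholds are worth stating plainly.
First, on event-free background the threshold adapts downward and the
detector reports a scale-invariant background event rate — low false
positives are only achievable when genuine events inflate the baseline
SD. Second, event *counts* are not monotone in k (merging fuses runs at
low thresholds; single runs split at high ones); what is monotone is the
total supra-threshold time, and with merging disabled every higher-k
event nests inside a lower-k event.

Durations measured as threshold-crossing extents systematically
under-read the physical envelope duration whenever the envelope tapers:
the tails sit below threshold by construction. At a peak z-score of 5, a
700 ms spindle is detected with ~400–460 ms extent. Users comparing
durations across conditions should compare like with like; absolute
durations depend on the threshold geometry.

## Coupling statistics

* **Amplitude cross-correlogram.** For each anchor (spindle centre, or
  delta onset for the ripple–delta variant) the anchor-band envelope over
  [c−W, c+W] is Pearson-correlated with the ripple-band envelope over
  [c−W+τ, c+W+τ] for every lag τ on a grid (W = 4 s, step 0.01 s;
  W = 0.5 s for ripple–delta), and coefficients are averaged across
  anchors. Envelopes are first bin-averaged to the lag-grid resolution
  (the lag grid is the statement of timing precision), and the analysis
  runs on NREM segments concatenated with exact bin boundaries. Anchors
  whose lagged windows would leave their NREM segment are dropped.
  Negative peak lag ⇒ ripple leads.
* **Peak extraction.** The full ±4 s correlogram is computed and stored,
  but the peak is extracted within ±0.5 s of zero lag by default: the
  ±4 s maximum is dominated by the multiple-comparison maximum of ~800
  correlated lags, which halves the power of the significance test, and
  physiological ripple–spindle lags are far inside ±0.5 s. The reported
  peak lag is the vertex of a quadratic fitted ±0.15 s around the grid
  argmax, snapped back to the grid — a lower-variance location estimate
  for broad correlogram peaks (plain argmax jitters by ±2 lag steps
  across sessions). The peak coefficient itself is the grid maximum.
* **Timestamp cross-correlogram.** Event centres are binarized at 0.1 s
  over concatenated NREM and Pearson-correlated at integer-bin lags over
  the overlapping stretch. The coefficient normalization for binary
  trains is not standardized anywhere; plain Pearson of 0/1 series is
  used and documented.
* **Joint occurrence rate.** Ripples whose centre lies within ±0.25 s of
  at least one spindle centre (each ripple counted once), divided by the
  spindle count.
* **Baseline normalization.** Post/pre ratios of the coupling measures
  (`normalize_to_baseline`, `compare_sessions`).

### Surrogate significance test

The observed amplitude-correlogram peak is compared with 100 surrogates
in which the ripple envelope is circularly time-shifted within
concatenated NREM; the result is significant when the observed peak
strictly exceeds the nearest-rank 99th percentile of surrogate peaks.
Two facts shaped the defaults:

1. **The shift distribution must span the trace.** Every surrogate peak
   is a windowed maximum of one underlying cross-correlogram evaluated at
   the shifted position. If shifts are confined to a narrow range (the
   classical 4–10 s), the 100 surrogates sample only ~12 s of that
   correlogram — roughly 15–30 effectively independent values given its
   ~0.3 s decorrelation — and the observed peak beats their 99th rank far
   too often (measured 11% false-positive rate on independent envelopes).
   The default therefore draws shifts uniformly over the whole
   concatenated-NREM circle with a 4 s minimum (measured 3% on
   independent envelopes, 0/90 sessions at generator level);
   `shift_range_s=(4, 10)` reproduces the narrow variant.
2. **The exact level of the rank rule is 2/101**, not 1%: "strictly above
   the 99th of 100" means ranking in the top two of the pooled 101.

`shuffle_mode="global"` (default) shifts the whole trace once per
surrogate, preserving ripple autocorrelation and the covariance between
overlapping anchor windows; `"per_window"` draws an independent shift per
anchor window (a slightly anti-conservative null, provided for
comparison). Given the seed, the test is exactly reproducible.

## Synthetic-data generator

The generator emulates what the pipeline needs to be tested against, not
hippocampal biophysics:

* **States** — fixed WAKE 60 s / NREM 240 s / REM 30 s blocks by default
  (REM deliberately minor, as in short rest recordings), or a semi-Markov
  mode with exponential block durations.
* **Background** — independent 1/f^α noise per LFP channel (α = 1),
  band-limited to 1–400 Hz, scaled so the 100–250 Hz envelope SD is 1.
* **Events** — Poisson counts at per-NREM-second rates (defaults: ripples
  0.25, spindles 0.15, deltas 0.30 Hz — 15, 9 and 18 per NREM minute,
  conventional rodent values), placed uniformly over NREM with edge
  margins and minimal separations. Templates: 80 ms Tukey-windowed 150 Hz
  ripple bursts; 700 ms cos^0.5-enveloped 13 Hz spindles (strictly
  unimodal so the envelope maximum defines the centre, yet
  broad-shouldered so the suprathreshold extent clears 200 ms); 250 ms
  half-wave delta deflections.
* **Amplitude calibration** — `event_snr` is the z-score of the
  detection-band envelope at the event peak relative to the background
  envelope (peak = mean + snr·SD), the same scale the detectors threshold
  on. Spindles and deltas are phase/polarity-aligned to the ongoing band
  activity at their centre: with independent phases, additive narrowband
  synthesis suffers Rician fading that can cancel an entire event against
  the background (measured as an irreducible ~7% spindle miss rate);
  aligned templates subtract the background envelope mean from the target
  amplitude, random-phase ripples use a quadrature correction.
* **Coupling** — each ripple is, with probability `p_couple`, placed at
  `couple_lag_s` (default −70 ms, ripple leading) from an unused spindle
  centre plus truncated-Gaussian jitter (±4 SD, default SD 30 ms); at
  most one ripple per spindle, so the expected joint rate stays analytic.
* **EMG** — broadband noise whose envelope is flat during sleep and
  carries 0.3–1.5 s movement bursts every ~0.5–4 s during WAKE. Wake is
  marked by burstiness rather than a tonic level: a mode-relative
  immobility threshold cannot distinguish uniformly-high from
  uniformly-low EMG, but it reliably flags bursts that pierce 3× the
  inter-burst mode.
* Independent seeded sub-streams drive states, noise, events, tonic
  components and EMG, so changing one leaves the others bit-identical.

REM epochs add narrowband ~7 Hz activity to both LFPs and NREM adds a
tonic delta component to CA1, giving the theta/delta scorer its contrast.

### What the synthetic validations show — and don't

Detector recall/precision ≥ 0.9, staging agreement ≥ 0.9, exact −70 ms
lag recovery, surrogate-test power ≥ 95% and false-positive rate ≈ 2%
are demonstrated on this generator's output: stationary 1/f background,
template events with sharply defined extents, calibrated SNR of 5, and
clean state blocks. Real recordings add artifacts, non-stationary
baselines, spindle–slow-oscillation nesting, laminar structure and
electrode drift, none of which are modelled; passing these validations
shows the implementation is correct and internally calibrated, not that
these operating characteristics transfer to any particular animal. One
trade-off is deliberate: at 9 spindles/min and SNR 5, the 1/f background
itself contains sigma-band stretches satisfying the printed spindle
criteria, so "precision against implanted events" is bounded by the
implanted share of all criterion-satisfying events (~0.96 here). That is
a property of any threshold detector on continuous background, not a
defect of the detector.

## Problem sizes in tests

The validation suite runs detection/staging checks on one seeded
30-minute session, surrogate-test calibration and power on 30 sessions of
14 minutes each (~10 min NREM), coupling monotonicity on 5 coupling
levels × 10 seeds of 10-minute sessions, and brute-force oracle
equivalence on 30 s fixtures — sizes chosen so the full suite completes
in a few minutes while keeping every Monte-Carlo bound at its stated
confidence. The acceptance script uses the same session sizes with 20
sessions per significance batch.

## Numerical details

* Times are float64 seconds from recording start; intervals are half-open
  `[start, end)`.
* Event `center_s` is the window midpoint (duration-symmetric and
  deterministic); the envelope-peak time is kept separately.
* Correlogram tie-breaks: equal maxima resolve toward the smallest |lag|,
  then the negative lag.
* Degenerate inputs raise typed errors: constant envelopes
  (`DegenerateSignalError`), empty NREM or too-short traces
  (`InsufficientDataError`, `ParameterError`); zero-variance anchor
  windows are skipped and counted.
* Pearson coefficients inside the correlogram engine are computed from
  precomputed dot tables and circular sliding sums; they match a naive
  per-lag `corrcoef` oracle to < 1e-10.
* EDF output is plain 16-bit EDF (one record per second); samples
  round-trip within (physical range)/2^16. The raw float32 + JSON sidecar
  format is lossless.
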