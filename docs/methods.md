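# Methods

This note documents the models and procedures implemented in `spindlekit`,
the choices made where the underlying analysis left details open, and what
the synthetic-data tests do and do not establish about real recordings.

## Sleep scoring

Behavioral state is scored on a uniform 1-s grid from three quiescence
features:

* **Jerk** — per bin, the sum over samples and accelerometer axes of
  `|a[i] − a[i−1]| · rate` (m/s³), the first sample's derivative taken as 0.
  Threshold: 1 m/s³.
* **EMG muscle tone** — the neck EMG band-passed 70–250 Hz (zero phase),
  rectified, smoothed with a 200-ms centered moving average, then averaged
  per bin.  The session-specific threshold, scored visually in the original
  workflow, is automated here as a quantile (default 0.6) of the whole
  session's tone distribution, logged, with a manual override
  (`sleep.emg_threshold`).  Estimating it from the full session rather than
  per analysis window matches the per-session semantics and keeps the
  estimate stable.
* **Speed** — per-frame displacement of the position track over the frame
  interval, median-filtered over 0.5 s, averaged per bin; NaN frames are
  linearly interpolated for gaps up to 1 s.  Threshold: 2 cm/s.

A bin is a sleep candidate when at least two of the three conditions hold;
with a missing stream, both remaining conditions are required (logged).
Maximal candidate runs **strictly longer than 40 s** become sleep bouts.
The time support of the conditions is not prescribed by the underlying
method; evaluating them on 1-s bins and gating run lengths strictly is one
deterministic reading, and brief condition dropouts inside a run are not
bridged.  Scoring is restricted to an analysis window per rest epoch
(default: 110 min beginning 5 min after epoch start; windows that overrun
the epoch are truncated with a warning).

## Spindle detection

The right-anterior ECoG channel is re-referenced by subtracting the mean of
the left-hemisphere channels, band-pass filtered to the sigma band
(9–16 Hz) with an order-12 Butterworth filter (second-order sections,
forward–backward so event timestamps are unbiased), and converted to an
amplitude envelope smoothed with a 20-ms unit-area Hanning kernel.

**Envelope definition.**  The envelope is `(2/π)·|analytic signal|` of the
filtered trace.  This equals the cycle-averaged rectified amplitude — a
pure in-band tone of amplitude `A` yields a plateau of `2A/π` — but is free
of the rectification ripple at twice the oscillation frequency.  That
ripple matters: a 20-ms Hanning kernel passes ≈86% of a 24-Hz component,
so a directly rectified-and-smoothed trace dips almost to zero twice per
sigma cycle and no excursion could ever remain above an edge threshold for
500 ms.  The analytic-signal form is the ripple-free limit of the same
quantity and is what makes a dual-threshold duration criterion operable.

Envelope samples within scored sleep are Winsorized at the 10th/90th
percentiles; the center and SD of the clipped sample define the z-scale
(the robust center is needed because a scale without a location cannot
produce z-scores).  Candidate events are maximal excursions with
`z > 1.7` (edge) containing at least one sample with `z > 2.5` (peak),
both strict; boundaries sit at the edge crossings.  Candidates lasting
0.5–2 s inclusive and falling entirely within a sleep bout become events.
Events separated by short gaps are not merged.

Per event:

* **Amplitude** — percent increase of the squared envelope during the event
  over baseline sleep (mean squared envelope over sleep samples outside all
  events).
* **Peak frequency** — the maximum of the order-40 Burg autoregressive
  spectrum of the raw re-referenced event segment, evaluated on a 0.05-Hz
  grid restricted to the sigma band (`spindle.burg_input: filtered` uses
  the sigma-filtered segment instead).  Segments shorter than order+1
  samples fall back to order ⌊N/3⌋ with a warning.  The Burg recursion is
  implemented here and cross-checked against an independent library fit in
  the test suite.

## Session metrics and QC

Fragmentation: percent time asleep, bouts per minute of analysis window,
mean bout duration, bout count.  Spindle metrics: events per minute of
sleep (missing, not zero, when there is no sleep), mean duration,
amplitude, and peak frequency.  When Rest1 and Rest2 are combined, seconds
and counts are pooled across both windows before forming ratios, not
averaged per epoch.  Subjects are excluded when they have more than two
zero-spindle days in either week, were recorded from a single hemisphere,
or did not complete the experiment; every exclusion is reported with its
reason.

## Group statistics

Two-sample comparisons are gated by Anderson–Darling normality on both
samples at α = 0.05: both pass → Welch t; otherwise Wilcoxon rank-sum.
Cohen's d always uses the classical pooled SD.  Families of p-values are
Holm-adjusted (note Holm adjustment is not idempotent; re-applying it to
adjusted values inflates them further).  Within-subject treatment
contrasts are one-way ANOVAs on per-subject week-2 − week-1 differences
across the four genotype × drug groups.  Motor learning is the OLS slope
of latency-to-fall on trial number; a "learning day" requires a positive
slope with p < 0.05.  The spindle–behavior link is the Pearson correlation
between the Rest1→Rest2 change in spindle density and mean latency to
fall.

## Synthetic sessions

The generator emulates the statistical structure the pipeline assumes and
provides full ground truth (true state intervals and true burst table).

* **State model** — alternating wake/sleep bouts with exponential
  durations (floor 5 s) inside each rest epoch; Task epochs are awake.
  Presets: WT-like mean sleep/wake bouts 180/90 s; G2019S-like 80/45 s —
  shorter, more frequent bouts at a similar total sleep fraction (64% vs
  67%).  Preset magnitudes were set so that the pipeline-level group
  contrasts are large (d ≈ 1), i.e. reliably recoverable at cohort sizes of
  20 per group; they are simulator presets, not estimates of real effect
  sizes.
* **ECoG** — 1/f background (spectral shaping of white noise, exponent 1)
  common to all six electrodes, plus independent per-channel 1/f noise.
  Common-average referencing cancels the shared term exactly, as in the
  real recording geometry.
* **Spindle bursts** — Tukey-windowed sigma tones (0.1-s tapers) with
  uniform frequency and duration draws, placed without overlap inside
  sleep bouts (WT-like: 4/min, 0.45–1.2 s, deliberately spanning the
  duration gate; G2019S-like: 6/min, 0.6–1.6 s).  Each burst is
  **crossfaded into** the right-anterior channel's own noise rather than
  added on top of it: a spindle is modelled as an oscillation that
  dominates the local field.  An additively injected burst rides on the
  channel's independent sigma-band noise, whose envelope fluctuations cut
  the supra-threshold excursion into sub-500-ms fragments near threshold —
  an interference pattern real spindles do not exhibit.  Reference-side
  interference (from the left-hemisphere average) remains.
* **Amplitude calibration** — burst amplitudes are set so the envelope
  peak, measured by the pipeline's own envelope and Winsorized statistics
  on the emitted session, hits a target height in detector SD units
  (default 5).  An analytic first guess (tone amplitude → `2A/π` envelope,
  corrected for the squared filter gain at the burst frequency) is refined
  by one measure-and-rescale pass through the full chain; achieved peaks
  land within a few percent of target.
* **EMG / accelerometer / position** — state-switched broadband noise
  scale (25 vs 5), sparse acceleration steps sized to per-bin jerk targets
  (20 vs 0.1 m/s³), and an Ornstein–Uhlenbeck walk (mean wake speed
  8 cm/s, reflected in an 18-cm box) that freezes during sleep except for
  tracking jitter.

**What passing tests show.**  Recovery results on these sessions validate
the implementation — thresholds, gating, calibration, statistics — under
features that are genuinely well separated between states and bursts that
are narrowband tones.  Real recordings have artifacts, non-stationary
backgrounds, REM (not modelled; scoring is sleep-vs-wake only), and
spindles with chirps and asymmetric envelopes; detector performance there
is not established by these tests.

## Problem sizes and numerical choices

* Desk-scale sessions (the test default) use 10/5/10-min epochs, ECoG at
  200 Hz, EMG at 800 Hz, accelerometer at 100 Hz, position at 30 fps, and
  a scaled analysis window (9 min starting 0.5 min into each rest epoch);
  full-scale sessions mirror the 2 h/1 h/2 h layout with 1-kHz ECoG/EMG.
  The acquisition rate (12.5 kHz) is far above analysis needs; 1 kHz keeps
  every defined filter valid.
* Detector recovery is evaluated over 20 seeds (density 2/min, durations
  0.7–1.5 s — typical mouse spindle durations, clear of the duration
  gate); sleep-scoring accuracy over 10 seeds; the end-to-end phenotype
  contrast over 12 replicate cohorts of 20+20 sessions; the gated
  comparison chain over 2000 Gaussian null replicates.
* Threshold-boundary sweeps embed a shape-controlled probe burst
  (cross-faded, 1-s, flat-topped) and bisect its amplitude until the
  measured peak z sits just below the requested value (within 0.004 SD),
  so the strict `> 2.5` rule resolves deterministically at the 2.50 step.
* Filters are second-order-section Butterworth run forward–backward;
  "order 12" refers to the final band-pass order.  Envelope smoothing uses
  a unit-area kernel; moving averages use nearest-edge padding.  Winsorized
  SD uses ddof = 1.  Duration-gate comparisons are exact (inclusive ≥/≤);
  candidate boundaries are sample-aligned at the analysis rate.
* Degenerate inputs fail loudly: constant tone (threshold estimation),
  zero Winsorized SD, zero pooled variance, groups smaller than 2 (ANOVA)
  or 4 (normality gate).

## Known limitations

* No REM/NREM substaging and no spectral sleep scoring.
* The EMG threshold quantile (0.6) assumes the session contains both
  states in non-extreme proportions; heavily sleep-dominated sessions may
  need the manual override.
* Spindle detection requires the right-anterior channel and at least one
  left-hemisphere channel; there is no alternative montage.
* Burg peak frequencies at the band edges (9, 16 Hz) are attenuated by the
  band-pass when `burg_input: filtered` is used; the default operates on
  the raw segment and does not have this bias.
* The pipeline's bout statistics are conditioned on the >40-s persistence
  rule: true bouts shorter than 40 s are deliberately invisible, which
  attenuates fragmentation contrasts relative to the generating state
  process.
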