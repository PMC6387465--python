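# Methods

This note documents the models, conventions, and numerical choices behind
`neuroproxy`, and what the synthetic cohorts do and do not establish.

## Signal model of the synthetic cohort

Each simulated subject has an individual alpha frequency (IAF) drawn
uniformly from 8–12 Hz and quantized to the 0.25 Hz analysis grid — the
quantization makes *exact* IAF agreement between channels sharing a source
achievable by construction, which is the phenomenon the difference map is
meant to detect.  A session is 8 condition blocks (4 eyes-closed OC, 4
eyes-open OA) in seeded random order, default 120 s each at 250 Hz.

Four band-limited sources are simulated per block, each an
amplitude-modulated sinusoid: carrier at a fixed frequency, multiplied by
a slow random envelope (white noise low-passed at 0.2 Hz, depth 0.5,
clipped positive).  The modulation gives spectral peaks a realistic
nonzero width; a pure tone would make the gravity estimator trivially
exact and hide interpolation bugs.  Source centre frequencies are
anchored to the subject's IAF-defined bands: alpha at IAF, theta at
IAF − 4, delta mid-way through the in-range Delta band, beta at
min(IAF + 6, 18) Hz so it survives the 20 Hz low-pass.

Condition effects are carried by the per-condition RMS amplitudes
(μV, defaults in parentheses): alpha OC ≫ OA (8.0 / 1.0) — the classical
eyes-closed alpha synchronization — while theta (1.0 / 3.2), delta
(1.2 / 3.6) and beta (0.8 / 2.6) are stronger eyes-open, so *every*
analysis band carries an eye-state signature, as required for band-wise
classification to beat chance everywhere.  **These amplitudes are
generator parameters, not empirical facts**: the study this package
emulates reports no effect sizes, so the defaults were calibrated once so
that the acceptance checks pass with margin, and they should be treated as
defining the simulated regime.

Scalp channels mix the sources with fixed topographic weights (alpha
posterior-dominant, theta/delta fronto-central, beta central) over
independent 1/f background noise (exponent 1, RMS 3 μV; noEEG background
2 μV).  Each noEEG channel receives the *posterior* source mixture scaled
by a volume-conduction coefficient in [0, 1] (defaults 0.4–0.7 for the 8
designated feature channels, 0 elsewhere) plus its own noise —
instantaneous scalar mixing, no propagation delay, consistent with
passive tissue conduction at these frequencies.

Artifact transients are injected at Poisson rates with ground-truth logs:
blinks (0.25/min, 250 μV Gaussian deflections, σ = 80 ms, frontal
channels), EMG bursts (0.2/min, 300 μV broadband, 0.3 s, one random
channel), and ECG-like biphasic spikes on the neck ring (60/min, 25 μV —
deliberately *sub*-threshold, as realistic cardiac contamination).  Blink
and EMG amplitudes are pre-filter values chosen so the events remain above
the ±100 μV rejection rule after the 1–20 Hz band-pass (which attenuates
a 150 μV blink to ~96 μV); with the default rates, epoch retention sits
at 96–98%, matching the regime the protocol reports.

**What the generator does not emulate:** realistic head geometry or
electrode montage physics, line noise, non-stationary drift of the IAF,
condition-dependent 1/f slope changes, EMG spectral colouring, or any
inter-channel noise correlation.  Passing tests therefore demonstrate the
*pipeline's* correctness and sensitivity under a known ground truth — not
that real neck recordings contain cerebral alpha.

## Preprocessing conventions

- Butterworth band-pass realised as an 8th-order high-pass (1 Hz) cascaded
  with an 8th-order low-pass (20 Hz), applied forward–backward
  (`sosfiltfilt`), i.e. zero phase with squared magnitude response.  The
  zero-phase choice preserves the timing of alpha bursts relative to block
  labels; single-pass application is available via `FilterSpec`.
- Epoch starts within a block are 0, s, 2s, … with count
  ⌊(block − epoch)/step⌋ — deliberately *without* the fencepost +1, the
  only convention reproducing 1160 epochs per 120-s block.  Computed in
  integer samples to avoid floating-point fenceposts.
- Block intervals are half-open [onset, onset + duration), sample indices
  0-based, time in seconds from recording start.
- Both artifact rules use strict inequalities (a sample at exactly
  100 μV, or a slope of exactly 10 μV/s, does not flag), and flag the
  epoch for **all** channels if **any** channel violates a rule.  The
  trend slope is the least-squares line over the full 4-s window, absolute
  value.  Flagging operators are idempotent and order-independent; they
  apply to the filtered signal (whether the original protocol screened
  before or after its component-based cleaning is not recoverable).

## Spectral conventions

- One Hann-windowed periodogram per retained 4-s epoch (1000 samples →
  0.25 Hz grid), one-sided, window-power corrected so white noise of
  variance σ² integrates back to σ² (verified to 5%).
- Averaging is two-level: epoch → repetition mean → condition mean as the
  *unweighted* mean of the four repetition means.  With unequal retained
  epoch counts this differs from pooling all epochs; the unweighted
  convention is tested explicitly.
- dB conversion uses 20·log10(PSD) — kept exactly as the source analysis
  prints it, although 10·log10 is conventional for power — and is
  display-only: IAF, correlations and classifier features all consume
  linear PSD.

## IAF and bands

- Peak estimator: argmax bin in [7.5, 12.5] Hz; local maxima are counted
  as strictly-greater-than-both-neighbours (optional 3-bin smoothing, off
  by default); a window with no interior local maximum yields a flagged
  degenerate estimate.  Ties resolve to the lowest frequency.
- Combined policy: peak when the window has exactly one interior local
  maximum, gravity otherwise (multiple alpha peaks or none).
- Band bins are half-open [f1, f2) on the 0.25 Hz grid, intersected with
  the half-open 1–20 Hz analysis range.  This gives 16 bins for the 4-Hz
  Theta and Alpha bands — hence 9 × 16 = 144 EEG and 8 × 16 = 128 noEEG
  features — the only convention consistent with those published feature
  counts.  The published Delta (8 bins) and Beta (40 bins) per-channel
  counts cannot be derived from the band formulas under a 1–20 Hz
  band-pass for plausible IAF values; the package exposes the actual bin
  lists and asserts counts only for Theta/Alpha, leaving the discrepancy
  documented rather than resolved.
- The subject-level IAF (band anchor) is estimated from the mean-OC
  spectrum at Oz; the per-channel IAF table for the difference map uses
  the peak method so grid-exact equality is observable.

## Correlation and common pattern

The alpha-range bins of the mean-OC spectra are the paired observations:
one Pearson R per EEG-noEEG couple per subject (21 bins, p from the exact
t transform with n − 2 df).  The window is the fixed 7.5–12.5 Hz range —
correlation precedes IAF estimation in the workflow.  The common pattern
keeps couples positive and significant in every subject, with **no**
multiple-testing correction across the 27 × 16 grid (fidelity to the
emulated analysis; a Benjamini–Hochberg switch exists).  Mean IAF
differences are categorised with a ±0.25 Hz tolerance; |d| > 0.25 Hz is
out of range.

## SWLDA

Forward entry and backward elimination on OLS coefficient p-values
(two-sided t, equivalent to the partial F-test for a single term), labels
coded OC = 1 / OA = 0 so the 0.5 score threshold is natural.  One feature
enters per outer iteration (smallest p < 0.05), then backward removal
runs to exhaustion (largest p > 0.1); the procedure stops when neither
rule fires, with a state-set cycle guard and an iteration cap as
safeguards.  The candidate scan projects all excluded columns onto the
orthogonal complement of the current design in one pass — algebraically
identical to refitting OLS per candidate (verified against a brute-force
statsmodels oracle on 100 random instances) but linear-time per step.
Columns are standardized internally; weights are reported on the original
scale; rank-deficient candidates are skipped with a trace entry; ties
break to the lowest column index, making fits deterministic.  Scoring
matches features by *name*, so column order at test time is free.

`max_features` is unlimited in the library (bounded by rows − 2).  The
*pipeline* default caps it at 10: epochs overlapped at sub-second steps
are strongly autocorrelated, so row count vastly overstates the effective
sample size, OLS entry p-values become anti-conservative, and unlimited
stepwise selection admits ~45 of 144 alpha features and visibly overfits
across repetitions.  The cap was calibrated on the synthetic cohorts as
part of fixing the simulated regime.

## Evaluation

Repetition-paired cross-validation: each (OC_i, OA_i) couple calibrates
once; the three remaining couples are scored *separately* and the 12
(AUC, ACC) values averaged — metric averaging, not pooled ROC (a pooled
mode exists behind a flag).  AUC is the rank/Mann–Whitney statistic with
midrank ties, equal to brute-force pair counting (tested).  ACC uses the
fixed 0.5 threshold with no per-fold tuning.  Paired t-tests compare
per-subject band-averaged metrics between feature sets (within-subject
averaging first, then across subjects); all-zero difference vectors
return t = 0, p = 1, while zero-variance nonzero differences are an
error.  On zero-effect cohorts the test's type-I rate is verified ≈ 5%.

## Problem sizes

The default generator block length is 120 s with a 0.1-s epoch step (the
emulated protocol).  The committed analysis drivers, the acceptance
script, and the heavier tests run a desk-scale variant chosen as the
package's reference configuration: 5–6 subjects, 60-s blocks, 0.5-s step
(112 epochs per block, 896 per subject), full 43-channel montage.  The
classification margins at this scale (all band AUC ≥ 0.78, Alpha ACC
≥ 0.83 across master seeds) leave comfortable headroom over the 0.7/0.8
reference levels.  Property tests use a 6-channel mini montage and
shorter blocks.

## Known limitations

- EDF output is plain EDF (16-bit, 1-s records) with a JSON sidecar for
  block annotations and ground truth; EDF+ embedded annotations are read
  (via `mne`) but not written.  BrainVision is read-only.
- Pipeline resume is whole-run granular (manifest hash), not per-stage.
- The paired EEG-vs-noEEG t-tests on the synthetic cohort occasionally
  reach p < 0.05 in a band: the generator's EEG and noEEG feature sets
  have different SNR by construction, so exact EEG/noEEG parity is not a
  property the simulation enforces.
- Re-referencing is not applied; signals are assumed referenced as
  recorded.
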