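# Methods

This note documents the models and procedures implemented in
`neurophyskit`, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
conventions that matter for reproducing results.

## Inter-muscular coherence

Magnitude-squared coherence between two EMG channels is estimated by
averaging untapered periodograms over `L = floor(N / segment_len)`
non-overlapping segments; tail samples are discarded, no detrending is
applied.  Segment length defaults to 1 s, which gives a 1 Hz frequency
grid and makes `L` equal the usable recording length in seconds.  The
1 Hz grid is what makes the integer band sums and the printed band-width
divisors (15, 18, 46 for 15–30, 30–48, 52–98 Hz) commensurate; other
segment lengths are accepted but band statistics then require the grid to
land on the band edges.

A bin is significant when its coherence strictly exceeds
`CI = 1 − 0.05^(1/(L−1))`.  For independent Gaussian inputs the
periodogram-averaged estimator satisfies `P(Ĉ > c) = (1 − c)^(L−1)`, so
the exceedance probability at `CI` is exactly 0.05 — the null-coverage
test in the suite verifies this end to end through the synthetic
generator.  The estimator's small-sample bias for independent signals is
`E[Ĉ] ≈ 1/L`, which the suite also checks.

Band edges are inclusive on the grid.  The beta band therefore contains
16 bins while the printed divisor is 15, so a band saturated at C = 1
yields an area of 16/15: the two conventions (inclusive edges, printed
width divisors) are both part of the published statistic and are kept as
the default; a `bin_count` divisor convention is available and every
result records which was used.  The alpha band is excluded by design:
the emulated acquisition hardware high-passes EMG at 20 Hz, so alpha-band
coherence would not be interpretable.

## EMG preprocessing

* **DFT notch (48–52 Hz).**  The full-record DFT is taken, bins with
  |f| in [48, 52] Hz (edges inclusive) are zeroed, and the record is
  inverse-transformed.  Zeroing is idempotent and leaves out-of-band
  bins bit-identical.  Because the mains component is coherent between
  channels, notching it before coherence analysis matters.
* **Contraction epoching.**  The published workflow epochs contraction
  periods visually.  The automated stand-in thresholds a moving-RMS
  envelope (250 ms window) at 3× the resting RMS with a 1 s minimum
  duration, and manually supplied intervals are accepted everywhere, so
  the manual workflow remains possible.  A rest reference is required
  explicitly (a rest recording or a rest prefix duration); the package
  does not guess which part of a recording is rest.
* **MVErms.**  The maximum sliding-window rectified RMS (250 ms window,
  50 ms step — standard EMG envelope practice; recorded in the result)
  minus the rectified RMS of the first 1 s of an explicit rest
  recording.  A negative difference clamps to 0 and is flagged.
  Rectification is absorbed by squaring: rms(|x|) = rms(x).

## Evoked potentials

Epochs span 100 ms pre- to 100 ms post-stimulus, half-open in samples;
an event at sample 500 at 1000 Hz yields samples 400–599.  Trial
rejection quantifies the usual "compare pre- and post-stimulus
statistics" review as: reject when pre-stimulus variance exceeds 5× the
median pre-stimulus variance across epochs (configurable; ∞ disables).

The MEP search window is 10–100 ms post-stimulus; the first 10 ms are
excluded to avoid the stimulation artifact.  A response is peak-to-peak
≥ 50 μV, inclusive (the threshold rules are worded both as "at least"
and "greater than" in common usage; inclusive is used consistently and
is configurable).  Cortical RMT takes "in 50% of trial stimuli" as "at
least half"; spinal RMT takes "5 out of 10 consecutive trials" as any
sliding window of 10 consecutive trials containing ≥ 5 responses.
Amplitude at 110% RMT snaps to the nearest tested grid intensity, ties
upward; the multiple is configurable for protocols that acquire
dedicated supra-threshold blocks.  Normalization divides by a positive
reference — MVE RMS for cortical MEPs, the supra-maximal peripheral
response for spinal MEPs — and refuses a non-positive one.  The
peripheral plateau is the first intensity step whose relative amplitude
increase falls below 5%; the reference is the mean amplitude from that
step onward, and a series that never plateaus is flagged.

**SSEP presence.**  The averaged trace is compared against its own
pre-stimulus baseline: presence requires the deflection at the expected
component latency (default window 20 ± 1 ms) to exceed 3 baseline SDs.
The window is deliberately narrow: the criterion is evaluated where a
reader would mark the known component, and widening the search window
inflates the null exceedance of a max-deflection statistic through
multiple comparisons (measured on the synthetic null: ≈ 3% false
positives at ±1 ms versus ≈ 8% at ±5 ms and > 30% for a 10–100 ms
search).

## Adherence model

For each therapy phase, attendance `a = x/s`, timing `b = 1/(w+1)` with
`w` the assessment delay in weeks (fractional delays pass through the
same formula), and phase adherence `c = a/2 + b/2` with equal weighting.
Baseline has no preceding therapy block and is defined as `c := 1`.  The
source model defines follow-up as `c := 1/b`, which is ≥ 1 whenever the
assessment is late and so contradicts the stated range `c ∈ [0, 1]`; the
default here is `c := b` at follow-up (timing is the only thing left to
adhere to), preserving the range invariant.  The literal reading is kept
behind `followup_mode="literal"` (clipped to 1, with a warning).  Overall
adherence `C` is the unweighted mean of `c` over all phases including
both sentinels.  The relative series uses `b̄_k = 1/(w_k − w_j + 1)`
between successive phases and errors on `w_k < w_j` rather than guessing
an interpretation for assessments that catch up with the schedule.
Outcome groups (two neurophysiology visit groups and the
functional/clinical group) are computed independently.

## Reporting

Overview flags depend only on the ordering of values: presence at
baseline (value strictly above a per-measure threshold, default 0),
improvement (16-week value strictly above the pre-intervention value),
and sustained improvement (improved, and the follow-up value still above
pre-intervention).  Missing timepoints yield not-evaluable flags — blank
cells in output, never zeros.  GRASSP change flags use
minimal-detectable-difference thresholds of 4 (sensation), 5 (strength),
4 (prehension ability) and 3 (prehension performance) points, and a
minimal-clinically-important-difference threshold of 2 points — the
lower end of the reported 2–3 point range, chosen because a 2-point
strength change is credited as clinically meaningful under that reading.
Rank correlation is Spearman's ρ with tie-corrected ranks
(scipy), cross-checked in the suite against a brute-force rank oracle.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure each estimator
assumes, not the biophysics that produces it:

* **Paired EMG** mixes a shared band-limited Gaussian drive with
  independent band-limited noises, `sqrt(κ)·c + sqrt(1−κ)·n_i`, giving a
  closed-form in-band coherence target of κ² — verifiability over
  physiological fidelity.  The 20–460 Hz 4th-order Butterworth shaping
  (zero-phase) is applied identically to both channels after mixing, so
  it cannot alter coherence; the optional 50 Hz line term is common to
  both channels and genuinely coherent, which is why the notch matters.
  There is no motor-unit pool, no volume conduction, and outside the
  drive band the only energy is segment-boundary spectral leakage — so
  out-of-band coherence values are not meaningful for narrow-band specs.
* **MVE trials** are hard-limited (constant-modulus) band-limited noise:
  |x| equals the target envelope at every sample, so the rectified-RMS
  envelope is exact rather than merely an expectation.  With Gaussian
  noise the max-over-windows readout sits on the upper tail of the
  windowed-RMS sampling distribution (~7–10% above the generating RMS at
  these durations), which would misrepresent a generator whose declared
  envelope is the quantity the estimator recovers.  Real EMG amplitude
  statistics are not constant-modulus; tests passing here say the
  estimator arithmetic is right, not that real MVE readouts are
  unbiased.
* **MEP sessions** draw each trial as a Bernoulli response with
  probability `sigmoid(slope·(I − θ))`; a response contributes the full
  MEP amplitude (default 500 μV) plus Gaussian noise (floored at 0).
  The empirical response rate at each intensity therefore converges
  exactly to the sigmoid, and the ground-truth RMT is computed from the
  exact response probability `P(p2p ≥ 50 μV)`.  A graded
  amplitude-recruitment model was considered and rejected: it cannot
  simultaneously give a sigmoid response probability and an
  amplitude-independent threshold semantics.  Defaults (5 trials per
  intensity, the 30–50/55–100 cortical grid) follow the emulated
  acquisition protocol.
* **SSEP sessions** are 0.5–500 Hz band-limited noise epochs (the
  amplifier passband of the emulated EEG) with an identical half-sine
  deflection (10 ms wide, peak at 20 ms) added to every epoch.  Trial-to-
  trial latency or amplitude jitter is not modelled.
* **Attendance logs** copy configured rates and delays through the
  trial's phase schedule (16 + 15/10/15 scheduled sessions between the
  six assessment timepoints).

All generators are deterministic given their seed.

## Problem sizes and numerical conventions

The statistical suites run at the sizes the estimators are specified
for: coherence checks use 120 s records at 1000 Hz with 1 s segments
(L = 120, 100 independent replicates for coverage), RMT recovery uses
200 sessions with thresholds drawn uniformly over (56, 94)% at slope 5
and 10 trials per intensity (steep, low-noise sessions whose ground
truth is nearly deterministic), and SSEP error rates use 100 null and 25
signal sessions of 300 epochs.  The full suite completes in well under a
minute on one core.

Float comparisons in oracle-equivalence tests use 1e-10 absolute
tolerance; the DFT notch idempotence likewise.  Event indices are
0-based; all epoch and segment windows are half-open in samples.
Averages of n identical epochs are exact to 1e-12 (floating-point
summation only).  Degenerate inputs raise `ValidationError` rather than
returning silent defaults: empty segment lists, all-rejected epoch sets,
non-positive normalization references, fewer than two coherence
segments, and attendance exceeding the schedule are all errors.

## Known limitations

* Coherence is undirected and time-averaged; no EEG–EMG (corticomuscular)
  coherence, partial/directed measures, or time-resolved variants.
* The contraction detector is an envelope-threshold stand-in for expert
  visual epoching; on real data its boundaries inherit the smoothing
  window's resolution (±250 ms).
* MEP latency, cortical mapping and stimulation-hardware control are out
  of scope; the trial-rejection rule is a single variance ratio, not a
  full artifact taxonomy.
* The adherence model weights attendance and timing equally and all
  phases equally; alternative weightings are a constant away but not
  exposed as a modelling choice.
* Synthetic ground truths make the recovery tests sharp but say nothing
  about sensor placement, cross-talk, or non-stationarity in real
  recordings.
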