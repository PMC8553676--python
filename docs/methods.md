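# Methods

## Signal model and spectral analysis

A recording is a single-channel EEG-like series acquired while a
checkerboard of one check size reverses at rate *f*₁ (default
8 reversals/s). The steady-state response of interest is the sinusoid at
*f*₁. Recordings are cut into segments of length *T* (default 1 s); the
whole-cycles constraint *f*₁·*T* ∈ ℕ guarantees that *f*₁ falls exactly
on a DFT bin of the averaged segment, so the harmonic readout needs no
windowing or interpolation. Segments whose peak absolute amplitude
exceeds 120 µV are rejected (the blink criterion); peak-to-baseline is
the operative definition, with peak-to-peak available as a configuration
alternative. Accepted segments are averaged coherently in the time domain
before the DFT — the default route; a per-segment-spectrum route exists
behind a flag but is not used by the pipeline.

The noise estimate is the RMS amplitude of the K = 2 bins on each side of
the harmonic bin (4 bins total, harmonic excluded). Two derived
quantities follow:

- **Corrected amplitude** √max(A² − N², 0): power-domain subtraction
  floored at zero. The signed subtraction is unbiased — on noise-only
  data E[A² − N²] = 0, verified by simulation — but the floor necessarily
  retains a positive residual: for exponentially distributed bin power the
  floored estimate keeps ≈ e⁻¹ of the raw noise power no matter how many
  neighbour bins are used. Voltage-domain subtraction is a plausible
  alternative convention; the power-domain form was chosen for its
  unbiasedness-in-power and is a configuration point.
- **Significance** from the ratio of harmonic power to mean neighbour
  power. For white Gaussian noise each complex bin has two independent
  Gaussian quadratures, so the ratio is exactly F(2, 2·2K) under the
  null and the test is exactly calibrated — the acceptance benchmark
  measures the empirical rate at 0.049–0.050 over 10⁴ noise recordings.
  Degenerate zero-noise-floor cases use the conventions p = 1 for zero
  signal and p = 0 for positive signal.

Spatial frequency uses the edge convention, SF = 60/(2·check size in
arcmin); the diagonal convention (×√2) is available, and the acuity
conversion factor absorbs whichever is chosen.

## Heuristic acuity extrapolation

Point selection on the tuning curve (corrected amplitude vs log₁₀ SF):

1. Spurious significances may first be overridden — manually by index, or
   by the automatic rule that discards any significant point separated
   from the low-SF contiguous significant block by two or more
   consecutive non-significant points. The automatic rule emulates the
   manual correction for multiple-testing artifacts that arise when many
   check sizes are unresolvable.
2. The *peak* is the significant point with the largest corrected
   amplitude; ties break toward lower SF, keeping more of the flank.
3. The fit set runs from the peak through the highest-SF significant
   point (intervening non-significant points included at their measured
   amplitudes). Including the first non-significant point beyond the
   flank is supported (`include_trailing_nonsig=True`) but off by
   default: a zero-amplitude point beyond the true limit pulls the
   least-squares intercept upward by ~0.1 log unit on otherwise exact
   curves, and the published descriptions of this algorithm family do not
   pin the choice down.
4. A straight line is fitted by least squares and the abscissa intercept
   is the SF limit; estimates with fewer than two fit points, no
   significant point, or a non-negative slope are explicit `no_estimate`
   outcomes (not exceptions, not NaNs).

**Numerical choice — exact scale invariance.** Before the fit, amplitudes
are divided by their maximum and the ratios reduced to single precision.
The fit therefore depends only on amplitude ratios at a precision where a
common scale factor cancels exactly, making the documented invariance —
multiplying every amplitude by k > 0 leaves the SF limit bit-identical —
hold by construction rather than to within rounding error. The cost is an
SF-limit resolution of ~10⁻⁷ log units, far below any quantity of
interest.

Decimal acuity = conversion factor × SF limit, clipped to ≤ 1.6 (on the
decimal scale, before the logMAR transform), then logMAR =
−log₁₀(decimal). The default factor 1/17.6 decimal-acuity-per-cpd is a
**placeholder calibration constant** — it makes 17.6 cpd correspond to
decimal acuity 1.0 — and is an explicit argument everywhere so that no
clinical deployment inherits it silently.

## ML estimator

A one-hidden-layer feed-forward regressor (32 tanh units, deterministic
LBFGS fit) maps a 19-dimensional feature vector — per check size the
normalized corrected amplitude, significance flag and log SF, plus an
all-zero-curve sentinel — to logMAR. Features use the same
normalize-and-quantize scheme as the heuristic fit, so predictions are
exactly invariant under global amplitude scaling. Two validity guards
produce typed refusals instead of extrapolations: (1) a curve whose
significance fingerprint (which check sizes responded) never occurred in
the training corpus is out of distribution; (2) a predicted value outside
the training logMAR range ± 0.1 margin is out of range. The contract is
behavioural (self-consistency RMSE ≤ 0.1 logMAR on within-distribution
synthetic data, Spearman ρ ≥ 0.8 agreement with the heuristic, 100%
refusal on far-out-of-range corpora at the default acquisition
parameters); no claim is made about fidelity to any particular previously
trained network.

## Paired statistics

Within-participant logMAR differences between two conditions are tested
by sign flipping: exhaustive enumeration of all 2ⁿ patterns for n ≤ 20
pairs, Monte-Carlo with the identity permutation included otherwise.
Two-sided p is the proportion of permuted |statistic| ≥ the observed
|statistic| (inclusive counting, so all-zero differences give p = 1).
Medians of even counts are the mean of the central pair. Confidence
intervals are percentile bootstrap over participants (BCa behind a flag),
always reported as [lower, upper]. The Bonferroni adjustment is
min(1, factor·p) with factor 2 for the two vision levels. Participants
with a missing estimate in either condition are excluded pairwise.
Outlier sensitivity uses largest-|deviation-from-median| as the
"most outlying" definition.

## Synthetic generator

The generator emulates a 2×2 monocular acuity study: vision of the tested
eye (normal / degraded by +1.06 logMAR, the level produced by a strong
diffusing filter) × occlusion of the fellow eye (translucent / opaque),
with the planted occlusion effect (default −0.06 logMAR in translucent
conditions) as the quantity under test, and condition order
counterbalanced over a 4×4 balanced Latin square.

Per participant: normal-vision logMAR ~ N(0.02, 0.08) clipped to
[−0.2, 0.3] (a normally sighted adult cohort), first-harmonic peak
amplitude ~ U(6, 14) µV, white background EEG sd ~ U(15, 25) µV, blink
rate ~ U(1, 5)/min. Defaults: six check sizes in a factor-2 geometric
series (0.5–16 cpd), 80 one-second segments at 1000 Hz, 8 reversals/s.
The tuning amplitude is flat at the peak below 0.5 cpd and declines
linearly in log₁₀ SF to zero at the participant- and condition-specific
SF limit (the inverse acuity conversion of the condition's true logMAR).
This shape makes the heuristic's straight-line extrapolation exact, so
noise-free cohorts are a sharp recovery oracle (planted limits recovered
to < 10⁻⁶ log units; the test bound is 0.02). Blinks are 200-ms
raised-cosine transients of 150–300 µV placed wholly inside distinct
segments, so k blinks produce exactly k segment rejections. An optional
1/f noise component exists but is off by default, because the white-noise
null is the case in which the significance test's calibration is exactly
checkable.

**What the generator does not emulate:** realistic VEP waveshape beyond
the first harmonic, alpha rhythms and other structured EEG, electrode and
montage effects, drifts/nonstationarity, latency jitter, or any
dependence of noise on the stimulus. Passing the synthetic benchmarks
therefore demonstrates the correctness and calibration of the analysis
chain under its stated assumptions, not clinical performance on real
recordings; in particular the white-noise significance calibration will
degrade under strongly coloured EEG, which is why K, the test, and the
noise model are configuration points.

## Problem sizes used in the test suite

Unit tests run on reduced acquisitions (4–40 segments, 250–1000 Hz)
chosen so each check exercises the same code paths at a few seconds'
cost; the calibration benchmark uses the full default acquisition
(10⁴ × 80 segments), parameter recovery uses 100 participants at default
SNR, bootstrap coverage uses 1000 simulated cohorts, and the synthetic
study in the README runs the full default configuration
(16 × 4 × 6 recordings).

## Known limitations

- The acuity conversion factor is uncalibrated; absolute logMAR values
  from real data are meaningful only after site-specific calibration
  against behavioural acuity.
- The heuristic's point-selection rules are one member of a family; the
  configuration points (trailing point, tie-breaks, override rule) exist
  precisely because published descriptions underdetermine them.
- The ML estimator is retrained per study; serialized models carry their
  training range and corpus hash and refuse outside it, but transfer
  between acquisition protocols is untested.
- EDF support is input-only and requires `mne`; stimulus metadata must be
  supplied alongside, since EDF does not carry it.
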