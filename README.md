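# vepacuity

Objective visual-acuity estimation from steady-state visual evoked
potentials (VEPs), packaged as a tested, reusable pipeline together with a
synthetic SSVEP generator for validation.

## Who this is for

Visual electrophysiologists and methods researchers who estimate acuity
from pattern-reversal VEP tuning curves — e.g. in patients for whom
psychophysical testing is unreliable — and who want an open, scriptable
implementation of the full chain from raw single-channel recordings to
paired condition statistics, with every stage testable against planted
ground truth.

## The method

For each of six checkerboard check sizes, a steady-state VEP is recorded
while the stimulus reverses at a fixed rate. Per recording:

1. **Artifact rejection.** 1-s segments whose peak amplitude exceeds
   120 µV (blinks) are discarded.
2. **First harmonic.** The accepted segments are averaged coherently and
   the DFT bin at the reversal rate *f*₁ is read out, giving amplitude
   *A* and phase.
3. **Noise correction and significance.** The background level *N* is the
   RMS amplitude of the 2 bins on each side of *f*₁; the corrected
   amplitude is √max(*A*² − *N*², 0), and the response is tested against
   the neighbours with an F ratio, *A*²/⟨*N*ᵢ²⟩ ~ F(2, 2·4), significant
   at single-test α = 0.05.

The six corrected amplitudes against log₁₀ spatial frequency (cpd) form a
**tuning curve**. A heuristic selects the descending flank — from the
largest significant response to the highest-SF significant response,
after overriding spurious isolated significances — fits a straight line,
and extrapolates to the abscissa intercept: the **VEP spatial-frequency
limit** *f*ₗᵢₘ. Decimal acuity is a calibration factor times *f*ₗᵢₘ,
clipped to ≤ 1.6, and logMAR = −log₁₀(decimal acuity). A machine-learning
regressor (small feed-forward network on scale-free curve features)
provides an alternative estimate, refusing curves outside its training
range of validity.

Condition contrasts (e.g. translucent vs opaque occlusion of the fellow
eye, under normal and artificially degraded vision — a 2×2 design) are
tested with paired sign-flipping permutation tests on the median and
mean, percentile-bootstrap confidence intervals, and a Bonferroni factor
of 2 for the two vision levels.

The synthetic generator plants a participant-specific SF limit and
emulates the acquisition (white background EEG, >120 µV blink transients,
counterbalanced condition order), with the tuning amplitude declining
linearly in log SF so that the heuristic's extrapolation is exact by
construction — giving sharp recovery oracles for the whole pipeline.

## Worked example

Run the full synthetic study (16 participants, planted occlusion effect
ΔlogMAR = −0.06 in translucent conditions, degraded-vision offset
+1.06 logMAR):

```python
from vepacuity import StudyConfig, run_study

bundle = run_study(StudyConfig(n_participants=16, seed=1), out_dir="results/study")
print(bundle["comparisons"][["method", "vision", "statistic", "estimate",
                             "p_value", "p_bonferroni", "n_pairs"]])
```

```
   method   vision statistic  estimate  p_value  p_bonferroni  n_pairs
heuristic   normal    median -0.062189 0.003906      0.007812       16
heuristic   normal      mean -0.058696 0.000031      0.000061       16
heuristic degraded    median -0.057124 0.109375      0.218750       15
heuristic degraded      mean -0.048683 0.404724      0.809448       15
       ml   normal    median -0.064207 0.003906      0.007812       16
       ml   normal      mean -0.059599 0.000031      0.000061       16
       ml degraded    median       NaN      NaN           NaN        0
       ml degraded      mean       NaN      NaN           NaN        0
```

Reading this: under normal vision the planted −0.06 logMAR
translucent-occlusion advantage is recovered by both estimators (median
difference −0.062 and −0.064, significant after the Bonferroni ×2
adjustment). Under degraded vision one participant yields no estimate
(n = 15) and the effect is not significant; the ML estimator refuses all
degraded-vision curves because their acuity lies outside its training
range (n = 0). Per-participant estimates land where they were planted,
e.g. participant P00, degraded/opaque: SF limit 1.65 cpd → decimal 0.094
→ logMAR 1.03 (ground truth 1.03).

The same pipeline is available from the shell:

```sh
vepacuity simulate --n 16 --effect -0.06 --seed 1 --out cohort/
vepacuity analyze cohort/P00/normal_opaque/*.csv --out resp.csv
vepacuity estimate resp.csv
vepacuity train-ml --n-curves 200 --out model.json
vepacuity estimate resp.csv --method ml --model model.json
vepacuity compare results/study/estimates.csv --statistic mean
vepacuity run-study --n 16 --seed 1 --out results/study
```

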