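# Methods

`pttbp` estimates systolic and diastolic blood pressure (SBP/DBP), beat by
beat, from a simultaneously recorded single-lead ECG and a finger/ear
photoplethysmogram (PPG), using an invasive arterial blood pressure (ABP)
waveform only to supply reference labels during training. This note
documents the model, the numerical choices, and what the synthetic data
generator does and does not emulate.

## Physiological background

The pulse transit time (PTT) — the delay between the electrical activation
of the heart (ECG R-peak) and the arrival of the pressure pulse at a
peripheral site — shortens as arterial walls stiffen under higher pressure,
which makes it the classical cuffless BP surrogate. PTT alone, however,
explains only part of the BP variance, so the estimator also uses the
morphology of the PPG pulse, which reflects peripheral resistance and
vascular compliance.

## Per-beat features

Each beat contributes a 14-dimensional feature vector built from the ECG
R-peak, the five pulse landmarks (onset *b*, maximum-slope point *a*,
systolic peak *c*, minimum-slope point *e*, dicrotic peak *g*) and the
pulse cycle `[b, next b)`:

| feature | definition | units |
|---|---|---|
| PTTb, PTTa, PTTc | R-peak to *b* / *a* / *c* delay | s |
| K | (cycle mean − PPG(b)) / (PPG(c) − PPG(b)) | — |
| HR | 60 / RR | bpm |
| Tupr, Tdownr | rise time / fall time as fractions of the cycle (sum to 1) | — |
| Cslope | Hc / Tup, the main-wave rising slope | amp/s |
| Har, Her, Hgr | heights of *a*, *e*, *g* relative to Hc | — |
| S1, S2 | systolic `[b, e)` and diastolic `[e, cycle end)` areas of the onset-referenced pulse, each as a fraction of the whole-cycle area (sum to 1) | — |
| S1/S2 | their ratio | — |

Amplitudes are measured relative to the PPG value at the onset, which is
exactly zero after spline baseline removal. Where "relative area" admits
several readings, S1/S2 are normalized by the whole-cycle area so that
S1 + S2 = 1 holds identically; *e* (the minimum-slope point) is the
systole/diastole boundary.

## Preprocessing

*ECG*: 8-level decimated `sym8` wavelet decomposition with symmetric
extension; the scale-8 approximation is zeroed (baseline drift), the
scale-1 detail is zeroed (high-frequency muscle noise), and scales 2–8 are
soft-thresholded with the universal threshold `sigma * sqrt(2 ln N)`.
By default sigma is estimated once from the finest detail level
(`median|cD1| / 0.6745`), which at ECG sampling rates is nearly pure noise;
estimating sigma per level is available (`noise_est='per_level'`) but
over-thresholds coarse scales where the heartbeat itself dominates the
coefficients. Known limitation: soft thresholding biases the sharp QRS
transients, so the net SNR gain appears only under heavy broadband noise
(measured crossover ≈ 4 dB input SNR on synthetic records); R-peak
*detectability*, which is what the downstream pipeline needs, survives far
milder conditions.

*PPG*: a natural cubic spline through the detected pulse valleys is
subtracted, pinning the corrected signal to zero at every valley.

## Models

The estimator is an ε-support-vector regression with RBF kernel
`K(x, x') = exp(−gamma ||x − x'||²)`, solved by the libsvm SMO solver
behind a thin model type that stores support vectors, dual coefficients
(α* − α), and bias, and reproduces predictions from those fields alone.
Features are min–max normalized to [0, 1] before fitting; labels stay in
mmHg. The default normalization pools training and test rows (the
published protocol); a leak-free variant restricted to the training rows is
provided because pooled scaling leaks the test range.

Hyperparameters (c, gamma, epsilon) are tuned by a binary genetic
algorithm: three 16-bit fields decoded linearly onto [0, 100] × [0, 1000]
× [0.01, 1] (decoded c and gamma are clamped to ≥ 1e-6, since the
optimization problem requires positivity), fitness-proportional (roulette)
selection on 1/(1 + MSE), single-point crossover with probability 0.7,
independent per-bit mutation at 0.01, one elite, population 20, and 100
generations by default. Fitness is the average held-out MSE of a 5-fold
cross-validation whose folds are shuffled once per GA run, so fitness
comparisons between individuals are paired. The reported "best MSE" is the
best CV fitness ever seen. Evaluated chromosomes are cached within a run.

Feature reduction uses the mean impact value (MIV): after the first GA-SVR
fit, each normalized feature is scaled by 1 ± 10% across the training set
and the mean difference of the two prediction vectors is recorded (sign =
direction of association). Features are ranked by |MIV|; the retained set
is the largest rank-prefix whose cumulative contribution ratio stays within
90% — the only prefix rule consistent with retaining 8 of 14 features at a
cumulative 89.96% and 9 at 87.56% in the reference tables — and never
empty. A second GA-SVR on the retained features yields the final
GA-MIV-SVR model. Baselines fitted on the same split: ordinary least
squares on the same retained features (exactly collinear complements such
as S1/S2 are pruned first) and a GA-tuned SVR on PTTc alone.

## Evaluation

MAD (mean absolute deviation), STD (n−1 standard deviation of residuals)
and MSE, all in mmHg; AAMI acceptability (MAD ≤ 5 and STD ≤ 8 mmHg,
inclusive); BHS grading from the percentages of absolute errors within
5/10/15 mmHg (A: 60/85/95, B: 50/75/90, C: 40/65/85, all three columns
required). Some published comparison tables use C as a catch-all lowest
category; `bhs_grade(..., mode='floor_c')` reproduces that, the default
`'strict'` grades such rows as failures. Pearson r² and Bland–Altman
agreement (mean difference, d̄ ± 1.96 SD limits, fraction within) complete
the report.

## Synthetic data

`simulate_subject` builds a beat grid from heart rate, places a zero-mean
Ricker R wave per beat (an all-positive spike train would carry DC that the
zeroed approximation band removes; a real AC-coupled ECG does not), and a
piecewise raised-cosine PPG pulse per beat — systolic rise to the peak,
fall to a dicrotic notch, a smaller dicrotic wave, slow decay to zero — so
that all five landmarks and their heights are analytic in the shape
fractions. The ABP cycle is a raised cosine rescaled so its sampled
extrema equal the per-beat reference SBP/DBP exactly in the noise-free
case. Additive sinusoidal drift and white Gaussian noise are controlled
per channel; all randomness derives from one seed via spawned substreams.

`simulate_feature_dataset` skips the waveform layer: it draws feature rows
directly and produces labels from a named smooth mapping plus Gaussian
noise (default sigma 1 mmHg, the order of beat-to-beat reference
variability). The default "nonlinear" mapping combines an exponential
transit-time term, linear waveform terms of graded strength (spans ~13
down to ~3 mmHg across each feature's range) and a mild interaction
(K×Cslope for SBP, Her×HR for DBP) that a linear model cannot absorb. The
waveform features do not vary independently: a latent "vascular tone"
factor drives PTTc, K, Cslope, Har, Her and Hgr jointly (mixing weight
0.7) with independent residuals, because fully independent features would
make the 14-dimensional normalized kernel geometry far harder than real,
strongly collinear pulse data — pilot runs showed the GA then needs several
times more generations than published convergence behavior suggests. The
causal subsets are declared per target (everything tone-driven plus HR;
PTTb, PTTa, Tupr/Tdownr and S1/S2/S1ratio stay inert), which is what makes
MIV ranking testable: causal features must out-rank inert ones. Effect
spans below ~2 mmHg were avoided for causal features because they fall
under the SVR's spurious sensitivity to inert inputs. A "linear" mapping
with known coefficients exists for exact OLS recovery tests.

What the generator does **not** emulate: arrhythmias, motion artifacts,
sensor saturation, subject-to-subject morphology differences, calibration
drift over hours, or the measurement chain linking waveform shape to BP in
real arteries. Passing tests therefore demonstrate the correctness and
internal consistency of the pipeline — detectors that recover known
fiducials, models that recover known mappings, selection that recovers
known causal structure — not clinical accuracy on real patients.

## Problem sizes and numerical choices

* Pipeline-scale runs (tests, reproduction script) use 1000 beats and a GA
  budget of population 20 × 40 generations with CV fit tolerance 1e-2; a
  pilot at the full 100 generations reached the same optimum basin
  (best CV MSE ≈ 1.0–1.3 against a 1 mmHg² noise floor) at several times
  the cost. All operators, rates and ranges are the defaults above.
* SVR fits use libsvm tolerance 1e-6 (1e-4 inside cross-validation, 1e-2
  inside GA fitness) and an iteration cap of 2×10⁶.
* The spline baseline fit requires ≥ 4 valleys; wavelet denoising requires
  ≥ 2⁸ samples; fiducial detection enforces a 200 ms R-peak refractory
  period; beats missing any landmark (e.g. no dicrotic wave) are dropped
  and counted rather than patched.
* Ties in slope extrema (flat ramps) resolve to the plateau midpoint, so a
  triangular rise reports its max-slope point at the middle.
* `select_features` applies a 1e-9 tolerance at the threshold so a
  cumulative ratio of exactly 100% is retained at threshold 100.
* The 80/20 split, GA seeds and CV folds all derive deterministically from
  the run seed; two runs with the same seed produce byte-identical
  artifacts.

## Known limitations

* Universal soft thresholding over-smooths QRS complexes (see above).
* The GA explores gamma uniformly on [0, 1000]; when the informative
  region is narrow (many independent normalized dimensions), discovery can
  take tens of generations. Real pulse features are strongly collinear,
  which widens the useful gamma basin; the generator reproduces this.
* Pooled ("paper") normalization leaks test-range information; use
  `mode='leakfree'` for honest generalization estimates.
* Row-level 80/20 splitting of multi-beat records leaks subject identity
  across the split; `dataset_from_records` tags rows by record so a
  by-record split can be built, but the default replicates the published
  row-level protocol.
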