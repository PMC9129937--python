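# Methods

`mseeg` implements a hybrid EEG classification pipeline for screening
multiple sclerosis (MS) against healthy controls: wavelet subband
decomposition and overlapping windowing of multichannel resting EEG,
linear and nonlinear per-segment descriptors, wrapper feature selection
by a modified ant colony optimization (m-ACO), and an RBF-kernel SVM
whose hyperparameters are tuned by the grasshopper optimization
algorithm (GOA). Because the clinical recordings that motivated the
method are private, the package ships a synthetic-data module that
emulates their statistical structure, and the whole pipeline is
validated property-based: analytic limits, brute-force oracles, planted
signal recovery, and a null control.

## Synthetic EEG generator

Each recording is `n_channels x (fs * duration)` with defaults matching
the study conditions: 3 channels, 250 Hz, 15 s, 20 recordings per class
(40 total). Each channel sums:

* **1/f^β background** — Gaussian noise spectrally shaped to
  `S(f) ∝ f^(−β)` (default β = 1, SD 0.4), the scale-free floor of
  resting EEG;
* **per-band oscillations** — for each of delta/theta/alpha/beta/gamma,
  white noise band-passed (4th-order zero-phase Butterworth) to the
  band, slowly amplitude-modulated (~0.2 Hz envelope, depth 0.5), and
  normalized to unit variance before scaling by a per-band amplitude
  (healthy defaults: delta 1.0, theta 0.8, alpha 1.0, beta 0.7, gamma
  0.5 — a conventional monotone-decreasing resting profile). Narrowband
  noise rather than sinusoids keeps entropy and fractal descriptors
  non-degenerate. Channels mix a shared band source with an independent
  one (weight 0.5), mimicking inter-electrode correlation;
* **white noise** — SD 0.3 (healthy).

The class contrast is a single scalar `effect_size`: MS recordings scale
the alpha/beta/gamma oscillation amplitudes by `(1 + effect_size)` (the
bands the original analysis found influential) and the white-noise SD by
`1 + 0.2 * effect_size`, so irregularity descriptors discriminate too.
Writing the noise multiplier this way (rather than a fixed 1.2) makes
`effect_size = 0` produce *identical* class generators — the property
the null-control experiment depends on — while still giving the
intended 1.2 factor at unit effect size. Because oscillations are
unit-variance before scaling, the planted band-power ratio is
`(1 + effect_size)^2` up to dilution by background and noise (≈ 3.9
measured at effect_size 1).

What the generator does **not** emulate: dipole geometry and volume
conduction, eye-blink/muscle artifacts, non-stationary state changes,
inter-subject variability beyond seed-to-seed variation, or any actual
MS electrophysiology (the paper characterizes none quantitatively; the
planted effects are free parameters of the benchmark, not claims about
the disease). Passing tests therefore demonstrate that the *pipeline*
recovers a planted band-power/complexity contrast without leakage —
not that it would reach any particular accuracy on clinical data.

## Preprocessing

**Windowing.** Frame starts form the arithmetic progression
`a_n = a_1 + (n − 1) d` with `a_1 = 0`, integer step
`d = round(frame_len (1 − overlap))` floored at 1, and maximal `n` such
that the last frame fits. Defaults: 400 ms frames, 35 % overlap (the
study's stated configuration). Indices are 0-based, frames half-open.

**Subband decomposition.** A 5-level multilevel DWT with symmetric
boundary extension; each band signal is the inverse transform of one
coefficient level with the others zeroed, so bands are full-length and
sum (with the D1 residual, 62.5–125 Hz) back to the input to machine
precision. Dyadic mapping at 250 Hz: D2 → gamma (31.25–62.5), D3 → beta
(15.6–31.25), D4 → alpha (7.8–15.6), D5 → theta (3.9–7.8), A5 → delta
(0–3.9). The default wavelet is Daubechies-8: with db4 only ~83–85 % of
a band-centered tone's energy stays in its band, while db8 keeps ≥ 92 %
(93.8 % for a 10 Hz alpha tone); any PyWavelets wavelet can be
substituted. Decomposition precedes windowing, so a recording yields
`frames x 5 bands x channels` segments.

## Descriptors

Per segment (17 features), tagged by group and by analysis domain
(time/frequency — the axis the model-1/model-2 ablation splits on):

* **statistical** (time): rectified integral Σ|x|, mean absolute value,
  |raw moments| of order 3–5 of the mean-removed segment, RMS, v-order
  statistic `(mean |x|^3)^(1/3)`, waveform length Σ|Δx|, strict zero
  crossings. Moments are computed on the mean-removed segment; band
  signals are near zero-mean already, so this is a mild detrend.
* **entropy**: sample entropy (m = 2, r = 0.2 SD, Chebyshev distance,
  self-matches excluded; `-ln(A/B)` over the standard N−m template
  pairs; 0 for constant series, `inf` sentinel when no (m+1)-matches) —
  time domain; spectral entropy `−Σ p ln p` of the normalized Welch
  spectrum (unnormalized by default; a flag divides by `ln N`) —
  frequency domain.
* **fractal** (time): Katz dimension in the amplitude-difference form
  `log(N−1) / (log(N−1) + log(d/Len))` with `Len = Σ|Δx|` and
  `d = max|x_i − x_1|` (exactly 1 on a ramp, ≫1 on noise); Higuchi
  dimension with the standard curve-length normalization
  `L_m(k) = Σ|x(m+ik) − x(m+(i−1)k)| (N−1)/(n_k k) / k`, slope fitted
  over k = 1..8; Petrosian dimension from sign changes of the first
  difference; Grassberger–Procaccia correlation dimension (embedding
  dimension 2, delay 1).
* **spectral** (frequency): total Welch power and peak frequency.

Welch defaults: 128-sample segments (clamped to the signal length),
50 % overlap, Hamming window, density scaling.

Numerical choices worth noting: the correlation-sum radius grid is
log-spaced from the 2nd percentile to the *median* of pairwise
embedded distances and the slope is fitted over the central quartiles
of that grid — beyond the median the correlation sum saturates toward
1 and its slope no longer reflects dimension (with the full range the
estimator reads ~1.6 instead of ~1.9 for planar iid noise). All slope
fits use closed-form least squares.

**Matrix assembly.** Rows are (recording, frame) pairs; columns
`band.channel.feature`. The pipeline default averages homologous
columns across channels (the generator's channels share sources) and
aggregates frames to one row per recording, giving a 40 x 85 matrix —
the same order of magnitude as the ~36 descriptors of the original
analysis, and the layout that recording-level cross-validation needs.
Segment-level rows with per-recording majority voting remain available
(`FeatureConfig(aggregate="none")`). Z-scoring is fitted on
caller-designated training rows only and stored with the matrix.

## m-ACO feature selection

A wrapper selector. Static heuristic `η_j` = information gain of
feature j about the label (equal-width binning, 10 bins, nats);
pheromone `τ_j` initialized uniform at 1. Each iteration, `k = n` ants
draw subset sizes uniformly from `ceil(0.25 n) .. ceil(0.5 n)` (the
25–40 % band reported effective, widened to 50 % and configurable) and
sample features without replacement with probability ∝ `τ^a η^b`
(a = b = 1), realized by Efraimidis–Spirakis weighted order statistics
— one uniform draw per feature, distributionally identical to
sequential proportional sampling. Subsets are scored by the pooled
misclassification rate of a fixed RBF-SVM (C = 1, γ = "scale") under a
deterministic stratified 3-fold CV on the training rows; evaluations
are memoized per subset. Pheromone update is elitist:
`τ ← (1 − ρ) τ` with ρ = 0.1, the iteration-best subset deposits
`Q/(1 + error)` with Q = 1, floor `τ_min = 1e-3`. Termination: 50
iterations (the budget under which the original convergence was
reported), stagnation patience 15, or error ≤ target (default 0, so
separable data stops immediately). After 10 stagnant iterations ants
restart construction seeded with the global-best subset (the "jump"
move), resetting exploration around the incumbent.

Design points that were genuinely open and decided here: deposits come
from the iteration's best ant only (the description names only a "best
local subset"); η is computed once and never re-updated (it is a
data-determined quantity; re-updating it has no defined semantics);
the jump mechanism is realized as global-best-seeded construction.

## GOA-tuned SVM

The classifier is `SVC(kernel="rbf")`; the kernel's width and the
Gaussian σ are redundant, collapsed into one γ. GOA searches
`(log10 C, log10 γ) ∈ [−2, 4] x [−5, 1]` — log-space because both
parameters act multiplicatively — with 25 agents for 100 iterations
(swarm size chosen here; the iteration budget, comfort bounds
c_max = 1, c_min = 1e-5 and fitness weight α = 1.25 are the published
settings). Agent update: canonical GOA,

    x_i ← c Σ_{j≠i} [ c (ub−lb)/2 · s(|x_j − x_i|) · (x_j − x_i)/d_ij ] + T

with social function `s(r) = 0.5 e^(−r/1.5) − e^(−r)`, positions
clipped to bounds, pairwise distances floored at 1e-12, and the target
T the best position ever evaluated. The comfort coefficient decays
linearly, computed as a convex combination `c_max (1 − l/L) + c_min
(l/L)` so both endpoints are floating-point exact. The objective is

    Fitness = 1 − α·Accuracy + α·(1 − Gmean)

evaluated by pooled predictions of an inner stratified 3-fold CV on the
training rows; Gmean = √(sensitivity · specificity) guards against
class-skewed solutions. α = 1.25 > 1 makes a perfect classifier score
−0.25; harmless for minimization. On a 2-D sphere benchmark the
implementation reaches a median best below 1e-3 within the default
budget.

## Evaluation protocol

Stratified 10-fold cross-validation at **recording** level: all of a
recording's segments stay in one fold. Inside each fold, z-scoring,
m-ACO and GOA see training rows only. The segment-split bookkeeping of
the original writeup suggests segment-level splitting, which would let
a subject's own segments appear on both sides; recording-level folds
are the defensible protocol and the one implemented. Recording-level
labels come from majority vote over segment predictions (trivial under
the default one-row-per-recording layout), ROC scores from mean SVM
decision values oriented so larger means more MS-like; MS is the
positive class. AUC is the trapezoid area of the threshold-sweep ROC
(equal to the Mann–Whitney statistic, which the tests check to 1e-12).

The ablation ladder: model-1 time-domain features only, model-2
frequency-domain only, model-3 both, model-4 both + m-ACO, model-5
both + m-ACO + GOA.

A leakage canary test plants a feature that is discriminative only on
test-fold rows and asserts the pipeline cannot exploit it.

## Problem sizes and runtimes

The shipped experiments use 40 recordings x 15 s x 3 channels —
identical subject count, rate, channel count and segment length to the
original study; per-recording aggregation keeps the learning problem at
40 rows x 85 columns. On one CPU: feature extraction ≈ 45 s per
dataset, model-5 ≈ 1.5–4.5 min per run (m-ACO terminates immediately on
separable data, runs its full budget on null data). The end-to-end
tests fix seeds; the acceptance script derives all seeds from a single
`--seed`.

## Known limitations

* The synthetic benchmark cannot validate clinical performance; the
  reported 98.5 %+ clinical accuracies of the motivating study are not
  reproducible without the private recordings and are not targets here.
* At effect_size 2 the planted contrast is strong enough that the whole
  ladder saturates (accuracy 1.0); the ladder ordering check is
  therefore a non-inferiority check rather than a strict improvement.
* Equal-width binning makes information gain sensitive to outliers in
  a feature's range; adequate here where features are z-scored and
  bounded, but quantile binning would be the robust alternative.
* The GOA social term is O(N² d) per iteration — irrelevant at d = 2
  but the implementation is not meant for high-dimensional searches.
* Binary classification only; multi-class extensions (and non-RBF
  kernels) are out of scope.
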