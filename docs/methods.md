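# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerically delicate corners.

## Signal front end

All audio is down-sampled to 8 kHz (polyphase, anti-aliased) and processed
in 32 ms frames (256 samples). Voicing detection is deliberately minimal:
non-overlapping frames whose short-time energy falls below a configurable
fraction (default 0.1) of the mean frame energy are discarded and the
survivors concatenated. A mean-relative threshold is scale-invariant but not
strictly idempotent — discarding frames raises the mean, so a second pass
can in principle discard more. On the bimodal silence/speech signals the
rule is designed for, the kept set is stable, and the test suite pins that
case. Pre-emphasis is `y(n) = x(n) − a·x(n−1)` with `a = 15/16 = 0.9375`,
`y(0) = x(0)` (the `x(−1) = 0` convention); voiced-frame selection runs
before pre-emphasis.

## Glottal estimation

The glottal flow is estimated by a two-pass, IAIF-flavoured inverse
filtering per Hamming-windowed frame (256 samples, 50% hop, overlap-add
with window-sum normalization). Because the input arrives pre-emphasized,
the exact inverse `1/(1 − a·z⁻¹)` is applied first — an extra
differentiation in the input would otherwise shift the recovered source one
derivative away from the flow (on synthetic vowels this step raises the
correlation with the true source from ~0.4 to ~0.8). Then, per frame:

1. order-2 LP fit → inverse filter removes the residual glottal tilt;
2. order-12 LP fit on the de-tilted frame models the vocal tract;
3. the original frame is inverse-filtered by the vocal-tract model and the
   residual is leakily integrated (`1/(1 − 0.99 z⁻¹)`) to approximate flow.

All LP fits use the autocorrelation method (Levinson–Durbin). Degenerate
(all-zero or numerically singular) frames pass through as zeros with a
warning. The order 12 mirrors the LPC order used for the cepstral features;
both are configurable. No closed-phase analysis or glottal parameterization
is attempted — correlation with a true source of about 0.6–0.9 on synthetic
vowels is the accuracy level this realization provides.

## The 614 features

307 per stream (voiced speech / glottal waveform), seven families, 32 ms
frames with 50% overlap throughout, frame-averaged where a family is
per-frame:

- **MFCC (24)** — power spectrum → 26 triangular mel filters over 0–4 kHz →
  log (floor 1e−10, so silence stays finite) → orthonormal DCT-II,
  coefficients 0–23. Including c₀ means overall level is captured there and
  only there: doubling the input changes c₀ alone.
- **LPCC (18)** — order-12 LPC, cepstral recursion extended to 18 with the
  higher-order LPC terms zero.
- **GTFBO (24)** — log mean energy per channel of a 4th-order gammatone
  bank (`scipy.signal.gammatone` IIR design), ERB-spaced centers over
  50–3999 Hz. The upper edge backs off one bin from Nyquist because the IIR
  design rejects fs/2 exactly. The per-channel reduction (log mean energy)
  is the simplest summary consistent with "filterbank outputs".
- **PLP (13)** — Bark-scale triangular critical-band integration (1-Bark
  spacing), equal-loudness weighting, cube-root compression, inverse DFT to
  autocorrelation, order-12 all-pole fit, cepstra c₀–c₁₂ with c₀ = log
  model error.
- **TTF (24)** — six per-frame series (spectral centroid, spectral flux of
  unit-norm magnitude spectra, 90% rolloff, energy entropy over 8
  sub-blocks, short-time energy, zero-crossing rate) × four statistics
  (σ, max/σ, max/median, σ²/μ²). Sample (ddof = 1) standard deviation by
  default; any zero denominator defines the affected ratio as 0. Timbral
  frames are rectangular — windowing would only rescale the time-domain
  series.
- **SWT-TTF (144)** — 5-level stationary (undecimated) wavelet transform,
  Daubechies-10; the input is symmetrically padded to a multiple of 32 and
  coefficients truncated back. The six subband sequences (cA5, cD5…cD1) are
  summarized exactly like the time-domain timbral family.
- **RWPF (60)** — per frame, a 4-level Daubechies-10 wavelet packet tree
  (30 nodes over levels 1–4, periodized). Node energy is
  `log10(Σ|C| / L²)` — the normalization as printed in the source recipe;
  the more conventional log-energy reading `log10(Σ|C|² / L)` is available
  via `FeatureConfig(rwpf_energy="energy")`. Node entropy is
  `−Σ|C|²·log10|C|²` with `0·log 0 := 0`. Both are divided by their total
  over the 30 nodes, so each 30-vector sums to exactly 1 per frame;
  all-zero frames (or a vanishing total) are skipped with a warning and
  excluded from the frame average.

The Daubechies filters are constructed at import time by spectral
factorization of the Daubechies polynomial (minimum-phase root selection);
orthonormality and vanishing moments are asserted in the tests rather than
trusting transcribed constants.

## PSO cluster-center weighting

A swarm of 30 particles (100 iterations, c₁ = c₂ = 2, inertia from 0.9
multiplied by 0.85 per iteration) searches for K = number-of-classes
centers minimizing the summed Euclidean distance of each sample to its
nearest center. Particles are initialized from randomly chosen data rows;
when the global best stagnates for 10 iterations, velocities reset to zero
and all non-best particles are re-drawn from the data. Per feature
dimension, the weight is |data mean / mean center coordinate|; the ratio
falls back to 1 when the denominator is ~0, the ratio is non-finite, or it
is ~0 — the weights are multiplicative and must stay positive and finite.
Weights are always fitted on training rows only.

Two properties worth knowing:

- the per-dimension Fisher ratio (between-class over within-class variance,
  averaged over dimensions) is **invariant** under any positive column
  scaling, so weighting can never lower it; what weighting changes is the
  joint geometry seen by distance-based methods (the Gaussian kernel),
  which is what the recognition-rate comparisons exercise;
- the ratio of means is only meaningful for features with a nonzero
  baseline. Real acoustic features (log energies, cepstra, entropies) have
  strong baselines; the synthetic table generator therefore adds a fixed
  per-column offset by default (see below).

## Binary-PSO wrapper selection

Fitness is `α(1 − Gmean) + (1 − α)·n_selected/D` with α = 0.8; the G-mean
comes from stratified 3-fold cross-validation of the kernel ELM on the
masked training columns (classifier failure ⇒ worst fitness 1.0 with a
warning). Mechanics: mixed initialization (half the particles at 10% of the
features, half at 60%), velocities clamped to ±6, the v-shaped transfer
`T(v) = |(2/π)·atan((π/2)v)|` as the bit-flip probability, inertia starting
at 1.4 updated by `w ← (w − 0.4)(t_max − t)/(t_max + 0.4)` each iteration
(the schedule as printed in the source recipe, including the +0.4
denominator), and empty masks repaired to one random bit.

Personal and global bests follow the two-situation rule: accept a candidate
iff it has strictly better G-mean with no more features, or strictly fewer
features with G-mean no worse. Every accepted update strictly lowers the
Eq-type fitness, so the recorded global-best fitness history is
non-increasing. The initial global best is the particle with the highest
G-mean (ties to fewer features) — choosing it by fitness instead can strand
the whole search at a lucky tiny mask, because the rule never accepts a
larger subset afterwards.

Because single runs are high-variance, repeated independent runs are
aggregated by per-feature selection frequency; "most frequently selected"
means chosen in more than half the runs (frequency ranking breaks ties by
feature index). The evaluation pipeline can use this aggregation per
training fold (`PipelineConfig.selection_runs`).

## Kernel ELM

With Gaussian Gram matrix `Ω_ij = exp(−‖xᵢ−xⱼ‖²/γ)` and one-vs-all ±1
targets `T`, the output weights solve `(I/ε + Ω)·α = T` via Cholesky (never
explicit inversion); scores for new rows are `k(x, X_train)·α` and the
label is the argmax (exact ties go to the lowest class index). `ε` is the
positive regularization coefficient — `1/ε` loads the diagonal, so larger
`ε` means weaker regularization, and at `ε = 1e8` the solution matches the
unregularized interpolant to 1e−6. `γ = None` applies the median
pairwise-squared-distance heuristic of the training rows at fit time
(deterministic), which keeps the classifier sensible across feature counts
without tuning; `tune()` offers a cross-validated grid search maximizing
G-mean (ties → smaller ε, then smaller γ) over `2⁻⁵…2¹⁵` by default.

## Evaluation protocols

SD = stratified k-fold over utterances (10 folds by default, capped at the
smallest class count); SI = leave-one-speaker-out; GD = SD restricted to
one sex. Weights, masks and the classifier are refit on each training fold.
Confusion matrices are pooled over folds and reported row-normalized in
percent; the average recognition rate is the unweighted mean of per-class
recalls (macro average), matching the per-emotion diagonal convention. The
paired t-test on per-fold rates is two-sided at level 0.05 and refuses
all-zero difference vectors.

## Synthetic generators

`synth_vowel` renders a raised-cosine glottal flow pulse train (open
quotient 0.6) with cycle-level jitter and shimmer, differentiates it, runs
it through a cascade of three formant resonators, and adds noise at a
target SNR; the true flow is returned for oracle tests. Class identity
varies the source (f0 220/180/120/90 Hz with decreasing jitter, shimmer and
energy for angry/happy/neutral/sad-like classes); speaker identity scales
the formant frequencies (0.88–1.15, the upper half tagged female). This
emulates the *structure* of an emotional-speech corpus — source-dominated
class differences, tract-dominated speaker differences — not perceptual
realism: a green end-to-end test establishes that the pipeline's stages
compose and discriminate as designed, not that the accuracy transfers to
human speech.

`synth_table` plants K Gaussian clusters (unit within-class σ) whose means
live in a known informative subspace with mean pairwise distance equal to
`separation`; remaining dimensions are label-independent unit-variance
noise, and every column carries a fixed baseline offset drawn from
`N(8, 2²)` (`baseline=0` disables it). Offsets leave all pairwise distances
— and therefore clustering, the kernel and selection — untouched; they
exist solely so that ratio-of-means weighting operates in the regime real
features occupy.

## Numerical choices and degenerate inputs

- log floors at 1e−10 keep silence finite in every spectral family;
- all-zero frames: LPC returns "degenerate" and the frame is skipped
  (features) or passed through as zeros (glottal);
- `ttf_stats` defines zero-denominator ratios as 0 rather than raising;
- weight ratios fall back to 1 on degenerate denominators;
- every stochastic component takes an explicit seed and is bit-reproducible.

## Known limitations

- Energy thresholding is not a VAD; noisy recordings need external cleanup.
- The glottal estimate is a textbook LP realization, not a closed-phase or
  EGG-validated method.
- The as-printed RWPF energy normalization (`Σ|C|/L²` inside the log) is
  unusual; the alternative reading is provided but not the default.
- The wrapper's two-situation rule optimizes G-mean-then-count
  lexicographically more than it optimizes the blended fitness; on small
  exhaustive benchmarks it reaches the fitness optimum, but the guarantee
  is empirical, not structural.
- Weighting's benefit is geometry-dependent: on zero-baseline, mean-centered
  tables the ratio of means is uninformative by construction.
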