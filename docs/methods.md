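# Methods

`emoeeg` reimplements, as a tested pipeline, an analysis for distinguishing
four music-evoked emotions (calm, joy, sad, angry) from multi-channel EEG:
per-electrode extraction of 27 features (18 linear, 9 nonlinear),
correlation-based feature selection (CFS), and multi-classifier evaluation.
The original recordings were never deposited, so the pipeline ships a
synthetic EEG generator whose planted structure makes every stage testable;
the study's printed summary tables (class-correlation averages, selection
counts, t-test grids, repeatability accuracies) are embedded in
`emoeeg.reference` and the derived columns are recomputed from them.

## Signal model of the generator

Each trial of each channel is

    x(t) = sum_b A_b sin(2 pi f_b t + phi) + c z(t) + e(t)

with one sinusoid per band (theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz;
amplitudes `A_b` in uV, centre frequencies `f_b` inside the band, seeded
random phase), a chaotic component `z` — the logistic map x_{t+1} = 4 x_t
(1 − x_t), standardized to zero mean and unit variance — weighted by the
mixing fraction `c` in [0, 1], and white noise `e` of configurable sd.
Emotion classes differ per channel in `A_b`, `f_b` and `c`; a channel whose
recipe is identical across emotions carries no class information.  The
logistic map is used because its largest Lyapunov exponent is known in
closed form (ln 2 ≈ 0.693), giving the Lyapunov estimator a free oracle,
and because mixing it in raises every regularity/complexity feature
monotonically.

Defaults mirror the study design: 15 datasets (sessions), 20 trials per
emotion presented in the fixed block order calm → joy → sad → angry, 12
named 10–20 electrodes (FP1, FP2, F3, F4, F7, F8, Fz, C3, C4, T3, T4, Pz),
15 s epochs at 256 Hz.  Pz, T3 and T4 are emotion-responsive by default
(matching the electrodes the study singles out); the rest carry
emotion-flat background oscillations.  The per-emotion recipes encode the
usual qualitative physiology: calm = strong regular alpha with low chaotic
fraction; sad = theta-weighted with slow centre frequencies; joy = mixed
alpha/beta, moderate irregularity; angry = beta-dominant and strongly
chaotic (c = 0.9).

A second, feature-level generator (`synthetic_feature_table`) draws
trials × 27 Gaussian tables in which exactly a chosen 12 feature dimensions
receive per-class mean offsets (−1.5, −0.5, 0.5, 1.5) × 0.5 sd in a random
per-feature assignment.  The 0.5-sd adjacent-class spacing was chosen so the
resulting class correlations reproduce the magnitudes the study reports
(mean SU ≈ 0.15 for informative features against a ≈ 0.05 plug-in noise
floor at 80 trials and 5 bins).  This generator expresses "exactly k
dimensions are informative", which the raw-signal generator cannot: changing
a centre frequency or the chaotic fraction moves many features at once.

What the generator does **not** emulate: volume conduction and inter-channel
correlation, ocular/muscle artifacts, 1/f background spectra,
non-stationarity within an epoch, and any genuine music-driven neural
response.  Passing tests therefore demonstrate that the pipeline recovers
structure of this planted kind, not that the original biological claims
replicate.

## Preprocessing

* Centred epoching: the middle `E` seconds of a `T`-second trial, starting
  at floor((T − E)/2) whole seconds (a 45 s trial yields samples
  [15 fs, 30 fs)).  Pure slice; 0-based, half-open.
* 50 Hz suppression: zero-phase IIR notch (Q = 30) applied as two cascaded
  `filtfilt` passes; residual of a pure 50 Hz tone < 3% RMS, passband
  (4–30 Hz) change < 1%.
* Band decomposition: zero-phase 4th-order Butterworth bandpass per band
  (default).  A wavelet-packet backend (db20, depth 6) is provided for
  comparison; its half-band filters leak across the 8 and 13 Hz edges, so it
  is not the default (the Butterworth split keeps ≥ 90% of broadband energy
  in-band, the packet split does not).
* Optional denoising: hard-threshold wavelet shrinkage (db4, universal
  threshold, MAD noise estimate).

## The 27 features

Canonical ids are fixed: 1–18 linear — per band (alpha 1–6, theta 7–12,
beta 13–18): peak, average value, variance, centre frequency, maximum
power, power sum; 19–27 nonlinear — singular spectral entropy, K entropy,
approximate entropy, maximum Lyapunov exponent, C0 complexity, sample
entropy, spectral entropy, Lempel–Ziv complexity, correlation dimension.

Linear block (on band-filtered signals; computing mean/variance/peak on the
raw epoch was the open alternative, but band-wise statistics match the
feature names "alpha average value" etc.):

* peak = signed maximum; mean/variance = sample statistics (ddof 1).
* centre frequency: wavelet pseudo-frequency Fa = Fc · fs / a, choosing the
  scale `a` whose Morlet CWT response energy is maximal among scales whose
  pseudo-frequency lies in the band (0.25 Hz grid).  A zero band signal is
  reported as the band midpoint with a degeneracy flag.
* maximum power / power sum: max and sum of the spectrum of the biased
  autocorrelation estimate.  That spectrum equals the periodogram
  |X(ω)|²/N, evaluated on the full N-point DFT grid so it is non-negative
  and exactly Parseval-consistent (grid mean = variance + mean²).

Nonlinear block (broadband epoch; all tolerances sd-relative, so every
estimate is amplitude-scale invariant):

* ApEn (Pincus): m = 2, r = 0.2 sd, Chebyshev distance, self-matches
  included.  SampEn (Richman–Moorman): self-matches excluded; A = 0 maps to
  the documented ceiling ln((N−m)(N−m−1)/2).  Both are vectorized over 2-d
  accumulated difference matrices and verified against naive O(N²) double
  loops to 1e−10.
* Correlation dimension (Grassberger–Procaccia): delay = first
  autocorrelation zero crossing, Chebyshev correlation integrals on ≤ 1000
  strided points, Theiler window m·τ.  The r grid is placed at log-spaced
  *probability* quantiles of the pair-distance distribution (20/n_pairs up
  to 0.6), which keeps grid resolution where C(r) changes and prevents the
  exact recurrences of periodic signals from swamping the grid.  The slope
  is fitted on the best-R² contiguous window spanning half the usable grid
  (bins below 10 pairs or above C = 0.5 excluded; flat runs collapsed); D2
  is taken at the first embedding dimension (m = 2..8) where the slope
  changes by < 0.1, with flags for no saturation (stochastic series) and
  fit R² < 0.95.
* K entropy: correlation entropy K2 from the same correlation sums, as
  minus the slope of ln C_m(r) against m (m = 2..7) averaged over usable r
  bins, divided by τ.  ≈ 0 for periodic signals, ≈ ln 2 for the logistic
  map, large for noise.
* Largest Lyapunov exponent (Rosenstein): m = 5 (2 for maps), τ = first
  autocorrelation zero crossing, Theiler window = max(mean period, m τ),
  nearest-neighbour log-divergence curve; slope fitted from 0 up to where
  the curve comes within 1 nat of saturation; a flag marks curves that jump
  straight to saturation (no deterministic divergence, e.g. white noise).
* C0 complexity: Fourier coefficients with |F|² > 5 × mean|F|² form the
  regular part; C0 = residual energy / total energy.
* Singular spectral entropy: 64-lag trajectory matrix, entropy of
  normalized singular values / ln 64.
* Spectral entropy: entropy of the normalized one-sided power spectrum
  (mean removed) / ln(bins).
* LZ76: median binarization, Kaspar–Schuster exhaustive-history pattern
  count c(n), normalized c(n) log2(n)/n.

Degenerate (zero-variance) epochs return 0 for all nine with per-feature
flags rather than raising, so batch extraction never aborts a dataset.

## Feature selection

Features are discretized by equal-frequency binning (5 bins; ties share a
bin via average ranks, constant columns collapse to one bin with a flag).
Associations use base-2 plug-in entropies and symmetric uncertainty
SU = 2 IG / (H(X) + H(Y)); information gain is computed as
H(X) + H(Y) − H(X,Y) so symmetry holds to machine precision.  Subsets are
scored by the CFS merit k r̄_cf / sqrt(k + k(k−1) r̄_ff) (the redundancy
term vanishing at k = 1, where merit equals the class SU), and ranked by
greedy forward search with ties broken toward lower canonical ids.  Two
study-level summaries: (i) per-feature class SU averaged over datasets with
a strict threshold (default 0.1); (ii) chosen-times counts of top-10
appearances across rankings with a strict > 20 cut.  Rankings for the
frequency summary are computed per dataset × electrode: a per-music-group
ranking would be ill-defined, since within one group the class label is
constant and every class SU is zero; with 3 electrodes × 15 datasets the
45 possible counts are consistent with the reported maximum of 41.

`CfsSelector` (threshold / best-merit / top-k modes) and `CfsRanker` expose
the procedure as sklearn estimators.

## Evaluation

Classifiers: RBF SVM (C = 1, gamma scale), C4.5-style tree (entropy
criterion, min leaf 2, light cost-complexity pruning α = 0.002), BP-style
MLP (one hidden layer of 2·d + 1 units, trained to convergence — an early
stopping validation slice starves the fit at ~72 training trials), and LDA.
Every model sits behind a train-fold-only standardizer, so no test-fold
statistics leak.  Protocols: stratified 10-fold CV repeated to 100 fold
evaluations (the "10% cross validation … 10% training" description in the
source is self-contradictory; a literal 10%-train shuffle split is available
via `train_fraction`); nested-subset accuracy curves over CFS-prefix sizes
with a plateau flag (smallest size within 3 points of the maximum); one-vs-
rest ROC with macro AUC; and the repeatability protocol — 10 random draws
of 8 test trials per emotion (32 test / 72 train), reporting per-repeat
accuracies (multiples of 100/32) and their mean.

## Statistics

Paired t-tests (pairing by within-dataset trial rank) per electrode ×
emotion pair × dataset × feature, counting p > 0.05 (non-rejections) with
per-electrode totals; zero-variance difference vectors count as
non-rejections with a flag; no multiple-testing correction, matching the
raw counting convention of the tables being reproduced.  Levene
(median-centred) and one-way ANOVA wrap scipy.  Histograms share bin edges
across emotions so distributions are directly comparable.

## Validation sizes

Tests and the acceptance script exercise the pipeline at reduced sizes
chosen as this package's validation conditions: 4 s epochs at 256 Hz, one
session of 80 trials with one emotion-responsive and one pure-noise
electrode for the classifier checks, 50 replicates of 5 × 80-trial tables
for selection recovery, and N = 100–4096 signals for the estimator oracles.
Generator defaults remain the full study conditions.

## Known limitations

* The t-test and repeatability tables are reproduced from their printed
  cells; the underlying recordings do not exist publicly, so the study's
  headline per-electrode recognition rates are not reproducible quantities.
* Correlation-dimension and K2 estimates on short noisy epochs are
  variance-heavy; they are features for classification here, not certified
  dynamical invariants.
* The wavelet-packet band backend trades edge alignment for dyadic
  structure and is not energy-equivalent to the Butterworth default.
* Plug-in SU has a positive small-sample bias (≈ 0.05 at 80 trials / 5
  bins / 4 classes); the 0.1 selection threshold sits about twice that
  floor, which is what makes the thresholded selection meaningful at the
  study's trial counts.
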