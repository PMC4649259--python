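# Methods

`arteeg` re-implements, as a tested analysis pipeline, a study design in
which mobile EEG is recorded from freely moving museum visitors while they
view art pieces of varying visual complexity. Because the raw museum EEG is
not publicly deposited, the pipeline ships with a first-class synthetic-data
module whose directed structure is known exactly; every downstream stage is
validated as a closed generator/detector loop. This note records the models,
the defaults and why, the numerical choices, and what the synthetic results
do and do not say about real data.

## Synthetic sessions

Each channel is a damped second-order oscillator — a diagonal VAR(2) with
pole radius *r* (default 0.95) at an alpha-range frequency (10 ± 1 Hz per
channel, jittered deterministically per subject) driven by white noise.
Directed coupling from channel *j* to *i* is an off-diagonal lag-1
coefficient; VAR order 2 is the smallest order that yields band-specific
spectral peaks, and lag-1 coupling is the simplest term the connectivity
stage must recover. Couplings switch instantaneously at block boundaries, so
the Kalman tracker is tested against a step. Every coupling regime is
checked for stability (companion-matrix spectral radius < 1) and an unstable
specification is rejected with the per-regime report.

A session is a baseline block (default 60 s) followed by annotated
piece-viewing epochs (default 6 s each). Viewing epochs carry, per stimulus
class:

* elevated right→left and posterior→anterior lag-1 gains
  (complex 0.30, moderate 0.15, baseline 0.0) on a fixed template of
  electrode pairs, and
* narrowband amplitude boosts — occipital gamma (40 Hz) and frontal delta
  (2 Hz), 6 µV and 8 µV SD for the complex class, half that for moderate —
  giving the feature stage band- and site-specific class information in the
  bands this kind of study finds informative.

Amplitudes are calibrated after simulation: each channel is scaled to a
15 µV SD so that clean traces span roughly ±50 µV, keeping artifact
thresholds physically meaningful regardless of how sharply the oscillator
chain resonates (the nominal gains remain in the ground-truth sidecar). A
shared alpha-range background (20 µV SD, identical on all channels)
emulates the strong common signal that volume conduction puts on real scalp
recordings; the correlation-based bad-channel rule depends on such
correlation, and the common average reference later removes the shared
component exactly. The effect sizes above are a design choice calibrated to
the detectability properties the test suite asserts, not to the original
museum recordings, which report no quantitative effect sizes.

What the generator does **not** model: biophysical forward/head models
(channel-specific mixing), dry-electrode noise, nonstationary artifact
statistics, or demographic effects (group attributes modulate gains only
when explicitly configured). Passing tests therefore demonstrate that the
pipeline recovers the effects it is pointed at under EEG-like dynamics —
not that it would achieve the same numbers on museum data.

## Preprocessing

The cleaning chain runs high-pass filter → bad-channel rejection →
peripheral removal → artifact subspace reconstruction (ASR) → common average
reference → segmentation, and never changes the sample count (only channel
rejection changes the montage).

* High-pass: 8th-order Butterworth at 0.1 Hz applied forward–backward
  ("zero-phase 8th order" read as an 8th-order design run in both
  directions, the common EEG convention; the magnitude response is squared).
* Bad channels: 2-s windows; a channel is flagged in a window when ≥ 80% of
  its absolute Pearson correlations with other channels fall below the
  threshold, and rejected when ≥ 50% of windows flag it. The threshold is
  user-set in this kind of protocol; the default here is 0.4. Zero-variance
  windows have undefined correlations, treated as 0.
* Peripheral removal: the 12 peripheral sites most exposed to myoelectric
  and motion artifact (Fp1/2, F7/8, T7/8, TP9/10, P7/8, PO9/10) reduce the
  32-channel cap to the 20-channel analysis montage. PO7/PO8 are treated as
  EOG-repurposed auxiliaries and never analyzed.
* ASR (simplified): principal components from the calibration covariance
  (calibration = lowest-variance contiguous run); per 0.5-s window,
  components whose RMS exceeds the calibration mean + 3 SD are *clipped* to
  that threshold and the window reconstructed. Clipping, rather than
  deleting, the offending subspace preserves the waveform shape of genuine
  high-power activity while removing the excess amplitude of transients.
  This is a deliberately simplified method in the spirit of the published
  sliding-window subspace algorithms; no bit-compatibility with any EEGLAB
  plug-in is claimed.
* Segmentation: the first 5 s after each piece annotation, split into five
  1-s segments. The baseline epoch is the lowest-variance 5-s window of the
  baseline block — the block's most artifact-free stretch — since nothing
  in the protocol pins down which 5 s of the 1-min baseline to use.

## Image complexity classes

Per image: luminance Y = 0.299 R + 0.587 G + 0.114 B with mean/SD/kurtosis/
skewness and the fraction of pixels darker than 64; a Gabor bank of 4 dyadic
scales (peak frequency 0.25…0.03125 cycles/px) × 4 orientations
(0°/45°/90°/135°) summarized by magnitude mean and variance; central-
difference gradient-magnitude statistics (Sobel via config); and 4 × 4
composite block deviations (block mean gray minus global mean gray, exactly
invariant to additive brightness changes). Features are z-scored, then
average-linkage agglomerative clustering under cosine distance is cut into
three groups; the group containing the blank-wall image is "baseline" and
the remaining groups are ordered by mean luminance SD (higher → "complex").
Standardization before cosine clustering is a package decision; cosine alone
is scale-blind but not offset-blind, and z-scoring makes the three class
directions well separated.

## EEG features

Bands: delta 1–4, theta 4–7.5, alpha 8–12, beta 15–25, gamma 30–50 Hz.

* Time domain (24/channel): kurtosis (Pearson convention), SD, max
  |amplitude| and Shannon entropy of a 32-bin amplitude histogram, on the
  raw 1-s segment and on each band-filtered version (4th-order Butterworth
  band-pass, forward–backward). A constant segment reports entropy 0 and
  kurtosis 0.
* Frequency domain (15/channel): multitaper PSD (DPSS, time–bandwidth 2,
  3 tapers — appropriate for 1-s segments); per band the integrated power,
  the SD across in-band PSD bins, and the Shannon entropy of the in-band
  PSD normalized to a probability vector. "SD across bins" (not across
  tapers) is the package's reading of the ambiguous estimator.
* Wavelet domain (15/channel): complex Morlet scalogram (center frequency
  1.5 Hz·s bandwidth parameterization) on a 1–50 Hz, 1-Hz grid — every band
  contains at least 3 rows — with the same three statistics on scalogram
  power.

Tables carry one row per (subject, piece, 1-s segment); each of the five
segments is one observation (no aggregation — the original protocol leaves
the aggregation unstated, and per-segment rows preserve the most
information). For the 20-channel montage the time domain yields 480 columns.

## Feature selection and clustering

* mRMR: greedy difference criterion (relevance − mean redundancy) with
  mutual information on 3-level discretized features (cut points at
  mean ± SD). Deterministic; ties broken by column order. Verified against
  an exhaustive mutual-information oracle on small instances.
* US-ELM: inputs z-scored; random input weights orthonormalized by QR (in
  blocks when the layer is wider than the input dimension — at most *d*
  directions can be mutually orthonormal); sigmoid hidden layer (default
  200 units); output weights solve (I + λ HᵀLH)v = γ HᵀHv where L is the
  unnormalized Laplacian of the symmetrized k-nearest-neighbor heat-kernel
  graph (width = median neighbor distance); the first (trivial) eigenvector
  is discarded and the next nλ give the embedding. Defaults: nλ = 3, k = 9,
  λ = 1.
* Clustering: GMM (full covariances, 10 restarts, 200 EM iterations,
  tolerance 1e-4) or k-means (10 restarts), three classes.
* Accuracy: the plain Rand index (pair agreements / all pairs) per the
  study's description, with the adjusted version behind a flag. Because two
  random balanced 3-partitions have an expected plain Rand of 5/9 while the
  usual "chance = 1/3" refers to per-observation agreement, the package
  reports both the Rand index and the best-matching agreement accuracy
  everywhere, and verifies both chance levels by Monte Carlo.
* The parameter search spreads its iterations (default 100) round-robin
  over the (nλ, k, λ) grid, each with a fresh random hidden layer, and
  tests the accuracy distribution against the shuffled-label chance level.

## Time-varying directed connectivity

The MVAAR model X(t) = Σᵢ Λ(i,t) X(t−i) + E(t) is tracked by a Kalman
filter in recursive-least-squares form: the state is the stacked
coefficient matrix [Λ(1,t) … Λ(p,t)], the measurement-noise-normalized
state covariance is shared across output channels, and a random-walk state
is realized by covariance forgetting with factor 1/(1 − UC). The update
coefficient UC (default 1e-3) sets the effective memory to about 1/UC
samples: 4 s at the 250 Hz fitting rate — slow enough for stable 5-s
estimates, fast enough to follow block-boundary steps within about one
second when a faster UC is chosen. Epochs are decimated to 250 Hz
(anti-aliased) before fitting; gamma (≤ 50 Hz) stays well inside Nyquist
and a 5-s fit is desk-scale. Model order defaults to p = 5.

The transfer matrix is H(f,t) = Λ(f,t)⁻¹ with
Λ(f,t) = I − Σₖ Λ(k,t) e^(−i2πfΔt·k), evaluated on a 1–50 Hz, 1-Hz grid and
a 10-ms time grid (γ² is computed independently per frequency bin, so
stages that need one band may evaluate only that band's grid — the values
are identical). The adaptive directed transfer function is
γ²(i,j,f,t) = |Hᵢⱼ|² / Σₘ |Hᵢₘ|², normalized to 1 across sources for every
(target, f, t); that normalization is asserted on every emitted tensor.
A numerically singular Λ(f,t) falls back to a pseudo-inverse and flags the
tensor.

Six directed region patterns are built from the montage by row: anterior =
F/FC rows, posterior = CP/P/O rows (the central row belongs to neither),
left = odd-numbered sites, right = even-numbered, midline excluded from
lateral patterns; each pattern is the full ordered cross product without
self-pairs. The exact regional membership is a package decision — the
row-based reading of the montage figure.

Pattern statistics: supra-threshold γ² values (threshold 0.3, applied
per-bin and per-time before concatenation) are pooled per (subject,
condition, band, pattern) for the descriptive histograms and counts;
supra-threshold counts are non-increasing in the threshold by construction.
"Wilcoxon" comparisons are realized as the rank-sum (Mann–Whitney) test,
since the two samples are unpaired and of unequal size.

### Calibration of the condition contrast

The concatenated per-bin samples are heavily autocorrelated (Kalman
coefficients drift slowly), so a rank-sum test on them has no nominal
level. The Monte-Carlo calibration therefore draws independent epochs per
condition and reduces each epoch to a single observation — its mean in-band
pattern coefficient — before the one-sided rank-sum. Under a null generator
(equal gains in both conditions) the rejection rate over 200 replicates sits
at the nominal 5% (±2%); with the boosted right→left viewing gain every
replicate is significant at 0.05. The pooled-concatenation variant remains
available for descriptive, histogram-style output.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: the
clustering cohort is 20 subjects × (6 pieces + baseline) × five 1-s
segments = 700 observations × 480 time-domain features, with a 12-s
baseline block per session; the contrast calibration uses a 4-channel
lateralized montage (F3, F4, O1, O2), 3-s epochs, 10 epochs per condition
and 200 replicates; coefficient-recovery checks use 3 channels × 5 s at
250 Hz. These sizes are the package's chosen study conditions for the
synthetic analogue; the full 20-subject, 60-s-baseline, 8-piece session
profile is available through the pipeline configuration.

## Known limitations

* The synthetic generator encodes class effects as narrowband boosts and
  lag-1 couplings; real aesthetic-viewing EEG effects are surely subtler
  and mixed through volume conduction. High synthetic clustering accuracy
  (≈ 0.99 Rand) reflects the designed separation, not an expected
  real-data number.
* The simplified ASR is not the published geometric-median implementation;
  it shares the window/threshold semantics only.
* DTF-family estimators are scale-sensitive and can allocate large γ² to a
  sharply resonant source channel even for weak estimated couplings; the
  exactly-diagonal closed form is used where a zero-coupling oracle is
  needed.
* Fig.-for-fig. parity with the original museum analysis (dendrograms over
  the actual art photographs, per-subject scalp maps) is out of scope; the
  pipeline reproduces the quantities, not the figures.
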