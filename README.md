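# arteeg

Analysis pipeline for mobile EEG recorded while people view visual art.

The scientific question is whether scalp EEG from freely moving viewers
carries recoverable structure about what they are looking at: can the
visual complexity of the viewed piece be decoded from band-limited EEG
features, and does directed cortical connectivity reorganize during
viewing relative to a blank-wall baseline? The package implements the full
analysis chain for that question — recording cleanup, stimulus-image
complexity classes, EEG featurization, unsupervised clustering, and
time-varying directed connectivity — together with a synthetic-data module
that generates sessions with known ground truth, so the whole chain is
testable end to end without any recording on hand.

It is written for researchers doing mobile/naturalistic EEG who want a
tested, scriptable reference implementation of this analysis style.

## The models at the core

**Directed connectivity.** Each 5-s epoch is modeled as a time-varying
(multivariate adaptive) autoregressive process

&nbsp;&nbsp;X(t) = Σᵢ₌₁..ₚ Λ(i,t) X(t−i) + E(t),

whose coefficient matrices Λ(i,t) are tracked by a Kalman filter
(recursive least squares with covariance forgetting; update coefficient
1e-3). Fourier-transforming the coefficients gives
Λ(f,t) = I − Σₖ Λ(k,t) e^(−i2πfΔt·k), the transfer matrix
H(f,t) = Λ(f,t)⁻¹, and the adaptive directed transfer function

&nbsp;&nbsp;γ²(i,j,f,t) = |Hᵢⱼ(f,t)|² / Σₘ |Hᵢₘ(f,t)|²,

the normalized directed influence of source channel j on target i per
frequency (1–50 Hz) and time. Values above 0.3 are pooled over six directed
region patterns (anterior↔posterior, left↔right, within-hemisphere) and
compared between viewing and baseline with rank-sum tests.

**Decoding complexity.** Stimulus images are assigned to three classes
(complex / moderate / baseline) by cosine-distance hierarchical clustering
of luminance (Y = 0.299R + 0.587G + 0.114B), Gabor-texture, gradient and
block-deviation features. EEG features (24 time-domain, 15 spectral, 15
wavelet per channel, over delta/theta/alpha/beta/gamma bands) are ranked by
mRMR, embedded by an unsupervised extreme learning machine (random
orthonormal sigmoid layer + graph-Laplacian-regularized eigenproblem) and
clustered with a GMM; agreement with the image classes is scored by the
Rand index against a 1/3 per-observation chance level.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a small synthetic study and run the analysis drivers (tables land
in `results/`, raw fixtures in `scratch/`):

```bash
cd analysis
python 01_simulate.py      --seed 1          # 4 sessions + stimulus images
python 02_preprocess.py    --seed 1          # cleaning chain per session
python 03_image_classes.py --seed 1          # 3 complexity classes
python 04_features.py      --seed 1          # feature tables (3 domains)
python 05_cluster.py       --seed 1          # mRMR -> US-ELM -> GMM
python 06_connectivity.py  --seed 1          # Kalman-ADTF contrasts
```

`03_image_classes.py` recovers the generator's classes exactly:

```
piece_id assigned_class generator_class    lum_sd  dark_fraction  recovered
       1        complex         complex 43.159110       0.108215       True
       2       moderate        moderate 12.621286       0.000000       True
       4        complex         complex 43.222624       0.108154       True
baseline       baseline        baseline  2.044310       0.000000       True
```

`05_cluster.py` reports the clustering-accuracy distribution and where the
informative features sit — on this quick 4-subject pass the gamma band
carries the largest share of the top-50 features (41%), with delta next:

```
80 observations x 480 features; top-50 by mRMR
mean Rand index over 24 runs: 0.586 (chance 0.537); mean agreement accuracy: 0.546 (chance 0.375)
```

`06_connectivity.py` compares per-subject mean pattern strengths between
viewing the first complex piece and baseline (one-sided rank-sum). The
generator elevates right→left and posterior→anterior coupling during
viewing, and the detector finds it, e.g. in the gamma band:

```
gamma  P->A : viewing 0.0344 vs baseline 0.0202  p=0.0143
gamma  R->L : viewing 0.0220 vs baseline 0.0124  p=0.0143
gamma  R->R : viewing 0.0237 vs baseline 0.0170  p=0.0286
```

Numbers here mean: the average in-band γ² over all electrode pairs of the
pattern, per condition, and the rank-sum p-value for viewing > baseline
over the 4 subjects (0.0143 is the smallest value attainable at n = 4).

A `arteeg` console command exposes the same stages
(`arteeg simulate / preprocess / images / run-all ...`), and
`arteeg.pipeline.run_study` runs the whole flow from one `StudyConfig`.

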