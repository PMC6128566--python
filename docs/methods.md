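# Methods

This note records the models implemented, the defaults chosen where the
design was genuinely open, and what the synthetic test material does and
does not establish.

## Canonical frame

Every image is rescaled so that max(H, W) = 1000 px (bilinear; upscaling
included, so all lesions are analysed at a uniform spatial scale), the
lesion is segmented, and the mask's tight bounding box is cropped, padded
to a square and bilinearly resampled to 512 × 512. Details:

* **Rounding.** The non-maximal dimension rounds half-up; a 333 × 999
  input becomes 333 × 1000.
* **Blank pixels.** Padding is zero (black) in all channels, split evenly
  between the two sides of the shorter dimension (odd deficit: extra pixel
  after). Padding is *not* masked downstream — the feature extractor sees
  it, and the zero-variance rows/columns it creates are exactly why the
  degenerate-moment rule below exists.
* **Order of operations.** Pad-then-resample is the default because an
  arbitrary crop can never hit 512 exactly by padding alone;
  `pad_before_resize=False` gives the resample-then-pad alternative.
* No hair removal, specular suppression or histogram normalisation is
  performed anywhere.

## Segmentation

Two-region Chan-Vese on colour images: one shared contour, per-channel
region means c₁, c₂, fidelity summed over R, G, B. The level-set function
starts from a checkerboard (sin(πx/5)·sin(πy/5)) so the contour can form
anywhere without seeding; the Heaviside/delta pair is smoothed over
ε = 1 px.

Defaults μ₁ = 0.25 (length), μ₂ = 0 (area), λ₁ = λ₂ = 1 are the classic
choices for images in [0,1]; the study platform's own defaults are not
recoverable, so these are exposed as parameters. Region means use the
sharp partition (φ > 0), which is both the model's definition and what
reference implementations do — smoothed-Heaviside means wash out to the
global mean under a low-amplitude initialisation and the contour never
breaks symmetry.

The evolution is explicit gradient descent (curvature + fidelity forcing)
with a bidirectional step-size line search: each iteration evaluates a
ladder of time steps and accepts only a step that lowers the monitored
energy (sharp-partition fidelity and area + smoothed length), so the
energy trace is non-increasing *by construction*; if no step improves, the
contour has converged. Convergence is declared at a relative φ-change
below `tol` (1e-3). The lesion is the region with lower mean luminance
(pigmented lesions are darker than skin); `select="lighter"` inverts the
rule. Constant images and collapsed (single-region) outcomes raise a
degenerate-segmentation error.

`chan_vese_energy` evaluates the sharp functional for monitoring/testing:
length as the 4-neighbour boundary-edge count (total variation of the
indicator), area as the inside pixel count.

## Wavelet feature bank

Separable 2-D DWT, periodic boundary handling, LL recursively decomposed
six times (512 → 8 at level 6). Two back-ends:

* **FIR** (haar, db4, sym4, dmey): circular correlation with stride-2
  downsampling; taps from PyWavelets. The analysis operator is orthogonal
  for exact-QMF banks, so energy is conserved per level (tolerance 1e-9)
  and synthesis is the adjoint. dmey's taps are a truncated Meyer
  approximation — orthonormal only to ~1e-3; tests treat it accordingly.
* **Fourier "shannon"** (default): the ideal half-band split computed
  exactly on the periodic power-of-two frames used here. The boundary
  frequency bin is divided between bands — its cosine component to the
  low band, sine to the high band — which keeps the transform orthogonal
  and perfectly invertible. The name follows the wavelet family; the
  original study's "Shannon4" filter has no published coefficient table,
  so the family is implemented in its exact spectral form and the wavelet
  is configurable throughout.

The transform convention is orthonormal (filters carry the √2). The
printed textbook form with a leading factor 2 and an m−2n+2 index shift is
available as `literal_normalisation=True`; it multiplies each level's
bands by 2 and circularly shifts them one sample, which rescales
mean/energy/variance features but leaves all shape statistics (skewness,
kurtosis) and any rank-based use of the features unchanged.

Per band, 12 statistics in fixed order: mean, absolute mean, energy,
variance; then mean and variance of per-row skewness, per-column skewness,
per-row kurtosis, per-column kurtosis. Choices:

* **Energy** is the *mean* of squared coefficients, making it comparable
  across levels with different band sizes.
* Moments are population (biased) estimators; kurtosis is raw (Gaussian →
  3), skewness m₃/m₂^{3/2}.
* A row/column with zero variance contributes 0 to both skewness and
  kurtosis aggregates, so constant regions (e.g. blank padding) yield
  finite features.
* Luminance is Rec.601 (0.299 R + 0.587 G + 0.114 B).

Feature order is (level, band LL/LH/HL/HH, channel R/G/B/Luma, statistic),
named `L{level}_{band}_{channel}_{stat}`; 6·4·4·12 = 1152.

## ReliefF

Standard two-class ReliefF: every instance is a query (exhaustive, hence
deterministic), k = 10 nearest hits and misses by Manhattan distance on
range-normalised features, weight update = mean miss-difference − mean
hit-difference, normalised to [−1, 1]. Constant features score exactly 0.
k and the neighbour metric are configurable; the study reports neither.
The feature-count sweep runs k-fold CV of the classifier on the top-n
features for each n and reports the smallest n within 0.005 of the curve
maximum — reported, never silently applied.

## PCA

SVD of the standardised (zero-mean, unit sample-variance) training matrix.
Eigenvalues of the correlation matrix are d²/(p−1); the eigenvalue curve
is zero-padded to q for rank-deficient tables. Column signs of V are fixed
so each loading's largest-magnitude entry is positive. Test data — down to
a single 1 × q lesion — are standardised with training statistics and
projected onto the training V; nothing is ever refit at test time.
Constant training columns are dropped with a warning (or rejected in
strict mode). Defaults: PCA on the top-125 ReliefF features, 22 components
retained (16 maximises sensitivity; 7–40 is the sensible sweep range).

## Classifiers

* **SVM** (primary): RBF kernel exp(−γ‖x−x′‖²), C = 30, γ = 0.007.
  Probabilities by Platt sigmoid calibration fitted via internal 3-fold
  CV with a fixed seed (`CalibratedClassifierCV(..., ensemble=False)`), so
  margins are deterministic and probabilities depend only on the seed.
  No re-standardisation after PCA: the components are already
  variance-ordered and the RBF is isotropic in that basis.
* **RF**: bagged CART trees, `n_trees` and `min_leaf_size` exposed
  (leaf size 1 is the optimum reported for the reference data).
* **LR**: penalised maximum likelihood; `reg_param` is the penalty
  strength λ (the liblinear C is 1/λ). L1/L2 selectable.

Class encoding: excise = 1 everywhere. Decision rule P(excise) ≥ 0.5, the
tie at the cutoff resolving toward excision — the clinically conservative
direction.

## Cross-validation protocol

Stratified folds by default (the 165/85 imbalance otherwise destabilises
per-fold specificity); plain random folds via `stratify=False`, which
refolds with a new seed (warning) if a fold loses a class. Folds are
reseeded per repeat; a fixed seed makes the whole procedure bit
reproducible. ReliefF and PCA are refit inside every training fold by
default, so the held-out lesion never influences feature selection or the
projection; `global_selection=True` reproduces the leaky variant in which
both are computed once on the full table (the two protocols bracket the
optimism attributable to selection leakage, and the reproduction helper
reports both). Leave-one-out (folds = p) is deterministic, runs once, and
pools its p held-out predictions for sensitivity/specificity, since
per-fold metrics are undefined at n = 1.

DOR uses the standard formula sens·spec/((1−sens)(1−spec)) and rejects
boundary values explicitly. Note the reproducible closed-form anchor is
DOR(0.97, 0.89) ≈ 261.6.

## Synthetic data

* **Images**: skin-toned background (fixed plausible dermoscopy RGB
  constants), darker elliptical lesion, border perturbed by a random
  order-2–5 sinusoid, multi-octave value noise inside the lesion, faint
  vertical illumination gradient. Excise-class defaults have strictly
  larger fine-octave texture amplitude and border irregularity than
  benign defaults, so level-1 detail-band energies genuinely separate the
  classes. The generating region is returned as the ground-truth mask.
* **Tables**: columns in blocks of 12 with equicorrelation ρ = 0.5
  (mimicking the strong within-level/within-statistic correlations of
  real wavelet features), unit marginal variance; the excise class is
  shifted by δ = 2 on 20 informative columns spread across distinct
  blocks. Class sizes default to the study scale (165/85).

What passing on this material shows: the pipeline's operations are
correct, leak-free, deterministic, and able to recover a planted
class-separating structure of realistic dimensionality at the study's
sample size. What it does not show: performance on real dermoscopic
images — synthetic lesions have no hair, rulers, specular highlights,
colour variegation or inter-patient variability, and the synthetic table's
signal geometry (mean shifts on independent blocks) is far cleaner than
real wavelet statistics. The original study's accuracy figures can only be
checked against its supplementary feature tables, which are not bundled.

## Problem sizes in the default runs

The test suite and the acceptance script size their simulations to run
comfortably on one CPU: segmentation examples at 256–512 px, DWT property
checks at 32–64 px, tabular pipelines at 60–250 samples with 30–1152
features, repeated CV at 2–10 repeats. All sizes are parameters of the
public APIs, so larger studies are a matter of changing arguments.

## Known limitations

* The Chan-Vese energy is non-convex; the checkerboard initialisation is
  a good general-purpose basin explorer, but adversarial illumination can
  still trap the contour. The energy-monotone line search stops rather
  than oscillates in that case.
* dmey is only approximately orthonormal (truncated taps).
* ReliefF is O(p²q) per ranking; at the study scale this is fractions of
  a second, but leave-one-out with per-fold refitting multiplies it by p.
* The literal (factor-2) transform convention changes feature scales;
  models trained under one convention do not transfer to the other.
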