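# dermdecide

Decision support for the management of melanocytic skin lesions from
dermoscopic images. Instead of diagnosing melanoma, the classifier
reproduces the *management decision* of expert dermatologists — **excise**
or **do not excise** — which lets it aim for high specificity without the
clinical risk attached to calling a lesion benign: many lesions that should
be excised are not melanoma, and a decision-support tool only has to agree
with the expert that they warrant excision.

Intended users are researchers in automated dermoscopy analysis: the
package is a complete, scriptable re-implementation of a classical
(non-deep-learning) texture pipeline, with every stage exposed as a library
function and as a CLI subcommand.

## The pipeline

1. **Canonical frame** (`preprocess`, `segmentation`). The photograph is
   rescaled so its larger dimension is 1000 px, the lesion is segmented
   with a vector-valued two-region Chan-Vese active contour minimising

   f(c₁, c₂, Ψ) = μ₁·L(Ψ) + μ₂·A(D) + λ₁·∬_D |F − c₁|² + λ₂·∬_{Ω∖D} |F − c₂|²

   (c₁, c₂ are the per-channel region means, recomputed each iteration),
   and the mask's bounding box is cropped, squared with blank pixels and
   bilinearly resampled to 512 × 512.
2. **Features** (`features`). A 6-level separable 2-D DWT of each of
   R, G, B and luminance; for every level × sub-band (LL/LH/HL/HH) ×
   channel, 12 statistics (mean, absolute mean, energy, variance, and the
   mean/variance of per-row and per-column skewness and kurtosis):
   6 × 4 × 4 × 12 = **1152 features**. The default wavelet is the Shannon
   (ideal half-band) transform evaluated exactly in the Fourier domain;
   Haar, Daubechies-4, symlet-4 and discrete-Meyer filter banks are also
   registered.
3. **Selection** (`select`). ReliefF ranks all 1152 features
   (k = 10 nearest hits/misses, Manhattan distance on range-normalised
   features); a cumulative-feature-count sweep locates the plateau where
   additional features stop improving cross-validated performance
   (around 125 features on the original study's tables).
4. **Extraction** (`extract`). PCA by SVD of the standardised training
   matrix, X = W·D·Vᵀ; scores are PC = X·V, test rows are standardised
   with *training* statistics only. The operating point keeps 22
   components.
5. **Classification** (`classify`). RBF-kernel SVM,
   K(x, x′) = exp(−γ‖x − x′‖²) with C = 30, γ = 0.007, Platt-scaled
   probability and a 0.5 excision cutoff (P ≥ 0.5 ⇒ excise). Random
   forests and penalised logistic regression are included for comparison.
6. **Evaluation** (`evaluate`). Repeated stratified k-fold and
   leave-one-out cross-validation with ReliefF and PCA refit inside every
   training fold (no leakage; a `global_selection` switch reproduces the
   optimistic variant), confusion metrics, ROC curves, and the diagnostic
   odds ratio DOR = sens·spec / ((1−sens)(1−spec)).

Because the original 250 Graz photographs are not redistributable, the
`synth` module generates seeded surrogates with known ground truth:
textured elliptical lesions with irregular borders for the image stages,
and block-correlated Gaussian feature tables (165 excise / 85 benign rows,
a recorded set of shifted informative columns) for the tabular stages.

## Worked example

```
$ dermdecide simulate table --npos 165 --nneg 85 --delta 2 --seed 7 \
      --out excision.csv noexcision.csv
$ dermdecide train --features excision.csv noexcision.csv \
      --algo svm --c 30 --gamma 0.007 --top 125 --pcs 22 --seed 7 \
      --out model.bundle
INFO dermdecide: trained svm on 250 lesions -> model.bundle
$ dermdecide cv --features excision.csv noexcision.csv \
      --folds 10 --repeats 3 --seed 7 --report report.json
INFO dermdecide: mean error 0.000 sens 1.000 spec 1.000
$ dermdecide predict --model model.bundle --in noexcision.csv | head -3
0.0065	do not excise
0.0104	do not excise
0.0105	do not excise
```

The synthetic table has a standardised effect size of 2 on 20 informative
columns, so the full chain (ReliefF top-125 → 22 PCs → SVM) separates the
classes essentially perfectly: 10-fold cross-validated error 0.000,
sensitivity and specificity 1.000. `predict` prints, per lesion, the
Platt probability of the excise class and the binary recommendation at
the 0.5 cutoff — the three rows shown are benign-class lesions, all with
excision probabilities near zero.

Images work the same way: `dermdecide simulate images`, `preprocess`,
`segment` and `features` move a PNG through the canonical frame to a
feature CSV, and `predict --model ... --in lesion.png` scores a single
photograph end to end.

## Layout

| module | contents |
| --- | --- |
| `dermdecide.preprocess` | rescaling, crop/pad to the 512×512 frame |
| `dermdecide.segmentation` | colour Chan-Vese level-set segmentation |
| `dermdecide.features` | DWT engine (FIR + Fourier Shannon), 1152-feature bank |
| `dermdecide.select` | ReliefF ranking, feature-count sweep |
| `dermdecide.extract` | PCA fit/transform, eigenvalue curve |
| `dermdecide.classify` | SVM / RF / LR, full-pipeline training, prediction |
| `dermdecide.evaluate` | repeated CV, ROC, diagnostic odds ratio |
| `dermdecide.synth` | seeded synthetic images and feature tables |
| `dermdecide.io`, `dermdecide.cli` | CSV/bundle/config formats, umbrella CLI |

See `docs/methods.md` for the modelling choices and their rationale.
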