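# Methods

This note records the model, the parameter choices that matter, what the
synthetic data does and does not emulate, and the numerical conventions —
the decisions a maintainer would otherwise have to reverse-engineer.

## Stain model and unmixing

Transmitted light through a two-stain section follows Beer–Lambert:
`I_c = I0_c · 10^(−Σ_s a_{s,c} x_s)` per RGB channel c, with unit-norm
absorption vectors `a_s` and per-pixel stain amounts `x_s`.  We use the
community-standard H-DAB pair, hematoxylin (0.650, 0.704, 0.286) and DAB
(0.269, 0.568, 0.778), both configurable; published references vary by a
few percent between scanners, so treat these as a dialect, not a constant
of nature.  The OD transform is `−log10((I + 1)/255)` — the +1 guard keeps
I = 0 finite.  Unmixing is an unconstrained per-pixel least-squares solve
(pinv of the 3×2 system) with negative amounts clipped to zero; a true
non-negative solve is available (`nnls=True`) and differs only at
near-blank pixels.  The per-pixel reconstruction residual is retained.

The synthetic generator renders `I = 255·10^(−OD) − 1`, i.e. with the same
guard, so the OD transform inverts the float render *exactly*: noise-free
round trips agree to ~1e-15, and the quantized uint8 view adds only ~2e-3
OD.  Tests that claim 1e-6 use the float render; pipeline code uses the
uint8 images.

## Synthetic cohorts — what they emulate, what they do not

An image is textured stroma (faint hematoxylin), random nuclei disks
(full hematoxylin), and a protein-stain mask built by thresholding a
two-scale Gaussian random field (regional scale min(H,W)/8 plus a 4-px
cell scale) at the exact area quantile, so the stained fraction is
controlled to pixel rounding.  Expression levels map to
(stained fraction, DAB OD) pairs: low (0.15, 0.4), medium (0.40, 0.7),
high (0.70, 1.0).  Cohorts assign levels to proteins, render both
conditions, and can shift the cancer renderings' fraction and/or OD
(`effect`) and add within-level parameter jitter (`level_jitter`,
default off) to emulate annotation coarseness.  Camera noise is additive
Gaussian in intensity space, clipped to [0, 255].

Not emulated: real tissue morphology (glands, membranes, cell types),
scanner white-balance variation, chromogen saturation nonlinearity, or
annotation noise.  Passing tests therefore demonstrate that the *pipeline
machinery* is correct and recovers planted signal under a faithful optical
model — not that the feature set would reach any particular accuracy on
real microscopy data.

## Patch extraction and the choice of K

The response map is an exact box-filter mean (integral images) over all
stride-1 origins.  Selection is greedy by descending response with
Chebyshev non-overlap suppression at the patch size; when the admissible
origins are exhausted the separation halves, so overlapping (redundant)
patches appear only once the image's disjoint capacity is exceeded.  We
adopted suppression after finding that literal unsuppressed top-K returns
K near-identical shifts of the argmax window, which makes the K-search
criterion insensitive to K on any image family.  `min_separation=1`
restores the unsuppressed behavior.  Ties break row-major via a stable
sort; extraction is deterministic.

A patch's protein fraction is the percentage of pixels whose protein OD
exceeds a positivity floor (default 0.15 OD — a conventional DAB
threshold; the binarization rule is configurable).  The patch count K is
searched over 11–201 step 10 by pooling, per expression level, the top-K
patch fractions of sampled images and maximizing the repeat-averaged sum
of the three pairwise W₁ distances.  W₁ is computed between the empirical
samples (merged-support CDF integration), not between fitted gamma
densities — the empirical distance is exact and assumption-free; gamma
MLE fits (`fit_gamma`, zeros imputed at half the smallest positive value)
are provided for distribution summaries.  On the scaled study cohort
(600-px images, 45-px patches — the same patch/image ratio as 224 on
3000 px — 10 images per level, 3 repeats) the summed distance rises to an
interior peak and falls, and `d(H,L) = d(H,M) + d(M,L)` holds exactly
because the three level distributions are stochastically ordered.

The Gaussian threshold baseline fits a normal per level and takes the
density crossings between adjacent levels (equal variances → midpoint;
otherwise the root of the log-density quadratic inside the mean
interval).  Thresholding is left-closed upward: a value equal to a
threshold belongs to the upper class; image labels are majority votes over
patches with ties resolved high > medium > low.

## Feature descriptor (1247 components)

Only the block totals are canonical; the internal layouts are this
package's documented dialect:

* **histogram, 1012** = 10×10×10 joint RGB (value·10 // 256 per axis) +
  12-bin hue histogram, each sub-histogram normalized to sum 1;
* **moments, 33** = mean / population variance / skewness / excess
  kurtosis for R, G, B, H, S, V (zero-variance channels score 0) plus
  median / min / max for R, G, B;
* **CCV, 54** = 27 quantized RGB colors (3 levels per axis), 8-connected
  components, coherent iff component size ≥ τ = 25 px (≈0.05% of a
  224×224 patch); (coherent, incoherent) fractions sum to 1;
* **correlogram, 128** = autocorrelogram over 32 HSV colors (4×4×2) at
  Chebyshev ring distances {1, 3, 5, 7}, in-bounds neighbor pairs only,
  empty colors → 0;
* **characteristic curve, 20** = percentage of pixels with hue in
  [20°, 50°) (DAB brown), value in [0.2, 0.95) and saturation strictly
  above s_low, for the 20 bounds 0.10, 0.12, …, 0.48; non-increasing by
  construction.

HSV uses hue ∈ [0, 360), s, v ∈ [0, 1]; gray pixels get hue 0.  Patch-mode
image descriptors are component-wise means of per-patch vectors.

## Feature selection and classifiers

SDA is classic forward stepwise on Wilks' Λ = det(W_S)/det(T_S) with
partial-F thresholds F-enter 3.84 / F-remove 2.71 (≈α 0.05 / 0.10), a
ridge guard 1e-8·tr(W)/p on the scatter matrices (p = 1247 easily exceeds
n), tie-breaks by lowest column index, and default cap
min(p, n − classes − 1) on the selected count.  Λ is recomputed from
submatrix determinants at every step.  Selection runs *inside* each
training fold; a spy-based test asserts it never receives held-out rows.

Classifiers: RBF SVM (inner 3-fold grid search over C ∈ 2⁻³..2⁷ and
γ ∈ 2⁻⁹..2¹ by default, Platt-scaled probabilities at the winner), random
forest (tree count ∈ {100, 300, 500} by default), and a feed-forward
network with two 200-unit hidden layers trained with Adam for 200 epochs
against one-hot targets under squared-error loss, softmax applied at
inference (squared-error training does not itself produce probabilities).
SVM and the network standardize features; inputs to all three come from
the same selected columns.  Class probabilities are reported in the fixed
(high, medium, low) order with argmax ties resolved in that order.

Cross-validation folds group by protein and are stratified by the
protein's modal label: the plain grouped deal leaves each training set
biased *against* its test fold's classes, which drives noise-fit models
systematically below chance on null data — stratification (the
`StratifiedGroupKFold` idea) restores chance behavior without touching
the grouping guarantee.  Metrics are accuracy and macro-averaged
precision / recall / F1 (zero-division → 0), with weighted averaging
available off the default path.

## Screening

Per-image probability vectors are scalarized to the expected ordinal
level `2·p_high + p_medium ∈ [0, 2]`; the expression-change test is a
two-sided pooled-variance t-test between the normal and cancer score
groups (Welch and a per-class Bonferroni variant by flag).  Degenerate
zero-variance groups use the conventions P = 1 (equal means) / P = 0
(unequal), flagged in the output.  Voted levels use majority with
probability-sum then class-order tie-breaks.  A protein is flagged at
P < α (default 0.05, no multiple-testing correction by default — matching
the published screen; Benjamini–Hochberg available by flag).  The bundled
`table1_lbd.csv` transcribes the published 22-protein colon-cancer screen
(expression and per-compartment location P values with their printed
significance marks); at α = 0.05 it yields 14/22 by expression alone and
21/22 (95.45%) combined.

Type-I calibration of the screen is tested at the prediction-vector level
(200 null proteins with Dirichlet-distributed probability vectors, 5
images per condition) rather than through 2 000 rendered images — the
test targets the t-test stage, and the image route would add cost without
changing what is being tested.

## Problem sizes and determinism

Default configuration keeps the published operating point (224-px
patches, K = 81, grid 11–201, 10 folds, α = 0.05).  The test-suite and
acceptance-script study conditions are scaled once and fixed: 96–160-px
images for contracts and round trips, the 600/45 geometry for the
K-search, 30 proteins × 5 images at 128 px for CV recovery, and a 44-
protein 21:18:5 cohort with level jitter (0.12, 0.15) for the imbalance
property.  Every stochastic step takes an explicit seed; images,
extraction, selection and the network are bit-reproducible under a fixed
seed (forest and SVM inner searches are seeded through scikit-learn).

## Known limitations

* Deep-CNN features (pre-trained ResNet/DenseNet embeddings) are out of
  scope; `Dataset` accepts any external per-image feature table, which is
  the extension hook.
* The subcellular-location predictor is not reimplemented; its P values
  are consumed as a table.
* The stain matrix is assumed known; automatic stain-vector estimation is
  not provided.
* Published full-scale accuracy figures depend on thousands of real
  annotated images and are not reproducible from synthetic data; the
  acceptance quantities are property-based substitutes computed at the
  scaled conditions above.
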