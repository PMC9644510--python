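# ihcscreen

Automated classification of protein **expression levels** (high / medium /
low) in immunohistochemistry (IHC) images, and downstream **cancer-biomarker
screening** that combines expression-change significance with
subcellular-location-change significance.

IHC images show a brown DAB chromogen marking the target protein over a
purple hematoxylin counterstain.  Resources such as the Human Protein Atlas
annotate each image with a coarse expression level; proteins whose level or
subcellular location changes between normal and cancerous tissue are
candidate biomarkers.  `ihcscreen` implements the full pipeline:

1. **Stain unmixing** — optical density `OD = −log10((I+1)/255)` per channel;
   stains mix linearly (Beer–Lambert), so a per-pixel least-squares solve
   against the H-DAB stain matrix yields protein and nuclear concentration
   maps.
2. **Patch extraction** — a mean filter slid over the protein channel scores
   every 224×224 window; the K highest-response windows (greedy, with
   non-overlap suppression that relaxes only when the image's disjoint
   capacity is exhausted) are the patches of interest.  K is selected by
   maximizing the summed pairwise first-order Wasserstein distance
   `W₁(F_a, F_b) = ∫|F_a⁻¹(q) − F_b⁻¹(q)| dq` between the per-level
   distributions of patch protein-fraction values over a grid of candidate
   K (default 11–201 step 10; shipped operating point K = 81).  Gaussian
   fits of the per-level fraction distributions and their density
   intersections give a simple threshold baseline classifier.
3. **Features** — a 1247-dimensional handcrafted color descriptor per image
   or patch: 1012 histogram + 33 moment + 54 color-coherence-vector +
   128 color-correlogram + 20 characteristic-curve components, where the
   characteristic curve is the fraction of stain-colored pixels
   (h₁ ≤ h < h₂, v₁ ≤ v < v₂, s > s_low) as the saturation floor s_low
   rises.
4. **Selection + classification** — stepwise discriminant analysis (forward
   Wilks' Λ = det(W_S)/det(T_S) with partial-F entry/removal) inside each
   training fold, then RBF-SVM, random-forest or a 2×200 MSE-trained
   feed-forward network, evaluated under protein-grouped stratified
   10-fold cross-validation (all images of a protein share a fold).
5. **Screening** — per protein, voted levels per condition and an
   independent two-sample t-test on the expected ordinal expression score
   `s = 2·p_high + p_medium` between the n normal and m cancer images;
   a protein is a biomarker when its expression P value or any
   compartment's location-change P value (consumed as a table) falls
   below α = 0.05.

A synthetic cohort generator renders two-stain tissue images through the
exact Beer–Lambert forward model (with ground-truth stain masks), so every
stage is testable end-to-end without any image download.

## Worked example

```python
import numpy as np
from ihcscreen import (
    CohortSpec, SyntheticSpec, generate_cohort, PipelineConfig,
    run_pipeline, load_table1, screen_pvalues,
)

# 1) published screen: expression + location P values of the 22-protein LBD
rows, rate = screen_pvalues(load_table1())
print(f"expression biomarkers: {sum(r.expression_flag for r in rows)}/22")
print(f"combined biomarkers : {sum(r.biomarker_flag for r in rows)}/22 ({rate:.2f}%)")

# 2) synthetic cohort end-to-end: 8 proteins; cancer shifts the rendering
#    by one full expression level (stained fraction +0.3, stain OD +0.3)
images, manifest = generate_cohort(CohortSpec(
    n_proteins=8, images_per_protein=4, effect=(0.3, 0.3),
    image_spec=SyntheticSpec(width=96, height=96, n_nuclei=10), seed=1,
))
result = run_pipeline(
    manifest,
    PipelineConfig(model="rf", folds=4, rf_tree_grid=(100,), sda_max_features=6),
    out_dir="demo_out",
    images={im.image_id: im.pixels for im in images},
)
print(result["report"].summary())
print(f"synthetic detection rate: {result['detection_rate']:.1f}%")
```

Output:

```
expression biomarkers: 14/22
combined biomarkers : 21/22 (95.45%)
accuracy  : 0.8594
recall    : 0.8472 (macro)
precision : 0.8528 (macro)
F1-score  : 0.8496 (macro)
confusion (rows true, cols predicted; order high/medium/low):
  high        12      4      0
  medium       3     20      1
  low          0      1     23
synthetic detection rate: 87.5%
```

The first two lines screen the bundled transcription of the published
22-protein literature biomarker dataset: 14 proteins change expression
significantly, and adding the location route flags 21 of 22 (95.45%).  The
cross-validation block shows held-out predictions on the synthetic cohort —
cancer renderings shifted by a full level collide with the adjacent class,
which is exactly the confusion the screen then detects: 7 of 8 proteins
(87.5%) reach expression-change significance.

## Command line

```bash
ihcscreen synth --n-proteins 6 --images-per-protein 3 --size 512 --out-dir cohort/
ihcscreen unmix cohort/prot000_normal_00.png --out protein.tiff
ihcscreen patches cohort/prot000_normal_00.png --k 81 --size 224 --out patches.csv
ihcscreen select-k cohort/manifest.csv --size 224 --out ksearch.csv
ihcscreen features cohort/manifest.csv --out features.csv
ihcscreen cv cohort/manifest.csv --model svm --folds 10 --out-dir cv_out/
ihcscreen screen cv_out/predictions.csv cohort/manifest.csv --out screen.csv
ihcscreen run cohort/manifest.csv --out-dir full_out/
```

## Layout

```
src/ihcscreen/
  synthetic.py   # Beer–Lambert cohort generator with ground truth
  unmixing.py    # H-DAB linear spectral unmixing
  patches.py     # response map, top-K patches, W1 K-search, thresholds
  features.py    # the 1247-component color descriptor
  selection.py   # stepwise discriminant analysis (Wilks' Λ)
  classify.py    # SVM / RF / DNN + protein-grouped CV + metrics
  screening.py   # voting, expression-change t-test, biomarker flags
  config.py      # YAML pipeline configuration
  pipeline.py    # unmix → patches → features → cv → screen
  cli.py         # `ihcscreen` subcommands
  data/table1_lbd.csv  # transcribed published LBD screen (P values)
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
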