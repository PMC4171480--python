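# tmahet

Quantification of intra-tumoural biomarker heterogeneity from
multi-channel immunofluorescence images of tissue-microarray (TMA)
cores, with survival modelling of the resulting high-dimensional
feature distributions.

The package is aimed at image-analysis and biostatistics groups working
with fluorescence TMA cohorts of small-round-cell tumours (the
motivating setting is Ewing sarcoma, where DAPI marks nuclei, CD99
delimits the cytoplasm, and markers such as Ki67, EGR1, Foxo3a or pS6
report proliferation and signalling).  It covers the full chain:

1. **Segmentation** (`tmahet.segment`) — nuclei from DAPI by Otsu
   initialisation of a region-based morphological level set plus a
   distance-transform watershed to split clumps; cytoplasm from CD99 by
   marker-controlled watershed on the intensity gradient, bounded by
   the Voronoi partition between neighbouring nuclei.  Validation via
   Bland-Altman agreement of areas and Hausdorff boundary distances.
2. **Quality control** (`tmahet.qc`) — twelve high-content-screening
   features on the DAPI channel (inverse coefficient of variation
   mean/SD, focus score Var/mean, 8-level GLCM correlation, and the
   power log-log slope over the whole spatial-frequency range and in
   eight bands), feeding a logistic good/poor classifier evaluated by
   leave-one-out ROC/AUC.
3. **Features** (`tmahet.features`) — per-cell compartment intensities
   and log2 nucleus/cytoplasm ratios; CD99 positivity (mean cytoplasmic
   CD99 strictly above nuclear); the per-patient Ki67 index (fraction
   of CD99⁺ cells that are Ki67⁺ under ratio thresholds); and each
   patient's cell-feature distributions encoded as Gaussian
   kernel-density estimates evaluated at 100 equally spaced points of a
   cohort-wide grid, stratified by CD99 status.
4. **Cut-point analysis** (`tmahet.cutpoint`) — the conventional
   dichotomisation workflow: an exhaustive Cox p-value grid over all
   centile pairs of the CD99/Ki67 ratio thresholds, a log-rank scan
   over every dichotomised patient split, and Kaplan-Meier curves.
   Scanning the grid for the minimum p is a massive implicit multiple
   test; the module quantifies exactly how anti-conservative that
   minimum is under a survival-independent null.
5. **Random survival forest** (`tmahet.rsf`) — bagged survival trees
   with the log-rank random splitting rule (random candidate split
   points per sampled feature, mtry = ⌈N/3⌉), Nelson-Aalen terminal
   hazards, out-of-bag Harrell concordance error (0 = perfect, 0.5 =
   chance), variable-hunting feature selection over repeated 80/20
   partitions with selection-frequency ranking, and randomised
   two-thirds/one-third cross-validation.
6. **Synthetic cohorts** (`tmahet.synth`) — elliptical-cell
   multi-channel images with exact ground truth, focus/noise
   degradation, and survival cohorts whose hazard depends log-linearly
   on a planted cell-subpopulation fraction — so every stage above is
   testable end to end without any external image download.
7. **Pipeline** (`tmahet.pipeline`) — one config drives
   synthesis/loading → QC filtering (a case stays informative while at
   least one image passes) → segmentation → features → cut-point and
   forest analyses, with full cohort accounting in the run report.

## The statistic at the core

For a patient with covariate (feature) vector x the forest predicts a
mortality score M(x) = Σₖ Ĥ(tₖ | x), the ensemble Nelson-Aalen
cumulative hazard summed over the training event times tₖ.  Model error
is 1 − C with Harrell's concordance

C = ( Σ_{comparable pairs (i,j)} [ 1(Mᵢ > Mⱼ) + ½·1(Mᵢ = Mⱼ) ] ) / #comparable,

where pair (i, j) is comparable when subject i dies strictly before
subject j's observed time (or at the same recorded time at which j is
censored).  Out-of-bag evaluation scores every subject only with trees
whose bootstrap sample omitted it.

## Worked example

```python
import numpy as np
from tmahet import synth, segment, features, cutpoint, rsf

# 1. synthetic image -> segmentation -> cell features
spec = synth.SyntheticImageSpec(image_size=256, n_cells=10, noise_sigma=2.0, seed=7)
image, truth = synth.generate_image(spec)
seg = segment.segment_cells(image)
cells = features.extract_cell_features(image, seg)
print(f"segmented {seg.n_cells} cells (truth: {len(truth.cell_table)})")
print(f"CD99-positive fraction: {cells['cd99_positive'].mean():.2f}")

# 2. cohort-level cut-point analysis on a planted prognostic subpopulation
cells2, survival, frac = synth.sample_ratio_cohort(60, 150, log_hazard_coef=2.0, seed=17)
grid = cutpoint.threshold_grid_cox(
    cells2, survival,
    cd99_centiles=range(5, 100, 5), ki67_centiles=range(5, 100, 5))
opt = grid.optimal
print(f"optimal pair: CD99 {opt['centile_cd99']:.0f}%tile, "
      f"Ki67 {opt['centile_ki67']:.0f}%tile, "
      f"b = {opt['coef']:.2f}, z = {opt['z']:.2f}, p = {opt['p']:.2g}")

# 3. patient KDE features -> random survival forest
pdf = features.patient_distribution_features(
    cells2.assign(cd99_positive=cells2["cd99_log2_nc_mean"] < 0),
    ["cd99_log2_nc_mean", "ki67_log2_nc_mean"])
X = pdf.flat().fillna(0.0)
surv = survival.set_index("patient_id").loc[X.index]
model = rsf.fit_rsf(X, surv["time_days"], surv["event"],
                    rsf.RSFParams(n_trees=500, seed=1))
print(f"feature vector length: {X.shape[1]}")
print(f"OOB concordance error: {model.oob_error:.3f}")
```

prints

```
segmented 10 cells (truth: 10)
CD99-positive fraction: 1.00
optimal pair: CD99 90%tile, Ki67 10%tile, b = 15.01, z = 3.95, p = 8e-05
feature vector length: 600
OOB concordance error: 0.401
```

All ten planted cells are recovered and (with no planted CD99-low
population in this image) every cell is CD99-positive.  The cut-point
scan finds a strongly "significant" pair — its p-value is the minimum
of 361 correlated tests, which is precisely the bias the module is
built to expose.  The forest, which needs no threshold at all, reaches
an out-of-bag concordance error of 0.40 against the chance level 0.5
from the two 100-point ratio-distribution vectors per CD99 stratum
(600 features for 60 patients).

A shell interface mirrors the stages
(`tmahet synth|segment|qc|features|cutpoint|rsf|pipeline ...`); see
`tmahet --help`.

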