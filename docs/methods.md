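# Methods

This note records the models, parameter choices and numerical
conventions behind `tmahet`, and what the synthetic validation does and
does not establish about real tissue data.

## Synthetic image and cohort model

Cells are rendered as elliptical nuclei (semi-major axis 8–13 px at the
512-px default scale, eccentricity bounded so axes differ by at most
30%) inside concentric elliptical cytoplasms (thickness 4–8 px).  Each
compartment of each cell receives one intensity value drawn from a
truncated normal per-channel model (`ChannelModel`); the default
baseline channels are DAPI 180/20 (nuclear/cytoplasmic mean), CD99
30/120 and Ki67 30/60 on a background of 8 intensity units, with
cell-to-cell SDs of 8–15.  The planted prognostic subpopulation flips
CD99 to 30/22 (CD99-low) and Ki67 to 120/40 (Ki67-positive, log2 N/C
ratio ≈ +1.6).  These values were chosen once to give compartment
contrasts comparable to well-stained immunofluorescence (nuclear stain
~20:1 over background, marker ratios within ±2 on the log2 N/C scale)
and are not revisited per experiment.

Placement is sequential rejection sampling.  Disjoint cells enforce a
centre distance of at least the sum of outer radii + 1 px; a
configurable `overlap_fraction` of cells is instead attached to a
random earlier cell at 0.75 of that distance, producing clumps of 2–3
whose nuclei nearly touch (the input the watershed correction is
tested on).  Contested pixels in clumps belong to the later-drawn cell;
the per-cell ground-truth means are therefore measured on the *final*
masks of the rendered noiseless image, which keeps the ground truth
exact by construction.  Degradation is Gaussian blur (out-of-focus
surrogate) plus additive Gaussian noise, optionally Poisson; images are
clipped at 0.

Survival is exponential given the covariate: patient hazard
λ(f) = λ₀·exp(b·f) with f ~ Beta(2, 4) the planted subpopulation
fraction, λ₀ = 1/1500 days⁻¹ and b = 1.5 by default, censored by an
independent exponential at rate 1/4000 days⁻¹ (≈70–80% observed
events, median follow-up of a few years — the shape of a sarcoma
outcome cohort).  Setting b = 0 gives the survival-independent null
used for calibration; setting the censoring rate to 0 observes every
event.  `sample_ratio_cohort` skips rendering and draws cell-level log2
N/C ratios directly from the two-component mixture implied by the
channel models (baseline CD99 ratio ≈ −2, Ki67 ≈ −1; subpopulation
CD99 ≈ +0.5, Ki67 ≈ +1.5, SDs 0.4–0.5); it exists so the survival
modules can be exercised at cohort scale in seconds.

What the generator does *not* emulate: stromal architecture and
texture, intensity vignetting/bias fields, chromatic registration
error, 3-D sectioning artefacts, and the heavy-tailed staining
variability of archival material.  Passing tests therefore demonstrate
correctness of the algorithms under their stated models, not
performance on arbitrary archival TMAs.

## Segmentation

Nuclei: Otsu's threshold initialises a morphological Chan-Vese level
set (region-based family; 25 iterations, smoothing 2).  Morphological
evolution was chosen over a PDE formulation for determinism and speed;
the iteration cap and smoothing are exposed in `NucleusParams`.  The
refined foreground is hole-filled and split by watershed on the
Gaussian-smoothed (σ = 2 px) Euclidean distance transform, seeded at
regional maxima with a minimum separation of 7 px.  Objects under
30 px² (512-px scale) and border-touching objects are removed — partial
cells would bias the area and intensity distributions.  Flood order and
seed labelling are deterministic.

Cytoplasm: the CD99 foreground is Otsu-thresholded (override available),
forced to include all nuclei, and partitioned by marker-controlled
watershed on the Sobel gradient of the σ = 1 px smoothed channel,
seeded from the nuclei.  Assignments are clipped to each nucleus's
Voronoi cell (nearest-nucleus partition via the distance transform), so
no cytoplasm crosses the equidistant boundary between neighbours; with
a flat gradient the boundary falls exactly on the perpendicular
bisector.  Cells left without cytoplasm (e.g. a blank marker channel)
are retained with zero area and flagged, never imputed.

Validation utilities follow agreement-analysis practice: Bland-Altman
mean difference with mean ± 1.96 sample-SD limits (A − B convention),
and the symmetric Hausdorff distance (max of the two directed max-min
boundary distances), in pixels or µm.

## Quality-control features

x1 = mean/SD and x2 = variance/mean use the population (1/n) variance —
the convention is recorded here because the two differ at small n and
either is defensible.  x3 quantises intensities into 8 equal-width
levels over the observed range and averages the Haralick correlation of
the symmetric GLCM at 1-px offset over the horizontal and vertical
directions.  x4 regresses log10 squared FFT magnitude on log10 radial
frequency over every non-DC coefficient (orientation ignored); x5–x12
repeat the fit in 8 equal-width bands of log10 frequency between the
lowest non-DC radial frequency and the radial Nyquist.  A band with
fewer than two distinct frequencies yields NaN; an all-zero or
single-level image raises a degenerate-image error rather than
returning a number.  The classifier is plain maximum-likelihood
logistic regression on standardised features (ridge available for
separable data); LOOCV refits the model once per held-out image and the
ROC/AUC is a threshold sweep with trapezoid integration, which equals
the Mann-Whitney U statistic normalised by the number of
good × poor pairs.

## Cell features and distribution encoding

Totals are sums over compartment pixels; means are totals/area.  Log2
nucleus/cytoplasm ratios add a pseudocount of 1 intensity unit to both
compartments, keeping ratios finite for dim cells; a cell with *no*
cytoplasm gets NaN and a flag instead.  CD99 positivity is the strict
rule mean cytoplasmic > mean nuclear.  The Ki67 index supports both
that fixed rule and centile thresholds on the pooled log2-ratio scales
(CD99-positive below the CD99 ratio threshold — cytoplasm-dominant —
and Ki67-positive above the Ki67 threshold); the rule is a required
argument because the two are not interchangeable.  An empty denominator
raises `UndefinedIndexError`.

Per patient and stratum (all / CD99⁺ / CD99⁻), cell values pooled over
all the patient's images are encoded as a Gaussian KDE with
Scott's-rule bandwidth, evaluated at 100 equally spaced points of a
grid fixed *before* any per-patient evaluation: the pooled
cross-patient [0.5th, 99.5th] percentile range of the feature.  The
robust bounds keep one outlier cell from stretching every patient's
grid; grid identity across patients is what makes position k of one
patient's vector comparable with position k of another's (features are
named by grid centile, e.g. `cd99_neg` Ki67 mean N/C ratio at the 63rd
grid point).  Strata with fewer than 5 cells give an all-NaN vector —
a KDE on fewer points is noise; the pipeline later encodes such missing
strata as zero density for the forest.  A zero-variance sample is
treated as a near-delta (Gaussian of one grid-step bandwidth) because
the sample covariance the KDE needs is singular there.

## Cut-point analysis

The single-covariate Cox solver is a Newton-Raphson maximiser of the
Efron-tied partial likelihood with centring, step-halving and a ±5 step
clip; convergence is |Δβ| < 1e-10 within 60 iterations.  Efron was
chosen over Breslow as the standard default for tied survival data.
The solver exists because the centile grid fits ~10⁴ models
(99 × 99 pairs by default); lifelines reproduces its estimates to
~10⁻⁶ and serves as the oracle in the test suite.  Grid cells whose
Ki67 indices are undefined for a patient drop that patient; cells that
end degenerate (constant index, < 2 events, < 3 patients) are marked
invalid (NaN) and excluded from the optimum.  No multiple-testing
correction is applied inside the grid — exposing the uncorrected
minimum-p bias is the module's purpose — but
`permutation_adjusted_min_p` provides an honest family-wise p when one
is wanted.  The log-rank scan enforces a minimum group size of 5 per
side to avoid degenerate extreme splits.  Kaplan-Meier curves and
Greenwood-type (exponential log-log) confidence intervals come from
lifelines.

## Random survival forest

Trees are grown on bootstrap samples (with replacement, original size).
At each node, ⌈N/3⌉ features are sampled; for each, 10 candidate split
values are drawn from the node's observed values, and the (feature,
value) pair maximising the two-group log-rank statistic wins —
the "log-rank random" rule.  Splits must leave ≥ 3 observed events in
each child (configurable); a node that cannot split becomes terminal
with a Nelson-Aalen cumulative hazard estimated from its in-bag
samples and evaluated on the grid of all training event times.
Mortality is the ensemble cumulative hazard summed over that grid; the
predicted survival curve is exp(−H̄(t)), supported up to the last
training event time.  OOB error uses, for each subject, only the trees
that omitted it.  All randomness flows from one seed through spawned
sub-streams (one per tree, plus partition streams), so identical seeds
reproduce forests, errors and selection counts exactly.  Internally,
subjects are kept time-sorted so each node's risk table and all
candidate splits are scored in one vectorised pass; 1000 trees on
100 × 50 data fit in a few seconds on one core.

Variable hunting repeats, for `n_iter` (default 100) iterations: draw a
random 80/20 partition; grow a forest on the 80% part and rank the
features by *minimal depth* (the depth of a feature's first split,
averaged over trees, with unused features penalised one past the
deepest level) — the importance the variable-hunting procedure in the
RSF literature uses, and effectively free to compute; then introduce
features in rank order, keeping each while the model's error on the
held-out 20% strictly decreases, stopping otherwise (the explicit
operationalisation of "until no significant features remain"), capped
at 20 features.  Selection counts aggregate over iterations; ranking is
by descending count with ties broken by feature order.  Randomised
cross-validation repeats (default 50×) a two-thirds/one-third random
partition, optionally runs variable hunting confined to the training
part (default 10 VH iterations inside CV — 50 × 100 would be
disproportionate to what the check needs), and scores the held-out
concordance error.

Concordance convention (Harrell): pair (i, j) comparable iff
tᵢ < tⱼ with subject i's event observed, or tᵢ = tⱼ with i dead and j
censored; prediction ties count ½; tied-time double-event pairs are not
comparable.  This matches scikit-survival's estimator, which the tests
use as an independent oracle alongside brute-force enumeration.

A practical note on calibration: on survival-independent features the
OOB error centres slightly above 0.5 (typically 0.51–0.54 at n = 100)
— the familiar behaviour of internal error estimates of a null model
that fits spurious in-bag structure — and this is the regime the
chance-level checks accept.

## Pipeline

QC modes: `none`, `manual` (pass/fail labels in the manifest), or
`classifier` (logistic QC model trained on the manifest's labelled
images, threshold P(poor) = 0.5).  A case is informative while at least
one of its images passes; eliminated percentages are reported rounded
to the nearest integer with the exact fraction alongside.  Images
failing QC never reach feature extraction or any downstream analysis.
The forest stage requires ≥ 20 patients and ≥ 5 events; below that the
report records the patient count it was given and marks the stage
skipped rather than fitting an unstable model.  The config is echoed
verbatim into every run directory and unknown keys are rejected, so a
run is reproducible from its outputs.

## Problem sizes used in the checked examples

Tests run at deliberately desk-scale sizes chosen as the package's own
defaults for continuous verification: 96–256-px images with 2–40
cells, cohorts of 20–200 patients, forests of 25–1000 trees, 20 × 20
to 99 × 99 centile grids, 50 cross-validation repetitions and 100
variable-hunting iterations (25-tree forests inside the
selection loop).  The acceptance script uses the full 1000-tree,
50-feature, 100-patient null-calibration configuration.

## Known limitations

- The level-set stage is a morphological approximation of the
  region-based family; boundaries of any specific legacy pipeline are
  not reproduced exactly.
- Flat-field/bias-field correction is not applied by default; strong
  vignetting should be corrected upstream.
- The forest handles right censoring only — no competing risks,
  time-varying covariates, or left truncation.
- Cut-point and forest analyses treat the patient, not the image, as
  the unit; image-level correlation within a patient is absorbed by
  pooling cells before the KDE.
- The weighted residualisation of ratios on total intensity sometimes
  used to de-trend staining strength is not part of the default
  pipeline.
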