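# Methods

This note documents the models, conventions and numerical choices behind
`qsmradiomics`, in the order the pipeline runs. It is the place to look
when a result depends on a convention the field leaves open.

## Inputs and coordinate conventions

The pipeline starts from a reconstructed 3D susceptibility volume (ppm)
and a co-registered binary VOI mask; susceptibility reconstruction and
VOI segmentation are upstream of this package. Volumes travel as NIfTI-1
float32 with voxel spacing in the header (default 0.86 × 0.86 × 1.0 mm);
masks as NIfTI uint8 0/1. Voxel indices are 0-based and "slice" means
the third (axial) array axis. Texture distances are measured in voxel
steps on the lattice, ignoring anisotropic spacing; physical spacing
enters only the shape features and TotalEnergy. This is the standard
lattice-based convention for gray-level matrices.

## Discretization

Texture features require integer gray levels. The default policy is a
fixed bin count of 16 over the VOI's own [min, max]:
`level = 1 + floor((x − min)/(max − min) · N)`, with the maximum clamped
into bin N. A constant VOI yields the single level 1. A fixed-bin-width
policy (`level = 1 + floor((x − min)/w)`, w in ppm) is available in the
config for sensitivity analyses.

Why 16: reference radiomics tooling defaults to a fixed bin width of 25
units, and susceptibility expressed in ppb over the ~0.3–0.4 ppm VOI
ranges implied by the reported group statistics yields roughly 12–16
levels. A relative (bin-count) policy was preferred because QSM values
in ppm make any absolute width dataset-dependent; 16 levels also keeps
run- and zone-statistics non-degenerate for VOIs of ~500–650 voxels
(~35 voxels per level rather than ~17 at 32 levels).

## Direction scheme

GLCM and GLRLM are computed along the 13 unique axes of the 3D
26-neighbourhood at distance δ = 1 — the three axial offsets, six face
diagonals and four body diagonals, one representative per (offset,
−offset) pair — and per-direction feature values are averaged.
Pair counting is symmetrized (transpose added) and run counting is
insensitive to traversal direction, so the choice of representative sign
does not affect any feature. GLCM directions with no valid voxel pair
are dropped from the average. GLSZM, GLDM and NGTDM are direction-free
and use full 26-connectivity.

## Feature definitions and degenerate conventions

The 105-feature roster is 18 first-order + 13 shape + 74 texture
(GLCM 23, GLDM 14, GLRLM 16, GLSZM 16, NGTDM 5), matching the standard
open-source feature definitions. Conventions that matter:

- Percentiles use linear interpolation between order statistics
  (`numpy.percentile` default); first-order Entropy/Uniformity are
  computed on the discretized histogram, log base 2; Kurtosis is
  non-excess; Variance and the SD inside Skewness/Kurtosis are
  population moments.
- `0·log 0 = 0` throughout; sums with `1/i²` or `1/j²` terms run only
  over non-empty cells; GLCM InverseVariance excludes the diagonal.
- Degenerate VOIs: a constant VOI has Entropy 0, Uniformity 1,
  JointEntropy 0, MaximumProbability 1; Skewness/Kurtosis of a constant
  or single-voxel VOI are 0; GLCM Correlation of a single-level matrix
  is 1; Imc1 is 0 when HX = HY = 0; NGTDM Coarseness returns 10⁶ when
  its denominator vanishes. All are logged at debug level.
- Shape: Volume is the raw voxel count (the scale on which the group
  table reports it); SurfaceArea comes from marching cubes on the
  zero-padded mask at physical spacing; Sphericity and
  SurfaceVolumeRatio use the physical volume (count × voxel volume).
  Diameters are maximal pairwise distances between voxel centres in
  physical coordinates (a single voxel has diameter 0); the 2D diameters
  group voxel centres by slice/column/row index. Axis lengths are
  4·√eigenvalue of the voxel-centre covariance (sample covariance);
  a planar mask has Flatness 0, a single voxel has all axis lengths 0.
- GLDM: a neighbour is dependent when its level equals the centre's
  (α = 0); the matrix stores voxels of level i with j dependent
  neighbours in column j+1, and feature formulas use the 1-based column
  index (dependence size including the centre).

## Synthetic cohort

The generator defines the study conditions for every downstream test;
no real data are shipped. Defaults: 87 patients vs 77 controls on a
64 × 64 × 12 grid at 0.86 × 0.86 × 1.0 mm.

**Mask.** Each subject has a bilateral VOI: two mirrored, rotated,
per-slice-jittered elliptical blobs spanning exactly four axial slices,
with total voxel count drawn per class from the reported volume
distributions (519.5 ± 128.7 vs 629.1 ± 129.6). The reported volumes are
consistent with a combined left+right mask, and a two-component VOI also
halves the sampling noise of texture statistics.

**Intensity field.** A Gaussian random field (smoothing σ = 0.6 voxels
for spatial correlation) is mapped through a monotone quantile transform
to a gamma marginal (shape 3, skewness ≈ 1.15): iron-laden tissue has a
long high-susceptibility tail, and a right-skewed marginal is what makes
low-gray-level texture features carry mass, as the reported magnitudes
of the run-length features require. The top 0.5% of the marginal is
clipped — a saturation ceiling that keeps per-subject [min, max]
discretization ranges stable. The field is anchored at a low-tissue
baseline (the VOI 10th-percentile scale, ~0.0225 ppm IPD vs ~0.0195 ppm
HC, between-subject SD 0.004) and between-subject severity variation
multiplies the scale of the distribution *above* the anchor
(scale 0.072/0.0655 ppm, CV 0.27). This anchored-scale structure
reproduces a pattern visible in the reported table: the 10th percentile
varies less across subjects (SD 0.007) than the median (SD 0.016) —
iron load varies, baseline tissue does not.

**Nigrosome pocket.** Each hemisphere contains an elongated band
(in-plane anisotropic nearest-k region, 10% of the hemisphere VOI) that
is relatively homogeneous (residual variability damped to 0.35 of the
field scale) and offset below the anchor by a continuous per-subject
depth: relative depth ~ N(0.55, 0.22) in HC versus N(0.10, 0.20) in IPD
(clipped at 0), scaled by 0.045 ppm. Depth is continuous rather than
present/absent because the nigrosome does not vanish discretely — its
conspicuity declines; the binary radiologist's reading (sign visible in
67.5% of HC vs 9.2% of IPD) corresponds to thresholding this depth, and
a binary mixture would inflate within-class variance far beyond the
reported SDs.

**Motor score.** Patients get a UPDRS-III-like score (25 ± 10,
unitless — correlation is scale-free) coupled to the latent anchor
deviate with population correlation 0.35, so the reported
feature–severity correlation is recoverable. In the image cohort the
measured correlation is slightly attenuated (~0.31–0.33) because the
extracted 10th percentile adds measurement noise to the latent anchor.

**Calibration against the reported statistics.** At defaults, across
seeds: per-feature AUCs of the five representative features ~0.77/0.65/
0.74/0.68/0.72 versus reported 0.75/0.68/0.73/0.64/0.71; group means of
the 10th percentile ≈ 0.020 vs 0.013 ppm and median ≈ 0.081 vs 0.073 ppm
(reported 0.023/0.015 and 0.076/0.066); 24–41 of 105 features
significant at the Bonferroni threshold per seed, versus 29 of the 40
selected in the study; pooled CV AUC 0.89–0.97 versus the reported
0.96 ± 0.02.

**What the generator does not emulate.** MRI physics (noise spectra,
phase processing, reconstruction artifacts), anatomy beyond a two-blob
VOI (no red nucleus, no segmentation variability), inter-hemispheric
asymmetry of disease onset, and any subject covariates (age, sex).
Passing tests therefore demonstrate correctness and calibrated behaviour
of the *pipeline*, not clinical performance on real QSM.

A second generator bypasses image synthesis entirely and draws the five
representative features from class-conditional Gaussians at the reported
means/SDs (other 100 columns are standard-normal nuisance). It backs the
tests with closed-form oracles — e.g. the binormal AUC
Φ(Δμ/√(σ₁²+σ₂²)) — where an image model would only add noise.

## Feature selection

ANOVA F (for two groups, F = t²), 10-tree random-forest impurity
importance (unlimited depth, √p features per split, fully seeded), and
RFE with a linear SVM (C = 1, features standardized internally, one
feature eliminated per round on smallest squared weight, ties dropping
the later canonical column). Rank = reverse elimination order; the
training-accuracy curve has one point per retained-set size (105
points). Ensemble rank is the arithmetic mean of the three; ties break
by best single-method rank, then canonical order. Ranking is performed
once on the full sample — this stage estimates importance, not
generalization, mirroring the study design — and a leakage-safe mode
(selection refit inside each training fold) is available via
`StudyConfig.leakage_safe_selection` for honest generalization
estimates.

## Classification

Standardization (population SD; constant columns map to 0) and PCA (all
components, fitted on the training fold only) precede an RBF-SVM with
C = 30, γ = 0.001. Folds are stratified by class (the 164-subject,
3-fold split gives test folds of 55/55/54 and training sets of 109/110);
shuffling is re-seeded per repetition from the config seed, so a fixed
seed reproduces the entire report bit for bit. A `paper_mode` flag
instead fits scaler and PCA once on the full sample before splitting,
for comparison with the original single-pipeline description. AUC is
the Mann–Whitney rank statistic with half credit for ties, computed
from the SVM margin; hard labels use the SVM's threshold 0. Pooled
metrics are mean ± sample SD (ddof = 1) over all fold records;
per-repetition means are also emitted. A test fold containing one class
records its AUC as missing and is excluded from the AUC pool (logged).

## Group statistics

The t-test defaults to the classical equal-variance form (Welch by
flag); zero-variance features degenerate to p = 1 (equal means) or the
p = 0 limit. Per-feature AUC is reported as max(AUC, 1 − AUC) with a
direction flag, matching the convention of printing all AUCs on the
≥ 0.5 side. The sign-reading analysis is pure contingency arithmetic on
supplied counts — presence of the sign calls the subject a control, so
sensitivity is the fraction of controls showing the sign and specificity
the fraction of patients lacking it; no image-based sign detector is
built. From the study's counts (52/77 and 8/87) this gives accuracy
79.88%, sensitivity 67.53%, specificity 90.80% (the source text prints
both 67.52% and 67.53% for 52/77; the arithmetic gives 67.53% at two
decimals).

## Problem sizes used in the test suite

Oracle-equivalence tests run the full brute-force comparison on 100
random VOIs of up to 6 × 6 × 4 voxels; pipeline-level tests use the
full 164-subject cohort for protocol checks and 10 full cohorts for the
selection-stability check; simulation-based statistical tests use 200
replicate cohorts where a closed form exists to compare against. These
sizes make every Monte-Carlo tolerance a ≥3-SE band.

## Known limitations

- Selection stability: with all reported group statistics reproduced,
  the five representative features are *individually* selected into the
  top 40 in most seeds, but their *joint* membership is unstable
  (roughly 1–2 seeds in 10). Volume-coupled and pocket-coupled feature
  families provide ~40–60 competitors of comparable strength, and
  random-forest importance splitting plus RFE redundancy pruning
  randomize mid-field ranks across cohort draws. This reflects a real
  property of ensemble selection on correlated radiomic features, not a
  defect of the ranking code: a single-dataset selection outcome is not
  a stable population property at these effect sizes.
- The per-feature AUC of the 10th percentile in the *image* cohort runs
  above the binormal value implied by the printed means/SDs (the pocket
  makes the HC low-quantile distribution left-skewed rather than
  Gaussian); the Gaussian-table generator is the faithful route for
  checks pinned to the printed numbers.
- Shape features use voxel-centre conventions for diameters; tools that
  measure diameters on mesh vertices report slightly larger values
  (about one voxel diagonal).
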