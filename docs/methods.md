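# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, and what the synthetic cohort does
and does not establish about real data.

## Geometry

Volumes are (x, y, z) grids with x the left-right axis and index 0 the
left-most slice. The mid-sagittal plane is declared once, between
columns L/2−1 and L/2 of an even-sized x axis, so mirroring is an exact
voxel permutation with no ambiguous centre voxel. Every mirror/flip
operation (atlas construction, hemispheric alignment, mask mirroring)
uses this single definition; odd-sized x axes are rejected.

## Synthetic cohort generator

The generator emulates the statistical structure a lesion-decoding
analysis assumes, at desk scale (default 32³ grid; all operations are
shape-agnostic):

- **Atlas**: n mirrored region pairs (spheres placed in the left
  hemisphere and reflected) plus a tube-shaped corticospinal-tract (CST)
  pair running inferior–superior. A configurable fraction of pairs
  (default 40%) is flagged *motor*. Default region radii are scaled to
  the grid (up to 4.5 voxels on 32³).
- **Lesions**: one ellipsoidal blob per subject, centred at a random
  in-brain voxel, log-uniform target volume in `size_range`
  (default 120–2500 voxels — highly variable extent), probabilities
  decaying from ~1 to 0 over `edge_softness` voxels via a sigmoid of
  normalized ellipsoid distance; confined to one hemisphere with
  probability `unilateral_prob` (default 0.9).
- **Scores**: a latent damage score gᵢ = −effect_scale · Σ_v β(v)pᵢ(v),
  mapped to four clinical scales by per-scale slope and intercept, plus
  N(0, noise_sd) noise, then clipped to each scale's floor/ceiling.
  NHPT (a timed test) has a negative slope, so the PCA sign convention
  is genuinely exercised. Defaults: ARAT [0, 57] slope +40 int. 50;
  GS [0, 100] +60/80; MI [0, 100] +70/85; NHPT [0, 120] −60/30, in
  clinical units, with noise_sd = 5 by default (package-wide realistic
  choice; the tested decoding conditions use noise_sd = 2 with
  effect_scale = 3, a moderate-noise regime).

Two properties of β deserve emphasis:

- **Mirror symmetry.** β is symmetrized about the mid-sagittal plane
  (support still restricted to the signal regions). Without this, the
  canonical right-flip would scramble the lesion–score relationship for
  flipped subjects; symmetry encodes the premise that damage to a
  structure matters regardless of hemisphere — the same premise that
  justifies flipping in the analysis.
- **Focal structure.** By default (`beta_mode="focal"`) each signal
  region carries one compact Gaussian bump (scale `focal_radius` = 2
  voxels) around a random in-region locus, with multiplicative lognormal
  per-voxel jitter. Spatially iid heterogeneous weights average out over
  blob-shaped lesions, making the regional damage fraction a nearly
  sufficient statistic; focal loci encode the standard account of
  lesion-symptom structure (eloquent subregions, tract bottlenecks)
  under which *where* a lesion falls within a region matters. This is
  the regime in which voxel-pattern features can out-decode region
  summaries.

**With noise_sd = 0** the four scales are exactly collinear before
clipping and the FPC reproduces the latent score up to an affine map;
this is asserted in the tests.

What the generator does **not** emulate: real lesion morphology
(non-ellipsoidal shapes, vascular-territory anatomy), spatial
correlation of lesion location with anatomy, registration error,
multi-focal lesions, or realistic clinical score distributions. Passing
tests show the pipeline's machinery is correct and that its qualitative
contrasts hold under the stated generative assumptions — not that the
same effect sizes would be observed on patients.

## Segmentation and alignment

Segmentation keeps voxels with probability strictly greater than the
threshold (default 0.3) in connected components of at least
`min_cluster` voxels (default 100). Connectivity is configurable
(6/18/26) with 26 the default — the most permissive standard 3-D
definition; results depend on it, which is why it is exposed. The flip
decision uses the segmented binary mask (injury is what segmentation
says it is), with a strict-majority rule: ties leave the subject
unchanged. Both steps are per-subject and are applied once, outside the
folds.

## Standardization

Feature matrices are standardized in two steps: each row divided by its
Euclidean norm, then each column z-scored with training-fold statistics.
Two degenerate cases are fixed by rule: all-zero rows pass through
unchanged (a legitimate lesion-outside-mask case), and constant training
columns are centred but not scaled (they then contribute nothing to the
kernel). Row normalization applies only to matrices with more than one
column: dividing a single-column feature (e.g. whole-brain lesion load)
by its own magnitude would collapse it to a binary damaged/undamaged
flag and destroy the model. The decoding target (the FPC) is z-scored
with training mean/sd; row normalization is meaningless for a scalar.

A consequence worth knowing: row normalization discards each subject's
overall feature magnitude. When lesion sizes (and hence feature-row
norms) vary widely, the voxel-pattern model sees damage *direction* but
not amount, which caps even noiseless decoding below R = 1 (about 0.85
under the default wide size range; 0.98 when sizes are similar). The
pinned noiseless-recovery test therefore uses a narrow size range.

## FPC of the motor scales

Training columns are mean-centred, the 4×4 covariance eigendecomposed,
and subjects projected on the leading eigenvector; test subjects are
centred with training means and projected with the training
eigenvector. The sign is oriented so the loading sum is positive
("higher FPC = better function" once the slope signs are harmonized);
near-ties of the two leading eigenvalues emit a warning and keep the
first. The VLSM ROI construction consumes the *z-scored* FPC, whose
unit scale makes the rounded −2…2 binning meaningful.

## VLSM ROIs

Training scores are rounded to the closest integer (halves away from
zero) and clamped to [−2, 2]; for each voxel lesioned in at least one
training subject, the median of the lesioned subjects' rounded scores
assigns the voxel to one of five ROIs. Half-integer medians (even
counts) go to the bin nearer zero by default (configurable): no standard
rule exists for this tie, and shrinking toward the neutral category is
symmetric in sign. The five ROIs partition the training
lesion union by construction. Both the VLSM ROIs and the lesion-union
mask are rebuilt inside every fold from training subjects only.

## GP regression and MKL

The marginal likelihood is computed via Cholesky factorization with one
jitter retry (10⁻⁸·trace/n) before failing. Single-source fits optimize
(log s, log σₙ²) by L-BFGS-B from the supplied initialization plus fixed
spread restarts (deterministic, no hidden randomness); the best optimum
wins and never falls below the initialization. MKL optimizes
(log w₁…w_M, log σₙ²) — positivity of the "relevance" weights is
enforced by the log parameterization — with the analytic gradient
∂L/∂wᵢ = ½ tr((ααᵀ − K⁻¹)Cᵢ), uniform-weight start plus seeded random
restarts. The noise variance is jointly optimized by default (the
covariance must be invertible, and the observation model declares
Gaussian noise); it can be pinned. Reported weights are raw, with a
sum-normalized view alongside. Source kernels are built from one jointly
standardized voxel-pattern matrix split by region, so weights are
comparable across sources.

Predictions use the dual form: mean = K*·α with α = K_y⁻¹y, variance =
prior diagonal − K*K_y⁻¹K*ᵀ. For a linear kernel this equals primal
ridge regression X*(XᵀX + (σ²/s)I)⁻¹Xᵀy, which the tests exploit as an
independent oracle.

## Cross-validation and comparison

Unstratified uniform-random fold assignment (seeded, near-equal sizes).
Per fold: FPC and target scaling fitted on training subjects;
data-driven masks rebuilt from training subjects; feature
standardization fitted on training rows; model fitted on the training
kernel; held-out predictions scored by Pearson R and RMSE. The reported
R is the plain mean of per-fold correlations — computed on as few as 5
subjects per fold, hence high-variance, but implemented exactly as
stated; a pooled-prediction R over concatenated folds is additionally
reported as a clearly-labelled diagnostic. Folds with an undefined
correlation (constant predictions or targets) are excluded from the R
mean and counted in the result. The rank-sum test on fold RMSEs uses
midranks for ties and the exact null distribution (full enumeration of
rank assignments) for combined samples up to 20 — ten folds per arm is
enumerable — and a tie-corrected normal approximation beyond.

## Problem sizes

The test suite and the acceptance script run at desk scale: 16³–32³
grids, 12–100 subjects, 6–22 atlas regions. These sizes make the whole
suite run in well under a minute per stochastic replication while
keeping every pipeline stage nondegenerate (folds of ≥ 2 subjects,
multi-voxel regions, lesions spanning several regions).

## Known limitations

- Regions and lesions are axis-aligned ellipsoids/spheres; no realistic
  morphology.
- The MKL weight field has no uncertainty quantification and no sparsity
  penalty; equal-source splits are non-identifiable (only the weight sum
  is meaningful in that case).
- The pooled-R diagnostic mixes fold-specific target scalings and should
  not be compared against the per-fold mean R.
- Mean-of-5-point correlations is a noisy accuracy measure; treat
  single-cohort differences below ~0.1 in mean R as within noise.
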