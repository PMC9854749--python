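# Methods

## Signal models and units

Signals are handled on the normalized scale S/S₀ throughout; division by
the b = 0 image happens once at ingest. Diffusivities are stored in
mm²/s everywhere (Table-style values of e.g. 1.5 × 10⁻³ mm²/s appear as
`1.5e-3`); report layers may rescale for display. The IVIM-DKI equation

S/S₀ = f·exp(−b·D\*) + (1 − f)·exp(−b·D + (1/6)·b²·D²·k)

is evaluated exactly as written. Because the tissue exponent is
quadratic in b, the model is non-monotone for b > 3/(D·k); no
monotonicity is enforced, but note that beyond that point the model is
an extrapolation artifact, and for D near its upper box bound the
exponent overflows double precision at b = 2500 s/mm². Recovery
experiments therefore sample the physiologic domain
D ∈ [0.4, 3]·10⁻³, D\* ∈ [5, 100]·10⁻³ mm²/s, f ∈ [0.05, 0.45],
k ∈ [0.3, min(2, 3/(b_max·D))], which covers all four lesion classes
with wide margins.

The default acquisition is the 14-b-value pancreatic protocol
(0–2500 s/mm², with 1–7 signal averages per b); it ships as a packaged
b-value table. ADC uses the monoexponential model on the
{0, 500, 800, 1000} subset, solved by nonlinear least squares with a
log-linear warm start (the log-linear solution serves only as a test
oracle).

## Voxelwise fitting

Each voxel is fitted by bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`, analytic Jacobian) inside the box
D ∈ [0, 0.05], D\* ∈ [0, 0.5], f ∈ [0, 1], k ∈ [0, 3], initialized at
(1.3 × 10⁻³, 13 × 10⁻³, 0.3, 0.7). Per-voxel evaluation caps: 500
function evaluations for cold fits, 30 for warm-started refits.
Voxels are independent, so results do not depend on traversal order.
Inside the fitting objective the tissue exponent is capped at 60
(e⁶⁰ ≈ 10²⁶): far outside the kurtosis-validity region the exponent
overflows double precision, which a trust-region solver cannot digest;
the cap keeps residuals finite while leaving a misfit so enormous that
iterates are driven straight back to physical parameters. The public
signal function is uncapped. Warm starts whose residuals are non-finite
fall back to the fixed initialization.
Goodness of fit is the per-voxel adjusted R² (n = 14, p = 4) averaged
over the mask; an ROI-mean variant is available by flag. Signal ratios
above 1 (noise at low b) are kept as-is by default; a config flag can
clip them.

## The IDTV alternation

The regularized estimator minimizes, conceptually,

½ Σ_v ‖model(p_v) − s_v‖² + Σ_m w_m · TV(map_m)

where TV is the anisotropic (L1) total variation of the
bound-normalized 3D map — forward differences on a unit grid, Neumann
boundaries, differences only between in-mask voxel pairs. The
implementation is a half-quadratic splitting:

1. fit every voxel independently (standard model);
2. TV-denoise each of the four normalized maps over the whole volume at
   once (ROF problem, Chambolle–Pock primal–dual, θ = 1, fixed steps
   τσ‖∇‖² = 1);
3. re-fit every voxel warm-started at the denoised values with a
   quadratic anchor `anchor_mu · ‖p_norm − denoised_norm‖²` added to the
   residual (the splitting's coupling term). Each refit is solved from
   two start points — the denoised value and the previous iterate — and
   the lower-objective solution kept, because the voxel subproblem is
   non-convex (a flat valley couples f and D\* when D\* approaches D);
4. repeat 2–3 until the maps change by less than `tol` (relative L∞,
   normalized scale) or `max_outer_iters` is reached. If the penalized
   objective rises on two consecutive outer iterations the best iterate
   is returned.

A refit *without* the anchor would simply return to the unregularized
optimum, nullifying the smoothing; the anchored splitting is the
standard alternating minimization of the joint objective.

**Adaptive weight.** w_m is noise-proportional: the signal noise
variance is estimated as the median per-voxel RSS/(n − p) of the current
fit and propagated to each parameter through the Gauss–Newton covariance
diag((JᵀJ)⁻¹); the weight is `tv_alpha` × the median propagated
parameter SD on the normalized scale (capped at 0.5). Two properties
motivated this choice over curvature-based proxies (e.g. a robust MAD of
the map Laplacian): (i) on clean data the residuals — and hence all
weights — vanish, so exact fits are left untouched (a Laplacian proxy
reads genuine lesion edges and smooth heterogeneity as noise and biased
clean maps by up to 27%); (ii) the weight automatically differs per
parameter, giving D\* (noisiest by far) the strongest smoothing.

Defaults: `tv_alpha = 1.0`, `anchor_mu = 1.0`, `max_outer_iters = 10`,
`tol = 1e-3`. `anchor_mu` was chosen on development phantoms as the
value minimizing map RMSE without over-smoothing D; larger values trade
D accuracy for smoothness.

## TV denoiser

`tv_denoise` solves argmin_u ½‖u − g‖² + w·TV(u) on the masked region
with the dual variable clamped componentwise to [−w, w] (anisotropic
TV). The masked-pair gradient makes the ROI a closed domain: the masked
mean is preserved exactly at every iteration, and the w → ∞ limit is the
mean of each face-connected component. An independent dense-matrix ADMM
solver (exact shrinkage, direct linear solves) serves as the test
reference; the two agree to < 10⁻⁴ on small volumes.

## Texture analysis

Maps are quantized to Ng = 64 gray levels inside the ROI, by default
with equal-frequency (histogram-equalizing) binning — a rank-based rule,
so every downstream feature is invariant under strictly monotone
intensity transforms. Equal-width binning is available. A constant ROI
maps to level 1.

The 30 features, in canonical order f1…f30:

- **f1–f9 GLCM** (Energy, Contrast, Entropy(log₂), Homogeneity,
  Correlation, SumAverage(½Σ(i+j)p), Variance, Dissimilarity,
  AutoCorrelation): one symmetric matrix merged over the 13 unique
  offsets of 26-connectivity, pairs counted only when both voxels are
  masked, normalized to sum 1.
- **f10–f22 GLRLM** (SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE,
  LRLGE, LRHGE, GLV, RLV): one matrix merged over the 13 directions,
  runs broken at the mask boundary; GLV/RLV are the probabilistic
  variances of gray level / run length over runs.
- **f23–f25 Global**: sample variance (n−1), Fisher skewness and Pearson
  kurtosis (biased moments) of the quantized intensities — quantized,
  not raw, because quantization precedes texture analysis.
- **f26–f30 NGTDM** (Amadasun–King Coarseness, Contrast, Busyness,
  Complexity, Strength): neighborhood averages over masked 26-neighbors;
  voxels with no masked neighbor are excluded from N.

Degenerate (constant-ROI) outputs are fixed documented constants:
Entropy 0, Correlation 0, skewness 0, kurtosis 0, Busyness/Strength 0,
Coarseness capped at 10⁶ — so vectors stay finite for the classifier.
A single merged matrix per family (not per-direction feature averaging)
is used. The within-family feature order is a package convention; the
group memberships of the indices (f9 GLCM; f12, f13, f16, f21 GLRLM;
f29 NGTDM) are fixed.

## Statistics

- CV = sample SD × 100 / mean of the ROI voxel values.
- Kruskal–Wallis with tie correction; post-hoc pairwise comparison of
  group mean ranks with Tukey–Kramer (studentized-range, unequal n)
  critical values — validated against a permutation max-statistic
  oracle.
- Wilcoxon signed-rank: zero differences dropped, exact null up to
  n = 25, continuity-corrected normal approximation above.
- ROC: AUC = scaled Mann–Whitney U (ties ½); cutoff by the Youden index
  (ties resolved toward higher specificity); sensitivity / specificity /
  accuracy / F1 at the cutoff; AUC CI by stratified percentile bootstrap
  (2000 resamples). The positive class of each comparison is its
  first-named group.

## Classifier and validation

Chi-square ranking discretizes each feature into 10 equal-frequency bins
(distinct values become their own bins when fewer than 10) and tests the
bin × class contingency without continuity correction; features are
ranked by ascending p, ties by descending statistic; the top 10 are
kept.

The ANN is input → 221 → 16 → 3 → 2 → 2 → softmax, tanh hidden
activations, trained full-batch by L-BFGS on the L2-penalized
cross-entropy (λ = 0.0061374 on weights only; cap 1000 iterations,
gradient tolerance 10⁻⁶). Weights are He-initialized; biases start at
one (the reading of "weights and bias … started with one using the 'he'
initializer" consistent with common ANN tooling: He for weights, ones
for biases). Features are z-scored with training-fold statistics stored
in the model. These architecture and regularization values are fixed
configuration (they were tuned upstream by Bayesian optimization, which
this package does not re-run).

Validation is stratified 5-fold CV with fresh seeded partitions,
repeated (100 by default), so each case is tested exactly `repeats`
times; scaling, ranking and selection are re-fit inside each training
fold (leakage-safe; a `global` one-shot selection mode exists for
comparison). Metrics are pooled per repeat by default (per-fold
aggregation by flag) and reported as mean ± SD.

## Phantom generator

A phantom is an ellipsoidal organ with an embedded ellipsoidal lesion of
one of the four classes. Ground-truth fields are class mean + a smooth
Gaussian random field (FWHM 3 voxels) scaled to the class SD — the
reported class means/SDs for D, D\*, f, k act as the within-lesion
heterogeneity scale; between-patient mean shifts are not separately
modeled, so class separations on phantom cohorts are cleaner than in
patients. Fields are truncated to a physiologic interior of the fit box
(D ≥ 10⁻⁴, D\* ≥ 3 × 10⁻³ mm²/s, f ≥ 0.01, k ≥ 0.05) and k is capped at
the kurtosis-validity limit 3/(b_max·D): the box boundary itself is
degenerate tissue (D\* = 0 makes the model non-identifiable) and beyond
the validity limit the forward signal diverges. Background
(normal-pancreas) defaults D = 1.7 × 10⁻³, D\* = 20 × 10⁻³, f = 0.12,
k = 0.6 with 10% relative SD are invented plausible values — any study
relying on background tissue must override them.

Noise is Rician on the ratio scale, σ = 1/SNR(b=0), with per-b magnitude
averaging over the protocol's number of signal averages (complex
averaging is not modeled). The default SNR 20 makes standard-fit noise
clearly visible while fits still converge. ADC ground truth is defined
as the monoexponential fit to the noiseless 4-b signal (ADC is
model-derived, not independent physiology).

What passing phantom tests shows — and does not: the pipeline recovers
known parameters, TV regularization strictly improves precision and
accuracy under Rician noise, and class-level *mean* differences
propagate through the ROI-statistics path (perfusion fraction separates
pNET from PDAC in essentially every cohort replicate). The *texture*
classification path, however, faces a structural ceiling on these
phantoms: equalized (rank-based) quantization is invariant to monotone
intensity transforms by design, and the generator differentiates
classes only by mean shifts and amplitude scalings of random fields
with one shared smoothness and geometry — transformations the texture
representation cannot see. The only class signal reaching the
classifier is the indirect, noise-mediated difference in fitted-map
roughness (largely via D*), which at desk scale yields near-chance
cross-validated AUC. Discriminating real tumor types by texture relies
on genuine class-specific spatial heterogeneity that this generator
deliberately does not invent; phantom texture-classification results
therefore exercise the machinery (leakage-safe selection, metrics,
permutation null) rather than demonstrate discriminative power. Nor do
phantom results establish clinical performance generally: real lesions
have irregular geometry, partial-volume and motion effects,
non-stationary noise, and between-patient variability that the
generator omits.

## Problem sizes

Default experiment scales, chosen so a full run takes minutes on one
CPU: recovery sweeps use 100 voxels; the TV-benefit experiment one
32 × 32 × 12 phantom (≈ 4700 organ voxels); the end-to-end cohort 48
cases (25 PDAC / 13 pNET / 6 MFCP / 4 SPEN) on 12 × 12 × 6 grids with
IDTV capped at 3 outer iterations, 10 CV repeats and a 100-permutation
null; the f-separation experiment 100 cohort replicates of truth maps.

## Known limitations

- The ROF solver is first-order; default 200 iterations give ~10⁻³
  accuracy, adequate inside the alternation (tests push it further).
- GLRLM/GLCM dialects differ between toolboxes; this package's exact
  conventions are stated above and enforced against brute-force oracles,
  but numerical identity with any specific external toolbox is not
  claimed.
- D\* remains the least identifiable parameter; its CV criterion is
  deliberately excluded from the "strict improvement" set even though in
  practice it benefits most from TV.
- Whether the adjusted R² of a tumor ROI should be computed per voxel
  then averaged, or on the ROI-mean signal, is a convention; per-voxel
  is the default, the alternative is a flag.
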