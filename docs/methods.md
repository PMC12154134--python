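# Methods

This note documents the models, conventions, and design choices behind
`ipmnrisk`, in the order the pipeline runs.

## Synthetic cohort model

The generator emulates the *structure* of a seven-center T2-weighted MRI
cohort of pancreatic cysts, not its radiological appearance. Each subject is
a 3D volume (default 40×40×18 voxels, 1×1 mm in-plane) containing:

- a dark background (intensity 0.05),
- a duller organ ellipsoid (0.35 plus mild texture),
- a bright ellipsoidal cyst (fluid = 1.0; fluid is hyperintense on T2W),
  with in-plane radii drawn from 7–13 mm.

**Class model.** High-risk cysts differ from low-risk ones only through
internal heterogeneity: 2–4 hypointense Gaussian blobs (mural-nodule-like),
1–2 septation planes, and extra within-cyst speckle. All heterogeneity
amplitudes are multiplied by `label × effect_size`, so at `effect_size = 0`
the two classes come from the bit-identical generator — the null case used to
verify the pipeline sits at chance. The structural parameters (blob count and
positions, plane orientations) are always drawn from the random stream
regardless of class, which is what makes the null exact.

**Center model.** Centers act only on acquisition: slice thickness (the
defaults span 4–7.3 mm, within the 3–8 mm range such cohorts report), a
smooth multiplicative bias field (exponential of a random order-3 polynomial
in normalized coordinates, so it is strictly positive), additive Gaussian
noise, and a global intensity scale. Center is therefore a confounder of
image quality but never of the class-conditional texture, which is the
premise leave-center-out validation is meant to test.

**Cohort defaults** mirror the study design this pipeline targets: 359
subjects over 7 centers, a 142/359 high-risk fraction, per-center shares
consistent with the four-trial test-set sizes (29/36/35/71), and cyst-subtype
(BD vs MD/mixed) probabilities conditional on the risk class matching the
reported subtype breakdown. Exact-count class assignment is the default so
downstream checks are not flaky. Desk-scale experiments in the tests use
smaller volumes (32×32×16) and cohorts (n = 30–120); those sizes are stated
with each experiment.

What the generator does *not* emulate: MR physics (no k-space, Rician noise,
partial voluming), anatomy beyond a two-ellipsoid phantom, or any claim about
real intra-class texture distributions. Passing tests therefore demonstrate
that the pipeline recovers a planted texture-heterogeneity signal under
center-confounded acquisition — not that it would reach any particular
performance on clinical data.

**Perturbed masks** jitter the signed Euclidean distance of a mask with a
smooth seeded noise field (σ = 2 voxels) scaled by `magnitude` (voxels) and
re-threshold; magnitude 0 is the identity and expected Dice is monotonically
non-increasing in magnitude. **Simulated raters** emit {no, low, high}
scores: a true-high subject is called "high" with probability `sens`
(otherwise "no"/"low" at random), a true-low subject is called "low" with
probability `spec` (otherwise a false-positive "high"), so binarized calls
(positive = "high") recover the configured operating point in expectation.

## Preprocessing

Fixed order: resample → bias-correct → min-max normalize.

- Resampling: linear interpolation to 1 mm isotropic (3D mode) or 1 mm
  in-plane with slice spacing preserved (2D mode); masks are resampled
  nearest-neighbour and re-binarized. Desk-scale experiments resample to
  2 mm to keep volumes small; the target is a parameter.
- Bias correction is a contract, not an algorithm: output = input divided by
  a strictly positive smooth field, mean foreground intensity preserved. The
  default estimator fits an order-3 polynomial to log-intensities on the
  foreground by least squares (a projection, hence idempotent given a fixed
  foreground); SimpleITK's N4 is available via `method="n4"`.
- Min-max normalization is over the whole volume by default (an ROI-restricted
  option exists); constant regions raise with the subject named.
- The CNN crop takes the organ-mask bounding box expanded by a voxel margin,
  clipped to the volume, and linearly resizes to the network input (96³
  nominal, 32³ desk-scale). Crop intervals are 0-based half-open.

## Radiomics conventions

- Quantization: equal-width bins between ROI min and max, labels 1..L,
  outside-mask voxels flagged 0 and ignored. This makes all co-occurrence
  features invariant to positive affine intensity rescaling.
- GLCM: distance-1 offsets, all unique symmetric directions (4 in 2D, 13 in
  3D), pooled into a single matrix per (window, levels) pair; symmetric
  accumulation; normalized to sum 1. Windows 3/5/7 and levels 4/8/16/32/64 by
  default (195 Haralick maps in either mode).
- Haralick set: the classic 13 statistics, log base 2. Conventions for
  degenerate cases: correlation is 0 when a marginal standard deviation is 0;
  sum variance is taken about the sum average; a window with no valid
  co-occurring pair falls back to the single-entry matrix (energy 1, all
  entropies 0). The 14th statistic (maximal correlation coefficient) is
  omitted, as in common toolkits.
- CoLlAGe: per voxel, the dominant orientation is the principal eigenvector
  of the windowed gradient second-moment matrix; the angle (θ in 2D; θ and φ
  separately in 3D, orientation mapped to the z ≥ 0 hemisphere) is quantized
  into B bins (64 default) over its span, zero-gradient voxels taking a
  reserved bin; the co-occurrence of quantized orientations in the window is
  summarised by Haralick entropy (other statistics configurable). With an
  even bin count and the pooled symmetric offsets, in-plane 90° rotations
  permute the bins and leave the entropy unchanged — a tested invariance.
- Laws: separable correlation with the five 5-tap kernels (L5, E5, S5, W5,
  R5); 25 outer products in 2D, 125 in 3D; the absolute response is emitted.
- Gradient: per-axis Sobel (2D Sobel smooths only in-plane, so slices stay
  independent), Sobel magnitude, and central-finite-difference magnitude.
- All maps use edge-replication padding; only in-mask voxels are aggregated.
  2D mode computes maps slice-wise and aggregates the pooled in-mask pixels
  of all slices, with quantization over the pooled 3D ROI.
- Aggregation statistics: median, standard deviation (population), Fisher
  skewness and excess kurtosis (bias-uncorrected); constant maps define
  skewness = kurtosis = 0 to avoid NaN propagation.
- The default configuration enumerates 1,328 features in 3D and 920 in 2D
  (the manifest of `FeatureSpec`s is the authoritative count); the reduced
  `FeatureConfig.small()` bank (window 3, levels {8, 16}, 16 orientation
  bins; 652 features in 3D) is used for desk-scale experiments. Published
  per-family totals for this kind of bank are not exactly reconstructible
  from the stated families alone, so the config documents its own
  enumeration rather than targeting a fixed total.

## Feature selection

- Spearman filter: greedily remove one member of the worst offending pair
  (|ρ| ≥ 0.6) — the member with the larger mean absolute correlation to all
  remaining features; ties break by column order. Constant columns are
  dropped with a warning.
- mRMR: MID (difference) form, mutual information on equal-frequency-binned
  features (⌈√n⌉ bins, capped at 10). Greedy forward selection; the test
  oracle is a stepwise-exhaustive scan of the same objective, which is the
  objective the greedy procedure optimizes (the greedy sequence does not in
  general maximize the summed objective over ordered tuples).
- Stability selection: iteration r reshuffles a label-stratified 5-fold split
  with seed `base_seed + r`; each fold's training subset contributes one mRMR
  top-`n_candidates` list; a feature's frequency is the fraction of all
  iteration×fold subsets that recorded it; retention threshold 0.7. With
  `n_candidates="auto"`, a small random-forest cross-validation picks the
  list size from a grid per subset. An empty selection falls back to the
  top-frequency set with a warning. Desk-scale experiments use 10–15
  iterations instead of 50; the procedure is otherwise identical.

## Classification and trials

The four-trial leave-center(s)-out design holds out AHN+MCA, EMC, IU, and NYU
in turn. Redundancy filtering, stability selection, and random-forest fitting
see cross-validation subjects only — a property asserted by a test that
perturbs feature values exclusively in held-out rows and requires bit-identical
training artifacts. The forest uses 500 trees, √p features per split, and a
fixed seed (exposed; no hyperparameter tuning). AUC is pairwise concordance
with ties counting ½; thresholded metrics default to 0.5 on P(high risk).
Aggregation over trials is the unweighted arithmetic mean or the
test-size-weighted mean. Reported dispersion, where shown, is over seeded
repetitions of the pipeline.

## CNN stage

A compact, fully seeded 3D CNN implemented in NumPy: three 3³ stride-2
conv+ReLU blocks (4/8/16 channels), global mean+std pooling, and a sigmoid
head; inputs are standardized per volume. The std-pooling channel exposes
within-ROI response dispersion — the heterogeneity signal — directly to the
head, which keeps the network tiny yet able to learn the class difference.
Training follows the configured schedule exactly: SGD with momentum 0.9,
batch size 2, 200 epochs nominal, lr 0.001 divided by 10 every 30 epochs;
`DLConfig.desk()` switches to 32³ inputs and 30 epochs for desk-scale runs.
The stage shares its output contract (a P(high risk) vector in subject order)
with `load_external_scores`, so externally computed deep-learning
probabilities can be fused without retraining. Architectural backbones beyond
this default are out of scope; the config carries an architecture id for
adapters.

## Fusion

If p_rad > t the fused output is p_rad; otherwise (1−k)·p_rad + k·p_dl. Both
hyperparameters live in [0, 1]; `t` applies to P(high risk). The grid search
is exhaustive over t, k ∈ {0, 0.05, …, 1} (covering both pure-model limits),
maximizing mean-fold AUC on a stratified five-fold split, with deterministic
tie-breaking toward smaller k then smaller t (prefer the simpler blend).

## Agreement and QC

- Dice: two empty masks define 1.0, exactly one empty 0.0 (logged).
- HD95: surfaces are mask voxels with a face-adjacent background neighbour
  (volume edges count as background); distances between boundary voxel
  centers in physical mm; the 95th percentile (linear interpolation) of the
  pooled symmetric nearest-distance set, hence symmetric in its arguments
  and bounded by the exact Hausdorff distance.
- Weighted kappa: linear disagreement weights by default (quadratic
  available) over the ordered {no, low, high} levels; degenerate marginals
  raise.
- Rater operating points binarize positive = "high" only (configurable);
  the majority row uses the score given by more than half the raters and
  excludes subjects with no majority, returning the excluded count.
  Cochran's Q uses the standard statistic with a χ²(raters−1) reference;
  all-identical calls give Q = 0, p = 1.
- QC: 21 named indicators per scan (foreground intensity statistics,
  contrast-per-pixel, entropy focus criterion, foreground–background energy
  ratio, four SNR variants, CNR, CJV, PSNR against a median-filtered
  reference, background mean). Foreground/background is an Otsu split unless
  a mask is given; background-dependent indicators are NaN with a recorded
  reason when the background is empty. Normalizations: z-score, min-max, and
  ZCA whitening (identity sample covariance). The 2D embedding is pluggable
  (UMAP with a fixed `random_state`, or PCA) since it serves visualization
  only.

## Known limitations

- The phantom's texture classes are far easier to separate than clinical
  dysplasia grades; desk-scale AUCs near 1.0 say nothing about clinical
  performance.
- The polynomial bias surrogate removes only low-order smooth shading; N4
  should be preferred on real data.
- The NumPy CNN is CPU-bound and intended for reduced-scale runs; paper-scale
  (96³, 200-epoch) settings are configurable but slow.
- Per-slice 2D analysis pools all in-mask pixels rather than weighting
  slices, so thick-slice subjects contribute fewer pixels.
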