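# ipmnrisk

Cyst-level malignancy-risk stratification of intraductal papillary mucinous
neoplasms (IPMNs) from T2-weighted MRI, as a tested, fully synthetic-data-driven
pipeline.

IPMNs are premalignant pancreatic cysts. Deciding which harbour high-grade
dysplasia or invasive carcinoma (and therefore warrant surgery) from routine
imaging is hard: expert visual scoring is subjective, and invasive sampling has
limited sensitivity. This package implements a complete computational
stratification pipeline for that problem — radiomic texture analysis of the
segmented cyst, a convolutional probability stage, and their decision-level
fusion — together with the statistics used to audit such a study: segmentation
agreement, inter-rater agreement, and scan-quality assessment. Everything is
exercised on seeded synthetic multi-center cohorts, so no imaging data is
required to run, test, or extend any stage.

It is intended for medical-image-analysis researchers who want a reproducible,
leakage-audited reference implementation of this class of multi-center
radiomics study design.

## The pipeline

1. **Synthetic cohort** (`synthcohort`) — seeded phantoms of a 7-center cohort:
   a bright ellipsoidal cyst inside a duller organ; high-risk cysts carry extra
   *internal heterogeneity* (hypointense mural blobs, septation planes, higher
   within-cyst variance) scaled by an `effect_size`; centers differ only in
   acquisition (slice thickness 3–8 mm, multiplicative bias field, noise,
   intensity scale), never in class-conditional texture.
2. **Preprocessing** (`prep`) — isotropic resampling (1 mm³ for 3D analysis,
   1 mm² in-plane for 2D) by linear interpolation, bias-field correction
   (log-domain polynomial surrogate or N4), min-max normalization, in that
   fixed order; plus ROI crop/resize for the CNN stage.
3. **Radiomics** (`radiomics`) — six feature families over the cyst ROI: Raw,
   Gray (median/mean/std/range filters), Gradient (Sobel and finite
   differences), Laws texture-energy masks, Haralick GLCM statistics (windows
   3/5/7, gray levels 4/8/16/32/64), and CoLlAGe (co-occurrence of local
   dominant gradient orientations). Every per-voxel map is summarised over the
   ROI by median, standard deviation, skewness, and kurtosis.
4. **Feature selection** (`featselect`) — Spearman |ρ| ≥ 0.6 redundancy filter,
   then stability selection: mRMR ranking inside a reshuffled stratified
   5-fold × 50-iteration loop, retaining features chosen in ≥ 70% of training
   subsets.
5. **Classification** (`classify`) — a seeded random forest scored on held-out
   centers in a leave-center(s)-out four-trial design; metrics (AUC, accuracy,
   sensitivity, specificity, PPV, F1) aggregated by unweighted or
   test-size-weighted means.
6. **Deep stage** (`dlstage`) — a compact seeded 3D CNN (NumPy; SGD momentum
   0.9, batch 2, lr 0.001 divided by 10 every 30 epochs) producing P(high
   risk), interchangeable with externally computed score files.
7. **Fusion** (`fuse`) — decision-level rule with threshold `t` and weight `k`:
   if the radiomics probability exceeds `t` it is used alone, otherwise the
   output is `(1-k)·p_rad + k·p_dl`; `(t, k)` chosen by exhaustive grid search
   on five-fold cross-validation.
8. **Agreement & QC** (`agreement`, `qc`) — Dice and 95th-percentile surface
   distance (HD95) for segmentations; per-rater and majority-vote operating
   points, pairwise weighted kappa, and Cochran's Q for ordinal rater scores; a
   21-indicator scan-quality vector with z-score/min-max/whitening
   normalization and a 2D (UMAP or PCA) embedding.

## Worked example

```python
import ipmnrisk as ir
from ipmnrisk.prep import preprocess
from ipmnrisk.featselect import SelectionConfig

cfg = ir.SynthConfig(n_subjects=60, n_centers=7, effect_size=2.0,
                     volume_shape=(32, 32, 16), seed=42)
cohort = ir.generate_cohort(cfg)

features, specs = ir.extract_cohort_features(
    cohort, mode="3D", config=ir.FeatureConfig.small(),
    preprocess_fn=lambda v, m: preprocess(v, m, mode="3D", target_mm=2.0))

trials = ir.make_center_trials(cohort.manifest, [("NYU",)])
result = ir.run_radiomics_experiment(
    cohort, trials, feature_table=features,
    selection_config=SelectionConfig(n_iterations=15, n_candidates=20, seed=0),
    seed=0)
t = result.trials[0]
print(f"trial {t.split.trial_id}: {len(t.selected_columns)} stable features, "
      f"held-out AUC {t.metrics.auc:.3f}, accuracy {t.metrics.acc:.3f}")

mask = cohort.cyst_masks[cohort.subjects[0].subject_id]
redo = ir.perturb_mask(mask, magnitude=1.0, seed=0)
print(f"re-segmentation agreement: Dice {ir.dice_coefficient(mask, redo):.3f}, "
      f"HD95 {ir.hausdorff95(mask, redo):.2f} mm")
```

prints

```
trial T1: 11 stable features, held-out AUC 1.000, accuracy 0.833
re-segmentation agreement: Dice 0.896, HD95 4.00 mm
```

The cohort here is small (60 subjects) and the class effect deliberately strong
(`effect_size=2.0`), so the pipeline separates the classes almost perfectly on
the held-out center: 11 texture features survive the stability loop and the
random forest ranks every held-out subject correctly. The Dice/HD95 pair
quantifies how far a seeded boundary perturbation (standing in for a second
rater's segmentation) drifts from the original mask. With `effect_size=0.0`
the two classes are generated identically and the same pipeline returns
chance-level AUC — the standard null check that no center or acquisition
information leaks into the label.

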