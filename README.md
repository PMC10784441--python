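# ptrarad

Non-contrast CT radiomics for predicting which patients with severe
atherosclerotic renal artery stenosis (ARAS) will benefit from percutaneous
transluminal renal angioplasty (PTRA).

## The problem

After angioplasty of a severely stenosed renal artery, only a minority of
patients show a sustained recovery of renal function — defined here as a
relative increase in estimated glomerular filtration rate (eGFR) of at
least 20% lasting at least 3 months.  Identifying likely responders before
the intervention, from imaging that is already part of the routine workup,
would let clinicians target the procedure.  `ptrarad` implements a
radiomics pipeline that quantifies the pre-treatment imaging phenotype of
the affected kidney (ROI1) and the surrounding perirenal adipose tissue
(ROI2) on a single non-contrast axial CT slice and builds predictive
signatures from it.

Because the patient images behind this design are not publicly available,
the package ships a first-class synthetic phantom generator
(`ptrarad.phantom`) that produces CT-like slices in Hounsfield units, ROI
masks, an unlabeled 64×64 patch corpus, and outcome-labeled cohorts
(default 18 benefit / 34 non-benefit) whose labels depend on planted
texture effects through a known logistic model — so every stage of the
pipeline can be validated against ground truth.

## The pipeline

1. **Preprocess** (`preprocess`): decile-landmark histogram alignment,
   cubic-B-spline resampling to 0.5 mm, and the image triple X (original),
   XL (Gaussian-smoothed) and XH = X − XL (detail-enhancing residual).
2. **Handcrafted features** (`handcrafted`): a frozen 116-feature catalog —
   8 shape features on the mask plus, per variant X/XL/XH, 14 histogram,
   13 GLCM, 8 GLRLM and 1 differential box-counting fractal feature.
3. **Deep features** (`deepfeat`): a four-block squeeze-and-excitation CNN
   trained by self-supervision to recognize five patch degradation classes
   (normal / blur / noise / distortion / shift).  The six final-block
   channels with the largest fully-connected weight mass (D1..D6) are
   upsampled to the image grid and summarized over the ROI by 13 statistics
   each: 78 deep features.  The network is pure NumPy with hand-derived
   backprop; gradients are finite-difference checked.
4. **Selection** (`select`): z-scoring; a Shapiro-Wilk-routed univariate
   screen (t-test or Mann-Whitney, retain P < 0.1); consensus clustering of
   features with partitioning-around-medoids on 1 − |Spearman ρ| distances
   (50% feature resampling, 500 times), growing k until every feature
   correlates with its subset medoid at |ρ| > 0.6; then an L1-logistic
   (LASSO) path whose strength maximizes stratified 10-fold CV AUC.
5. **Models** (`model`): logistic regression, RBF-SVM, random forest, k-NN
   and a small neural network, tuned by grid search over nested LASSO-ranked
   feature prefixes, compared by leave-one-out cross-validation (LOOCV); the
   per-region winner becomes the renal or perirenal signature, and the two
   are fused by logistic regression over out-of-fold scores (with Wald
   tests and variance inflation factors).
6. **Explanation** (`explain`): exact Shapley enumeration and a KernelSHAP
   weighted-least-squares estimator (two independent routes that agree to
   1e-3), plus volcano tables, clustered radiomics heatmaps (cophenetic
   correlation, adjusted Rand index) and PCA projections.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical conventions.

## Worked example

```python
from ptrarad import deepfeat, model, phantom, pipeline

# one-off: self-supervised pretext training on synthetic patches
patches, kinds, pids = phantom.sample_patches(50, 10, seed=123)
tr, va, te = phantom.grouped_split(pids, seed=123)
enc = deepfeat.build_encoder(seed=123)
trained = deepfeat.train_pretext(
    enc, patches[tr], kinds[tr], patches[va], kinds[va],
    deepfeat.TrainingSchedule(max_epochs=12, seed=123),
)
print(f"pretext validation accuracy {trained.best_val_accuracy:.2f}")

# an outcome-labeled cohort with planted perirenal-texture effects
cohort = phantom.build_cohort(n=52, n_benefit=18, seed=1, image_size=(128, 128))
res = pipeline.run_study(cohort, enc, seed=1, grids=model.FAST_GRIDS,
                         consensus_resamples=50, search_resamples=20,
                         max_features=4)
for region, rr in res.regions.items():
    sig = rr.signature
    print(f"{region}: {sig.spec.family} on {len(sig.spec.features)} features, "
          f"LOOCV accuracy {sig.cv.accuracy:.3f}, AUC {sig.cv.auc:.3f}")
print(f"majority baseline {res.majority_accuracy:.3f}, "
      f"combined AUC {res.combined.auc:.3f}")
```

Output from this exact script:

```
pretext validation accuracy 0.56
renal: LR on 3 features, LOOCV accuracy 0.865, AUC 0.899
perirenal: LR on 1 features, LOOCV accuracy 0.846, AUC 0.897
majority baseline 0.654, combined AUC 0.936
```

Reading: the encoder learned the degradation pretext well above 5-class
chance (0.2); both signatures recover the planted texture effects far above
the 34/52 majority baseline (0.654), and fusing the two out-of-fold score
columns raises the AUC above either signature alone.  Which family wins and
how many features each signature keeps varies with the cohort seed — on
median across seeds the perirenal signature, built on the stronger planted
effect, is the stronger one.

A thin CLI mirrors this flow: `ptrarad simulate`, `ptrarad pretrain`,
`ptrarad run-study` (see `ptrarad --help`).

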