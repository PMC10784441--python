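# Methods

`ptrarad` implements a non-contrast CT radiomics pipeline for a severe
atherosclerotic renal artery stenosis (ARAS) cohort treated with
percutaneous transluminal renal angioplasty (PTRA).  The clinical question
is pre-treatment triage: which patients will show a sustained (≥ 3 months)
≥ 20% relative increase in estimated glomerular filtration rate (eGFR)
after angioplasty — the "benefit" group — based only on the imaging
phenotype of the affected kidney (ROI1) and its perirenal adipose ring
(ROI2) on a single axial slice.  Because no patient imaging is publicly
available, the package is driven end to end by a synthetic phantom cohort
with planted, recoverable texture effects; every quantitative claim in the
test suite and acceptance script is made on data whose ground truth the
generator records.

## Outcome model

`phantom.classify_outcome` is a total function on (pre-eGFR, post-eGFR,
follow-up): relative change ≥ +20% sustained ≥ 3 months → improvement
(benefit); ≤ −20% → exacerbation; otherwise stable; improvement alone
defines benefit.  Thresholds are inclusive.  Follow-up under 3 months
returns an explicit `undetermined` status rather than defaulting to
non-benefit, because the rule requires persistence — silently labeling
short-follow-up cases would contaminate the negative class.

## Phantom cohorts

A slice is a soft-tissue body ellipse (~+40 HU) on air (−1000 HU), with an
elliptical kidney (~+32 HU) inside a hypodense fat annulus (~−90 HU); these
means follow standard tissue HU ranges.  Tissue heterogeneity is i.i.d.
per-pixel Gaussian texture (kidney SD 12 HU, fat SD 15 HU by default) plus
global acquisition noise (SD 5 HU).  I.i.d. texture keeps the ROI-mean
sampling error analytic (SD/√N), which the generator tests exploit.

`build_cohort` fixes the class composition (default 18 benefit / 34
non-benefit, n = 52) and draws per-case texture SDs class-conditionally on
the log scale: log sd ~ N(log base + label·d·τ, τ²) with τ = 0.25.  This
case-control construction implies an exact logistic model
logit P(benefit | sd) = const + (d/τ)·z, recorded in `effect_model` for
recovery tests.  Default standardized effects are d = 1.5 on perirenal fat
texture and d = 1.0 on kidney texture — the perirenal signal is deliberately
the stronger one, mirroring the scientific claim that perirenal adipose
tissue carries added predictive value.  eGFR trajectories are drawn
consistently with the assigned label and re-validated through the outcome
rule; follow-up is 3 + Exp(1.01) months (median ≈ 3.7).

What the phantom does **not** emulate: organ anatomy, partial-volume and
beam-hardening artifacts, scanner-to-scanner calibration drift, spatially
correlated texture, or any link between image texture and the eGFR numbers
beyond the planted label coupling.  Passing tests therefore demonstrate
that the pipeline's machinery recovers planted effects of realistic size at
the study's n — not that real perirenal CT texture predicts PTRA benefit.

## Preprocessing (X / XL / XH)

Histograms are aligned by piecewise-linear decile-landmark mapping against
a pooled cohort reference (per-decile mean of all cases); the mapping is
monotone, so ranks are preserved, and a constant image passes through with
a warning.  Resampling to the 0.5 mm protocol grid uses a cubic B-spline
kernel (SimpleITK) with nearest-neighbor for masks; the spline's
mirror-boundary prefilter transient means exactness-on-linears holds only
away from edges, which the tests respect.  The analysis triple is X
(standardized), XL = Gaussian(σ = 1.5 px)·X, and the unsharp residual
XH = X − XL.  XH was chosen as the differencing operator because it is the
simplest filter that enhances boundaries and streak-like detail while
satisfying X = XL + XH exactly; σ and the operator are configurable.

## Handcrafted features (116)

Frozen catalog: 8 shape features computed once on the mask, and per variant
(X, XL, XH) 14 histogram, 13 GLCM, 8 GLRLM and 1 fractal feature:
8 + 3×36 = 116.  Conventions:

- Discretization is fixed-bin-number (32 equal-width bins over the in-ROI
  range); a constant ROI maps to bin 1.  Fixed bin number is robust to the
  residual HU offsets that survive histogram alignment.
- GLCM: distance 1, four directions (0°, 45°, 90°, 135°), symmetric,
  normalized per direction then averaged.  Degenerate rules: 0·log 0 := 0;
  correlation of a zero-variance ROI := 1; a single-pixel ROI yields the
  all-zero matrix and the corresponding degenerate feature values.
- GLRLM: runs broken by the mask, counted per direction with features
  averaged over directions.  LRHGLE is long-run high-gray-level emphasis,
  Σ P(i,r)·i²·r² / N_runs.
- Fractal: differential box counting over box sizes {2, 4, 16, 8}; the ROI
  bounding-box crop (≥ 8×8) is mean-filled outside the mask, rescaled to
  256 gray levels, and the dimension is the slope of log N(s) against
  log(1/s).  A flat surface gives 2.0; the value is invariant to intensity
  shifts.
- Shape is computed once (it depends only on the mask); fractal is computed
  per variant.  This split is what makes the catalog total exactly 116.

GLCM and GLRLM are verified against brute-force pair/run enumeration
oracles (independent loop-level implementations in the tests) to 1e-10 on
random masked ROIs.

## Self-supervised encoder and deep features (78)

The pretext task: classify a 64×64 abdominal patch as normal or as one of
four computer-generated degradations — Gaussian blur (σ ∈ [1, 3] px),
additive HU noise (σ ∈ [10, 30] HU), smooth elastic distortion (amplitude
∈ [2, 6] px), or translation with reflection padding (8–16 px).  Magnitude
ranges were chosen once to be visibly non-trivial yet learnable at 64×64;
exactly one degradation applies per patch, and non-normal degradations with
zero magnitude are rejected so the identity cannot leak the "normal" label.
The patch corpus is split 7:1:2 with no synthetic patient crossing splits.

The network (NumPy, hand-derived backprop, Adam): four blocks of
[2×2 conv → 8 ch, 2×2 conv → 8 ch, batch-norm, ReLU, squeeze-and-excitation,
plus a 1×1-conv skip added to the block output], each followed by 2×2 max
pooling (64 → 32 → 16 → 8 → 4), then global average pooling to an 8-vector,
dropout (0.3), and a 5-way softmax head trained with categorical
cross-entropy.  Every layer's gradient is checked against central finite
differences.  The learning rate (initial 1e-3, batch 32) is multiplied by
0.1 after each 5 epochs without validation improvement and training halts
after 10 such epochs, restoring the best-validation weights.  The FC head
carries an elastic-net penalty (λ₁ = λ₂ = 1e-4): the L2 term enters the
gradient; the L1 term is applied as a proximal soft-threshold after each
optimizer step, so weights of uninformative GAP nodes reach exact zero.

Deep features: channels are ranked by Σ_classes |W_fc|, the top 6
("information-dense maps", D1..D6, ties to the lower index) are kept; the
conv trunk runs fully convolutionally over the whole slice (reflect-padded
to a multiple of 16), each selected map is bilinearly upsampled to the
image grid, and 13 statistics are computed over the ROI: the node mean,
six histogram statistics (variance, skewness, kurtosis, entropy,
uniformity, range) and six GLCM statistics (contrast, correlation, energy,
entropy, homogeneity2, cluster shade) with 16-bin in-ROI discretization —
6 × 13 = 78.  Whole-slice inference (rather than ROI tiling) was adopted
because it is deterministic, single-pass, and respects the ROI exactly via
the upsampled maps.  The module never imports outcome records; the encoder
is outcome-blind by construction and may be trained once and reused across
cohorts.

## Selection funnel

Features are z-scored per column (population SD); columns whose SD is at
floating-point noise level relative to their magnitude are dropped as
constant (the phantom's fixed kidney geometry makes several shape features
bit-identical across cases).  The univariate screen runs Shapiro-Wilk per
class at α = 0.05 and routes to the independent-samples t-test when both
classes are normal, otherwise Mann-Whitney U (two-sided throughout; classes
smaller than 3 route to Mann-Whitney since normality is then undefined).
Retention is P < 0.1; significance is P < 0.05; no multiplicity correction
is applied because the gate is a screen, not an inference.

Consensus clustering: distance 1 − |Spearman ρ| (redundancy is
sign-agnostic), PAM (greedy BUILD + steepest-descent SWAP, deterministic
with lower-index tie-breaks, implemented in-package).  Zero-distance
feature groups are collapsed before clustering so indistinguishable
features are never split.  Features are resampled at 50% without
replacement (500 times by default); a feature's consensus value is its mean
co-membership with final-subset peers over resamples containing both, and
the subset medoid is its consensus maximizer (alphabetical tie-break;
singletons have consensus 1).  k grows from 2 until every feature has
|ρ| > 0.6 with its subset medoid; if the criterion is unreachable the
all-singleton partition is returned with a warning.

LASSO: L1-penalized logistic regression over 50 log-spaced strengths
(C ∈ [1e-2, 1e2]), strength chosen by mean stratified 10-fold CV AUC, ties
toward the stronger penalty; the selected set is the nonzero support of the
full-data refit, ordered by |coefficient|.

## Models, LOOCV and fusion

Five families with predict-proba surfaces: logistic regression, RBF-kernel
SVM (Platt-calibrated), random forest, k-NN, and a one-hidden-layer MLP
(lbfgs — the right solver at n ≈ 52).  Default grids: LR C ∈ {0.01, 0.1, 1,
10}; SVM C ∈ {0.1, 1, 10} × γ ∈ scale-heuristic × {0.5, 1, 2}; KNN
k ∈ {9, 7, 5, 3}; RF {100, 300} trees × depth {3, 5, ∞}; MLP hidden ∈ {4,
8, 16}.  Tuning searches nested prefixes of the LASSO ranking × the grid by
mean stratified 10-fold CV accuracy (ties → fewer features, then lower
capacity).  The per-region winner is chosen by LOOCV accuracy (ties → LOOCV
AUC, then the fixed order LR < SVM < RF < KNN < ANN).  Accuracy CIs use a
2000-resample percentile bootstrap of the per-case correctness vector; AUC
CIs use a vectorized case bootstrap of the rank AUC (ties ½).

Fusion is a logistic regression over the two signatures' **out-of-fold**
LOOCV scores — refit scores would leak each case into its own fusion input.
Wald P values and VIFs come from the multivariate statsmodels fit; under
perfect separation the Wald quantities are reported as NaN (not identified)
while scores, VIF and AUC remain defined.  Perfectly collinear score pairs
refuse fusion.  The combined per-case score is itself produced by a
leave-one-out refit of the fusion model.  Threshold curves evaluate
accuracy, sensitivity, specificity, Youden index and F1 at 101 thresholds
with score ≥ threshold counted positive.

## Explanation and descriptive analytics

Exact Shapley values are enumerated over all 2^d coalitions (d ≤ 15),
marginalizing absent features over a background set (default: the full
training cohort).  The KernelSHAP estimator solves the Shapley-kernel
weighted least squares over all proper coalitions (or sampled ones for
large d) with the efficiency constraint eliminated into the last
coefficient; the two routes agree to 1e-3 on d ≤ 10 and the exact route
satisfies efficiency/dummy/symmetry by construction.  Volcano tables use
the signed standardized mean difference (configurable to AUC − 0.5) against
−log₁₀ P with a handcrafted/deep family flag.  The heatmap report clusters
cases and features by average linkage on correlation distance, reporting
the cophenetic correlation and the adjusted Rand index of the k = 2 case
partition against outcome labels (correlation distance ignores per-case
mean shifts; classes must differ in profile shape to separate).  PCA is
centered, on the z-scored table.

## Scaled study sizes

All simulations are sized for a single CPU: phantom slices 128×128 on the
native 1 mm grid for multi-seed studies (the 0.5 mm resampling protocol is
exercised separately); pretext training uses 500 patches (50 patients × 10)
for 12 epochs; screen calibration uses 200 permutation replicates × 50
features; LASSO recovery 100 replicates (20-point strength grid); the
null-bias check 100 seeds with the five families at fixed mid-grid
hyperparameters (reduced grids: RF 10 trees/depth 3, MLP hidden 8,
single-point KNN); end-to-end studies run 20 seeds with consensus
resampling 30 (15 during the k search), a 20-point LASSO grid and the
LASSO prefix capped at 3 features.  On null cohorts the five-family mean LOOCV
accuracy sits slightly below the majority rate — the pessimistic
noise-fitting direction — and the suite asserts strictly that it is never
optimistic.

## Known limitations

- The phantom's texture is spatially white; features sensitive to spatial
  correlation structure (GLCM/GLRLM/fractal) mostly inherit their signal
  from the variance knob, so their relative importance on real CT will
  differ.
- The encoder is small and trained briefly; its deep features are
  meaningful summaries of learned degradation-sensitive filters, not
  transferable abdominal-CT representations.
- Shape features are uninformative in cohorts generated with fixed organ
  geometry (they are constant and dropped at normalization).
- Exact Shapley enumeration is exponential in d and capped at 15 features;
  signatures here use far fewer.
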