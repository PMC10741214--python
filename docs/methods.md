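# Methods

This note documents the models, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Temperature decoding and validity

Thermograms are 8-bit grayscale with a per-image range (t_min, t_max) supplied
as sidecar values (mimicking cameras that print only a colorbar). Decoding is
affine, T = t_min + g/255·(t_max − t_min); it is exact up to the quantization
step (t_max − t_min)/255 (≈ 0.1 °C for a 25 °C span), which is the tolerance
used whenever a constructed temperature is compared with a decoded one. Pixels
below the **18 °C floor** are removed from the validity mask (temperatures are
never modified); an angiosome left empty by the floor would have an undefined
mean, so such subjects are dropped by QC rather than silently contributing
zeros.

## Feet and angiosomes

Plantar imaging mirrors the subject: by default the component with the larger
centroid column is the left foot (`left_on_image_right` flips this for other
conventions). Masks with more than two components keep the two largest; a
single component means the feet touch and the subject is flagged unusable.

The anatomical boundaries of the four plantar angiosomes cannot be recovered
from a binary mask, so a geometric proxy is used and documented as such: the
posterior `heel_fraction` (default **0.30**) of the foot's bounding-box rows is
the calcaneal region, and both it and the anterior remainder are split into
medial/lateral halves across the foot's principal axis (minor PCA axis of the
pixel coordinates; ties on the axis go medial, which keeps the partition
exactly mirror-equivariant). The partition is a true set partition — no
overlap, no gap — verified property-style on arbitrary masks. The fraction and
orientation (toes-up assumed; a flip flag handles toes-down) are configurable.

## The 188-feature registry

Ten unilateral regions (L, R, and the eight foot-angiosomes) × 12 statistics
{mean, std, max, min, skew, kurtosis, HSE, NTR_C1..C5} = 120; four bilateral
angiosomes × 14 (adding ET and ETD) = 56; bilateral Foot × 12 {mean, std, max,
min, ET, ETD, TCI, NTR_C1..C5} = 12; total 188. The inventory is config-driven
so alternative registries are drop-in.

Composite indices are reconstructions of indices from the angiosome
thermometry literature, with every knob exposed:

* **HSE** — mean of the hottest ⌈5%⌉ of region pixels (fraction configurable).
* **ET** — pixel-count-weighted mean of the pooled bilateral region; **ETD** —
  |mean(L) − mean(R)|.
* **NTR_Ck** — fraction of region pixels with u = (T − floor)/(T_max,subject −
  floor) in [(k−1)/5, k/5) (last bin closed); five bins by default; a
  degenerate subject (max = floor) puts all mass in C1.
* **TCI** — mean over the eight foot-angiosomes of |mean − reference|, against
  healthy-control reference temperatures (defaults MPA 30.5, LPA 30.0,
  MCA 29.0, LCA 28.5 °C, matching the phantom's healthy pattern).

Moments are population moments (skew = m₃/m₂^1.5, excess kurtosis), with the
zero-variance convention skew = kurtosis = 0, chosen for determinism on
degenerate regions.

## Synthetic phantoms

Each phantom is two mirrored ellipse-plus-heel-lobe blobs; angiosome zones are
painted by the *same* partition rule preprocessing applies, so ground truth
aligns by construction. Healthy subjects get a symmetric pattern (per-foot
means above); diabetic subjects get +2 °C on one randomly chosen foot's
angiosomes plus three Gaussian hot spots (σ = 5 px, +3 °C) mimicking focal
inflammation; sensor noise is additive Gaussian (σ = 0.3 °C). Temperatures are
clipped to the colorbar range and encoded with background at gray 0. One RNG
stream per subject, derived from (dataset seed, subject index), makes any
subject reproducible in isolation. Default class counts 88:34 match the
imbalance regime of public plantar cohorts.

What the phantoms do **not** emulate: realistic foot outlines and toe
morphology, spatially correlated sensor noise, emissivity and viewing-angle
effects, segmentation errors, or biophysically grounded diabetic patterns (the
literature gives no quantitative description; phantom parameters are
benchmarks, not claims). Passing tests therefore demonstrate correctness of
the computational pipeline, not clinical performance.

Planted tables draw all features standard normal, shift the informative subset
by `effect_size` SDs in the majority class, and optionally give a block of
noise features a shared latent factor (pairwise correlation r). The
single-feature AUC is Φ(d/√2) in closed form, anchoring the recovery
benchmarks; the default benchmark (141 features, 10 informative, d = 3,
88 + 34 subjects SMOTE-balanced to 88 + 88) mirrors the real cohort's
post-pruning dimensionality and sample size.

## Feature selection

Correlation pruning scans ordered pairs (i < j) and drops j whenever
|r| > 0.95; survivors provably contain no pair above the threshold (tested
against an exhaustive scan). Constant features have undefined r and are kept
with a log message.

All rankers share the fold protocol: stratified 5-fold CV (each fold trains on
80% — the 80:20 reading of the published protocol), per-fold scores averaged,
ties broken by (score, column order) via a stable sort.

* **Univariate** — per-feature logistic fit on the training split, AUC-ROC on
  the held-out split.
* **Lasso** — L1 logistic regression, z-scored per training fold, penalty by
  3-fold inner CV over 10 C values; relevance |coefficient|.
* **Random forest** — 500 trees, impurity-decrease importances.
* **Concrete dropout** — input gate z_i = x_i·m_i, m_i a binary-concrete
  sample sigmoid((logit p_i + logit u)/t) with temperature t = 0.1; loss =
  cross-entropy + λ·Σp_i with λ = 1/n_train; relevance p_i. Keep-probabilities
  start at 0.5.
* **Variational dropout** — z_i = x_i·(1 + √α_i ε), log α_i learned against
  the standard sparsifying KL approximation (k₁σ(k₂ + k₃ log α) − ½log(1 +
  α⁻¹) with k = 0.63576/1.87320/1.48695), weighted 1/n_train; log α clipped to
  [log 1e−8, log 1e4]; relevance −log α_i. **Initialization**: log α₀ = −1
  (α₀ ≈ 0.37). Starting closer to the decision boundary between "kept" and
  "prunable" lets the KL term carry uninformative features into the large-α
  regime within the fixed 500-epoch budget; from a near-noiseless start
  (α₀ ≈ 0.02) the gap to the prunable regime is too wide for the protocol's
  step count and informative and noise features stay interleaved.

Both neural selectors share a numpy MLP backbone (input gate → 128 → 64 → 2,
ReLU, dropout 0.5 between hidden layers, He initialization) trained with
mini-batch Adam (β₁ = 0.9, β₂ = 0.999), batch 32, 500 epochs; learning rate
1e−2 for the concrete gate, 1e−3 for variational dropout. A non-finite
training loss aborts the fold with diagnostics rather than returning garbage
scores. Gradients are verified against central finite differences in the test
suite.

**Consensus** — a feature qualifies if every approach ranks it strictly inside
rank 50; its final rank is the minimum across approaches, bucketed at
<10/<20/<30/<50. The operation is order-independent in its arguments and is
tested against a brute-force oracle.

## Balancing and classification

SMOTE raises the minority class to the majority count; each synthetic sample
is x + u·(x_nn − x), u ∼ U(0,1), toward one of k = 5 nearest minority
neighbors; originals are preserved verbatim and every synthetic lies on a
minority segment (tested by reconstruction). A minority smaller than k + 1 is
an error advising a smaller k.

Two SMOTE placements are exposed because they answer different questions:
`pre` (the published protocol) balances the whole table before CV — synthetic
relatives of test subjects can then appear in training folds, which biases
metrics optimistically; `fold` re-balances inside each training fold only and
is the leakage-safe default recommendation for new analyses. The ablation
helper runs both arms on identical folds and reports paired deltas.

SVM: RBF kernel, z-scaling fit per training fold. Standard mode pins γ = 0.1,
C = 1; optimized mode samples 50 (γ, C) pairs log-uniformly from γ ∈ [1e−4, 1],
C ∈ [0.1, 100] — ranges bracketing the optima reported for plantar cohorts —
and keeps the best mean CV accuracy. Metrics are binary with diabetic (=1)
positive; report std is the fold-wise population standard deviation.

## Problem sizes

The recovery benchmark runs the full training protocol (500 epochs × 5 folds)
on the 176 × 141 balanced table — about 10 s per neural selector fit; the
stochastic selectors are benchmarked over five seeds. End-to-end pipeline
tests use a scaled-down cohort (18 + 10 subjects, 80 × 104 px phantoms,
25-epoch selectors, 4 search draws), which exercises every stage boundary
while keeping the default suite around two minutes.

## Known limitations

* Angiosome geometry is a documented proxy, not a registration to arterial
  anatomy; features tied to exact boundaries (per-angiosome moments) inherit
  this approximation on real data.
* The composite indices (HSE, ET, NTR, TCI) are reconstructions; their
  defining publications are not reprinted here, and defaults may differ from
  the originals in detail. All are configurable.
* The `pre` SMOTE placement reproduces the published protocol including its
  leakage; metrics from that mode should not be read as generalization
  estimates.
* Phantom-based results validate code paths, not clinical discrimination; no
  claim is made about performance on real thermograms.
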