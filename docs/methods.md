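# Methods

This note documents the models, numerical choices and defaults behind
`connectogcn`, and what the synthetic validation does and does not show.

## Synthetic multisite cohort

The generator (`connectogcn.synth`) draws regional BOLD-like time series
from a latent-factor Gaussian model, which makes every implied correlation
matrix positive definite by construction and every target correlation exact
at the population level:

* every region loads `sqrt(background_r)` on a global factor
  (`background_r = 0.1`);
* non-signal regions additionally load on one of six block factors of 15
  regions each, giving within-network correlation `within_block_r = 0.4` —
  blocks exist so that KNN node neighborhoods are non-trivial (pure white
  noise would give degenerate graphs);
* the designated signal regions share a *signal factor* instead of their
  block factor, giving `signal_within_r = 0.7` among themselves.

**Disease effect.** Patients' signal-factor loading is reduced so that the
correlation between any two signal regions drops by
`effect_size × m_subject`, where the per-subject effect magnitude
`m ~ N(1, 0.25²)` is truncated symmetrically (±2.8 sd, so its mean stays 1)
and additionally capped at
`(signal_within_r − background_r) / effect_size` to keep the loading real.
This models hypoconnectivity with between-subject severity variation; edges
not connecting two signal regions are identical in distribution across
groups. Default `effect_size = 0.3`; the recovery experiments use 0.5.

**Sites.** The default layout is six sites with (patients, controls) =
(301, 217), (0, 340), (49, 63), (32, 83), (67, 72), (56, 132) — a 1412-
subject cohort of 505 patients and 907 controls in which the second site
contributed controls only. Site effects are injected at the Fisher-z edge
level (where ComBat operates, not in the time series):
`y → γ_site(edge) + δ_site(edge)·y` with `γ ~ N(0, site_shift²)`
(`site_shift = 0.3`) and `δ` lognormal with mean exactly 1 and sd
`site_scale = 0.2` (lognormal so δ > 0 always). Site parameters are drawn
once per site×edge from the seed and are independent of diagnosis.

**Symptoms.** Patients' negative-symptom raw score is built from the
standardized effect magnitude mixed with Gaussian noise at correlation
`symptom_coupling` (default 0.6), mapped onto a PANSS-negative-like 7–49
scale (center 17, spread 7) and clipped; the positive score is independent
noise (center 20, spread 9). Controls carry no scores, mimicking scales
administered to patients only. Clipping slightly attenuates the realized
coupling (well under the ±0.1 tolerance used in tests).

**What the generator does not emulate:** raw 4D volumes, head motion,
physiological noise, non-Gaussian BOLD marginals, spatial autocorrelation
of the parcellation, site-by-diagnosis interactions, and medication or
demographic confounding. Passing tests therefore demonstrate that the
pipeline recovers planted structure under its own statistical assumptions —
not that it would achieve comparable performance on real clinical data.

## Connectivity

Pearson correlation between all pairs of regional time series, diagonal set
to 0 (self-connectivity is meaningless as a node feature and a zero
diagonal keeps KNN distances finite), then Fisher r-to-z with r clipped at
±(1 − 1e−7) so perfect correlations stay finite. The edge vector is the
row-major strict upper triangle — one ordering declared once and shared by
the ComBat, SVM and topology modules (4005 edges for 90 regions).

## ComBat harmonization

Parametric empirical-Bayes ComBat, fitted per edge. Standardization uses
OLS on the full batch+covariate design; the pooled residual variance uses
the design's degrees of freedom, which makes the non-EB variant exactly
idempotent. Site locations γ̂ and scales δ̂² are shrunk by iterative
conditional updates (normal prior on γ, inverse-gamma on δ² with
moment-matched hyperparameters; convergence 1e-6, max 100 iterations) and
removed; covariate effects — diagnosis, age, sex — are restored, so the
case-control contrast is protected. `transform` applies a fitted model to
new subjects of known sites, enabling fold-wise harmonization.

Two deliberate consequences of EB shrinkage are worth stating: per-site
empirical means and variances are equalized only up to the fraction of the
per-edge sampling noise the shrinkage leaves in place, and a second
application of ComBat is a small but nonzero adjustment (RMS well under 1%
of the first). The `eb=False` option removes the raw γ̂, δ̂ instead, which
equalizes per-site moments exactly and is exactly idempotent, at the price
of borrowing no strength across edges. Tests cover both regimes.

The audit (`site_effect_scan`) is a per-edge one-way ANOVA across sites
within a chosen subgroup with Benjamini–Hochberg FDR at q = 0.05; the
two-site case reduces to a t-test. The test and correction for this audit
are configurable since any choice here is a convention.

## Graph construction

Node features are rows of the z-matrix (diagonal 0 included — one
consistent feature definition). Each node connects to its k = 10 nearest
neighbors by Euclidean distance between feature rows; ties break toward the
lower region index for determinism. The directed lists are symmetrized by
union (`W_ij = max(w_ij, w_ji)`), so no chosen neighbor is ever dropped.
Gaussian weights `exp(−d²/2σ²)` with σ the mean selected distance are the
default; binary weights are kept for ablation. Graph convolution uses the
renormalized operator `Ŵ = D̃^{-1/2}(W + I)D̃^{-1/2}` whose spectrum lies
in [−1, 1].

## GCN and CAM

Architecture: graph convolutions of widths (64, 64, 128) with ReLU, global
average pooling, one linear head — exactly this topology so that CAM is an
exact decomposition rather than a gradient approximation. Training:
class-weighted cross-entropy (inverse-frequency weights by default; the
default cohort is 505 vs 907), Adam (lr 1e-3, weight decay 5e-4), batch
size 32, up to 200 epochs with early stopping (patience 20) on an inner
stratified 10% validation split of the training data only; the returned
model is the best-validation snapshot. All arithmetic during training is
single precision with seeded initialization and shuffling, so runs are
bit-reproducible on a fixed platform; inference accumulates in double
precision so the GAP-CAM identity holds to ~1e-12.

Two identifiability choices:

* **Head gauge.** Softmax is invariant to adding a common vector to all
  class weights/biases, so the class-shared component of the head is
  unidentified and contaminates per-class CAM with activation common to
  both classes. After training the head is canonicalized to the zero-sum
  gauge (`w_patient = −w_control`), which changes no prediction and makes
  CAM purely discriminative; patient- and control-CAM then rank regions
  identically in magnitude.
* **Saliency ranking.** Regions are ranked by |mean activation| by default:
  planted *hypo*connectivity produces evidence with a negative sign at the
  affected nodes, and saliency should reflect the magnitude of a region's
  contribution regardless of direction. Signed ranking is available.

## Linear SVM baseline

`SVC(kernel="linear")` on the upper-triangle edge vector; C selected from
{1e-3 … 1e3} by an inner stratified 10-fold grid search maximizing balanced
accuracy, then refit on the full training set. Region weights are the mean
over a region's 89 incident edges of the absolute hyperplane weights
(default; "mean of the weights" is ambiguous, and magnitude reflects
contribution — the signed mean is kept as an option), averaged across folds
when a stack of fold models is supplied.

## Nodal topology and clinical correlation

Networks are thresholded to the strongest 20% of positive z-edges (negative
edges are discarded — path-length semantics need nonnegative weights; the
sparsity is configurable since any threshold is a convention). Centralities
use edge length = 1/weight: degree is the sum of incident weights
(strength), nodal efficiency is the mean inverse shortest-path length to
all other nodes (unreachable → 0), betweenness counts shortest paths
through a node with each unordered source-target pair counted once and
ties contributing fractionally. Group differences use a 10,000-permutation
two-tailed test on the difference of group means with
`p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1)`; FDR runs over the tested
regions × metrics family, separately for the GCN- and SVM-derived salient
sets. Symptom scores are standardized to Percent of Maximum Possible,
`100·(raw − min)/(max − min)`, with scale bounds carried in the subject
table rather than hard-coded; correlations are Pearson on complete cases
with FDR across regions × metrics × symptom dimension.

## Cross-validation and reporting

Stratified k-fold (default 10) preserves class proportions per fold; LOSO
holds out each site in turn, skipping sites that contain a single class
(they remain in training and are listed in the report). Balanced accuracy
= (sensitivity + specificity)/2 is asserted as an identity on every report
row. AUC is the rank-based (Mann–Whitney) statistic with midrank ties. CIs:
normal approximation across fold estimates for k-fold; for LOSO, where
per-site estimates are few and heterogeneous, a 1000-resample subject-level
bootstrap of the pooled test predictions. The CI method is stamped into
each report. Fold models receive seeds derived deterministically from the
scheme seed, and all report files are written with fixed float formats, so
a config + seed reproduces them byte-identically.

## Problem sizes used in the shipped experiments

The test-suite experiments run at deliberately modest scale: recovery runs
use 90 regions, 150 subjects per group, 200 timepoints and five seeds; the
harmonization audit uses 4 sites × 60 controls; calibration uses 500 null
simulations at 999 permutations; oracle equivalence uses 200 random graphs
of up to 8 nodes. These sizes give stable pass/fail behavior for the
planted effects while keeping a full run of the suite in the low minutes on
one CPU.

## Known limitations

* The GCN is CPU-bound NumPy; it is sized for ~10²–10³ subjects and ~10²
  regions, not for large parcellations or deep stacks.
* Exact bit-reproducibility holds for a fixed BLAS/platform; across
  platforms results agree only to floating-point tolerance.
* Pooled-first harmonization (the default, matching the replicated design)
  leaks distributional information across CV folds; use
  `within_folds: true` for strict separation.
* The hyperparameters of the GCN (widths, optimizer settings, epochs) are
  declared defaults of this package, exposed in `GCNClassifier`; no claim
  is made that they match any particular prior implementation.
* Saliency recovery is validated against planted ground truth only; on
  real data CAM rankings inherit all the identifiability caveats of
  post hoc attribution methods.
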