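# Methods

## Scope and model

The package predicts a binary radiation-pneumonitis (RP) outcome from
features of the 3-D dose distribution and the pre-treatment CT of the
lungs. Four logistic models are compared — DVH features only, dosiomic
features, CT radiomic features, and dosiomic+radiomic — on an
esophageal-style cohort (positive class: RP grade ≥ 1, ~62% prevalence),
and the esophageal-selected features are re-evaluated on a lung-style
cohort (positive class: grade ≥ 2, ~17% prevalence) to probe
transferability. Real cohorts of this kind are access-restricted, so the
package operates on synthetic phantoms whose statistical structure mirrors
the analysis assumptions; every empirical claim the test suite makes is
therefore a claim about *method behaviour under known ground truth*, not
about clinical performance.

## Dose accumulation

Per-fraction, per-voxel doses are accumulated into equivalent dose in 2-Gy
fractions under the linear-quadratic model,
`EQD2_k = Σ_i (d_ik + d_ik²/(α/β)) / (1 + 2/(α/β))`, with α/β configurable
and defaulting to 3 Gy (conventional for late lung toxicity). Applying the
correction fraction-by-fraction handles heterogeneous fractionation exactly
(e.g. alternating beam arrangements). Key algebraic properties are tested:
the all-2-Gy fixed point (EQD2 ≡ physical sum to 1e−12 relative),
hypofractionation penalty, additivity over fraction subsets, and the
α/β → ∞ limit. Accumulation happens on the native planning grid *before*
resampling, so each fraction is interpolated once at most.

## Geometry

All volumes are resampled to an isotropic analysis grid (1.5 mm default)
with cubic B-spline interpolation; masks use nearest-neighbour and stay
boolean. Output grids are voxel-center aligned (the origin is preserved and
output centers stay inside the input center hull), and the array is padded
by 12 voxels of odd reflection before spline prefiltering. Odd reflection
extends linear trends exactly, so a linear dose ramp is reproduced to
better than 1e−6 everywhere including the boundary — mirror-type boundary
handling in off-the-shelf resamplers leaves ~0.1 Gy edge artefacts on the
same test. Evaluation ROIs: `lung_eval` is the bilateral lungs (minus GTV
for lung-cancer patients); `lung_gt10`/`lung_gt20` keep lung voxels whose
total dose *strictly* exceeds 10/20 Gy. Strict ">" is used consistently for
ROI thresholds and Vx (many planning systems use "≥"; the difference is
visible on exact-valued synthetic doses). Patients with an empty
dose-thresholded sub-ROI get a missing radiomic block and are excluded
listwise from models that need it.

## Feature catalog

Per extraction context the catalog is 78 features: 17 first-order
statistics — the standard set *minus the mean*, which is excluded in all
three contexts because the mean dose duplicates MLD and a single uniform
catalog keeps the printed totals consistent (3 × 78; 51 first-order in
total) — plus 24 GLCM, 16 GLRLM, 16 GLSZM and 5 NGTDM features. Texture
matrices follow IBSI conventions: symmetric distance-1 GLCM summed over the
13 unique 3-D offsets before feature computation; GLRLM merged over the
same 13 directions (run percentage normalizes by 13 × voxel count); GLSZM
zones and NGTDM neighbourhoods under 26-connectivity, restricted to the
ROI. Matrices are indexed by the gray levels present in the ROI and
weighted by the actual level values; Ng in normalized GLCM features (IDMN,
IDN) is the number of present levels.

Discretization is fixed-bin-size, left-closed/right-open with level 1 at
zero: dose uses 1-Gy bins capped at level 100; CT HU are clamped to
[−1000, 100] (clamping, not zeroing — the stated resulting intensity range
requires it), shifted by +1000 and binned at width 50 (≤ 23 levels; the
exact value 1100 maps into the top bin). First-order intensity statistics
use the raw ROI values; entropy and uniformity use the discretized
histogram. Degenerate inputs have fixed fallbacks: GLCM correlation and MCC
on constant input are 1, information measures with zero denominators are 0,
NGTDM ratios with empty denominators are 0, skewness/kurtosis of a constant
are 0, and NGTDM coarseness of a perfectly homogeneous region is 1e6.

Every texture feature is verified on random ≤ 5×5×5 level grids against an
independent brute-force enumeration (plain Python loops over voxels, runs,
zones and matrix entries) to 1e−9, and the merged-offset construction makes
all features invariant under axis permutations, which is also tested.

## Synthetic cohorts

Phantoms are schematic: two ellipsoidal low-HU lungs (−700 ± 40 HU) in a
soft-tissue background (40 ± 30 HU), an optional spherical GTV inside one
lung (lung-cancer phantoms), and a mediastinal or intrapulmonary target.
Per-fraction doses alternate between an antero-posterior beam and opposed
laterals (Gaussian cross-profiles, exponential depth falloff), scaled so
the per-fraction target dose is prescription/N with the prescription drawn
per patient (41.4–54 Gy esophageal, 50–66 Gy lung; 25–30 fractions). Each
fraction is modulated by a smooth multiplicative noise field whose
amplitude is a per-patient latent "heterogeneity" draw; the same latent
also controls the number and intensity of high-HU nodular lung lesions in
the CT. This is deliberately *not* anatomically or dosimetrically realistic
(no organs beyond lungs/GTV, no motion, no TPS dose algorithm); the
analysis only consumes masks and intensities, and what passing tests show
is that the pipeline recovers known planted structure — not that it
predicts clinical RP.

Outcomes follow a logistic model
`logit P(RP) = c + b_mld·MLD + b_tex·H + ε`, where MLD is the mean EQD2
lung dose and H is the planted heterogeneity score: the cohort-standardized
weighted sum `0.35·z(var dose levels) + 1.0·z(var CT levels)` of the
within-lung variances of the discretized dose and CT. The CT component
dominates by design — dose-histogram variance is largely recoverable from
V5–V70, so a dose-only score would let the DVH model absorb the "texture"
effect, while CT texture is invisible to DVH metrics. Defaults
`b_mld = 0.25` per Gy, `b_tex = 1.4` per unit and `ε ~ N(0, 0.5)` give
log-odds contributions of roughly one SD each and DVH/combined ROCAUCs
around 0.70/0.76 — comparable in magnitude and ordering to published RP
models. The intercept `c` is solved by bisection so the expected prevalence
matches the target (0.62 esophageal, 0.17 lung); if the planted effects
push every patient's probability outside the reachable range the generator
fails loudly, naming the achievable interval. Positives are assigned grade
1 (majority) or 2 in esophageal cohorts and grade 2 (majority) or 3 in lung
cohorts, mirroring the emulated grade mix; negatives are grade 0.
Everything derives from `numpy.random.SeedSequence` children of the spec
seed, so a cohort is bit-reproducible.

## Selection and evaluation

Stage 1 keeps features with univariate logistic Wald p < 0.1 (statsmodels
maximum-likelihood fits; constant features are excluded with a warning;
perfect separation counts as p = 0 and is kept). Stage 2 ranks survivors by
the mean held-out ROCAUC of an unregularized univariate logistic model over
50 repetitions of stratified 5-fold CV and keeps the top 10 per group, with
ties broken by smaller univariate p, then name. Folds are stratified (not
stated in most published descriptions of such pipelines, but necessary to
guarantee both classes per fold at 17% prevalence). If no feature passes
the filter the smallest-p feature is kept so downstream stages remain
well-defined. An anti-leakage variant re-runs selection inside each outer
training split (`PneumonitisModel(..., selection=(cfg, group))`).

Evaluation uses stratified Monte-Carlo 80/20 outer splits (500 by default).
Per split: features are standardized on outer-train statistics only; an
inner loop (250 Monte-Carlo 80/20 splits of outer-train by default)
SMOTE-balances each inner-train and grid-searches the ridge strength
maximizing mean validation ROCAUC; the model is refit on the SMOTE-balanced
outer-train at the chosen strength and scored on the untouched test split.
SMOTE synthesizes minority points as `x + u·(x_nn − x)`, u ~ U(0,1), x_nn
among the k = 5 nearest minority neighbours (k shrinks with a warning when
the minority is small); the final refit is SMOTE-balanced symmetrically
with the inner loop. The L2 logistic solver is a damped-Newton minimizer of
`NLL + λ/2·‖w‖²` with unpenalized intercept, deterministic, and agrees with
scikit-learn's LBFGS solver to 1e−6; with λ = 0 on separable data it stops
at the iteration cap with near-perfect fitted probabilities (logged, not an
error), which only concerns the univariate ranking stage. ROCAUC is the
Mann-Whitney statistic with ties counted ½; PRAUC is the step (rectangle)
integral of the precision-recall curve over descending distinct-score
thresholds — identical to average precision, no interpolation. Model pairs
are compared with an *unpaired* two-sample Z-test on the per-split metric
lists, taken literally from the procedure it reimplements even though the
splits are shared; a paired variant (`paired=True`) is provided and is the
statistically tighter choice when split lists are common. The default
regularization grid is 13 log-spaced strengths in 1e−3…1e3.

The stored per-split diagnostics (chosen strength, scaler means, test
indices) support a leakage audit: perturbing rows only changes artifacts of
splits where those rows fall in the *training* portion.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced configurations chosen as the
package's own trade-off between statistical resolution and turnaround:
phantom grids of 16–24 voxels per axis at 3 mm spacing, 40–200 outer /
10–25 inner splits, and a 5-point regularization grid (1e−2…1e2). The
ordering check (combined > DVH) uses 20 generator seeds at n = 70; the
no-signal calibration uses 200 outer splits on an 80-patient null cohort.
Reported summaries (mean, SD, 10th/90th percentiles) are always
recomputable from the stored per-split lists. Seeds fan out through
`SeedSequence` with fixed stage keys, so any stage can be reproduced in
isolation and the full-study runner is byte-deterministic.

## Known limitations

- Phantom anatomy and dosimetry are schematic; absolute AUC values have no
  clinical meaning and depend on the planted effect sizes.
- The EQD2/physical choice for thresholding sub-ROIs and DVH features
  defaults to EQD2 (`use_eqd2=False` switches both); only one dose
  representation feeds the feature catalog per run.
- The within-CV selection variant is provided but the headline pipeline
  selects features on the full source cohort, which is optimistically
  biased for the source-cohort results (and is precisely why the transfer
  evaluation exists).
- DICOM/DICOM-RT ingestion, deformable registration, wavelet/filtered
  feature classes and non-logistic classifiers are out of scope.
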