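# dosiomics-rp

Radiation pneumonitis (RP) is the dose-limiting lung toxicity of thoracic
radiotherapy. The classical way to predict it is through dose-volume
histogram (DVH) summaries of the lung dose — the mean lung dose (MLD) and
the relative volumes Vx receiving more than x Gy. DVH metrics, however,
discard all spatial structure. **dosiomics-rp** implements an RP-prediction
pipeline that asks whether texture features of the 3-D dose distribution
(*dosiomics*) and of the pre-treatment CT (*radiomics*) improve on DVH
features, and whether features selected on one cancer cohort (esophageal)
transfer to another (lung). Because real treatment-planning data of this
kind are access-restricted, the package ships a synthetic phantom-cohort
generator with planted, recoverable dose and texture effects, so the entire
analysis is reproducible end to end from a seed.

## What it computes

1. **EQD2 accumulation.** Per-fraction, per-voxel doses d_ik are accumulated
   into the equivalent dose in 2-Gy fractions under the linear-quadratic
   model (α/β = 3 Gy by default):

   D_EQD2(k) = Σ_i [ d_ik + d_ik² / (α/β) ] / [ 1 + 2 / (α/β) ]

2. **Feature extraction** on a 1.5 mm isotropic grid (cubic B-spline for
   volumes, nearest-neighbour for masks): 15 DVH features (MLD, V5–V70 with
   a strict ">" threshold), 78 dosiomic features of the EQD2 dose in the
   lung ROI, and 2 × 78 radiomic features of the CT in the lung sub-regions
   receiving more than 10 and 20 Gy — 249 features per patient. The
   78-feature catalog per context is 17 first-order statistics (the standard
   set minus the mean) plus 24 GLCM, 16 GLRLM, 16 GLSZM and 5 NGTDM texture
   features under IBSI conventions (fixed 1-Gy bins capped at level 100 for
   dose; HU clamped to [−1000, 100], shifted and binned at width 50 for CT).

3. **Feature selection** (per group, on the esophageal cohort): univariate
   logistic regression keeps features with Wald p < 0.1, then 50 repetitions
   of stratified 5-fold CV rank survivors by mean held-out ROCAUC; the top
   10 per group enter the multivariate models.

4. **Model evaluation** by nested Monte-Carlo cross-validation: stratified
   80/20 outer splits; per split, an inner loop of Monte-Carlo 80/20 splits
   with SMOTE balancing grid-searches the L2 regularization strength
   maximizing validation ROCAUC; the refit model is scored on the outer test
   split by ROCAUC and PRAUC. Four models are compared (DVH, dosiomic,
   radiomic, dosiomic+radiomic) with a two-sample Z-test on mean AUCs, and
   the esophageal-selected features are transfer-evaluated on the lung
   cohort next to a DVH baseline selected on the lung cohort itself.

## Worked example

```python
import numpy as np
from dosiomics_rp import (
    CohortSpec, EvalConfig, PneumonitisModel, SelectionConfig,
    extract_cohort_features, generate_cohort, select_features,
)

spec = CohortSpec(n_patients=70, grid_shape=(16, 16, 12), seed=11)
table = extract_cohort_features(generate_cohort(spec))
y = table["label"].to_numpy()

sel = SelectionConfig(n_repeats=3, seed=11)
dvh = select_features(table, y, "dvh", sel).selected
dos = select_features(table, y, "dosiomic", sel).selected
rad = select_features(table, y, "radiomic", sel).selected

cfg = EvalConfig(n_outer_splits=40, n_inner_splits=20,
                 reg_strength_grid=tuple(np.logspace(-2, 2, 5)), seed=11)
print(PneumonitisModel(table, y, dvh, cfg, name="dvh").fit().summary())
print(PneumonitisModel(table, y, dos + rad, cfg, name="combined").fit().summary())
```

prints (ROCAUC/PRAUC mean, SD and 10th/90th percentiles over the 40 outer
test splits):

```
            mean        sd       p10       p90
dvh
rocauc  0.700521  0.127266  0.537500  0.875000
prauc   0.786495  0.094102  0.662417  0.908221
              mean        sd       p10       p90
combined
rocauc    0.744271  0.133189  0.581250  0.918750
prauc     0.817964  0.097453  0.710652  0.942629
```

The phantom cohort plants an MLD effect and a dose/CT heterogeneity effect
in the outcome, so the combined dosiomic+radiomic model (mean ROCAUC 0.74)
outperforms the DVH-only model (0.70) — the qualitative ordering the method
is designed to detect.

A command-line interface wraps the same pipeline:

```bash
dosiomics-rp generate --cohort esophageal --seed 1 --out cohort/
dosiomics-rp accumulate --manifest cohort/manifest.csv --alpha-beta 3 --mode eqd2 --out totals/
dosiomics-rp extract --manifest cohort/manifest.csv --out features.csv
dosiomics-rp run-all --seed 1 --outer 100 --inner 25 --out run/
```

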