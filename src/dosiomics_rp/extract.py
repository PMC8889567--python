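"""Per-patient feature extraction: 15 DVH + 78 dosiomic + 156 radiomic columns.

The extraction pipeline per patient is: accumulate the per-fraction doses on
the native grid (EQD2 by default), resample CT and total dose to the
isotropic analysis grid (B-spline) and the masks alongside (nearest
neighbour), derive the evaluation ROIs, then read

- DVH features (MLD, V5..V70) of the total dose in ``lung_eval``,
- the 78 dosiomic features of the total dose in ``lung_eval``,
- the 78 radiomic features of the CT in each of ``lung_gt10``/``lung_gt20``.

Column naming: DVH columns are plain (``MLD``, ``V5``...), texture columns
are ``<group>__<context>__<family>__<feature>`` (e.g.
``dosiomic__lung_eval__glcm__contrast``).  Patients whose dose-thresholded
sub-ROI is empty get NaN for that radiomic block and are excluded listwise
from models that use it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import PhantomPatient, positive_label
from .dvh import compute_dvh
from .eqd2 import Eqd2Params, accumulate_eqd2, accumulate_physical
from .grids import ImageVolume, RoiMask
from .texture import (
    CT_DISCRETIZATION,
    DOSE_DISCRETIZATION,
    FEATURE_NAMES,
    compute_features,
)
from .volume_ops import ANALYSIS_SPACING_MM, derive_rois, resample_mask, resample_volume

__all__ = [
    "DVH_COLUMNS",
    "DOSIOMIC_COLUMNS",
    "RADIOMIC_COLUMNS",
    "METADATA_COLUMNS",
    "feature_group_columns",
    "prepare_patient",
    "extract_patient_features",
    "extract_cohort_features",
]

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("patient_id", "cancer_type", "rp_grade", "label")

DVH_COLUMNS: tuple[str, ...] = ("MLD",) + tuple(f"V{x}" for x in range(5, 75, 5))
DOSIOMIC_COLUMNS: tuple[str, ...] = tuple(
    f"dosiomic__lung_eval__{name}" for name in FEATURE_NAMES
)
RADIOMIC_COLUMNS: tuple[str, ...] = tuple(
    f"radiomic__{ctx}__{name}"
    for ctx in ("lung_gt10", "lung_gt20")
    for name in FEATURE_NAMES
)

_GROUPS = {
    "dvh": DVH_COLUMNS,
    "dosiomic": DOSIOMIC_COLUMNS,
    "radiomic": RADIOMIC_COLUMNS,
    "combined": DOSIOMIC_COLUMNS + RADIOMIC_COLUMNS,
}


def feature_group_columns(group: str) -> tuple[str, ...]:
    """Column names of one feature group: dvh | dosiomic | radiomic | combined."""
    try:
        return _GROUPS[group]
    except KeyError:
        raise ValueError(f"unknown feature group {group!r}; expected one of {sorted(_GROUPS)}")


def prepare_patient(
    patient: PhantomPatient,
    alpha_beta: float = 3.0,
    use_eqd2: bool = True,
    target_spacing_mm=ANALYSIS_SPACING_MM,
) -> tuple[ImageVolume, ImageVolume, dict[str, RoiMask]]:
    """Accumulate, resample to the analysis grid and derive ROIs.

    Returns ``(ct, total_dose, rois)`` on the analysis grid.  Accumulation
    happens before resampling so each fraction grid is interpolated once.
    """
    if use_eqd2:
        total = accumulate_eqd2(patient.fraction_doses, Eqd2Params(alpha_beta))
    else:
        total = accumulate_physical(patient.fraction_doses)
    ct = resample_volume(patient.ct, target_spacing_mm, method="bspline")
    dose = resample_volume(total, target_spacing_mm, method="bspline")
    # B-spline overshoot can produce tiny negative dose; physical dose is >= 0
    dose = dose.with_values(np.clip(dose.values, 0.0, None))
    lung = resample_mask(patient.lung_mask, target_spacing_mm)
    gtv = (
        resample_mask(patient.gtv_mask, target_spacing_mm)
        if patient.gtv_mask is not None
        else None
    )
    rois = derive_rois(lung, gtv, dose, patient.cancer_type)
    return ct, dose, rois


def extract_patient_features(
    patient: PhantomPatient,
    alpha_beta: float = 3.0,
    use_eqd2: bool = True,
    target_spacing_mm=ANALYSIS_SPACING_MM,
) -> dict[str, float]:
    """One 249-entry feature row (plus metadata) for a phantom patient."""
    ct, dose, rois = prepare_patient(patient, alpha_beta, use_eqd2, target_spacing_mm)
    row: dict[str, float] = {
        "patient_id": patient.patient_id,
        "cancer_type": patient.cancer_type,
        "rp_grade": patient.rp_grade,
        "label": positive_label(patient.rp_grade, patient.cancer_type),
    }
    row.update(compute_dvh(dose, rois["lung_eval"]).as_dict())
    dosio = compute_features(dose, rois["lung_eval"], DOSE_DISCRETIZATION)
    row.update({f"dosiomic__lung_eval__{k}": v for k, v in dosio.items()})
    for ctx in ("lung_gt10", "lung_gt20"):
        roi = rois[ctx]
        if roi.n_voxels < 2:
            logger.warning(
                "patient %s: %s has %d voxels; radiomic block set to missing",
                patient.patient_id, ctx, roi.n_voxels,
            )
            row.update({f"radiomic__{ctx}__{name}": np.nan for name in FEATURE_NAMES})
            continue
        radio = compute_features(ct, roi, CT_DISCRETIZATION)
        row.update({f"radiomic__{ctx}__{k}": v for k, v in radio.items()})
    return row


def extract_cohort_features(
    patients: list[PhantomPatient],
    alpha_beta: float = 3.0,
    use_eqd2: bool = True,
    target_spacing_mm=ANALYSIS_SPACING_MM,
) -> pd.DataFrame:
    """Feature table: one row per patient, metadata + 249 feature columns."""
    rows = [
        extract_patient_features(p, alpha_beta, use_eqd2, target_spacing_mm)
        for p in patients
    ]
    df = pd.DataFrame(rows)
    ordered = list(METADATA_COLUMNS) + list(DVH_COLUMNS + DOSIOMIC_COLUMNS + RADIOMIC_COLUMNS)
    return df[ordered]
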