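"""Geometry layer: resampling to the analysis grid and ROI derivation.

All volumes (CT, accumulated dose) are resampled to a common isotropic grid
(1.5 mm by default) with cubic B-spline interpolation; masks use
nearest-neighbour so they stay boolean.  Before spline prefiltering the
volume is padded by odd reflection (linear-trend extension), so linear
intensity ramps are reproduced to numerical precision everywhere including
the grid boundary.

The evaluation ROIs are the bilateral lungs (minus the gross tumor volume
for lung-cancer patients) and their dose-thresholded sub-regions
``lung_gt10`` / ``lung_gt20`` — lung voxels whose total dose strictly
exceeds 10 / 20 Gy, the regions from which CT radiomic features are read.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .grids import GeometryError, ImageVolume, RoiMask

__all__ = ["resample_volume", "resample_mask", "derive_rois", "save_rois",
           "ANALYSIS_SPACING_MM"]

logger = logging.getLogger(__name__)

#: Isotropic analysis spacing (mm) used for feature extraction.
ANALYSIS_SPACING_MM = (1.5, 1.5, 1.5)

_METHOD_ORDER = {"bspline": 3, "nearest": 0, "linear": 1}

#: Spline-boundary padding width; coefficient boundary error decays like
#: (2 - sqrt(3))**distance, so 12 voxels leaves ~1e-7 of the edge kink.
_PAD = 12


def _target_size(shape, spacing, target_spacing) -> tuple[int, ...]:
    # Voxel-center alignment: keep the first voxel center (origin) fixed and
    # cover the input center span; the physical extent is preserved within
    # one voxel.
    return tuple(
        max(1, int(np.floor((n - 1) * s / t + 1e-9)) + 1)
        for n, s, t in zip(shape, spacing, target_spacing)
    )


def _resample_array(values, spacing, origin, target_spacing, order: int):
    size = _target_size(values.shape, spacing, target_spacing)
    # World x of index i is origin + i*spacing; output centers start at the
    # input origin and stay inside the input voxel-center hull.
    new_origin = tuple(origin)
    pad = _PAD if order > 1 else 1
    padded = np.pad(values.astype(np.float64), pad, mode="reflect", reflect_type="odd")
    axes = [
        (no + np.arange(n) * t - o) / s + pad
        for n, no, t, o, s in zip(size, new_origin, target_spacing, origin, spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(padded, coords, order=order, mode="nearest")
    return out, new_origin


def resample_volume(
    v: ImageVolume,
    target_spacing_mm,
    method: str = "bspline",
) -> ImageVolume:
    """Resample a scalar volume onto a grid with the requested spacing.

    ``method="bspline"`` (cubic B-spline, the default for CT and dose) or
    ``"nearest"``.  Resampling to the volume's own spacing returns the values
    unchanged; a constant volume stays constant under either method.
    """
    target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if method not in _METHOD_ORDER:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHOD_ORDER)}")
    if np.allclose(target, v.spacing_mm):
        return v
    out, new_origin = _resample_array(
        v.values, v.spacing_mm, v.origin_mm, target, _METHOD_ORDER[method]
    )
    return ImageVolume(values=out, spacing_mm=target, origin_mm=new_origin, modality=v.modality)


def resample_mask(m: RoiMask, target_spacing_mm) -> RoiMask:
    """Nearest-neighbour resampling of a boolean mask (stays boolean)."""
    target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if np.allclose(target, m.spacing_mm):
        return m
    out, new_origin = _resample_array(
        m.values.astype(np.float64), m.spacing_mm, m.origin_mm, target, 0
    )
    return RoiMask(values=out > 0.5, spacing_mm=target, origin_mm=new_origin)


def derive_rois(
    lung: RoiMask,
    gtv: RoiMask | None,
    total_dose: ImageVolume,
    cancer_type: str,
) -> dict[str, RoiMask]:
    """Derive the evaluation ROIs used for feature extraction.

    Returns ``{"lung_eval", "lung_gt10", "lung_gt20"}`` where ``lung_eval`` is
    the bilateral lungs (esophageal) or lungs minus GTV (lung cancer) and
    ``lung_gtX`` keeps lung voxels with total dose strictly greater than
    ``X`` Gy.  The nesting ``lung_gt20 ⊆ lung_gt10 ⊆ lung_eval`` holds by
    construction.  An empty ``lung_gtX`` is returned as-is (the caller marks
    the corresponding radiomic block missing); an empty ``lung_eval`` is an
    error.
    """
    if not lung.same_geometry(total_dose):
        raise GeometryError("lung mask and total dose are not on the same grid")
    eval_values = lung.values
    if cancer_type == "lung":
        if gtv is None:
            raise ValueError("lung-cancer patients require a GTV mask")
        if not gtv.same_geometry(lung):
            raise GeometryError("GTV mask and lung mask are not on the same grid")
        eval_values = lung.values & ~gtv.values
    if not eval_values.any():
        raise ValueError("evaluation lung ROI is empty")
    rois = {"lung_eval": lung.with_values(eval_values)}
    for x in (10, 20):
        sub = eval_values & (total_dose.values > x)
        if not sub.any():
            logger.warning("lung_gt%d is empty: no lung voxel exceeds %d Gy", x, x)
        rois[f"lung_gt{x}"] = lung.with_values(sub)
    return rois


def save_rois(rois: dict[str, RoiMask], directory) -> "Path":
    """Serialize an ROI map as one NIfTI per ROI plus a JSON index."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, mask in rois.items():
        path = directory / f"{name}.nii.gz"
        mask.to_nifti(path)
        index[name] = {"path": str(path), "n_voxels": mask.n_voxels}
    index_path = directory / "rois.json"
    with open(index_path, "w") as fh:
        json.dump(index, fh, indent=2)
    return index_path
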