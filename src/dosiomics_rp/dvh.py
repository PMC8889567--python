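"""Dose-volume histogram scalar features: mean lung dose and Vx.

Vx is the percentage of the ROI volume receiving a dose *strictly greater*
than x Gy, for x = 5, 10, ..., 70 (14 thresholds); together with the mean
lung dose (MLD) this yields the 15 DVH features.  Note many treatment
planning systems report Vx with ">=" — here the threshold is strict, so a
uniform 10-Gy dose gives V10 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GeometryError, ImageVolume, RoiMask

__all__ = ["VX_THRESHOLDS_GY", "DvhFeatures", "compute_dvh"]

VX_THRESHOLDS_GY: tuple[int, ...] = tuple(range(5, 75, 5))


@dataclass(frozen=True)
class DvhFeatures:
    mld_gy: float
    vx_percent: dict[int, float]
    #: absolute Vx in cm^3, provided alongside the relative default
    vx_cm3: dict[int, float]

    def as_dict(self, relative: bool = True) -> dict[str, float]:
        """Named feature map: ``{"MLD": ..., "V5": ..., ..., "V70": ...}``."""
        vx = self.vx_percent if relative else self.vx_cm3
        out = {"MLD": self.mld_gy}
        out.update({f"V{x}": vx[x] for x in VX_THRESHOLDS_GY})
        return out


def compute_dvh(dose: ImageVolume, roi: RoiMask) -> DvhFeatures:
    """Compute MLD and V5..V70 of ``dose`` within ``roi``.

    MLD is the arithmetic mean dose over ROI voxels; Vx is
    ``100 · |{k in roi : dose_k > x}| / |roi|`` (strict inequality).
    """
    if not dose.same_geometry(roi):
        raise GeometryError("dose and ROI are not on the same grid")
    if roi.n_voxels == 0:
        raise ValueError("cannot compute a DVH over an empty ROI")
    d = dose.values[roi.values]
    n = d.size
    voxel_cm3 = roi.voxel_volume_mm3 / 1000.0
    vx_percent = {}
    vx_cm3 = {}
    for x in VX_THRESHOLDS_GY:
        count = int((d > x).sum())
        vx_percent[x] = 100.0 * count / n
        vx_cm3[x] = count * voxel_cm3
    return DvhFeatures(mld_gy=float(d.mean()), vx_percent=vx_percent, vx_cm3=vx_cm3)
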