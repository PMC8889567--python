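"""Fixed-bin-size gray-level discretization of dose and CT volumes.

Dose (Gy) is binned with a 1-Gy bin width capped at level 100; CT Hounsfield
units are clamped to [-1000, 100], shifted by +1000 into [0, 1100] and binned
with a 50-HU bin width.  Bins are left-closed/right-open with level 1
starting at 0 Gy (dose) or at the lower clamp (CT); the exact top-of-range
value maps into the final bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grids import GeometryError, ImageVolume, Modality, RoiMask

__all__ = ["DiscretizationSpec", "DOSE_DISCRETIZATION", "CT_DISCRETIZATION", "discretize"]


@dataclass(frozen=True)
class DiscretizationSpec:
    modality: Modality
    bin_width: float
    max_levels: int | None = None
    clamp_low: float | None = None
    clamp_high: float | None = None
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.clamp_low is not None and self.clamp_high is not None:
            if not self.clamp_low < self.clamp_high:
                raise ValueError("clamp_low must be below clamp_high")
        if self.max_levels is not None and self.max_levels < 1:
            raise ValueError("max_levels must be a positive integer")

    @property
    def n_levels(self) -> int:
        """Upper bound on the level index this spec can produce."""
        if self.clamp_low is not None and self.clamp_high is not None:
            span = (self.clamp_high - self.clamp_low)
            top = int(np.floor((span + self.shift + self.clamp_low) / self.bin_width)) + 1
            return top if self.max_levels is None else min(top, self.max_levels)
        assert self.max_levels is not None
        return self.max_levels


#: 1-Gy fixed bins capped at the 100-Gy level.
DOSE_DISCRETIZATION = DiscretizationSpec(
    modality=Modality.DOSE_GY, bin_width=1.0, max_levels=100
)

#: HU clamped to [-1000, 100], shifted to [0, 1100], 50-HU bins (<= 23 levels).
CT_DISCRETIZATION = DiscretizationSpec(
    modality=Modality.CT_HU,
    bin_width=50.0,
    clamp_low=-1000.0,
    clamp_high=100.0,
    shift=1000.0,
)


def discretize(v: ImageVolume, roi: RoiMask, spec: DiscretizationSpec) -> np.ndarray:
    """Map intensities to integer gray levels within the ROI.

    Returns an integer grid of the volume's shape with level >= 1 inside the
    ROI and 0 outside.
    """
    if not v.same_geometry(roi):
        raise GeometryError("volume and ROI are not on the same grid")
    if roi.n_voxels == 0:
        raise ValueError("cannot discretize over an empty ROI")
    x = v.values.astype(np.float64, copy=True)
    if spec.clamp_low is not None:
        x = np.clip(x, spec.clamp_low, spec.clamp_high)
    x = x + spec.shift
    levels = np.floor(x / spec.bin_width).astype(np.int64) + 1
    cap = spec.n_levels
    levels = np.minimum(levels, cap)
    levels = np.maximum(levels, 1)
    out = np.zeros(v.shape, dtype=np.int64)
    out[roi.values] = levels[roi.values]
    return out
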