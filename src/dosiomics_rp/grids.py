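"""Core 3-D grid containers: scalar volumes, boolean ROI masks, dose series.

Arrays are indexed ``(x, y, z)`` following the NIfTI convention; world
coordinates are given by a diagonal affine built from ``spacing_mm`` and
``origin_mm`` (no oblique orientations — radiotherapy dose grids exported for
analysis are axis-aligned).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "ImageVolume",
    "RoiMask",
    "DoseSeries",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when grids that must share a geometry do not."""


class Modality(str, enum.Enum):
    CT_HU = "CT_HU"
    DOSE_GY = "DOSE_GY"


def _as_triple(t: Sequence[float]) -> tuple[float, float, float]:
    a, b, c = (float(v) for v in t)
    return (a, b, c)


@dataclass(frozen=True)
class ImageVolume:
    """A scalar 3-D grid (CT in Hounsfield units or dose in Gy)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.DOSE_GY

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {values.shape}")
        if not np.isfinite(values).all():
            raise ValueError("volume contains non-finite values")
        spacing = _as_triple(self.spacing_mm)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", _as_triple(self.origin_mm))
        object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def geometry(self) -> tuple[tuple[int, ...], tuple[float, ...], tuple[float, ...]]:
        return (self.shape, self.spacing_mm, self.origin_mm)

    def same_geometry(self, other: "ImageVolume | RoiMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def with_values(self, values: np.ndarray, modality: Modality | None = None) -> "ImageVolume":
        return ImageVolume(
            values=values,
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            modality=self.modality if modality is None else modality,
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.float64), self.affine)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, modality: Modality = Modality.DOSE_GY) -> "ImageVolume":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such volume file: {path}")
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(np.abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(
            values=np.asanyarray(img.dataobj, dtype=np.float64),
            spacing_mm=spacing,
            origin_mm=origin,
            modality=modality,
        )


@dataclass(frozen=True)
class RoiMask:
    """A boolean 3-D grid aligned to a volume (lungs, GTV, dose-threshold ROIs)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got shape {values.shape}")
        if values.dtype != np.bool_:
            uniq = np.unique(values)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be boolean / 0-1")
            values = values.astype(bool)
        spacing = _as_triple(self.spacing_mm)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", _as_triple(self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_geometry(self, other: "ImageVolume | RoiMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def with_values(self, values: np.ndarray) -> "RoiMask":
        return RoiMask(values=values, spacing_mm=self.spacing_mm, origin_mm=self.origin_mm)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.uint8), self.affine)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "RoiMask":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such mask file: {path}")
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(np.abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(
            values=np.asanyarray(img.dataobj) > 0,
            spacing_mm=spacing,
            origin_mm=origin,
        )


@dataclass(frozen=True)
class DoseSeries:
    """Ordered per-fraction 3-D dose grids sharing one geometry.

    Fraction ``i`` holds the dose (Gy) delivered to every voxel in delivery
    ``i``; per-voxel values may differ across fractions (different beam
    arrangements on different days).
    """

    fractions: tuple[ImageVolume, ...] = field(default=())

    def __post_init__(self) -> None:
        fractions = tuple(self.fractions)
        if len(fractions) < 1:
            raise ValueError("a dose series needs at least one fraction")
        ref = fractions[0]
        for i, frac in enumerate(fractions):
            if frac.modality is not Modality.DOSE_GY:
                raise ValueError(f"fraction {i} is not a dose volume")
            if not ref.same_geometry(frac):
                raise GeometryError(
                    f"fraction {i} geometry {frac.geometry()} differs from "
                    f"fraction 0 geometry {ref.geometry()}"
                )
            if (frac.values < 0).any():
                raise ValueError(f"fraction {i} contains negative dose")
        object.__setattr__(self, "fractions", fractions)

    def __len__(self) -> int:
        return len(self.fractions)

    def __iter__(self) -> Iterable[ImageVolume]:
        return iter(self.fractions)

    @property
    def reference(self) -> ImageVolume:
        return self.fractions[0]

    def stacked(self) -> np.ndarray:
        """All fractions as one ``(n_fractions, nx, ny, nz)`` array."""
        return np.stack([f.values for f in self.fractions], axis=0)
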