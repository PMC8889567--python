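"""Construction of GLCM, GLRLM, GLSZM and NGTDM texture matrices.

All matrices are built on an integer level grid (0 outside the ROI, levels
>= 1 inside) and are indexed by the *present* gray levels (rows for absent
levels are dropped; feature formulas use the actual level values).

Conventions:

- GLCM: distance-1 voxel pairs, symmetric, counts summed over the 13 unique
  3-D direction offsets before normalization.
- GLRLM: maximal same-level runs along each of the 13 directions, the 13
  matrices summed.
- GLSZM: connected zones of equal level under 26-connectivity.
- NGTDM: per level i, ``n_i`` counts ROI voxels of level i that have at least
  one ROI voxel among their 26 neighbours and ``s_i`` sums |i - mean
  neighbour level| over those voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["OFFSETS_13", "TextureMatrices", "build_matrices"]

#: The 13 unique distance-1 3-D direction offsets (one per +/- pair of the 26).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class TextureMatrices:
    """Texture count matrices over the present gray levels.

    Attributes
    ----------
    levels : (Ng,) int array of gray levels present in the ROI, ascending.
    glcm : (Ng, Ng) symmetric co-occurrence counts (13 offsets, both orders).
    glrlm : (Ng, Lmax) run counts; column j holds runs of length j+1.
    glszm : (Ng, Zmax) zone counts; column j holds zones of size j+1.
    ngtdm_n : (Ng,) voxel counts with a valid neighbourhood.
    ngtdm_s : (Ng,) summed absolute differences from the neighbourhood mean.
    n_roi_voxels : total ROI voxel count.
    """

    levels: np.ndarray
    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    ngtdm_n: np.ndarray
    ngtdm_s: np.ndarray
    n_roi_voxels: int


def _pad(levels: np.ndarray) -> np.ndarray:
    """Pad with 0 (non-ROI sentinel) so every shift is in-bounds."""
    return np.pad(levels, 1, mode="constant", constant_values=0)


def _shifted_view(padded: np.ndarray, d: tuple[int, int, int], shape) -> np.ndarray:
    """Value at voxel v + d for every v of the original grid."""
    sx, sy, sz = shape
    dx, dy, dz = d
    return padded[1 + dx : 1 + dx + sx, 1 + dy : 1 + dy + sy, 1 + dz : 1 + dz + sz]


def _glcm_counts(levels: np.ndarray, lmax: int) -> np.ndarray:
    full = np.zeros((lmax + 1, lmax + 1), dtype=np.int64)
    padded = _pad(levels)
    inroi = levels > 0
    for d in OFFSETS_13:
        nb = _shifted_view(padded, d, levels.shape)
        valid = inroi & (nb > 0)
        a = levels[valid]
        b = nb[valid]
        np.add.at(full, (a, b), 1)
    full = full + full.T  # count both orderings -> symmetric
    return full


def _glrlm_counts(levels: np.ndarray, lmax: int) -> np.ndarray:
    shape = levels.shape
    padded = _pad(levels)
    inroi = levels > 0
    idx = np.indices(shape)
    run_rows: list[np.ndarray] = []
    run_lengths: list[np.ndarray] = []
    for d in OFFSETS_13:
        fwd = _shifted_view(padded, d, shape)
        bwd = _shifted_view(padded, tuple(-c for c in d), shape)
        starts = inroi & (bwd != levels)
        ends = inroi & (fwd != levels)
        # scalar progression index: one unit per step along the direction
        # (the first non-zero component of every offset in OFFSETS_13 is +1)
        axis = next(i for i, c in enumerate(d) if c != 0)
        s = idx[axis]
        # line anchor: voxel coordinates rolled back to step 0; components may
        # leave the grid bounds for mixed-sign directions, so the packing
        # stride covers [-S, 2S] where S = sum of the grid dimensions
        anchors = [idx[i] - s * d[i] for i in range(3)]
        big = np.int64(sum(shape))
        stride = 3 * big + 1
        key = ((anchors[0] + big) * stride + (anchors[1] + big)) * stride + (
            anchors[2] + big
        )

        ks, ss, lev = key[starts], s[starts], levels[starts]
        ke, se = key[ends], s[ends]
        o_s = np.lexsort((ss, ks))
        o_e = np.lexsort((se, ke))
        # starts and ends alternate within each line, so after the lexsort the
        # i-th start closes with the i-th end
        lengths = se[o_e] - ss[o_s] + 1
        run_rows.append(lev[o_s])
        run_lengths.append(lengths)
    rows = np.concatenate(run_rows)
    lengths = np.concatenate(run_lengths)
    rmax = int(lengths.max()) if lengths.size else 1
    out = np.zeros((lmax + 1, rmax), dtype=np.int64)
    np.add.at(out, (rows, lengths - 1), 1)
    return out


def _glszm_counts(levels: np.ndarray, lmax: int) -> np.ndarray:
    present = np.unique(levels[levels > 0])
    zones: list[tuple[int, np.ndarray]] = []
    zmax = 1
    for g in present:
        lab, n = ndimage.label(levels == g, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.append((int(g), sizes))
        zmax = max(zmax, int(sizes.max()))
    out = np.zeros((lmax + 1, zmax), dtype=np.int64)
    for g, sizes in zones:
        np.add.at(out, (g, sizes - 1), 1)
    return out


def _ngtdm_counts(levels: np.ndarray, lmax: int) -> tuple[np.ndarray, np.ndarray]:
    shape = levels.shape
    padded = _pad(levels)
    inroi = levels > 0
    nb_sum = np.zeros(shape, dtype=np.float64)
    nb_cnt = np.zeros(shape, dtype=np.int64)
    for d in OFFSETS_13:
        for dd in (d, tuple(-c for c in d)):
            nb = _shifted_view(padded, dd, shape)
            valid = nb > 0
            nb_sum += np.where(valid, nb, 0)
            nb_cnt += valid
    valid_vox = inroi & (nb_cnt > 0)
    diffs = np.zeros(shape, dtype=np.float64)
    diffs[valid_vox] = np.abs(
        levels[valid_vox] - nb_sum[valid_vox] / nb_cnt[valid_vox]
    )
    n = np.bincount(levels[valid_vox], minlength=lmax + 1).astype(np.int64)
    s = np.bincount(
        levels[valid_vox], weights=diffs[valid_vox], minlength=lmax + 1
    )
    return n, s


def build_matrices(levels: np.ndarray, roi_values: np.ndarray | None = None) -> TextureMatrices:
    """Build all four texture matrices from an integer level grid.

    ``levels`` must be 0 outside the ROI and >= 1 inside (as produced by
    :func:`~dosiomics_rp.texture.discretize`).  ``roi_values`` may be passed
    to restrict a full level grid to a sub-ROI.
    """
    levels = np.asarray(levels)
    if roi_values is not None:
        levels = np.where(np.asarray(roi_values, dtype=bool), levels, 0)
    if (levels < 0).any():
        raise ValueError("levels must be non-negative (0 = outside ROI)")
    n_roi = int((levels > 0).sum())
    if n_roi < 2:
        raise ValueError(f"texture matrices need at least 2 ROI voxels, got {n_roi}")
    present = np.unique(levels[levels > 0])
    lmax = int(present.max())

    glcm_full = _glcm_counts(levels, lmax)
    glrlm_full = _glrlm_counts(levels, lmax)
    glszm_full = _glszm_counts(levels, lmax)
    ngtdm_n_full, ngtdm_s_full = _ngtdm_counts(levels, lmax)

    sel = present  # row/col indices == level values
    return TextureMatrices(
        levels=present.astype(np.int64),
        glcm=glcm_full[np.ix_(sel, sel)],
        glrlm=glrlm_full[sel, :],
        glszm=glszm_full[sel, :],
        ngtdm_n=ngtdm_n_full[sel],
        ngtdm_s=ngtdm_s_full[sel],
        n_roi_voxels=n_roi,
    )
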