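"""Scalar feature formulas for the first-order and texture-matrix families.

Per extraction context the catalog holds exactly 78 features:

- 17 first-order statistics (the standard set minus the mean, which is
  deliberately excluded: for dose it duplicates the mean lung dose).
  Intensity statistics use the raw ROI values; entropy and uniformity use the
  discretized histogram.
- 24 GLCM, 16 GLRLM, 16 GLSZM and 5 NGTDM features computed from the merged
  matrices, with gray-level weights taken from the actual level values.

Degenerate (constant) inputs use fixed fallbacks: GLCM correlation and MCC
are 1, information measures and NGTDM ratios with empty denominators are 0.
"""

from __future__ import annotations

import numpy as np

from ..grids import ImageVolume, RoiMask
from .discretize import DiscretizationSpec, discretize
from .matrices import TextureMatrices, build_matrices

__all__ = [
    "FEATURE_NAMES",
    "FAMILY_COUNTS",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "compute_features",
]

FIRST_ORDER_NAMES = (
    "energy",
    "entropy",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)

GLCM_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "mcc",
    "sum_average",
    "sum_entropy",
    "sum_squares",
)

GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_variance",
    "run_entropy",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

GLSZM_NAMES = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "size_zone_non_uniformity",
    "size_zone_non_uniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)

NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

FAMILY_COUNTS = {
    "firstorder": len(FIRST_ORDER_NAMES),
    "glcm": len(GLCM_NAMES),
    "glrlm": len(GLRLM_NAMES),
    "glszm": len(GLSZM_NAMES),
    "ngtdm": len(NGTDM_NAMES),
}

#: The ordered 78 feature names of one extraction context, "<family>__<name>".
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}__{name}"
    for family, names in (
        ("firstorder", FIRST_ORDER_NAMES),
        ("glcm", GLCM_NAMES),
        ("glrlm", GLRLM_NAMES),
        ("glszm", GLSZM_NAMES),
        ("ngtdm", NGTDM_NAMES),
    )
    for name in names
)


def _plogp(p: np.ndarray) -> float:
    """Shannon sum -sum p log2 p over strictly positive entries."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def first_order_features(values: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """17 first-order statistics of the raw ROI intensities.

    ``levels`` are the discretized gray levels of the same voxels, used only
    for entropy and uniformity.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    hist = np.bincount(np.asarray(levels, dtype=np.int64).ravel())
    p = hist / hist.sum()
    mean = x.mean()
    dev = x - mean
    m2 = float((dev**2).mean())
    m3 = float((dev**3).mean())
    m4 = float((dev**4).mean())
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0
    return {
        "energy": float((x**2).sum()),
        "entropy": _plogp(p),
        "minimum": float(x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": float(x.max()),
        "median": float(med),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(dev).mean()),
        "robust_mean_absolute_deviation": rmad,
        "root_mean_squared": float(np.sqrt((x**2).mean())),
        "standard_deviation": float(np.sqrt(m2)),
        "skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "variance": m2,
        "uniformity": float((p**2).sum()),
    }


def glcm_features(m: TextureMatrices) -> dict[str, float]:
    counts = m.glcm.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty GLCM (no valid voxel pairs)")
    p = counts / total
    iv = m.levels.astype(np.float64)
    ng = iv.size
    px = p.sum(axis=1)
    py = p.sum(axis=0)  # == px by symmetry
    ii = iv[:, None]
    jj = iv[None, :]
    mu_x = float((px * iv).sum())
    mu_y = float((py * iv).sum())
    sig_x = float(np.sqrt((px * (iv - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (iv - mu_y) ** 2).sum()))

    # p_{x+y}(k), k over achievable sums of level values
    sums = (ii + jj).astype(np.int64)
    diffs = np.abs(ii - jj).astype(np.int64)
    p_sum = np.bincount(sums.ravel(), weights=p.ravel())
    p_diff = np.bincount(diffs.ravel(), weights=p.ravel())
    k_sum = np.arange(p_sum.size, dtype=np.float64)
    k_diff = np.arange(p_diff.size, dtype=np.float64)

    diff_avg = float((k_diff * p_diff).sum())
    hx = _plogp(px)
    hxy = _plogp(p.ravel())
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(px[:, None] * py[None, :] > 0,
                            np.log2(np.maximum(px[:, None] * py[None, :], 1e-300)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-((px[:, None] * py[None, :]) * log_pxpy).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x > 0 and sig_y > 0:
        correlation = (float((p * ii * jj).sum()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0

    # MCC: sqrt of the second largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    a = p / np.where(px[:, None] > 0, px[:, None], 1.0)  # a[i,k] = p(i,k)/px(i)
    b = p / np.where(py[None, :] > 0, py[None, :], 1.0)  # b[j,k] = p(j,k)/py(k)
    q = a @ b.T
    if ng > 1:
        eig = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2].real)))
    else:
        mcc = 1.0

    off_diag = diffs > 0
    inverse_variance = float((p[off_diag] / (ii - jj)[off_diag].astype(float) ** 2).sum())

    return {
        "autocorrelation": float((p * ii * jj).sum()),
        "joint_average": mu_x,
        "cluster_prominence": float((p * (ii + jj - mu_x - mu_y) ** 4).sum()),
        "cluster_shade": float((p * (ii + jj - mu_x - mu_y) ** 3).sum()),
        "cluster_tendency": float((p * (ii + jj - mu_x - mu_y) ** 2).sum()),
        "contrast": float((p * (ii - jj) ** 2).sum()),
        "correlation": float(correlation),
        "difference_average": diff_avg,
        "difference_entropy": _plogp(p_diff),
        "difference_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": hxy,
        "imc1": float(imc1),
        "imc2": imc2,
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((p / (1.0 + ((ii - jj) ** 2) / ng**2)).sum()),
        "id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_variance": inverse_variance,
        "maximum_probability": float(p.max()),
        "mcc": mcc,
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": _plogp(p_sum),
        "sum_squares": float((p * (ii - mu_x) ** 2).sum()),
    }


def _run_zone_features(counts: np.ndarray, levels: np.ndarray, n_voxels: int,
                       kind: str) -> dict[str, float]:
    """Shared formulas for GLRLM (runs) and GLSZM (zones)."""
    counts = counts.astype(np.float64)
    nr = counts.sum()
    if nr <= 0:
        raise ValueError(f"empty {kind} matrix")
    p = counts / nr
    iv = levels.astype(np.float64)[:, None]
    jv = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    mu_i = float((p * iv).sum())
    mu_j = float((p * jv).sum())
    feats = {
        "short": float((counts / jv**2).sum() / nr),
        "long": float((counts * jv**2).sum() / nr),
        "gln": float((row**2).sum() / nr),
        "glnn": float((row**2).sum() / nr**2),
        "rln": float((col**2).sum() / nr),
        "rlnn": float((col**2).sum() / nr**2),
        "perc": float(nr / n_voxels),
        "glv": float((p * (iv - mu_i) ** 2).sum()),
        "rv": float((p * (jv - mu_j) ** 2).sum()),
        "entropy": _plogp(p.ravel()),
        "lgl": float((counts / iv**2).sum() / nr),
        "hgl": float((counts * iv**2).sum() / nr),
        "s_lgl": float((counts / (iv**2 * jv**2)).sum() / nr),
        "s_hgl": float((counts * iv**2 / jv**2).sum() / nr),
        "l_lgl": float((counts * jv**2 / iv**2).sum() / nr),
        "l_hgl": float((counts * iv**2 * jv**2).sum() / nr),
    }
    if kind == "glrlm":
        keys = GLRLM_NAMES
    else:
        keys = GLSZM_NAMES
    order = ("short", "long", "gln", "glnn", "rln", "rlnn", "perc", "glv",
             "rv", "entropy", "lgl", "hgl", "s_lgl", "s_hgl", "l_lgl", "l_hgl")
    return {name: feats[k] for name, k in zip(keys, order)}


def glrlm_features(m: TextureMatrices) -> dict[str, float]:
    # run percentage normalizes by voxel count x number of directions
    return _run_zone_features(m.glrlm, m.levels, 13 * m.n_roi_voxels, "glrlm")


def glszm_features(m: TextureMatrices) -> dict[str, float]:
    return _run_zone_features(m.glszm, m.levels, m.n_roi_voxels, "glszm")


def ngtdm_features(m: TextureMatrices) -> dict[str, float]:
    n = m.ngtdm_n.astype(np.float64)
    s = m.ngtdm_s.astype(np.float64)
    nvp = n.sum()
    if nvp <= 0:
        raise ValueError("empty NGTDM")
    present = n > 0
    pi = n / nvp
    iv = m.levels.astype(np.float64)
    p_p, s_p, i_p = pi[present], s[present], iv[present]
    ngp = int(present.sum())

    ps = float((p_p * s_p).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        pij = p_p[:, None] * p_p[None, :]
        d2 = (i_p[:, None] - i_p[None, :]) ** 2
        contrast = float((pij * d2).sum()) / (ngp * (ngp - 1)) * float(s_p.sum()) / nvp
    else:
        contrast = 0.0

    ipi = i_p * p_p
    denom_busy = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = ps / denom_busy if denom_busy > 0 else 0.0

    if ngp > 1:
        absdiff = np.abs(i_p[:, None] - i_p[None, :])
        num = (p_p[:, None] * s_p[:, None] + p_p[None, :] * s_p[None, :])
        den = p_p[:, None] + p_p[None, :]
        complexity = float((absdiff * num / den).sum()) / nvp
        strength_num = float(((p_p[:, None] + p_p[None, :]) *
                              (i_p[:, None] - i_p[None, :]) ** 2).sum())
    else:
        complexity = 0.0
        strength_num = 0.0
    s_total = float(s_p.sum())
    strength = strength_num / s_total if s_total > 0 else 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def compute_features(
    v: ImageVolume, roi: RoiMask, spec: DiscretizationSpec
) -> dict[str, float]:
    """Compute the 78-feature catalog of ``v`` within ``roi``.

    Returns an ordered mapping keyed ``<family>__<name>`` matching
    :data:`FEATURE_NAMES`.
    """
    if roi.n_voxels < 2:
        raise ValueError("feature extraction needs at least 2 ROI voxels")
    levels = discretize(v, roi, spec)
    mats = build_matrices(levels)
    out: dict[str, float] = {}
    fo = first_order_features(v.values[roi.values], levels[roi.values])
    out.update({f"firstorder__{k}": fo[k] for k in FIRST_ORDER_NAMES})
    gl = glcm_features(mats)
    out.update({f"glcm__{k}": gl[k] for k in GLCM_NAMES})
    rl = glrlm_features(mats)
    out.update({f"glrlm__{k}": rl[k] for k in GLRLM_NAMES})
    sz = glszm_features(mats)
    out.update({f"glszm__{k}": sz[k] for k in GLSZM_NAMES})
    nt = ngtdm_features(mats)
    out.update({f"ngtdm__{k}": nt[k] for k in NGTDM_NAMES})
    assert len(out) == 78
    return out
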