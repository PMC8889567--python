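"""Discretization, texture matrices and the 78-feature catalog."""

import numpy as np
import pytest

from dosiomics_rp import (
    CT_DISCRETIZATION,
    DOSE_DISCRETIZATION,
    FEATURE_NAMES,
    ImageVolume,
    Modality,
    RoiMask,
    build_matrices,
    compute_features,
    discretize,
)
from dosiomics_rp.texture.features import FAMILY_COUNTS, glcm_features

import oracles


def _vol_roi(values, modality=Modality.DOSE_GY):
    arr = np.asarray(values, dtype=float)
    v = ImageVolume(arr, (1.5, 1.5, 1.5), modality=modality)
    roi = RoiMask(np.ones_like(arr, dtype=bool), (1.5, 1.5, 1.5))
    return v, roi


# --- discretization --------------------------------------------------------


@pytest.mark.parametrize("dose,level", [(0.0, 1), (0.4, 1), (0.999, 1), (1.0, 2),
                                        (99.0, 100), (250.0, 100)])
def test_dose_binning_left_closed_and_capped(dose, level):
    v, roi = _vol_roi(np.full((2, 2, 2), dose))
    assert discretize(v, roi, DOSE_DISCRETIZATION).max() == level


@pytest.mark.parametrize("hu,level", [(-1500.0, 1), (-1000.0, 1), (-951.0, 1),
                                      (-950.0, 2), (0.0, 21), (99.0, 22),
                                      (100.0, 23), (400.0, 23)])
def test_ct_clamp_shift_binning(hu, level):
    v, roi = _vol_roi(np.full((2, 2, 2), hu), Modality.CT_HU)
    assert discretize(v, roi, CT_DISCRETIZATION).max() == level


def test_ct_shift_by_bin_width_preserves_histogram_shape():
    """Adding one bin width within the clamp range shifts levels but leaves
    entropy/uniformity of the level histogram unchanged."""
    rng = np.random.default_rng(0)
    hu = rng.uniform(-800, -200, size=(6, 6, 6))
    v1, roi = _vol_roi(hu, Modality.CT_HU)
    v2, _ = _vol_roi(hu + 50.0, Modality.CT_HU)
    f1 = compute_features(v1, roi, CT_DISCRETIZATION)
    f2 = compute_features(v2, roi, CT_DISCRETIZATION)
    for name in ("firstorder__entropy", "firstorder__uniformity"):
        assert f1[name] == pytest.approx(f2[name], abs=1e-9)


# --- matrices --------------------------------------------------------------


def test_constant_levels_put_all_glcm_mass_on_diagonal():
    m = build_matrices(np.full((4, 4, 4), 3, dtype=int))
    assert m.glcm.shape == (1, 1)
    assert m.glcm.sum() > 0


def test_line_grid_runs_and_zones():
    levels = np.array([1, 1, 2, 2]).reshape(1, 1, 4)
    m = build_matrices(levels)
    # along z: one run of length 2 per level; the 12 other directions
    # contribute only length-1 runs
    lv = {int(g): i for i, g in enumerate(m.levels)}
    assert m.glrlm[lv[1], 1] == 1 and m.glrlm[lv[2], 1] == 1
    assert m.glrlm[lv[1], 0] == 24 and m.glrlm[lv[2], 0] == 24
    # two 26-connected zones of size 2
    assert m.glszm[lv[1], 1] == 1 and m.glszm[lv[2], 1] == 1
    assert m.glszm.sum() == 2


def test_glcm_total_counts_equal_twice_the_valid_pairs():
    rng = np.random.default_rng(1)
    levels = rng.integers(1, 4, size=(4, 5, 3))
    levels[rng.uniform(size=levels.shape) < 0.3] = 0
    m = build_matrices(levels)
    naive = oracles.naive_glcm(levels)
    assert m.glcm.sum() == sum(naive.values())


def test_matrices_match_brute_force_counts():
    rng = np.random.default_rng(2)
    for _ in range(10):
        levels = rng.integers(0, 4, size=tuple(rng.integers(2, 6, size=3)))
        if (levels > 0).sum() < 2:
            continue
        m = build_matrices(levels)
        lv = {int(g): i for i, g in enumerate(m.levels)}
        for (a, b), count in oracles.naive_glcm(levels).items():
            assert m.glcm[lv[a], lv[b]] == count
        glrlm = oracles.naive_glrlm(levels)
        assert m.glrlm.sum() == sum(glrlm.values())
        for (a, length), count in glrlm.items():
            assert m.glrlm[lv[a], length - 1] == count
        for (a, size), count in oracles.naive_glszm(levels).items():
            assert m.glszm[lv[a], size - 1] == count
        for a, (n_i, s_i) in oracles.naive_ngtdm(levels).items():
            assert m.ngtdm_n[lv[a]] == n_i
            assert m.ngtdm_s[lv[a]] == pytest.approx(s_i, abs=1e-9)


def test_single_voxel_roi_is_error():
    levels = np.zeros((3, 3, 3), dtype=int)
    levels[1, 1, 1] = 2
    with pytest.raises(ValueError):
        build_matrices(levels)


# --- features --------------------------------------------------------------


def test_constant_volume_degenerate_features():
    v, roi = _vol_roi(np.full((4, 4, 4), 7.3))
    f = compute_features(v, roi, DOSE_DISCRETIZATION)
    assert f["firstorder__variance"] == pytest.approx(0.0, abs=1e-12)
    assert f["firstorder__uniformity"] == 1.0
    assert f["glcm__contrast"] == 0.0
    assert f["glcm__correlation"] == 1.0


def test_catalog_conformance():
    rng = np.random.default_rng(3)
    v, roi = _vol_roi(rng.uniform(0, 50, (6, 6, 6)))
    f = compute_features(v, roi, DOSE_DISCRETIZATION)
    assert len(f) == 78
    assert tuple(f.keys()) == FEATURE_NAMES
    assert all(np.isfinite(val) for val in f.values())
    assert FAMILY_COUNTS == {"firstorder": 17, "glcm": 24, "glrlm": 16,
                             "glszm": 16, "ngtdm": 5}
    assert "firstorder__mean" not in f  # mean is deliberately excluded


def test_glcm_joint_entropy_matches_probability_table():
    levels = np.array([[1, 2, 3], [2, 2, 1], [3, 1, 2]]).reshape(3, 3, 1)
    m = build_matrices(levels)
    mine = glcm_features(m)["joint_entropy"]
    ref = oracles.naive_glcm_features(levels)["joint_entropy"]
    assert mine == pytest.approx(ref, abs=1e-9)


def test_rotation_consistency_under_axis_permutation():
    rng = np.random.default_rng(4)
    v = rng.uniform(0, 30, (5, 6, 7))
    base = None
    for perm in [(0, 1, 2), (1, 0, 2), (2, 1, 0), (1, 2, 0)]:
        vol = ImageVolume(np.transpose(v, perm).copy(), (1.5, 1.5, 1.5))
        roi = RoiMask(np.ones(vol.shape, dtype=bool), (1.5, 1.5, 1.5))
        f = compute_features(vol, roi, DOSE_DISCRETIZATION)
        if base is None:
            base = f
        else:
            for k in base:
                assert f[k] == pytest.approx(base[k], rel=1e-9), k
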