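"""Resampling and ROI derivation."""

import numpy as np
import pytest

from dosiomics_rp import ImageVolume, Modality, RoiMask, derive_rois, resample_mask, resample_volume


def test_constant_volume_survives_any_spacing_change():
    v = ImageVolume(np.full((10, 10, 10), 50.0), (3, 3, 3))
    for target in [(1.5, 1.5, 1.5), (2, 3, 4), (5, 5, 5)]:
        out = resample_volume(v, target, "bspline")
        np.testing.assert_allclose(out.values, 50.0, atol=1e-9)


def test_resample_to_own_spacing_is_identity():
    rng = np.random.default_rng(0)
    v = ImageVolume(rng.uniform(0, 60, (9, 9, 9)), (2, 2, 2))
    out = resample_volume(v, (2, 2, 2), "bspline")
    np.testing.assert_array_equal(out.values, v.values)


def test_bspline_reproduces_linear_ramp():
    """Cubic B-spline to half spacing matches the analytic ramp to 1e-6."""
    x = np.linspace(0.0, 10.0, 16)
    v = ImageVolume(np.broadcast_to(x[:, None, None], (16, 8, 8)).copy(), (2, 2, 2))
    out = resample_volume(v, (1, 1, 1), "bspline")
    xs = out.origin_mm[0] + np.arange(out.shape[0]) * 1.0
    analytic = np.interp(xs, np.arange(16) * 2.0, x)
    assert np.abs(out.values[:, 4, 4] - analytic).max() < 1e-6
    # endpoints preserved
    np.testing.assert_allclose(out.values[0, 4, 4], 0.0, atol=1e-9)
    np.testing.assert_allclose(out.values[-1, 4, 4], 10.0, atol=1e-9)


def test_mask_resampling_stays_boolean():
    m = RoiMask(np.zeros((10, 10, 10), dtype=bool), (3, 3, 3))
    m.values[2:8, 2:8, 2:8] = True
    out = resample_mask(m, (1.5, 1.5, 1.5))
    assert out.values.dtype == np.bool_
    assert 0 < out.n_voxels < np.prod(out.shape)


def test_constant_mean_preserved_through_resampling():
    v = ImageVolume(np.full((8, 8, 8), 12.5), (3, 3, 3))
    out = resample_volume(v, (2, 2, 2), "bspline")
    assert abs(out.values.mean() - 12.5) < 1e-9


def test_invalid_spacing_and_method():
    v = ImageVolume(np.zeros((8, 8, 8)), (2, 2, 2))
    with pytest.raises(ValueError):
        resample_volume(v, (0, 1, 1))
    with pytest.raises(ValueError):
        resample_volume(v, (1, 1, 1), method="sinc")


# --- ROI derivation --------------------------------------------------------


def _lung_and_dose(dose_value):
    lung = RoiMask(np.zeros((10, 10, 10), dtype=bool), (2, 2, 2))
    lung.values[2:8, 2:8, 2:8] = True
    dose = ImageVolume(np.full((10, 10, 10), float(dose_value)), (2, 2, 2))
    return lung, dose


def test_uniform_15gy_thresholds():
    lung, dose = _lung_and_dose(15.0)
    rois = derive_rois(lung, None, dose, "esophageal")
    np.testing.assert_array_equal(rois["lung_gt10"].values, rois["lung_eval"].values)
    assert rois["lung_gt20"].n_voxels == 0


def test_zero_dose_gives_empty_subrois():
    lung, dose = _lung_and_dose(0.0)
    rois = derive_rois(lung, None, dose, "esophageal")
    assert rois["lung_gt10"].n_voxels == 0
    assert rois["lung_gt20"].n_voxels == 0


def test_gtv_subtraction_for_lung_cancer():
    lung, dose = _lung_and_dose(30.0)
    gtv = RoiMask(np.zeros((10, 10, 10), dtype=bool), (2, 2, 2))
    gtv.values[2:8, 2:5, 2:8] = True
    rois = derive_rois(lung, gtv, dose, "lung")
    expected = lung.n_voxels - int((gtv.values & lung.values).sum())
    assert rois["lung_eval"].n_voxels == expected
    with pytest.raises(ValueError):
        derive_rois(lung, None, dose, "lung")  # GTV required


def test_roi_nesting_on_random_dose():
    rng = np.random.default_rng(3)
    lung = RoiMask(rng.uniform(size=(12, 12, 12)) < 0.5, (2, 2, 2))
    dose = ImageVolume(rng.uniform(0, 40, (12, 12, 12)), (2, 2, 2))
    rois = derive_rois(lung, None, dose, "esophageal")
    assert (rois["lung_gt20"].values <= rois["lung_gt10"].values).all()
    assert (rois["lung_gt10"].values <= rois["lung_eval"].values).all()


def test_empty_lung_eval_is_error():
    lung = RoiMask(np.zeros((8, 8, 8), dtype=bool), (2, 2, 2))
    dose = ImageVolume(np.zeros((8, 8, 8)), (2, 2, 2))
    with pytest.raises(ValueError):
        derive_rois(lung, None, dose, "esophageal")


def test_save_rois_writes_niftis_and_index(tmp_path):
    import json

    from dosiomics_rp import RoiMask as _RoiMask
    from dosiomics_rp.volume_ops import save_rois

    lung, dose = _lung_and_dose(15.0)
    rois = derive_rois(lung, None, dose, "esophageal")
    index_path = save_rois(rois, tmp_path / "rois")
    with open(index_path) as fh:
        index = json.load(fh)
    assert set(index) == {"lung_eval", "lung_gt10", "lung_gt20"}
    for name, entry in index.items():
        back = _RoiMask.from_nifti(entry["path"])
        assert back.n_voxels == entry["n_voxels"] == rois[name].n_voxels
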