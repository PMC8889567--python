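"""Phantom cohort generation: determinism, calibration, planted signal,
grade rules and disk round-trip."""

import numpy as np
import pytest

from dosiomics_rp import (
    CohortSpec,
    cohort_to_disk,
    generate_cohort,
    load_cohort,
)

SMALL = dict(grid_shape=(16, 16, 12), voxel_spacing_mm=(3.0, 3.0, 3.0))


def test_study_arm_prevalences():
    """Cohort sizes and positive-class rates of the two emulated study arms."""
    esoph = generate_cohort(CohortSpec(n_patients=101, seed=42, **SMALL))
    assert len(esoph) == 101
    frac = np.mean([p.rp_grade >= 1 for p in esoph])
    assert abs(frac - 0.62) <= 0.10

    lung = generate_cohort(CohortSpec(
        n_patients=93, cancer_type="lung", target_prevalence=0.17, seed=42, **SMALL
    ))
    assert len(lung) == 93
    frac = np.mean([p.rp_grade >= 2 for p in lung])
    assert abs(frac - 0.17) <= 0.08
    assert all(p.gtv_mask is not None for p in lung)


def test_determinism_bit_identical():
    spec = CohortSpec(n_patients=5, seed=9, **SMALL)
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    for pa, pb in zip(a, b):
        assert pa.rp_grade == pb.rp_grade
        np.testing.assert_array_equal(pa.ct.values, pb.ct.values)
        np.testing.assert_array_equal(pa.lung_mask.values, pb.lung_mask.values)
        for fa, fb in zip(pa.fraction_doses, pb.fraction_doses):
            np.testing.assert_array_equal(fa.values, fb.values)


def test_grade_rules_mirror_cancer_type():
    esoph = generate_cohort(CohortSpec(n_patients=40, seed=1, **SMALL))
    for p in esoph:
        assert p.rp_grade in (0, 1, 2)
        assert p.positive == (p.rp_grade >= 1)
    lung = generate_cohort(CohortSpec(
        n_patients=40, cancer_type="lung", target_prevalence=0.17, seed=1, **SMALL
    ))
    for p in lung:
        assert p.rp_grade in (0, 2, 3)
        assert p.positive == (p.rp_grade >= 2)


def test_prevalence_calibration_across_seeds():
    """Mean empirical prevalence over seeds stays within 0.05 of target."""
    target = 0.62
    fracs = []
    for seed in range(10):
        pats = generate_cohort(CohortSpec(n_patients=50, seed=seed, **SMALL))
        fracs.append(np.mean([p.positive for p in pats]))
    assert abs(np.mean(fracs) - target) <= 0.05


def test_planted_mld_signal_is_monotone_in_effect():
    """Raising effect_mld strictly raises corr(MLD, label) on average."""
    corrs = []
    for effect in (0.0, 0.3, 0.9):
        cs = []
        for seed in range(5):
            pats = generate_cohort(CohortSpec(
                n_patients=50, effect_mld=effect, effect_texture=0.0,
                noise_sd=0.2, seed=seed, **SMALL
            ))
            mld = np.array([p.mld_gy for p in pats])
            y = np.array([float(p.positive) for p in pats])
            cs.append(np.corrcoef(mld, y)[0, 1])
        corrs.append(np.mean(cs))
    assert corrs[0] < corrs[1] < corrs[2]


def test_no_signal_cohort_has_near_target_prevalence():
    pats = generate_cohort(CohortSpec(
        n_patients=80, effect_mld=0.0, effect_texture=0.0, noise_sd=0.0,
        seed=3, **SMALL
    ))
    assert abs(np.mean([p.positive for p in pats]) - 0.62) < 0.15


def test_impossible_calibration_reports_achievable_range():
    with pytest.raises(ValueError, match="achievable range"):
        generate_cohort(CohortSpec(n_patients=10, effect_mld=1e4, seed=0, **SMALL))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        CohortSpec(target_prevalence=0.0)
    with pytest.raises(ValueError):
        CohortSpec(grid_shape=(4, 16, 16))
    with pytest.raises(ValueError):
        CohortSpec(n_fractions_range=(0, 5))
    with pytest.raises(ValueError):
        CohortSpec(cancer_type="breast")


def test_disk_round_trip(tmp_path):
    pats = generate_cohort(CohortSpec(n_patients=3, seed=2, **SMALL))
    manifest = cohort_to_disk(pats, tmp_path / "cohort")
    assert manifest.exists()
    assert len(manifest.read_text().strip().splitlines()) == 4  # header + 3 rows
    loaded = load_cohort(manifest)
    assert len(loaded) == 3
    for orig, back in zip(pats, loaded):
        assert back.patient_id == orig.patient_id
        assert back.rp_grade == orig.rp_grade
        np.testing.assert_array_equal(back.ct.values, orig.ct.values)
        np.testing.assert_array_equal(back.lung_mask.values, orig.lung_mask.values)
        assert len(back.fraction_doses) == len(orig.fraction_doses)
        for fa, fb in zip(back.fraction_doses, orig.fraction_doses):
            np.testing.assert_array_equal(fa.values, fb.values)


def test_missing_manifest_and_corrupt_path_name_the_file(tmp_path):
    with pytest.raises(FileNotFoundError, match="nope"):
        load_cohort(tmp_path / "nope.csv")
    pats = generate_cohort(CohortSpec(n_patients=1, seed=2, **SMALL))
    manifest = cohort_to_disk(pats, tmp_path / "c")
    ct_path = (tmp_path / "c" / pats[0].patient_id / "ct.nii.gz")
    ct_path.unlink()
    with pytest.raises(FileNotFoundError, match="ct.nii.gz"):
        load_cohort(manifest)
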