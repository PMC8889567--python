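import numpy as np
import pytest

from dosiomics_rp import CohortSpec, DoseSeries, ImageVolume, Modality, RoiMask, generate_cohort
from dosiomics_rp.extract import extract_cohort_features


def uniform_dose_series(dose_gy: float, n_fractions: int, shape=(8, 8, 8), spacing=(2, 2, 2)):
    fractions = tuple(
        ImageVolume(np.full(shape, float(dose_gy)), spacing, modality=Modality.DOSE_GY)
        for _ in range(n_fractions)
    )
    return DoseSeries(fractions)


def full_mask(shape=(8, 8, 8), spacing=(2, 2, 2)) -> RoiMask:
    return RoiMask(np.ones(shape, dtype=bool), spacing)


@pytest.fixture(scope="session")
def small_cohort():
    """40 esophageal-style phantoms on a coarse grid (shared, read-only)."""
    spec = CohortSpec(n_patients=40, grid_shape=(16, 16, 12), seed=5)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, patients = small_cohort
    return extract_cohort_features(patients)
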