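"""Synthetic phantom cohorts with the statistical structure of an RP study.

Each phantom patient carries a schematic thorax CT (two ellipsoidal low-HU
lungs in a soft-tissue background, with optional high-HU texture lesions
inside the lungs), a series of per-fraction 3-D dose grids produced by
alternating beam geometries (antero-posterior on odd fractions, opposed
laterals on even ones) with per-fraction smooth multiplicative noise, binary
lung / GTV masks, and a radiation-pneumonitis grade.

The outcome is drawn from a logistic model

    logit P(RP positive) = c + b_mld * MLD + b_tex * H + eps

where MLD is the mean EQD2 lung dose, H is a planted heterogeneity score —
the cohort-standardized sum of the within-lung variances of the discretized
dose and of the discretized CT.  Both variances are monotonically related to
several first-order and GLCM features, so the signal is recoverable without
privileging one feature, and the CT component is invisible to DVH metrics,
so dosiomic/radiomic models carry information a DVH model cannot.  The
intercept ``c`` is calibrated numerically so the empirical prevalence
matches the target.
Esophageal-style cohorts label positives grade 1 (majority) or 2; lung-style
cohorts label positives grade 2 (majority) or 3, with grade >=1 / >=2 as the
respective positive-class rules.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage, optimize, special

from .dvh import compute_dvh
from .eqd2 import Eqd2Params, accumulate_eqd2
from .grids import DoseSeries, ImageVolume, Modality, RoiMask
from .texture import CT_DISCRETIZATION, DOSE_DISCRETIZATION, discretize

__all__ = [
    "CohortSpec",
    "PhantomPatient",
    "generate_cohort",
    "cohort_to_disk",
    "load_cohort",
    "heterogeneity_score",
    "positive_label",
    "ESOPHAGEAL_DEFAULTS",
    "LUNG_DEFAULTS",
]

logger = logging.getLogger(__name__)

CancerType = Literal["esophageal", "lung"]

#: Positive-class rule per cancer type: minimum grade counting as RP-positive.
POSITIVE_GRADE_THRESHOLD = {"esophageal": 1, "lung": 2}


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration for one phantom cohort.

    The defaults emulate the esophageal study arm: 101 patients with 62%
    RP grade >=1.  ``effect_mld`` is the log-odds increase per Gy of mean
    lung dose; ``effect_texture`` the log-odds per unit of the planted
    heterogeneity score (cohort-standardized sum of the within-lung
    variances of the discretized dose and discretized CT);
    ``noise_sd`` the SD of the unexplained log-odds noise.
    """

    n_patients: int = 101
    cancer_type: CancerType = "esophageal"
    target_prevalence: float = 0.62
    grid_shape: tuple[int, int, int] = (24, 24, 20)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_fractions_range: tuple[int, int] = (25, 30)
    effect_mld: float = 0.25
    effect_texture: float = 1.4
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.cancer_type not in ("esophageal", "lung"):
            raise ValueError(f"unknown cancer_type {self.cancer_type!r}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        if any(int(s) < 8 for s in self.grid_shape):
            raise ValueError("grid_shape components must all be >= 8")
        if any(float(s) <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        lo, hi = self.n_fractions_range
        if lo < 1 or hi < lo:
            raise ValueError("n_fractions_range must be a non-empty interval with lower bound >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm)
        )
        object.__setattr__(self, "n_fractions_range", (int(lo), int(hi)))


#: Study-arm presets (cohort sizes and prevalences of the emulated study).
ESOPHAGEAL_DEFAULTS = CohortSpec()
LUNG_DEFAULTS = CohortSpec(
    n_patients=93, cancer_type="lung", target_prevalence=0.17
)


@dataclass(frozen=True)
class PhantomPatient:
    patient_id: str
    ct: ImageVolume
    fraction_doses: DoseSeries
    lung_mask: RoiMask
    gtv_mask: RoiMask | None
    rp_grade: int
    cancer_type: CancerType
    #: generator diagnostics (mean EQD2 lung dose, planted heterogeneity score)
    mld_gy: float = field(default=float("nan"), compare=False)
    heterogeneity: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if self.rp_grade not in (0, 1, 2, 3, 4):
            raise ValueError(f"rp_grade must be in 0..4, got {self.rp_grade}")
        if self.lung_mask.n_voxels < 1:
            raise ValueError("lung mask is empty")
        if self.cancer_type == "lung" and self.gtv_mask is None:
            raise ValueError("lung-cancer patients require a GTV mask")
        for g in (self.fraction_doses.reference, self.lung_mask):
            if not self.ct.same_geometry(g):
                raise ValueError("patient grids do not share one geometry")

    @property
    def positive(self) -> bool:
        return self.rp_grade >= POSITIVE_GRADE_THRESHOLD[self.cancer_type]


def positive_label(rp_grade: int, cancer_type: str) -> int:
    """Binary RP label under the cancer-type grade rule (>=1 vs >=2)."""
    return int(rp_grade >= POSITIVE_GRADE_THRESHOLD[cancer_type])


def _seed_seq(spec_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(spec_seed) % (2**31), *key))


def _smooth_noise(rng: np.random.Generator, shape, sigma_vox: float = 1.5) -> np.ndarray:
    """Zero-mean, unit-SD smooth random field."""
    w = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = w.std()
    return w / sd if sd > 0 else w


def _ellipsoid(coords, center, semi) -> np.ndarray:
    return sum(((c - m) / s) ** 2 for c, m, s in zip(coords, center, semi)) <= 1.0


def _generate_anatomy(rng, spec: CohortSpec):
    """CT + lung mask + target geometry for one patient (normalized coords)."""
    shape = spec.grid_shape
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) / n for n in shape], indexing="ij"
    )
    jit = lambda a, b: float(rng.uniform(a, b))  # noqa: E731
    lung_semi = (jit(0.13, 0.17), jit(0.24, 0.30), jit(0.32, 0.40))
    left = _ellipsoid(coords, (jit(0.26, 0.30), 0.5 + jit(-0.03, 0.03), 0.5), lung_semi)
    right = _ellipsoid(coords, (jit(0.70, 0.74), 0.5 + jit(-0.03, 0.03), 0.5), lung_semi)
    lungs = left | right

    ct = np.full(shape, 40.0) + 30.0 * rng.standard_normal(shape)
    ct[lungs] = -700.0 + 40.0 * rng.standard_normal(int(lungs.sum()))
    return coords, lungs, ct


def _plant_ct_lesions(rng, ct, lungs, coords, amplitude: float) -> None:
    """High-HU nodular lesions inside the lungs; count/intensity scale with
    the patient's latent heterogeneity amplitude."""
    n_lesions = int(rng.poisson(1.0 + 8.0 * amplitude))
    lung_idx = np.argwhere(lungs)
    if lung_idx.size == 0 or n_lesions == 0:
        return
    shape = ct.shape
    for _ in range(n_lesions):
        cx, cy, cz = lung_idx[rng.integers(len(lung_idx))]
        center = ((cx + 0.5) / shape[0], (cy + 0.5) / shape[1], (cz + 0.5) / shape[2])
        radius = rng.uniform(0.03, 0.07)
        lesion = _ellipsoid(coords, center, (radius,) * 3) & lungs
        ct[lesion] = rng.uniform(-300.0, -50.0)


def _beam_fields(coords, target, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized AP and lateral beam dose shapes (1.0 at the target).

    Each beam has a Gaussian cross-profile around the target axis and an
    exponential falloff with distance from the target plane along its own
    incidence direction (y for the AP beam, x for the laterals)."""
    x, y, z = coords
    x0, y0, z0 = target
    ap = np.exp(-0.5 * (((x - x0) / width) ** 2 + ((z - z0) / width) ** 2))
    ap *= np.exp(-1.2 * np.abs(y - y0))
    lat = np.exp(-0.5 * (((y - y0) / width) ** 2 + ((z - z0) / width) ** 2))
    lat *= np.exp(-1.2 * np.abs(x - x0))
    ap /= ap.max()
    lat /= lat.max()
    return ap, lat


def _generate_patient(index: int, spec: CohortSpec) -> PhantomPatient:
    rng = np.random.default_rng(_seed_seq(spec.seed, 1000 + index))
    shape = spec.grid_shape
    coords, lungs, ct = _generate_anatomy(rng, spec)

    # latent heterogeneity amplitude: drives dose noise and CT lesions
    u = float(rng.uniform(0.0, 1.0))
    _plant_ct_lesions(rng, ct, lungs, coords, u)

    if spec.cancer_type == "lung":
        # GTV: a sphere inside one lung
        side = rng.choice([0.28, 0.72])
        target = (float(side), 0.5 + float(rng.uniform(-0.05, 0.05)), float(rng.uniform(0.4, 0.6)))
        gtv_values = _ellipsoid(coords, target, (rng.uniform(0.05, 0.10),) * 3)
        prescription = float(rng.uniform(50.0, 66.0))
    else:
        # mediastinal target between the lungs
        target = (0.5, float(rng.uniform(0.42, 0.50)), float(rng.uniform(0.35, 0.65)))
        gtv_values = None
        prescription = float(rng.uniform(41.4, 54.0))

    n_fractions = int(rng.integers(spec.n_fractions_range[0], spec.n_fractions_range[1] + 1))
    width = float(rng.uniform(0.10, 0.18))
    ap, lat = _beam_fields(coords, target, width)
    d_per_fraction = prescription / n_fractions
    noise_amp = 0.10 + 0.80 * u

    fractions = []
    for i in range(n_fractions):
        base = ap if i % 2 == 0 else lat
        noise = _smooth_noise(rng, shape)
        dose = d_per_fraction * base * np.clip(1.0 + noise_amp * noise, 0.0, None)
        fractions.append(
            ImageVolume(
                values=dose,
                spacing_mm=spec.voxel_spacing_mm,
                modality=Modality.DOSE_GY,
            )
        )

    ct_vol = ImageVolume(values=ct, spacing_mm=spec.voxel_spacing_mm, modality=Modality.CT_HU)
    lung_mask = RoiMask(values=lungs, spacing_mm=spec.voxel_spacing_mm)
    gtv_mask = (
        RoiMask(values=gtv_values, spacing_mm=spec.voxel_spacing_mm)
        if gtv_values is not None
        else None
    )
    return PhantomPatient(
        patient_id=f"{spec.cancer_type[:4]}-{index:04d}",
        ct=ct_vol,
        fraction_doses=DoseSeries(tuple(fractions)),
        lung_mask=lung_mask,
        gtv_mask=gtv_mask,
        rp_grade=0,  # assigned after prevalence calibration
        cancer_type=spec.cancer_type,
    )


def _eval_roi(patient: PhantomPatient) -> RoiMask:
    eval_mask = patient.lung_mask.values
    if patient.cancer_type == "lung" and patient.gtv_mask is not None:
        eval_mask = eval_mask & ~patient.gtv_mask.values
    return patient.lung_mask.with_values(eval_mask)


def heterogeneity_components(
    patient: PhantomPatient, alpha_beta: float = 3.0
) -> tuple[float, float]:
    """Within-lung variances of the discretized dose and discretized CT.

    These are the raw ingredients of the planted heterogeneity score; the
    generator standardizes each across the cohort and sums them.
    """
    total = accumulate_eqd2(patient.fraction_doses, Eqd2Params(alpha_beta))
    roi = _eval_roi(patient)
    dose_levels = discretize(total, roi, DOSE_DISCRETIZATION)
    ct_levels = discretize(patient.ct, roi, CT_DISCRETIZATION)
    inside = roi.values
    return float(dose_levels[inside].var()), float(ct_levels[inside].var())


#: Weights of the (dose-variance, CT-variance) components in the planted
#: heterogeneity score.  The CT component dominates: dose-histogram variance
#: is partially recoverable from DVH metrics, whereas CT texture is not, so
#: this weighting keeps the planted texture signal distinct from the DVH
#: signal while still touching both modalities.
HETEROGENEITY_WEIGHTS = (0.35, 1.0)


def _combined_heterogeneity(components: np.ndarray) -> np.ndarray:
    """Cohort-standardized weighted sum of the dose- and CT-variance
    components."""
    z = np.zeros(components.shape[0])
    for col, w in zip(range(components.shape[1]), HETEROGENEITY_WEIGHTS):
        v = components[:, col]
        sd = v.std()
        z += w * (v - v.mean()) / sd if sd > 0 else 0.0
    return z


def heterogeneity_score(patient: PhantomPatient, alpha_beta: float = 3.0) -> float:
    """Un-standardized planted texture signal of a single patient (sum of the
    dose- and CT-variance components); the generator uses the
    cohort-standardized version."""
    return float(sum(heterogeneity_components(patient, alpha_beta)))


def _patient_mld(patient: PhantomPatient, alpha_beta: float = 3.0) -> float:
    total = accumulate_eqd2(patient.fraction_doses, Eqd2Params(alpha_beta))
    eval_mask = patient.lung_mask.values
    if patient.cancer_type == "lung" and patient.gtv_mask is not None:
        eval_mask = eval_mask & ~patient.gtv_mask.values
    return compute_dvh(total, patient.lung_mask.with_values(eval_mask)).mld_gy


def _assign_grades(rng, positives: np.ndarray, cancer_type: str) -> np.ndarray:
    """Map the binary outcome to RP grades mirroring the study's grade mix."""
    grades = np.zeros(positives.size, dtype=int)
    if cancer_type == "esophageal":
        # positives are mostly grade 1, occasionally grade 2
        grades[positives] = np.where(rng.uniform(size=positives.sum()) < 58 / 63, 1, 2)
    else:
        # positives are mostly grade 2, occasionally grade 3
        grades[positives] = np.where(rng.uniform(size=positives.sum()) < 14 / 16, 2, 3)
    return grades


def generate_cohort(spec: CohortSpec) -> list[PhantomPatient]:
    """Generate a fully reproducible phantom cohort.

    Raises ``ValueError`` naming the achievable prevalence range if the
    intercept calibration cannot reach the target prevalence.
    """
    patients = [_generate_patient(i, spec) for i in range(spec.n_patients)]

    mld = np.array([_patient_mld(p) for p in patients])
    comps = np.array([heterogeneity_components(p) for p in patients])
    het = _combined_heterogeneity(comps)
    label_rng = np.random.default_rng(_seed_seq(spec.seed, 7))
    eta = spec.effect_mld * mld + spec.effect_texture * het
    if spec.noise_sd > 0:
        eta = eta + spec.noise_sd * label_rng.standard_normal(spec.n_patients)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor in outcome model")

    lo = float(special.expit(-60.0 + eta).mean())
    hi = float(special.expit(60.0 + eta).mean())
    if not lo < spec.target_prevalence < hi:
        raise ValueError(
            "prevalence calibration impossible: achievable range "
            f"({lo:.4f}, {hi:.4f}) excludes target {spec.target_prevalence}"
        )
    intercept = optimize.brentq(
        lambda c: special.expit(c + eta).mean() - spec.target_prevalence, -60.0, 60.0
    )
    prob = special.expit(intercept + eta)
    positives = label_rng.uniform(size=spec.n_patients) < prob
    grades = _assign_grades(label_rng, positives, spec.cancer_type)

    out = []
    for p, g, m, h in zip(patients, grades, mld, het):
        out.append(replace(p, rp_grade=int(g), mld_gy=float(m), heterogeneity=float(h)))
    emp = np.mean([p.positive for p in out])
    logger.info(
        "generated %d %s phantoms: empirical prevalence %.3f (target %.3f)",
        spec.n_patients, spec.cancer_type, emp, spec.target_prevalence,
    )
    return out


# ---------------------------------------------------------------------------
# disk round-trip

MANIFEST_COLUMNS = (
    "patient_id", "cancer_type", "rp_grade",
    "ct_path", "dose_paths", "lung_mask_path", "gtv_mask_path",
)


def cohort_to_disk(patients: list[PhantomPatient], directory: str | Path) -> Path:
    """Write a cohort as NIfTI volumes plus a CSV manifest; returns the
    manifest path.  Round-trips losslessly through :func:`load_cohort`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for p in patients:
            pdir = directory / p.patient_id
            pdir.mkdir(exist_ok=True)
            ct_path = p.ct.to_nifti(pdir / "ct.nii.gz")
            dose_paths = []
            for i, frac in enumerate(p.fraction_doses):
                dose_paths.append(str(frac.to_nifti(pdir / f"dose_f{i:03d}.nii.gz")))
            lung_path = p.lung_mask.to_nifti(pdir / "lung.nii.gz")
            gtv_path = ""
            if p.gtv_mask is not None:
                gtv_path = str(p.gtv_mask.to_nifti(pdir / "gtv.nii.gz"))
            writer.writerow({
                "patient_id": p.patient_id,
                "cancer_type": p.cancer_type,
                "rp_grade": p.rp_grade,
                "ct_path": str(ct_path),
                "dose_paths": ";".join(dose_paths),
                "lung_mask_path": str(lung_path),
                "gtv_mask_path": gtv_path,
            })
    return manifest


def load_cohort(manifest_path: str | Path) -> list[PhantomPatient]:
    """Read a cohort back from a manifest written by :func:`cohort_to_disk`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"no such manifest: {manifest_path}")
    patients = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            ct = ImageVolume.from_nifti(row["ct_path"], modality=Modality.CT_HU)
            fractions = tuple(
                ImageVolume.from_nifti(path, modality=Modality.DOSE_GY)
                for path in row["dose_paths"].split(";")
            )
            lung = RoiMask.from_nifti(row["lung_mask_path"])
            gtv = RoiMask.from_nifti(row["gtv_mask_path"]) if row["gtv_mask_path"] else None
            patients.append(
                PhantomPatient(
                    patient_id=row["patient_id"],
                    ct=ct,
                    fraction_doses=DoseSeries(fractions),
                    lung_mask=lung,
                    gtv_mask=gtv,
                    rp_grade=int(row["rp_grade"]),
                    cancer_type=row["cancer_type"],  # type: ignore[arg-type]
                )
            )
    return patients
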