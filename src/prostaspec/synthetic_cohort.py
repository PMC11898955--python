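"""Phantom BP-MRI cohorts with planted ground truth.

Stands in for the clinical data (a PI-CAI-style cohort) and for a trained
AI detector's outputs, so that every pipeline stage is testable without any
download.  Each phantom patient is an ellipsoidal prostate filled with
correlated 3-band Gaussian tissue; patients with ISUP grade ≥ 1 carry an
embedded ellipsoidal tumor whose properties follow grade-conditional linear
models with Gaussian noise:

* spectral contrast (in background-σ units, direction low ADC / high HBV /
  low T2 — the green tumor of the usual RGB composite) increases with grade;
* volume (mL) increases with grade;
* eccentricity decreases with grade (adenocarcinomas grow more symmetric as
  grade rises).

The three sequences are emitted at distinct spacings and origins (T2 finer
in-plane, HBV offset by one voxel) so cube assembly genuinely exercises
resampling, translation, and cropping.  The prostate mask written per
patient is the *normal-tissue* outline — prostate minus tumor — emulating
the expert-drawn normal prostate mask used for covariance estimation.

Surrogate AI outputs are a per-patient likelihood, monotone in grade
through a logistic link with noise, and a detection map built from the
ground-truth tumor mask under a mild dilation/erosion/shift perturbation,
mimicking an imperfect detector.

Identical spec + seed reproduce a cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_formats import (
    CohortRecord,
    SequenceVolume,
    write_cohort_metadata,
    write_volume,
)

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticPatient",
    "SyntheticCohort",
    "generate_patient",
    "generate_cohort",
    "generate_ai_outputs",
    "DEFAULT_ISUP_HISTOGRAM",
]

#: Grade histogram skewed low, emulating a biopsy cohort whose mean grade
#: is near 1 and where ~3 in 4 cases are clinically insignificant.
DEFAULT_ISUP_HISTOGRAM = {0: 0.31, 1: 0.43, 2: 0.10, 3: 0.07, 4: 0.05, 5: 0.04}


def _default_background_cov() -> np.ndarray:
    # Per-band standard deviations and inter-band correlations of normal
    # prostate tissue (arbitrary intensity units).
    sigma = np.array([100.0, 20.0, 60.0])
    corr = np.array(
        [
            [1.0, -0.45, 0.35],
            [-0.45, 1.0, -0.25],
            [0.35, -0.25, 1.0],
        ]
    )
    return corr * np.outer(sigma, sigma)


@dataclass
class SyntheticCohortSpec:
    """Study conditions of the phantom cohort (defaults are the conditions).

    Lengths in mm, volumes in mL, contrasts in background-σ units.
    """

    n_patients: int = 42
    grid_shape: tuple[int, int, int] = (48, 48, 20)
    adc_spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    hbv_spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    t2_spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    hbv_origin_offset: tuple[float, float, float] = (2.0, 0.0, 0.0)
    t2_origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    prostate_semi_axes: tuple[float, float, float] = (30.0, 24.0, 20.0)
    background_mean: tuple[float, float, float] = (1200.0, 150.0, 500.0)
    background_cov: np.ndarray = field(default_factory=_default_background_cov)
    outside_mean_factor: float = 0.45
    tumor_direction: tuple[float, float, float] = (-1.0, 1.0, -1.0)
    contrast_base: float = 3.0  # σ-units at grade 1
    contrast_per_grade: float = 0.4  # σ-units per grade above 1
    contrast_noise_sd: float = 0.15
    volume_base_ml: float = 0.8
    volume_slope_ml: float = 0.7  # mL per grade
    volume_noise_sd: float = 0.2
    ecc_base: float = 0.68  # eccentricity at grade-0 extrapolation
    ecc_slope: float = -0.08  # per grade (anti-correlated with grade)
    ecc_noise_sd: float = 0.05
    tumor_center_jitter_mm: float = 3.0
    n_tumors: int = 1
    ai_slope: float = 0.9  # logistic link: p = σ(ai_slope·(isup − 2) + ε)
    ai_noise_sd: float = 0.5
    ai_map_perturb: bool = True
    isup_histogram: dict = field(default_factory=lambda: dict(DEFAULT_ISUP_HISTOGRAM))
    seed: int = 0

    def __post_init__(self) -> None:
        self.background_cov = np.asarray(self.background_cov, dtype=float)
        eigvals = np.linalg.eigvalsh(self.background_cov)
        if np.any(eigvals <= 0):
            raise ValueError("background covariance must be positive definite")
        total = sum(self.isup_histogram.values())
        if total <= 0:
            raise ValueError("ISUP histogram must have positive mass")
        self.isup_histogram = {int(k): v / total for k, v in self.isup_histogram.items()}


@dataclass
class SyntheticPatient:
    """One phantom patient with its planted ground truth."""

    record: CohortRecord
    volumes: dict  # label -> SequenceVolume
    mask: SequenceVolume  # normal-prostate outline on the ADC grid
    truth: dict  # JSON-serializable ground-truth record
    detection_map: Optional[SequenceVolume] = None


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    patients: list

    @property
    def records(self) -> list[CohortRecord]:
        return [p.record for p in self.patients]

    def write(self, out_dir) -> Path:
        """Serialize to a directory tree: volumes, masks, metadata, truth."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for patient in self.patients:
            pdir = out_dir / patient.record.patient_id
            for label, vol in patient.volumes.items():
                write_volume(vol, pdir / f"{label.lower()}.nii.gz")
            write_volume(patient.mask, pdir / "mask.nii.gz")
            if patient.detection_map is not None:
                write_volume(patient.detection_map, pdir / "ai_map.nii.gz")
        write_cohort_metadata(self.records, out_dir / "metadata.csv")
        truth = {p.record.patient_id: p.truth for p in self.patients}
        (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        return out_dir


# --------------------------------------------------------------------------
# Geometry helpers


def _world_coordinates(shape, spacing, origin=(0.0, 0.0, 0.0)):
    axes = [
        o + np.arange(n) * s for n, s, o in zip(shape, spacing, origin)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def _ellipsoid_mask(coords, center, semi_axes, rotation) -> np.ndarray:
    rel = np.stack([c - ctr for c, ctr in zip(coords, center)], axis=-1)
    local = rel @ rotation  # world -> ellipsoid frame
    return np.sum((local / np.asarray(semi_axes)) ** 2, axis=-1) <= 1.0


def _semi_axes_from_volume_ecc(volume_ml: float, ecc: float) -> tuple[float, float, float]:
    """Prolate-style ellipsoid a ≥ b = c with (a−b)/a = ecc and given volume."""
    b_over_a = 1.0 - ecc
    a = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi * b_over_a**2)) ** (1.0 / 3.0)
    return a, a * b_over_a, a * b_over_a


# --------------------------------------------------------------------------
# Patient generation


def generate_patient(
    spec: SyntheticCohortSpec, isup: int, seed: int, patient_id: Optional[str] = None
) -> SyntheticPatient:
    """Generate one phantom patient at the given ISUP grade.

    Grade-0 patients carry no tumor.  The returned truth record stores the
    planted signature, center, axes, volume, eccentricity, and the
    signature seed region (center + radius, mm, world frame).
    """
    rng = np.random.default_rng(seed)
    patient_id = patient_id or f"synthetic-{seed:08d}"
    shape = tuple(spec.grid_shape)
    spacing = spec.adc_spacing
    voxel_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0

    # Margin rows/cols so offset sequences still cover the full ADC grid.
    margins = tuple(
        int(np.ceil(abs(o) / s))
        for o, s in zip(spec.hbv_origin_offset, spacing)
    )
    big_shape = tuple(n + 2 * m for n, m in zip(shape, margins))
    big_origin = tuple(-m * s for m, s in zip(margins, spacing))
    coords = _world_coordinates(big_shape, spacing, big_origin)

    prostate_center = tuple((n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    prostate = _ellipsoid_mask(
        coords, prostate_center, spec.prostate_semi_axes, np.eye(3)
    )

    sigma = np.sqrt(np.diag(spec.background_cov))
    m = np.asarray(spec.background_mean)
    chol = np.linalg.cholesky(spec.background_cov)
    noise = rng.standard_normal(size=big_shape + (3,)) @ chol.T
    cube = np.where(
        prostate[..., None],
        m + noise,
        spec.outside_mean_factor * m + noise,
    )

    tumors, tumor_union = [], np.zeros(big_shape, dtype=bool)
    if isup >= 1:
        for _ in range(spec.n_tumors):
            volume_ml = max(
                spec.volume_base_ml
                + spec.volume_slope_ml * isup
                + rng.normal(0.0, spec.volume_noise_sd),
                2.0 * voxel_ml,
            )
            prostate_ml = (
                4.0 / 3.0 * np.pi * np.prod(spec.prostate_semi_axes) / 1000.0
            )
            if volume_ml >= prostate_ml:
                raise ValueError(
                    f"tumor volume {volume_ml:.1f} mL exceeds the prostate "
                    f"({prostate_ml:.1f} mL)"
                )
            # Cap eccentricity so the major axis fits inside the gland.
            a_max = 0.70 * min(spec.prostate_semi_axes)
            ecc_cap = 1.0 - np.sqrt(
                3.0 * volume_ml * 1000.0 / (4.0 * np.pi * a_max**3)
            )
            ecc = float(
                np.clip(
                    spec.ecc_base
                    + spec.ecc_slope * isup
                    + rng.normal(0.0, spec.ecc_noise_sd),
                    0.02,
                    min(0.92, max(ecc_cap, 0.02)),
                )
            )
            contrast = max(
                spec.contrast_base
                + spec.contrast_per_grade * (isup - 1)
                + rng.normal(0.0, spec.contrast_noise_sd),
                0.5,
            )
            semi_axes = _semi_axes_from_volume_ecc(volume_ml, ecc)
            jitter = rng.uniform(
                -spec.tumor_center_jitter_mm, spec.tumor_center_jitter_mm, size=3
            )
            center = tuple(c + j for c, j in zip(prostate_center, jitter))
            rotation = _random_rotation(rng)
            tmask = _ellipsoid_mask(coords, center, semi_axes, rotation)
            shift = np.asarray(spec.tumor_direction) * contrast * sigma
            cube[tmask] += shift
            tumor_union |= tmask
            tumors.append(
                {
                    "center_mm": list(center),
                    "semi_axes_mm": list(semi_axes),
                    "rotation": rotation.tolist(),
                    "target_volume_ml": float(volume_ml),
                    "rasterized_voxels": int(tmask.sum()),
                    "rasterized_volume_ml": float(tmask.sum() * voxel_ml),
                    "eccentricity": ecc,
                    "contrast_sigma": float(contrast),
                    "signature": (m + shift).tolist(),
                    "seed_radius_mm": float(max(min(semi_axes) * 0.7, 2.1)),
                }
            )

    window = tuple(slice(mg, mg + n) for mg, n in zip(margins, shape))

    def _crop(band_idx=None, arr=None):
        a = cube[..., band_idx] if arr is None else arr
        return a[window]

    adc = SequenceVolume(
        grid=_crop(0), spacing=spacing, origin=(0.0, 0.0, 0.0), sequence_label="ADC"
    )
    # HBV: same pitch, origin shifted by whole voxels; its grid is the truth
    # sampled at the shifted world positions.
    hbv_shift = tuple(
        int(np.rint(o / s)) for o, s in zip(spec.hbv_origin_offset, spec.hbv_spacing)
    )
    hbv_window = tuple(
        slice(mg + sh, mg + sh + n) for mg, sh, n in zip(margins, hbv_shift, shape)
    )
    hbv = SequenceVolume(
        grid=cube[..., 1][hbv_window],
        spacing=spec.hbv_spacing,
        origin=spec.hbv_origin_offset,
        sequence_label="HBV",
    )
    # T2: finer in-plane lattice over the same extent, trilinear from truth.
    t2_coarse = SequenceVolume(
        grid=_crop(2), spacing=spacing, origin=(0.0, 0.0, 0.0), sequence_label="T2"
    )
    from .registration import resample_volume  # local import avoids a cycle

    t2 = resample_volume(t2_coarse, spec.t2_spacing)
    t2 = SequenceVolume(
        grid=t2.grid,
        spacing=spec.t2_spacing,
        origin=spec.t2_origin_offset,
        sequence_label="T2",
    )

    normal_mask = prostate & ~tumor_union
    mask_vol = SequenceVolume(
        grid=normal_mask[window].astype(float),
        spacing=spacing,
        origin=(0.0, 0.0, 0.0),
        sequence_label="ADC",
    )

    record = CohortRecord(patient_id=patient_id, isup=int(isup))
    truth = {
        "isup": int(isup),
        "cspca": bool(record.cspca),
        "seed": int(seed),
        "prostate_center_mm": list(prostate_center),
        "prostate_semi_axes_mm": list(spec.prostate_semi_axes),
        "background_mean": m.tolist(),
        "tumors": tumors,
        "seed_region": {
            "center_mm": tumors[0]["center_mm"] if tumors else list(prostate_center),
            "radius_mm": tumors[0]["seed_radius_mm"] if tumors else 3.5,
        },
    }
    return SyntheticPatient(
        record=record,
        volumes={"ADC": adc, "HBV": hbv, "T2": t2},
        mask=mask_vol,
        truth=truth,
    )


def generate_cohort(
    spec: SyntheticCohortSpec, with_ai: bool = True
) -> SyntheticCohort:
    """Generate a full phantom cohort from the spec's root seed.

    Grades are drawn from the configured histogram; per-patient seeds fan
    out deterministically from the root seed, so any patient regenerates
    independently of cohort size.
    """
    if spec.n_patients < 4:
        raise ValueError("a cohort needs at least 4 patients for regression")
    root = np.random.SeedSequence(spec.seed)
    grade_rng = np.random.default_rng(root.spawn(1)[0])
    grades_pool = sorted(spec.isup_histogram)
    probs = [spec.isup_histogram[g] for g in grades_pool]
    grades = grade_rng.choice(grades_pool, size=spec.n_patients, p=probs)
    patients = []
    child_seeds = np.random.SeedSequence(spec.seed + 1).generate_state(spec.n_patients)
    for i, grade in enumerate(grades):
        pid = f"patient-{i:04d}"
        seed_i = int(child_seeds[i]) % (2**31)
        patients.append(generate_patient(spec, int(grade), seed_i, patient_id=pid))
    cohort = SyntheticCohort(spec=spec, patients=patients)
    if with_ai:
        generate_ai_outputs(cohort)
    return cohort


# --------------------------------------------------------------------------
# Surrogate AI outputs


def generate_ai_outputs(cohort: SyntheticCohort) -> SyntheticCohort:
    """Attach surrogate AI likelihoods and detection maps to a cohort.

    Likelihood: logistic link in grade, ``p = σ(a·(isup − 2) + ε)``, so the
    anchor grade 2 sits at p ≈ 0.5.  Detection map: the ground-truth tumor
    mask, optionally perturbed by one round of dilation or erosion plus a
    one-voxel shift, carrying a constant in-blob score of 0.95.
    """
    spec = cohort.spec
    for patient in cohort.patients:
        rng = np.random.default_rng(patient.truth["seed"] + 7_000_003)
        eps = rng.normal(0.0, spec.ai_noise_sd)
        logit = spec.ai_slope * (patient.record.isup - 2.0) + eps
        likelihood = float(np.clip(1.0 / (1.0 + np.exp(-logit)), 0.0, 1.0))
        adc = patient.volumes["ADC"]
        det = np.zeros(adc.shape, dtype=bool)
        coords = _world_coordinates(adc.shape, adc.spacing, adc.origin)
        for tumor in patient.truth["tumors"]:
            det |= _ellipsoid_mask(
                coords,
                tumor["center_mm"],
                tumor["semi_axes_mm"],
                np.asarray(tumor["rotation"]),
            )
        if spec.ai_map_perturb and det.any():
            op = rng.integers(0, 3)
            if op == 1:
                det = ndimage.binary_dilation(det)
            elif op == 2:
                eroded = ndimage.binary_erosion(det)
                det = eroded if eroded.any() else det
            axis = int(rng.integers(0, 3))
            det = np.roll(det, int(rng.integers(-1, 2)), axis=axis)
        patient.detection_map = SequenceVolume(
            grid=det.astype(float) * 0.95,
            spacing=adc.spacing,
            origin=adc.origin,
            sequence_label="ADC",
        )
        patient.record = CohortRecord(
            patient_id=patient.record.patient_id,
            isup=patient.record.isup,
            cspca=patient.record.cspca,
            ai_likelihood=likelihood,
        )
        patient.truth["ai_likelihood"] = likelihood
    return cohort
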