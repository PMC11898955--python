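"""Blob morphometrics: thresholding, labeling, volume and eccentricity.

The ACE detection map is thresholded (0.9 by default, boundary inclusive)
into a binary candidate-tumor mask.  Connected components ("blobs") under
26-connectivity are labeled; blobs smaller than 5 voxels (~1e-2 mL at
typical diffusion-map resolution) are filtered out as noise.

Per blob, two descriptors are computed:

volume
    voxel count × voxel volume, reported in mL;
eccentricity ``E_k``
    from the second-central-moment (scatter) matrix of the blob's
    voxel-center coordinates in mm.  With eigenvalues λ1 ≥ λ2 ≥ λ3 the axis
    lengths are ``l_k = √λ1`` and ``s_k = √λ2`` and
    ``E_k = (l_k − s_k)/l_k`` — 0 for a sphere, 1 for a line.  A single
    voxel has no extent, so its eccentricity is missing (NaN), not an error.

Per patient the blob list is aggregated into the morphometric feature set
used by the statistical layer: blob count, max/average/total volume, and
the eccentricity of the largest blob plus its unweighted and mass-weighted
cohort averages.  The same threshold→label→measure chain applies unchanged
to externally supplied AI detection maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .io_formats import CohortRecord
from .spectral_scores import ScoreMap

__all__ = [
    "Blob",
    "PatientFeatures",
    "DEFAULT_TAU",
    "DEFAULT_MIN_BLOB_SIZE",
    "threshold_map",
    "label_blobs",
    "blob_volume",
    "blob_eccentricity",
    "measure_blobs",
    "patient_features",
    "features_from_detection_map",
]

#: Default ACE threshold; a voxel with score ≥ τ is candidate tumor.
DEFAULT_TAU = 0.9
#: Blobs below this voxel count are discarded as noise.
DEFAULT_MIN_BLOB_SIZE = 5

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}


@dataclass
class Blob:
    """A labeled connected tumor component."""

    label: int
    voxel_ids: np.ndarray  # (size, 3) integer indices
    size: int
    volume: float = np.nan  # mL
    l_k: float = np.nan  # major axis length, mm
    s_k: float = np.nan  # second axis length, mm
    E_k: float = np.nan  # eccentricity in [0, 1]; NaN when undefined
    centroid: Optional[np.ndarray] = None


@dataclass
class PatientFeatures:
    """One patient's scalar predictors plus outcome labels.

    Eccentricities are NaN (missing) when no blob survives filtering or all
    surviving blobs are single voxels; volumes are 0 in the empty case.
    """

    patient_id: str
    scr: float = np.nan
    zscore: float = np.nan
    n_blobs: int = 0
    max_blob_volume: float = 0.0
    avg_blob_volume: float = 0.0
    total_volume: float = 0.0
    ecc_largest: float = np.nan
    ecc_avg: float = np.nan
    ecc_weighted: float = np.nan
    ai_likelihood: float = np.nan
    ai_n_blobs: float = np.nan
    ai_max_blob_volume: float = np.nan
    ai_avg_blob_volume: float = np.nan
    ai_total_volume: float = np.nan
    ai_ecc_largest: float = np.nan
    ai_ecc_avg: float = np.nan
    ai_ecc_weighted: float = np.nan
    isup: int = 0
    cspca: bool = False
    covariance_variant: str = "raw"
    gamma: float = 0.0

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "scr": self.scr,
            "zscore": self.zscore,
            "n_blobs": self.n_blobs,
            "max_blob_volume": self.max_blob_volume,
            "avg_blob_volume": self.avg_blob_volume,
            "total_volume": self.total_volume,
            "ecc_largest": self.ecc_largest,
            "ecc_avg": self.ecc_avg,
            "ecc_weighted": self.ecc_weighted,
            "ai_likelihood": self.ai_likelihood,
            "ai_n_blobs": self.ai_n_blobs,
            "ai_max_blob_volume": self.ai_max_blob_volume,
            "ai_avg_blob_volume": self.ai_avg_blob_volume,
            "ai_total_volume": self.ai_total_volume,
            "ai_ecc_largest": self.ai_ecc_largest,
            "ai_ecc_avg": self.ai_ecc_avg,
            "ai_ecc_weighted": self.ai_ecc_weighted,
            "isup": self.isup,
            "cspca": int(bool(self.cspca)),
            "covariance_variant": self.covariance_variant,
            "gamma": self.gamma,
        }


def threshold_map(scores, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Binary mask of voxels with score ≥ τ (boundary inclusive)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {tau}")
    arr = scores.scores if isinstance(scores, ScoreMap) else np.asarray(scores)
    return arr >= tau


def label_blobs(
    mask: np.ndarray,
    min_size: int = DEFAULT_MIN_BLOB_SIZE,
    connectivity: int = 26,
) -> list[Blob]:
    """Connected components of a binary mask, small components filtered out.

    Neighborhood is 26-connected in 3D by default (6/18 available for
    sensitivity checks).  Components with fewer than ``min_size`` voxels are
    discarded; survivors are labeled 1..K in raster-scan order of each
    component's first voxel.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be ≥ 1, got {min_size}")
    if connectivity not in _CONNECTIVITY_TO_SKIMAGE:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_TO_SKIMAGE)}")
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=_CONNECTIVITY_TO_SKIMAGE[connectivity])
    components = []
    for lab in range(1, labeled.max() + 1):
        ids = np.argwhere(labeled == lab)
        if len(ids) < min_size:
            continue
        # argwhere returns voxels in raster order, so ids[0] is the first.
        first = np.ravel_multi_index(ids[0], mask.shape)
        components.append((int(first), ids))
    components.sort(key=lambda item: item[0])
    return [
        Blob(label=k, voxel_ids=ids, size=len(ids))
        for k, (_, ids) in enumerate(components, start=1)
    ]


def blob_volume(blob: Blob, spacing: Sequence[float]) -> float:
    """Blob volume in mL: voxel count × voxel volume (mm³) / 1000, exact."""
    sr, sc, ss = (float(s) for s in spacing)
    if min(sr, sc, ss) <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return blob.size * (sr * sc * ss) / 1000.0


def blob_eccentricity(blob: Blob, spacing: Sequence[float]) -> float:
    """Eccentricity from the blob's moment (scatter) matrix.

    Voxel-center coordinates in mm are centered; the eigenvalues of their
    second-moment matrix give squared axis lengths.  ``E = (l − s)/l`` with
    ``l = √λ1``, ``s = √λ2``.  Undefined (NaN) for single-voxel blobs.
    """
    if blob.size < 2:
        return float("nan")
    coords = blob.voxel_ids * np.asarray(spacing, dtype=float)
    centered = coords - coords.mean(axis=0)
    scatter = centered.T @ centered / blob.size
    eigvals = np.sort(np.linalg.eigvalsh(scatter))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    l_k = float(np.sqrt(eigvals[0]))
    s_k = float(np.sqrt(eigvals[1]))
    if l_k == 0.0:
        return float("nan")
    return (l_k - s_k) / l_k


def measure_blobs(blobs: list[Blob], spacing: Sequence[float]) -> list[Blob]:
    """Fill volume, axes, eccentricity and centroid for each blob in place."""
    for blob in blobs:
        blob.volume = blob_volume(blob, spacing)
        blob.centroid = blob.voxel_ids.mean(axis=0) * np.asarray(spacing, dtype=float)
        if blob.size >= 2:
            coords = blob.voxel_ids * np.asarray(spacing, dtype=float)
            centered = coords - coords.mean(axis=0)
            scatter = centered.T @ centered / blob.size
            eigvals = np.clip(np.sort(np.linalg.eigvalsh(scatter))[::-1], 0.0, None)
            blob.l_k = float(np.sqrt(eigvals[0]))
            blob.s_k = float(np.sqrt(eigvals[1]))
            blob.E_k = (blob.l_k - blob.s_k) / blob.l_k if blob.l_k > 0 else float("nan")
    return blobs


def _aggregate(blobs: list[Blob]) -> dict:
    """Morphometric aggregation of a measured blob list."""
    if not blobs:
        return dict(
            n_blobs=0,
            max_blob_volume=0.0,
            avg_blob_volume=0.0,
            total_volume=0.0,
            ecc_largest=float("nan"),
            ecc_avg=float("nan"),
            ecc_weighted=float("nan"),
        )
    volumes = np.array([b.volume for b in blobs])
    sizes = np.array([b.size for b in blobs], dtype=float)
    eccs = np.array([b.E_k for b in blobs])
    # Largest-volume blob; ties broken by smallest label (raster order).
    largest = min(blobs, key=lambda b: (-b.volume, b.label))
    defined = ~np.isnan(eccs)
    return dict(
        n_blobs=len(blobs),
        max_blob_volume=float(volumes.max()),
        avg_blob_volume=float(volumes.mean()),
        total_volume=float(volumes.sum()),
        ecc_largest=float(largest.E_k),
        ecc_avg=float(eccs[defined].mean()) if defined.any() else float("nan"),
        ecc_weighted=(
            float((sizes[defined] * eccs[defined]).sum() / sizes[defined].sum())
            if defined.any()
            else float("nan")
        ),
    )


def patient_features(
    blobs: list[Blob],
    scr: float,
    zscore: float,
    outcome: CohortRecord,
    *,
    covariance_variant: str = "raw",
    gamma: float = 0.0,
) -> PatientFeatures:
    """Aggregate measured blobs and scores into one patient's feature row."""
    agg = _aggregate(blobs)
    return PatientFeatures(
        patient_id=outcome.patient_id,
        scr=scr,
        zscore=zscore,
        ai_likelihood=(
            outcome.ai_likelihood if outcome.ai_likelihood is not None else float("nan")
        ),
        isup=outcome.isup,
        cspca=bool(outcome.cspca),
        covariance_variant=covariance_variant,
        gamma=gamma,
        **agg,
    )


def features_from_detection_map(
    detection,
    spacing: Sequence[float],
    tau: float = DEFAULT_TAU,
    min_size: int = DEFAULT_MIN_BLOB_SIZE,
    connectivity: int = 26,
) -> dict:
    """Morphometrics of an externally supplied (AI) detection map.

    The identical threshold → label → volume → eccentricity chain as the
    spectral path, returning the aggregated feature dict.
    """
    mask = threshold_map(detection, tau)
    blobs = measure_blobs(label_blobs(mask, min_size, connectivity), spacing)
    return _aggregate(blobs)
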