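"""Reading and writing the volume and table formats the pipeline touches.

Volumes are NIfTI (``.nii``/``.nii.gz``) or MHA; tables are CSV with a header
row.  Nothing in here does science: this module only moves intensities,
spacings, origins and cohort labels between disk and the in-memory types the
rest of the package computes on.

Axis convention: volumes are held as ``grid[row, column, slice]``.  On read,
the file's (x, y, z) header spacing/origin are mapped onto (row, column,
slice) = (y, x, z); orientation matrices beyond spacing and origin are
ignored because registration works by resampling and integer translation
only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .calibration import cspca_label

SEQUENCE_LABELS = ("ADC", "HBV", "T2")

__all__ = [
    "SequenceVolume",
    "CohortRecord",
    "VolumeFormatError",
    "CohortSchemaError",
    "read_volume",
    "write_volume",
    "read_cohort_metadata",
    "write_cohort_metadata",
    "write_feature_table",
    "read_feature_table",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable, corrupt, or non-3D volume files."""


class CohortSchemaError(ValueError):
    """Raised when a cohort or feature table violates the expected schema."""


@dataclass(frozen=True)
class SequenceVolume:
    """A single MRI sequence on its native acquisition grid.

    Parameters
    ----------
    grid
        3D intensity lattice ordered (row, column, slice), arbitrary units.
    spacing
        Voxel pitch per axis, mm, all positive.
    origin
        World offset of voxel (0, 0, 0), mm, (row, column, slice) order.
    sequence_label
        One of ``"ADC"``, ``"HBV"``, ``"T2"``.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sequence_label: str = "ADC"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if grid.ndim != 3:
            raise VolumeFormatError(f"expected a 3D grid, got {grid.ndim}D")
        if not np.all(np.isfinite(grid)):
            raise VolumeFormatError("volume contains non-finite intensities")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacings must be 3 positive lengths, got {self.spacing}")
        if self.sequence_label not in SEQUENCE_LABELS:
            raise VolumeFormatError(
                f"sequence_label must be one of {SEQUENCE_LABELS}, got {self.sequence_label!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def with_grid(self, grid: np.ndarray, **changes) -> "SequenceVolume":
        return replace(self, grid=grid, **changes)


@dataclass(frozen=True)
class CohortRecord:
    """One patient's outcome labels.

    ``cspca`` is derived from the ISUP grade (significant ⇔ grade ≥ 2) when it
    is not supplied explicitly.
    """

    patient_id: str
    isup: int
    cspca: Optional[bool] = None
    ai_likelihood: Optional[float] = None

    def __post_init__(self) -> None:
        if self.isup not in range(6):
            raise ValueError(f"ISUP grade must be an integer 0–5, got {self.isup}")
        if self.ai_likelihood is not None and not 0.0 <= self.ai_likelihood <= 1.0:
            raise ValueError(f"ai_likelihood must lie in [0, 1], got {self.ai_likelihood}")
        if self.cspca is None:
            object.__setattr__(self, "cspca", cspca_label(self.isup))


# --------------------------------------------------------------------------
# Volumes


def _is_supported(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith((".nii", ".nii.gz", ".mha"))


def read_volume(path, sequence_label: str = "ADC") -> SequenceVolume:
    """Read a NIfTI or MHA volume; spacing and origin come from the header.

    Intensities are unmodified.  Raises :class:`VolumeFormatError` for
    unreadable files or non-3D payloads.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not _is_supported(path):
        raise VolumeFormatError(f"unsupported volume format: {path.name}")
    try:
        image = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on corrupt input
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    if image.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path} holds a {image.GetDimension()}D image, expected 3D"
        )
    arr = sitk.GetArrayFromImage(image)  # (z, y, x)
    grid = np.ascontiguousarray(arr.transpose(1, 2, 0)).astype(float)  # (y, x, z)
    sx, sy, sz = image.GetSpacing()
    ox, oy, oz = image.GetOrigin()
    return SequenceVolume(
        grid=grid,
        spacing=(sy, sx, sz),
        origin=(oy, ox, oz),
        sequence_label=sequence_label,
    )


def write_volume(vol: SequenceVolume, path) -> None:
    """Write a volume as NIfTI or MHA, chosen by the file extension."""
    path = Path(path)
    if not _is_supported(path):
        raise VolumeFormatError(f"unsupported volume format: {path.name}")
    arr = np.ascontiguousarray(vol.grid.transpose(2, 0, 1))  # (y,x,z) -> (z,y,x)
    image = sitk.GetImageFromArray(arr)
    sr, sc, ss = vol.spacing
    orr, oc, os_ = vol.origin
    image.SetSpacing((sc, sr, ss))
    image.SetOrigin((oc, orr, os_))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(image, str(path))


# --------------------------------------------------------------------------
# Cohort metadata


def read_cohort_metadata(path) -> list[CohortRecord]:
    """Read a cohort CSV with columns patient_id, isup[, cspca, ai_likelihood]."""
    table = pd.read_csv(path)
    required = {"patient_id", "isup"}
    missing = required - set(table.columns)
    if missing:
        raise CohortSchemaError(f"cohort table lacks required column(s): {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        isup = int(row["isup"])
        if isup not in range(6):
            raise ValueError(f"ISUP grade must be 0–5, got {isup} for {row['patient_id']}")
        cspca = None
        if "cspca" in table.columns and not pd.isna(row["cspca"]):
            cspca = bool(row["cspca"])
        likelihood = None
        if "ai_likelihood" in table.columns and not pd.isna(row["ai_likelihood"]):
            likelihood = float(row["ai_likelihood"])
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                isup=isup,
                cspca=cspca,
                ai_likelihood=likelihood,
            )
        )
    return records


def write_cohort_metadata(records: Sequence[CohortRecord], path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "isup": rec.isup,
                "cspca": int(bool(rec.cspca)),
                "ai_likelihood": rec.ai_likelihood,
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Feature tables


def write_feature_table(records, path) -> None:
    """Write per-patient features as CSV, one row per patient.

    ``records`` may be a list of mappings or of objects exposing
    ``as_dict()`` (see :class:`~prostaspec.morphology.PatientFeatures`).
    Missing values become empty cells, never sentinel numbers, so downstream
    regression can exclude them pairwise.  All records must share one feature
    set.
    """
    dicts = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in records]
    if dicts:
        keys = list(dicts[0].keys())
        for d in dicts[1:]:
            if list(d.keys()) != keys:
                raise CohortSchemaError("records have heterogeneous feature sets")
    frame = pd.DataFrame(dicts)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # 17 significant digits preserves float64 round-trips exactly.
    frame.to_csv(path, index=False, float_format="%.17g", na_rep="")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path)
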