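"""Assembly of the spatially registered 3-band vectorial image cube.

The three biparametric sequences (ADC, high b-value, T2) are acquired on
different grids: T2 is typically much finer in-plane than the diffusion
maps, and header origins differ by a few millimetres.  Registration here is
deliberately simple, mirroring how these cubes are built in practice for
spectral analysis:

1. every sequence is resampled to the *coarsest* transverse spacing among
   the three (information is never invented by upsampling the reference);
2. header-origin differences are rounded to whole voxels and applied as
   integer translations (sub-voxel registration is out of scope), plus any
   per-sequence manual shift corrections supplied by the operator;
3. all sequences are cropped to the intersection of their fields of view so
   every cube voxel carries data from all three bands;
4. the bands are stacked in fixed (ADC, HBV, T2) order — the red/green/blue
   assignment of the usual colour composite.

Conventions: voxel indices are 0-based, crop windows half-open ``[lo, hi)``,
and the world coordinate of a voxel centre is ``origin + index × spacing``.
Intensities are interpolated trilinearly; binary masks nearest-neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io_formats import SequenceVolume, SEQUENCE_LABELS

__all__ = [
    "RegisteredCube",
    "ProstateMask",
    "OverlapError",
    "ExtentError",
    "resample_volume",
    "align_to_reference",
    "assemble_cube",
    "split_cube",
    "align_mask_to_cube",
    "stitch_slices",
]

BAND_ORDER = SEQUENCE_LABELS  # (ADC, HBV, T2)

#: Minimum number of mask voxels accepted for covariance estimation.
MIN_MASK_VOXELS = 30


class OverlapError(ValueError):
    """Raised when volumes share no field of view after translation."""


class ExtentError(ValueError):
    """Raised when a resampling target leaves fewer than one voxel per axis."""


@dataclass(frozen=True)
class RegisteredCube:
    """Spatially registered 3-band volume: voxels[row, column, slice, band]."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if voxels.ndim != 4 or voxels.shape[3] != 3:
            raise ValueError(f"cube must be (row, col, slice, 3), got {voxels.shape}")
        if not np.all(np.isfinite(voxels)):
            raise ValueError("cube contains non-finite intensities")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def spectra(self) -> np.ndarray:
        """Voxel spectra flattened to (n_voxels, 3)."""
        return self.voxels.reshape(-1, 3)

    def band(self, label: str) -> np.ndarray:
        return self.voxels[..., BAND_ORDER.index(label)]


@dataclass(frozen=True)
class ProstateMask:
    """Binary lattice aligned to a RegisteredCube, marking normal prostate."""

    data: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.data.ndim}D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_against(self, cube: RegisteredCube) -> None:
        if self.data.shape != cube.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match cube {cube.shape}"
            )


# --------------------------------------------------------------------------
# Resampling and alignment


def resample_volume(
    vol: SequenceVolume,
    target_spacing: Sequence[float],
    *,
    is_mask: bool = False,
) -> SequenceVolume:
    """Resample onto ``target_spacing`` over the same world extent.

    Trilinear interpolation for intensities, nearest-neighbour when
    ``is_mask`` (preserves binarity).  The new lattice keeps the input
    origin; voxel centres never leave the input centre extent, so no
    extrapolation occurs.
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if target == vol.spacing:
        return vol
    shape = vol.grid.shape
    for n, s_old, s_new in zip(shape, vol.spacing, target):
        if s_new > n * s_old:
            raise ExtentError(
                f"target spacing {s_new} mm exceeds the {n * s_old} mm axis extent"
            )
    new_shape = tuple(
        int(np.floor((n - 1) * s_old / s_new)) + 1
        for n, s_old, s_new in zip(shape, vol.spacing, target)
    )
    # Index coordinates in the old lattice of each new voxel centre.
    axes = [
        np.arange(n_new) * s_new / s_old
        for n_new, s_new, s_old in zip(new_shape, target, vol.spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    order = 0 if is_mask else 1
    grid = ndimage.map_coordinates(vol.grid, coords, order=order, mode="nearest")
    return vol.with_grid(grid, spacing=target)


def _integer_shift(
    vol: SequenceVolume,
    ref: SequenceVolume,
    extra_shift: Sequence[int] = (0, 0, 0),
) -> tuple[int, int, int]:
    """Whole-voxel position of ``vol``'s first voxel in ``ref``'s index frame."""
    shift = []
    for ov, orf, s, e in zip(vol.origin, ref.origin, ref.spacing, extra_shift):
        shift.append(int(np.rint((ov - orf) / s)) + int(e))
    return tuple(shift)


def _overlap(
    shift: tuple[int, int, int], vol_shape, ref_shape
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    lo = tuple(max(0, t) for t in shift)
    hi = tuple(min(nr, nv + t) for nr, nv, t in zip(ref_shape, vol_shape, shift))
    if any(h <= l for l, h in zip(lo, hi)):
        raise OverlapError(f"no spatial overlap (shift {shift})")
    return lo, hi


def align_to_reference(
    vol: SequenceVolume,
    ref: SequenceVolume,
    extra_shift: Sequence[int] = (0, 0, 0),
    *,
    is_mask: bool = False,
) -> SequenceVolume:
    """Translate ``vol`` onto ``ref``'s grid by whole voxels.

    The translation is the header-origin difference rounded to whole voxels
    plus ``extra_shift`` (manual correction, voxels).  The output grid is
    congruent with ``ref``; voxels outside the overlap are zero-filled.
    ``vol`` must already be at ``ref``'s spacing.
    """
    if not np.allclose(vol.spacing, ref.spacing, rtol=1e-6, atol=1e-9):
        raise ValueError(
            f"volume spacing {vol.spacing} differs from reference {ref.spacing}; "
            "resample first"
        )
    shift = _integer_shift(vol, ref, extra_shift)
    lo, hi = _overlap(shift, vol.grid.shape, ref.grid.shape)
    out = np.zeros(ref.grid.shape, dtype=float)
    src = tuple(slice(l - t, h - t) for l, h, t in zip(lo, hi, shift))
    dst = tuple(slice(l, h) for l, h in zip(lo, hi))
    out[dst] = vol.grid[src]
    if is_mask:
        out = (out > 0.5).astype(float)
    return vol.with_grid(out, origin=ref.origin)


# --------------------------------------------------------------------------
# Cube assembly


def assemble_cube(
    adc: SequenceVolume,
    hbv: SequenceVolume,
    t2: SequenceVolume,
    manual_shifts: Optional[dict] = None,
) -> RegisteredCube:
    """Build the registered (ADC, HBV, T2) cube from the three sequences.

    Common spacing is the coarsest transverse spacing among the three (slice
    spacing follows the ADC reference); each sequence is resampled, aligned
    by integer translation, and all are cropped to the common field of view.
    ``manual_shifts`` maps sequence label to a per-axis integer voxel shift.
    """
    volumes = {"ADC": adc, "HBV": hbv, "T2": t2}
    for label, vol in volumes.items():
        if vol.sequence_label != label:
            raise ValueError(
                f"expected sequence {label!r}, got {vol.sequence_label!r}"
            )
    manual_shifts = manual_shifts or {}
    transverse = max(
        max(vol.spacing[0], vol.spacing[1]) for vol in volumes.values()
    )
    target_spacing = (transverse, transverse, adc.spacing[2])

    resampled = {
        label: resample_volume(vol, target_spacing)
        for label, vol in volumes.items()
    }
    ref = resampled["ADC"]

    shifts, aligned = {}, {}
    for label, vol in resampled.items():
        extra = tuple(manual_shifts.get(label, (0, 0, 0)))
        shifts[label] = _integer_shift(vol, ref, extra)
        aligned[label] = align_to_reference(vol, ref, extra)

    # Intersection of the three fields of view in the reference index frame.
    lo = [0, 0, 0]
    hi = list(ref.grid.shape)
    for label, vol in resampled.items():
        l, h = _overlap(shifts[label], vol.grid.shape, ref.grid.shape)
        lo = [max(a, b) for a, b in zip(lo, l)]
        hi = [min(a, b) for a, b in zip(hi, h)]
    if any(h <= l for l, h in zip(lo, hi)):
        raise OverlapError("sequences share no common field of view")

    window = tuple(slice(l, h) for l, h in zip(lo, hi))
    bands = [aligned[label].grid[window] for label in BAND_ORDER]
    origin = tuple(
        o + l * s for o, l, s in zip(ref.origin, lo, target_spacing)
    )
    return RegisteredCube(
        voxels=np.stack(bands, axis=-1), spacing=target_spacing, origin=origin
    )


def split_cube(cube: RegisteredCube) -> tuple[SequenceVolume, SequenceVolume, SequenceVolume]:
    """Decompose a cube back into its three SequenceVolumes (shared grid)."""
    return tuple(
        SequenceVolume(
            grid=cube.voxels[..., b],
            spacing=cube.spacing,
            origin=cube.origin,
            sequence_label=label,
        )
        for b, label in enumerate(BAND_ORDER)
    )


def align_mask_to_cube(mask_vol: SequenceVolume, cube: RegisteredCube) -> ProstateMask:
    """Bring a mask volume onto a cube's grid (nearest-neighbour, crop)."""
    ref = SequenceVolume(
        grid=np.zeros(cube.shape),
        spacing=cube.spacing,
        origin=cube.origin,
        sequence_label=mask_vol.sequence_label,
    )
    resampled = resample_volume(mask_vol, cube.spacing, is_mask=True)
    aligned = align_to_reference(resampled, ref, is_mask=True)
    return ProstateMask(aligned.grid > 0.5)


# --------------------------------------------------------------------------
# Mosaicking


def stitch_slices(cube: RegisteredCube, slice_ids: Sequence[int]) -> np.ndarray:
    """Concatenate the selected axial slices side by side, per band.

    Returns a (rows, n_slices × columns, 3) mosaic with values unmodified —
    the remote-sensing style swath used for batch visual inspection.
    """
    n_slices = cube.shape[2]
    for sid in slice_ids:
        if not 0 <= sid < n_slices:
            raise IndexError(f"slice index {sid} out of range [0, {n_slices})")
    if len(slice_ids) == 0:
        raise IndexError("at least one slice index is required")
    panels = [cube.voxels[:, :, sid, :] for sid in slice_ids]
    return np.concatenate(panels, axis=1)
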