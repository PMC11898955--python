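"""Per-patient contrast scores and the per-voxel ACE detection map.

A tumor signature ``S`` is the 3-vector of (ADC, HBV, T2) intensities that
characterizes the lesion, here taken as the mean spectrum over an in-scene
seed region.  Against the background model (m, CM) three statistics are
computed:

z-score
    per-band contrast ``(S_b − m_b)/σ_b`` and its root-mean-square as a
    single scalar; ignores inter-band correlation.
SCR (signal-to-clutter ratio)
    the Mahalanobis quadratic form ``(S−m)ᵀ CM⁻¹ (S−m)`` under the selected
    covariance variant's effective inverse — the whitened squared contrast.
ACE (adaptive cosine estimator)
    per voxel, the squared cosine of the angle between the whitened voxel
    spectrum and the whitened signature; scores fall in [0, 1] and trace a
    conical decision surface around ``S``.  Thresholding the ACE map (0.9 by
    default) yields the candidate tumor mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .background_model import BackgroundStats
from .registration import RegisteredCube

__all__ = [
    "TumorSignature",
    "ScoreMap",
    "DegenerateBackgroundError",
    "DegenerateSignatureError",
    "derive_signature",
    "zscore",
    "scr",
    "whiten",
    "ace_map",
    "ace_scores",
]


class DegenerateBackgroundError(ValueError):
    """Raised when a background band has zero variance or zero inverse."""


class DegenerateSignatureError(ValueError):
    """Raised when the signature coincides with the background mean."""


@dataclass(frozen=True)
class TumorSignature:
    """Spectral signature of the target tissue: (ADC, HBV, T2) intensities."""

    S: np.ndarray
    provenance: str = "roi_mean"

    def __post_init__(self) -> None:
        s = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", s)
        if s.shape != (3,) or not np.all(np.isfinite(s)):
            raise ValueError("signature must be a finite 3-vector")
        if self.provenance not in ("roi_mean", "automated", "manual"):
            raise ValueError(f"unknown signature provenance {self.provenance!r}")


@dataclass(frozen=True)
class ScoreMap:
    """3D lattice of ACE scores aligned to a RegisteredCube."""

    scores: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if scores.ndim != 3:
            raise ValueError(f"score map must be 3D, got {scores.ndim}D")
        if np.any((scores < -1e-9) | (scores > 1 + 1e-9)):
            raise ValueError("ACE scores must lie in [0, 1]")


def derive_signature(
    cube: RegisteredCube, seed_region: Iterable[tuple[int, int, int]]
) -> TumorSignature:
    """In-scene signature: mean spectrum over a seed region of voxel indices."""
    idx = [tuple(int(i) for i in v) for v in seed_region]
    if not idx:
        raise ValueError("seed region is empty")
    shape = cube.shape
    for v in idx:
        if any(not 0 <= i < n for i, n in zip(v, shape)):
            raise IndexError(f"seed voxel {v} outside grid {shape}")
    rows, cols, slcs = zip(*idx)
    spectra = cube.voxels[np.array(rows), np.array(cols), np.array(slcs), :]
    return TumorSignature(S=spectra.mean(axis=0), provenance="roi_mean")


def zscore(
    S: TumorSignature, stats: BackgroundStats
) -> tuple[np.ndarray, float]:
    """Per-band z-scores and their root-mean-square combined scalar.

    ``z_b = (S_b − m_b)/σ_b`` with σ the per-band background standard
    deviation.  The RMS reduction is sign-insensitive, as tumor contrast has
    opposite signs across bands (low ADC, high HBV, low T2).
    """
    if np.any(stats.sigma <= 0):
        raise DegenerateBackgroundError(
            "a background band has zero standard deviation"
        )
    per_band = (S.S - stats.m) / stats.sigma
    combined = float(np.sqrt(np.mean(per_band**2)))
    return per_band, combined


def scr(S: TumorSignature, stats: BackgroundStats) -> float:
    """Signal-to-clutter ratio: ``(S−m)ᵀ CM⁻¹ (S−m)``.

    Uses the covariance variant's effective (pseudo-)inverse; reported as
    the quadratic form itself, not its square root.
    """
    inv = stats.effective_inverse()
    if np.allclose(inv, 0.0):
        raise DegenerateBackgroundError("effective inverse covariance is zero")
    d = S.S - stats.m
    return float(d @ inv @ d)


def whiten(cube: RegisteredCube, stats: BackgroundStats) -> RegisteredCube:
    """Replace every voxel spectrum x by ``CM^(−1/2)(x − m)``.

    After whitening, background voxels are decorrelated with unit variance
    per band; requires a positive-definite covariance.
    """
    w = stats.inverse_sqrt()
    centered = cube.voxels - stats.m
    whitened = centered @ w.T  # symmetric w, but keep the convention explicit
    return RegisteredCube(voxels=whitened, spacing=cube.spacing, origin=cube.origin)


def ace_scores(
    spectra: np.ndarray, stats: BackgroundStats, S: TumorSignature
) -> np.ndarray:
    """ACE score for each row of an (n, 3) spectrum array.

    ``ACE(x) = [(x−m)ᵀCM⁻¹(S−m)]² / ([(x−m)ᵀCM⁻¹(x−m)]·[(S−m)ᵀCM⁻¹(S−m)])``

    Voxels with x = m (0/0) score 0 by convention.  Scores are clipped to
    [0, 1] against floating-point overshoot only.
    """
    inv = stats.effective_inverse()
    s_diff = S.S - stats.m
    s_quad = float(s_diff @ inv @ s_diff)
    if s_quad <= 0:
        raise DegenerateSignatureError(
            "signature equals the background mean (or lies in the removed subspace)"
        )
    d = np.asarray(spectra, dtype=float) - stats.m
    num = (d @ (inv @ s_diff)) ** 2
    den_x = np.einsum("ij,jk,ik->i", d, inv, d)
    out = np.zeros(d.shape[0])
    ok = den_x > 0
    out[ok] = num[ok] / (den_x[ok] * s_quad)
    return np.clip(out, 0.0, 1.0)


def ace_map(
    cube: RegisteredCube, stats: BackgroundStats, S: TumorSignature
) -> ScoreMap:
    """ACE detection map over a full cube."""
    flat = ace_scores(cube.spectra, stats, S)
    return ScoreMap(
        scores=flat.reshape(cube.shape), spacing=cube.spacing, origin=cube.origin
    )
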