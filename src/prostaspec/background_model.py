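"""Gaussian background model of normal prostate tissue.

Normal prostate voxels inside the outlined mask are modelled as draws from a
3-band Gaussian with mean spectrum ``m`` and covariance ``CM``.  Every
downstream detector statistic (z-score, SCR, ACE) is a function of ``m`` and
an *effective inverse* of ``CM``.  Because ``CM`` is estimated from a finite
(and sometimes small) sample, three conditioned variants are provided:

raw
    the unbiased sample covariance (n − 1 denominator);
pc_filtered
    the inverse restricted to the leading principal components — the noisy
    low-eigenvalue components are eliminated and the inverse becomes the
    eigen pseudo-inverse ``Σ_{i ≤ 3−k} λ_i⁻¹ v_i v_iᵀ``;
regularized / modified_regularized
    shrinkage toward a diagonal target, ``CM(γ) = (1−γ)·CM + γ·T`` with
    ``T = (trace(CM)/3)·I`` (regularized, trace-preserving) or
    ``T = diag(CM)`` (modified regularized).

The shrinkage weight γ can be selected by grid search minimizing the
leave-one-out Gaussian negative log-likelihood of the mask voxels, the
standard criterion of the regularized-discriminant literature.  Rank-one
downdate identities make the leave-one-out pass exact and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .registration import MIN_MASK_VOXELS, ProstateMask, RegisteredCube

__all__ = [
    "BackgroundStats",
    "SampleSizeError",
    "DegenerateFilterError",
    "GammaSelectionError",
    "compute_background_stats",
    "pc_filter",
    "shrink_covariance",
    "select_gamma",
    "DEFAULT_GAMMA_GRID",
]

#: Default grid-search candidates for the shrinkage weight.
DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))

_SINGULAR_RTOL = 1e-10


class SampleSizeError(ValueError):
    """Raised when too few mask voxels are available for estimation."""


class DegenerateFilterError(ValueError):
    """Raised when principal-component filtering would remove every component."""


class GammaSelectionError(RuntimeError):
    """Raised when no candidate shrinkage weight yields a usable covariance."""


def _eigh_descending(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eigvals, eigvecs = np.linalg.eigh(cm)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


@dataclass(frozen=True)
class BackgroundStats:
    """Normal-prostate background: mean spectrum, covariance, eigen-structure."""

    m: np.ndarray
    CM: np.ndarray
    sigma: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    n_voxels: int
    gamma: float = 0.0
    pcs_removed: int = 0
    variant: str = "raw"
    singular: bool = False

    def __post_init__(self) -> None:
        for name in ("m", "CM", "sigma", "eigvals", "eigvecs"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.CM.shape != (3, 3):
            raise ValueError(f"covariance must be 3×3, got {self.CM.shape}")
        if not np.allclose(self.CM, self.CM.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.pcs_removed not in (0, 1, 2):
            raise ValueError(f"pcs_removed must be 0–2, got {self.pcs_removed}")

    def effective_inverse(self) -> np.ndarray:
        """The (pseudo-)inverse covariance the detector statistics use.

        For pc_filtered stats this is the eigen pseudo-inverse over the
        retained subspace; otherwise the ordinary inverse of ``CM``.
        """
        if self.variant == "pc_filtered":
            keep = 3 - self.pcs_removed
            lam = self.eigvals[:keep]
            vecs = self.eigvecs[:, :keep]
            if np.any(lam <= 0):
                raise np.linalg.LinAlgError(
                    "retained principal components have non-positive variance"
                )
            return (vecs / lam) @ vecs.T
        return np.linalg.inv(self.CM)

    def inverse_sqrt(self) -> np.ndarray:
        """Symmetric inverse square root ``CM^(−1/2)`` (whitening matrix)."""
        lam, vecs = _eigh_descending(self.CM)
        if np.any(lam <= 0):
            raise np.linalg.LinAlgError(
                "covariance is not positive definite; whitening undefined"
            )
        return (vecs / np.sqrt(lam)) @ vecs.T


def _mask_spectra(cube: RegisteredCube, mask: ProstateMask) -> np.ndarray:
    mask.check_against(cube)
    return cube.voxels[mask.data]


def compute_background_stats(
    cube: RegisteredCube, mask: ProstateMask
) -> BackgroundStats:
    """Estimate mean and sample covariance over the masked voxels.

    Uses the unbiased (n − 1) covariance estimator.  A singular covariance is
    flagged, not fatal — shrinkage repairs it downstream.
    """
    x = _mask_spectra(cube, mask)
    return stats_from_spectra(x)


def stats_from_spectra(x: np.ndarray) -> BackgroundStats:
    """Background stats from an explicit (n, 3) spectrum sample."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < MIN_MASK_VOXELS:
        raise SampleSizeError(
            f"{n} mask voxels; at least {MIN_MASK_VOXELS} required for a "
            "stable covariance estimate"
        )
    m = x.mean(axis=0)
    cm = np.cov(x, rowvar=False, ddof=1)
    cm = (cm + cm.T) / 2.0
    eigvals, eigvecs = _eigh_descending(cm)
    singular = bool(eigvals[-1] <= _SINGULAR_RTOL * max(eigvals[0], 1.0))
    return BackgroundStats(
        m=m,
        CM=cm,
        sigma=np.sqrt(np.diag(cm)),
        eigvals=eigvals,
        eigvecs=eigvecs,
        n_voxels=n,
        singular=singular,
    )


def pc_filter(stats: BackgroundStats, n_remove: int) -> BackgroundStats:
    """Eliminate the ``n_remove`` lowest-eigenvalue principal components.

    The effective inverse becomes the pseudo-inverse built from the retained
    leading components.  ``n_remove`` must leave at least one component.
    """
    if stats.variant != "raw":
        raise ValueError("pc_filter applies to raw background stats only")
    if not 0 <= n_remove <= 2:
        if n_remove == 3:
            raise DegenerateFilterError("removing all 3 components leaves nothing")
        raise ValueError(f"n_remove must be 0–2, got {n_remove}")
    return replace(stats, variant="pc_filtered", pcs_removed=int(n_remove))


def _shrink_target(cm: np.ndarray, mode: str) -> np.ndarray:
    if mode == "regularized":
        return (np.trace(cm) / 3.0) * np.eye(3)
    if mode == "modified_regularized":
        return np.diag(np.diag(cm))
    raise ValueError(f"unknown shrinkage mode {mode!r}")


def shrink_covariance(
    stats: BackgroundStats, gamma: float, mode: str = "regularized"
) -> BackgroundStats:
    """Shrink the covariance toward a diagonal target with weight γ.

    ``CM(γ) = (1−γ)·CM + γ·T`` with ``T`` a scaled identity (mode
    ``regularized``, trace-preserving) or ``diag(CM)`` (mode
    ``modified_regularized``).  Positive definite whenever γ > 0 and the
    bands carry any variance.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if stats.variant != "raw":
        raise ValueError("shrink_covariance applies to raw background stats only")
    target = _shrink_target(stats.CM, mode)
    cm = (1.0 - gamma) * stats.CM + gamma * target
    eigvals, eigvecs = _eigh_descending(cm)
    return replace(
        stats,
        CM=cm,
        eigvals=eigvals,
        eigvecs=eigvecs,
        gamma=float(gamma),
        variant=mode,
        singular=bool(eigvals[-1] <= _SINGULAR_RTOL * max(eigvals[0], 1.0)),
    )


# --------------------------------------------------------------------------
# Shrinkage-weight selection


def _loo_nll(x: np.ndarray, gamma: float, mode: str) -> float:
    """Exact leave-one-out Gaussian NLL of the sample under CM(γ).

    Rank-one downdates give each held-out voxel's leave-one-out mean and
    covariance without refitting: with d_i = x_i − m,
    m_(−i) = m − d_i/(n−1) and S_(−i) = S − n/(n−1)·d_i d_iᵀ.
    """
    n = x.shape[0]
    m = x.mean(axis=0)
    d = x - m  # (n, 3)
    s_total = d.T @ d
    outer = d[:, :, None] * d[:, None, :]  # (n, 3, 3)
    s_loo = s_total[None] - (n / (n - 1.0)) * outer
    cm_loo = s_loo / (n - 2.0)
    if mode == "regularized":
        t_loo = (np.trace(cm_loo, axis1=1, axis2=2) / 3.0)[:, None, None] * np.eye(3)
    else:
        t_loo = np.zeros_like(cm_loo)
        diag = np.einsum("ijj->ij", cm_loo)
        np.einsum("ijj->ij", t_loo)[:] = diag
    cm_g = (1.0 - gamma) * cm_loo + gamma * t_loo
    sign, logdet = np.linalg.slogdet(cm_g)
    if np.any(sign <= 0):
        return np.inf
    inv = np.linalg.inv(cm_g)
    resid = d * (n / (n - 1.0))  # x_i − m_(−i)
    maha = np.einsum("ij,ijk,ik->i", resid, inv, resid)
    return float(0.5 * np.sum(logdet + maha))


def _insample_nll(x: np.ndarray, gamma: float, mode: str) -> float:
    """Plug-in Gaussian NLL of the sample under (m, CM(γ))."""
    n = x.shape[0]
    m = x.mean(axis=0)
    d = x - m
    cm = d.T @ d / max(n - 1, 1)
    cm_g = (1.0 - gamma) * cm + gamma * _shrink_target(cm, mode)
    sign, logdet = np.linalg.slogdet(cm_g)
    if sign <= 0:
        return np.inf
    inv = np.linalg.inv(cm_g)
    maha = np.einsum("ij,jk,ik->i", d, inv, d)
    return float(0.5 * (n * logdet + maha.sum()))


def select_gamma(
    cube_or_spectra,
    mask: Optional[ProstateMask] = None,
    mode: str = "regularized",
    grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> float:
    """Grid-search γ minimizing the leave-one-out NLL of the mask voxels.

    Deterministic given its inputs.  Accepts either (cube, mask) or an
    explicit (n, 3) spectrum array.  Candidates whose shrunk covariance is
    not positive definite score −∞ likelihood and are never selected.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("gamma grid must be non-empty")
    if any(not 0.0 <= g <= 1.0 for g in grid):
        raise ValueError("all gamma candidates must lie in [0, 1]")
    if mask is not None:
        x = _mask_spectra(cube_or_spectra, mask)
    else:
        x = np.asarray(cube_or_spectra, dtype=float)
    if len(grid) == 1:
        return grid[0]
    if x.shape[0] < 2:
        raise SampleSizeError("gamma selection needs at least 2 voxels")
    _shrink_target(np.eye(3), mode)  # validate mode early
    if x.shape[0] < 4:
        # Too few voxels for leave-one-out; score the in-sample NLL instead.
        # A singular sample covariance (e.g. n = 2) then forces gamma > 0.
        scores = {g: _insample_nll(x, g, mode) for g in grid}
    else:
        scores = {g: _loo_nll(x, g, mode) for g in grid}
    if all(np.isinf(v) for v in scores.values()):
        raise GammaSelectionError(
            "no candidate gamma yields a positive-definite covariance"
        )
    return min(sorted(scores), key=lambda g: scores[g])
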