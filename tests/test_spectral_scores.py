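"""z-score, SCR, whitening, and the adaptive cosine estimator."""

from dataclasses import replace

import numpy as np
import pytest

from prostaspec.background_model import pc_filter, stats_from_spectra
from prostaspec.registration import RegisteredCube
from prostaspec.spectral_scores import (
    DegenerateBackgroundError,
    DegenerateSignatureError,
    TumorSignature,
    ace_map,
    ace_scores,
    derive_signature,
    scr,
    whiten,
    zscore,
)


def stats_with(cm, m=(0.0, 0.0, 0.0)):
    """BackgroundStats carrying an exact, hand-chosen covariance."""
    rng = np.random.default_rng(0)
    base = stats_from_spectra(rng.standard_normal((50, 3)))
    cm = np.asarray(cm, dtype=float)
    ev, evec = np.linalg.eigh(cm)
    return replace(
        base,
        m=np.asarray(m, dtype=float),
        CM=cm,
        sigma=np.sqrt(np.diag(cm)),
        eigvals=ev[::-1],
        eigvecs=evec[:, ::-1],
        singular=bool(ev.min() <= 0),
    )


def test_derive_signature_mean_of_region(rng):
    voxels = np.zeros((3, 3, 3, 3))
    voxels[0, 0, 0] = [0.0, 0.0, 0.0]
    voxels[2, 2, 2] = [2.0, 2.0, 2.0]
    cube = RegisteredCube(voxels=voxels, spacing=(1, 1, 1))
    single = derive_signature(cube, [(2, 2, 2)])
    np.testing.assert_allclose(single.S, [2, 2, 2])
    pair = derive_signature(cube, [(0, 0, 0), (2, 2, 2)])
    np.testing.assert_allclose(pair.S, [1, 1, 1])
    with pytest.raises(ValueError):
        derive_signature(cube, [])
    with pytest.raises(IndexError):
        derive_signature(cube, [(5, 0, 0)])


def test_zscore_hand_cases_and_scaling():
    stats = stats_with(np.diag([1.0, 4.0, 1.0]), m=(2.0, 2.0, 2.0))
    per_band, combined = zscore(TumorSignature(S=np.array([4.0, 2.0, 2.0])), stats)
    np.testing.assert_allclose(per_band, [2.0, 0.0, 0.0])
    assert combined == pytest.approx(2.0 / np.sqrt(3.0))

    null_band, null_combined = zscore(TumorSignature(S=np.array([2.0, 2.0, 2.0])), stats)
    np.testing.assert_allclose(null_band, 0.0)
    assert null_combined == 0.0

    # Doubling every σ halves every z.
    doubled = stats_with(np.diag([4.0, 16.0, 4.0]), m=(2.0, 2.0, 2.0))
    per2, comb2 = zscore(TumorSignature(S=np.array([4.0, 2.0, 2.0])), doubled)
    np.testing.assert_allclose(per2, per_band / 2.0)
    assert comb2 == pytest.approx(combined / 2.0)

    degenerate = stats_with(np.diag([0.0, 1.0, 1.0]))
    with pytest.raises(DegenerateBackgroundError):
        zscore(TumorSignature(S=np.array([1.0, 0.0, 0.0])), degenerate)


def test_scr_hand_cases_and_cofactor_oracle():
    identity = stats_with(np.eye(3))
    assert scr(TumorSignature(S=np.array([1.0, 1.0, 1.0])), identity) == pytest.approx(3.0)

    diag = stats_with(np.diag([4.0, 1.0, 1.0]))
    assert scr(TumorSignature(S=np.array([2.0, 0.0, 0.0])), diag) == pytest.approx(1.0)

    cm = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 1.0]])
    d = np.array([1.0, 1.0, 0.0])
    # Explicit cofactor inverse of the 3×3 matrix as an independent oracle.
    det = np.linalg.det(cm)
    cof = np.array(
        [
            [
                cm[1, 1] * cm[2, 2] - cm[1, 2] * cm[2, 1],
                -(cm[0, 1] * cm[2, 2] - cm[0, 2] * cm[2, 1]),
                cm[0, 1] * cm[1, 2] - cm[0, 2] * cm[1, 1],
            ],
            [
                -(cm[1, 0] * cm[2, 2] - cm[1, 2] * cm[2, 0]),
                cm[0, 0] * cm[2, 2] - cm[0, 2] * cm[2, 0],
                -(cm[0, 0] * cm[1, 2] - cm[0, 2] * cm[1, 0]),
            ],
            [
                cm[1, 0] * cm[2, 1] - cm[1, 1] * cm[2, 0],
                -(cm[0, 0] * cm[2, 1] - cm[0, 1] * cm[2, 0]),
                cm[0, 0] * cm[1, 1] - cm[0, 1] * cm[1, 0],
            ],
        ]
    )
    oracle = float(d @ (cof / det) @ d)
    assert scr(TumorSignature(S=d), stats_with(cm)) == pytest.approx(oracle, rel=1e-12)


def test_scr_affine_invariance_under_band_remixing(rng):
    """SCR is unchanged by any invertible linear remixing of the bands."""
    x = rng.standard_normal((500, 3)) @ np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 0.7]])
    stats = stats_from_spectra(x)
    sig = TumorSignature(S=stats.m + np.array([1.0, -2.0, 0.5]))
    base = scr(sig, stats)
    for _ in range(5):
        a = rng.standard_normal((3, 3))
        while abs(np.linalg.det(a)) < 0.1:
            a = rng.standard_normal((3, 3))
        mixed = stats_from_spectra(x @ a.T)
        mixed_sig = TumorSignature(S=a @ sig.S)
        assert scr(mixed_sig, mixed) == pytest.approx(base, rel=1e-8)


def test_scr_zscore_consistency_for_isotropic_covariance():
    """With CM = σ²I the SCR equals the sum of squared per-band z-scores."""
    sigma2 = 2.5
    stats = stats_with(np.eye(3) * sigma2, m=(1.0, 1.0, 1.0))
    sig = TumorSignature(S=np.array([2.0, 0.0, 3.0]))
    per_band, _ = zscore(sig, stats)
    assert scr(sig, stats) == pytest.approx(float(np.sum(per_band**2)), rel=1e-12)


def test_whiten_centering_diagonal_case_and_simulation(rng):
    stats = stats_with(np.diag([4.0, 1.0, 1.0]), m=(1.0, 2.0, 3.0))
    voxels = np.zeros((1, 1, 2, 3))
    voxels[0, 0, 0] = [1.0, 2.0, 3.0]  # x = m
    voxels[0, 0, 1] = [3.0, 3.0, 4.0]  # x − m = (2, 1, 1)
    cube = RegisteredCube(voxels=voxels, spacing=(1, 1, 1))
    white = whiten(cube, stats)
    np.testing.assert_allclose(white.voxels[0, 0, 0], 0.0, atol=1e-12)
    np.testing.assert_allclose(white.voxels[0, 0, 1], [1.0, 1.0, 1.0], atol=1e-12)

    true_cov = np.array([[3.0, 1.0, 0.4], [1.0, 2.0, -0.2], [0.4, -0.2, 1.5]])
    x = rng.standard_normal((100_000, 3)) @ np.linalg.cholesky(true_cov).T + 7.0
    stats_big = stats_from_spectra(x)
    cube_big = RegisteredCube(
        voxels=x.reshape(100, 100, 10, 3), spacing=(1, 1, 1)
    )
    white_big = whiten(cube_big, stats_big)
    sample_cov = np.cov(white_big.spectra, rowvar=False)
    assert np.max(np.abs(sample_cov - np.eye(3))) < 0.02


def test_ace_cone_geometry():
    """Signature voxel scores 1, orthogonal scores 0, 45° scores cos²45 = 0.5."""
    stats = stats_with(np.eye(3))
    sig = TumorSignature(S=np.array([1.0, 0.0, 0.0]))
    x = np.array(
        [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 0.0]]
    )
    scores = ace_scores(x, stats, sig)
    np.testing.assert_allclose(scores, [1.0, 0.0, 0.5, 0.0], atol=1e-12)

    with pytest.raises(DegenerateSignatureError):
        ace_scores(x, stats, TumorSignature(S=np.zeros(3) + stats.m))


def test_ace_scale_invariance_and_unit_bound(rng):
    """ACE is invariant under positive rescaling of x−m and S−m, and ≤ 1."""
    for _ in range(20):
        cm = rng.standard_normal((3, 3))
        cm = cm @ cm.T + 0.5 * np.eye(3)
        m = rng.standard_normal(3)
        stats = stats_with(cm, m=m)
        s = TumorSignature(S=m + rng.standard_normal(3))
        x = m + rng.standard_normal((10, 3))
        base = ace_scores(x, stats, s)
        assert np.all(base <= 1.0 + 1e-12) and np.all(base >= 0.0)
        for a in (0.1, 3.0):
            scaled = ace_scores(m + a * (x - m), stats, s)
            np.testing.assert_allclose(scaled, base, atol=1e-9)
        s_scaled = TumorSignature(S=m + 2.5 * (s.S - m))
        np.testing.assert_allclose(ace_scores(x, stats, s_scaled), base, atol=1e-9)


def test_ace_unity_iff_whitened_parallel(rng):
    """Score is exactly 1 when the whitened voxel is parallel to the whitened signature."""
    cm = np.array([[2.0, 0.7, 0.1], [0.7, 1.5, -0.2], [0.1, -0.2, 1.0]])
    m = np.array([5.0, 1.0, 2.0])
    stats = stats_with(cm, m=m)
    s = TumorSignature(S=m + np.array([1.0, 2.0, -1.0]))
    # A voxel displaced along S − m (any positive multiple) is whitened-parallel.
    x = (m + 0.37 * (s.S - m))[None, :]
    assert ace_scores(x, stats, s)[0] == pytest.approx(1.0, abs=1e-12)


def test_ace_map_respects_pc_filtered_inverse(rng):
    """The detection map uses the same covariance variant as the SCR."""
    x = rng.standard_normal((2000, 3)) * np.array([3.0, 1.0, 0.2])
    stats = stats_from_spectra(x)
    filtered = pc_filter(stats, 1)
    cube = RegisteredCube(voxels=x[:1000].reshape(10, 10, 10, 3), spacing=(1, 1, 1))
    sig = TumorSignature(S=stats.m + np.array([3.0, 1.0, 0.0]))
    smap = ace_map(cube, filtered, sig)
    assert smap.scores.shape == (10, 10, 10)
    assert np.all((smap.scores >= 0) & (smap.scores <= 1))
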