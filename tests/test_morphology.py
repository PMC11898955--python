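"""Thresholding, blob labeling, volume, eccentricity, feature aggregation."""

import numpy as np
import pytest

from prostaspec.io_formats import CohortRecord
from prostaspec.morphology import (
    Blob,
    blob_eccentricity,
    blob_volume,
    features_from_detection_map,
    label_blobs,
    measure_blobs,
    patient_features,
    threshold_map,
)


def flood_fill_oracle(mask, connectivity=26):
    """Brute-force BFS connected components, independent of skimage."""
    mask = np.asarray(mask, dtype=bool)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and {6: abs(i) + abs(j) + abs(k) == 1,
             18: abs(i) + abs(j) + abs(k) <= 2,
             26: True}[connectivity]
    ]
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        queue, comp = [start], []
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= c < n for c, n in zip(w, mask.shape)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.append(frozenset(comp))
    return set(components)


def ball_mask(radius, shape=None):
    shape = shape or (2 * radius + 3,) * 3
    center = [(n - 1) / 2 for n in shape]
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2


def test_threshold_boundary_inclusive_and_degenerate():
    scores = np.array([[[0.95, 0.5, 0.9]]])
    np.testing.assert_array_equal(threshold_map(scores, 0.9), [[[True, False, True]]])
    assert not threshold_map(scores, 0.99).any()
    assert threshold_map(scores, 0.0).all()
    with pytest.raises(ValueError):
        threshold_map(scores, 1.5)


def test_two_clusters_and_corner_connectivity():
    mask = np.zeros((10, 10, 3), dtype=bool)
    mask[0:2, 0:2, 0:2] = True  # 8 voxels
    mask[0:2, 5:7, 0:2] = True  # 8 voxels, 3-column gap
    blobs = label_blobs(mask, min_size=5)
    assert [b.size for b in blobs] == [8, 8]

    corner = np.zeros((4, 4, 4), dtype=bool)
    corner[0, 0, 0] = corner[1, 1, 1] = True
    assert len(label_blobs(corner, min_size=1, connectivity=26)) == 1
    assert len(label_blobs(corner, min_size=1, connectivity=6)) == 2


def test_min_size_filter_semantics():
    """Clusters of 3 and 6 voxels with the 5-voxel floor: only the 6 survives."""
    mask = np.zeros((12, 12, 1), dtype=bool)
    mask[0, 0:3, 0] = True
    mask[5, 0:6, 0] = True
    blobs = label_blobs(mask, min_size=5)
    assert len(blobs) == 1 and blobs[0].size == 6
    assert label_blobs(np.zeros((4, 4, 4), dtype=bool)) == []


def test_labeling_matches_flood_fill_oracle(rng):
    """Partitions agree with a brute-force BFS on random 20³ masks."""
    for density in (0.05, 0.2, 0.5):
        for _ in range(4):
            mask = rng.random((20, 20, 20)) < density
            blobs = label_blobs(mask, min_size=1)
            ours = {frozenset(map(tuple, b.voxel_ids)) for b in blobs}
            assert ours == flood_fill_oracle(mask)
            # Partition property: sizes sum to the foreground count.
            assert sum(b.size for b in blobs) == int(mask.sum())


def test_blob_volume_unit_conversion():
    blob = Blob(label=1, voxel_ids=np.zeros((5, 3), dtype=int), size=5)
    assert blob_volume(blob, (2.0, 2.0, 0.5)) == pytest.approx(0.01)
    one = Blob(label=1, voxel_ids=np.zeros((1, 3), dtype=int), size=1)
    assert blob_volume(one, (1.0, 1.0, 1.0)) == pytest.approx(0.001)
    kilo = Blob(label=1, voxel_ids=np.zeros((1000, 3), dtype=int), size=1000)
    assert blob_volume(kilo, (1.0, 1.0, 1.0)) == pytest.approx(1.0)


def test_eccentricity_endpoints_and_ellipsoid():
    ball = ball_mask(7)
    [blob] = label_blobs(ball, min_size=1)
    assert abs(blob_eccentricity(blob, (1.0, 1.0, 1.0))) < 1e-6

    line = np.zeros((1, 1, 20), dtype=bool)
    line[0, 0, :] = True
    [seg] = label_blobs(line, min_size=1)
    assert blob_eccentricity(seg, (1.0, 1.0, 1.0)) == pytest.approx(1.0)

    # Solid 20:10:10 ellipsoid: eccentricity (l − s)/l = 0.5 in the continuum.
    grids = np.meshgrid(*[np.arange(n) for n in (45, 25, 25)], indexing="ij")
    center = (22.0, 12.0, 12.0)
    ell = (
        ((grids[0] - center[0]) / 20.0) ** 2
        + ((grids[1] - center[1]) / 10.0) ** 2
        + ((grids[2] - center[2]) / 10.0) ** 2
    ) <= 1.0
    [eblob] = label_blobs(ell, min_size=1)
    assert blob_eccentricity(eblob, (1.0, 1.0, 1.0)) == pytest.approx(0.5, abs=0.02)

    single = Blob(label=1, voxel_ids=np.zeros((1, 3), dtype=int), size=1)
    assert np.isnan(blob_eccentricity(single, (1.0, 1.0, 1.0)))


def test_eccentricity_lattice_symmetry_and_spacing_invariance(rng):
    """E is exact under 90° rotations/reflections and isotropic rescaling."""
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[2:9, 3:6, 4:6] = True
    [blob] = label_blobs(mask, min_size=1)
    base = blob_eccentricity(blob, (1.0, 1.0, 1.0))
    for axes in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
        rotated = np.transpose(mask, axes)
        [rblob] = label_blobs(rotated, min_size=1)
        assert blob_eccentricity(rblob, (1.0, 1.0, 1.0)) == pytest.approx(base, abs=1e-12)
    flipped = mask[::-1].copy()
    [fblob] = label_blobs(flipped, min_size=1)
    assert blob_eccentricity(fblob, (1.0, 1.0, 1.0)) == pytest.approx(base, abs=1e-12)
    for scale in (0.5, 2.0, 3.7):
        assert blob_eccentricity(blob, (scale,) * 3) == pytest.approx(base, rel=1e-9)


def test_patient_feature_aggregation_hand_case():
    """Two blobs (1 mL, E=0.2) and (3 mL, E=0.6): all aggregates by hand."""
    b1 = Blob(label=1, voxel_ids=np.zeros((100, 3), dtype=int), size=100,
              volume=1.0, E_k=0.2)
    b2 = Blob(label=2, voxel_ids=np.zeros((300, 3), dtype=int), size=300,
              volume=3.0, E_k=0.6)
    rec = CohortRecord(patient_id="p", isup=3)
    feats = patient_features([b1, b2], scr=10.0, zscore=2.0, outcome=rec)
    assert feats.n_blobs == 2
    assert feats.max_blob_volume == pytest.approx(3.0)
    assert feats.avg_blob_volume == pytest.approx(2.0)
    assert feats.total_volume == pytest.approx(4.0)
    assert feats.ecc_largest == pytest.approx(0.6)
    assert feats.ecc_avg == pytest.approx(0.4)
    assert feats.ecc_weighted == pytest.approx(0.5)
    assert feats.cspca is True

    empty = patient_features([], scr=0.0, zscore=0.0, outcome=rec)
    assert empty.n_blobs == 0 and empty.total_volume == 0.0
    assert np.isnan(empty.ecc_largest) and np.isnan(empty.ecc_avg)

    solo = patient_features([b2], scr=0.0, zscore=0.0, outcome=rec)
    assert solo.ecc_largest == solo.ecc_avg == solo.ecc_weighted == pytest.approx(0.6)


def test_detection_map_chain_matches_spectral_path(rng):
    """The AI-map chain is the identical threshold→label→measure pipeline."""
    scores = rng.random((15, 15, 8))
    scores[2:6, 2:6, 2:5] = 0.97
    spacing = (2.0, 2.0, 3.0)
    via_map = features_from_detection_map(scores, spacing, tau=0.9, min_size=5)
    mask = threshold_map(scores, 0.9)
    blobs = measure_blobs(label_blobs(mask, 5), spacing)
    rec = CohortRecord(patient_id="x", isup=0)
    direct = patient_features(blobs, scr=0.0, zscore=0.0, outcome=rec)
    assert via_map["n_blobs"] == direct.n_blobs
    assert via_map["total_volume"] == pytest.approx(direct.total_volume)
    assert via_map["ecc_largest"] == pytest.approx(direct.ecc_largest, nan_ok=True)

    zeros = features_from_detection_map(np.zeros((5, 5, 5)), spacing)
    assert zeros["n_blobs"] == 0 and np.isnan(zeros["ecc_largest"])


def test_planted_ellipsoid_detection_count():
    """A planted 100-voxel blob in an otherwise empty map yields one blob of 100."""
    detection = np.zeros((20, 20, 10))
    grids = np.meshgrid(np.arange(20), np.arange(20), np.arange(10), indexing="ij")
    region = (
        ((grids[0] - 10) / 4.0) ** 2
        + ((grids[1] - 10) / 3.0) ** 2
        + ((grids[2] - 5) / 2.0) ** 2
    ) <= 1.0
    detection[region] = 0.95
    n_planted = int(region.sum())
    feats = features_from_detection_map(detection, (1.0, 1.0, 1.0), tau=0.9)
    assert feats["n_blobs"] == 1
    assert feats["total_volume"] == pytest.approx(n_planted / 1000.0)
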