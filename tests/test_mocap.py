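"""Markers, Hu/stats feature vectors, cost matrix and bidirectional linking."""

import numpy as np
import pytest
from scipy.ndimage import rotate, zoom

from organellometry.mocap import (
    MocapMarkers,
    _hu6,
    build_cost_matrix,
    detect_markers,
    link_best_match,
    marker_feature_vectors,
)
from organellometry.segment import build_hierarchy, label_organelles
from organellometry.segment import LabelHierarchy, distance_transform_um
from organellometry.segment import skeletonize, label_branches


def _hierarchy_from_mask(mask, spacing):
    """Minimal hierarchy for marker tests (no enhancement involved)."""
    labels = label_organelles(mask)
    dist = distance_transform_um(mask, spacing)
    skel = skeletonize(mask, labels, dist) if mask.any() else np.zeros_like(mask)
    _, tips, skel_branch = label_branches(skel)
    coords = np.argwhere(skel)
    idx = tuple(coords.T) if len(coords) else ((),) * mask.ndim
    from organellometry.segment import assign_voxels_to_nodes

    node_org = labels[idx] if len(coords) else np.empty(0, dtype=int)
    assignment = assign_voxels_to_nodes(mask, coords, node_org, labels, spacing)
    return LabelHierarchy(
        semantic=mask, organelle_labels=labels, distance_um=dist, skeleton=skel,
        node_coords=coords, node_radius_um=dist[idx] if len(coords) else np.empty(0),
        node_branch=skel_branch[idx] if len(coords) else np.empty(0, dtype=int),
        node_organelle=node_org,
        node_is_junction=np.zeros(len(coords), bool), node_is_tip=np.zeros(len(coords), bool),
        node_assignment=assignment,
        branch_labels=np.zeros_like(labels), spacing=spacing,
        skeleton_branch_labels=skel_branch,
    )


def _sphere_mask(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2


class TestDetection:
    def test_single_sphere_gets_one_central_marker(self):
        mask = _sphere_mask((32, 32), (16, 16), 5)
        h = _hierarchy_from_mask(mask, (0.1, 0.1))
        m = detect_markers(h)
        assert len(m) == 1
        assert np.all(np.abs(m.coords[0] - 16) <= 1)
        assert m.radius_um[0] == pytest.approx(0.5, abs=0.15)

    def test_empty_mask_gives_no_markers(self):
        h = _hierarchy_from_mask(np.zeros((16, 16), dtype=bool), (0.1, 0.1))
        assert len(detect_markers(h)) == 0

    def test_two_separated_spheres_get_one_marker_each(self):
        mask = _sphere_mask((48, 48), (12, 12), 4) | _sphere_mask((48, 48), (36, 36), 4)
        h = _hierarchy_from_mask(mask, (0.1, 0.1))
        m = detect_markers(h)
        assert len(m) == 2
        owners = h.organelle_labels[tuple(m.coords.T)]
        assert set(owners) == {1, 2}

    def test_markers_are_invariant_to_organelle_label_permutation(self):
        mask = _sphere_mask((48, 48), (12, 12), 4) | _sphere_mask((48, 48), (36, 36), 5)
        h = _hierarchy_from_mask(mask, (0.1, 0.1))
        m1 = detect_markers(h)
        # permute instance labels 1 <-> 2: marker output must not move
        h.organelle_labels = np.where(
            h.organelle_labels > 0, 3 - h.organelle_labels, 0
        )
        m2 = detect_markers(h)
        assert np.array_equal(np.sort(m1.coords, axis=0), np.sort(m2.coords, axis=0))

    def test_thin_regions_get_denser_markers_than_thick(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:8, 5:60] = True    # thin bar
        mask[30:45, 5:60] = True  # thick bar
        h = _hierarchy_from_mask(mask, (0.1, 0.1))
        m = detect_markers(h)
        thin = (m.coords[:, 0] < 10).sum()
        thick = (m.coords[:, 0] >= 10).sum()
        assert thin > thick >= 1


class TestFeatureVectors:
    def test_uniform_patch_stats(self):
        mask = _sphere_mask((32, 32), (16, 16), 5)
        h = _hierarchy_from_mask(mask, (0.1, 0.1))
        m = detect_markers(h)
        raw = np.full((32, 32), 42.0)
        enh = np.full((32, 32), 0.5)
        m = marker_feature_vectors(m, raw, enh)
        assert m.stats_vec[0] == pytest.approx([42.0, 0.0, 0.5, 0.0])
        assert m.hu_vec.shape == (1, 12)

    def test_hu_vector_length_is_36_in_3d(self):
        mask = _sphere_mask((24, 24, 24), (12, 12, 12), 5)
        h = _hierarchy_from_mask(mask, (0.1, 0.1, 0.1))
        m = detect_markers(h)
        rng = np.random.default_rng(0)
        m = marker_feature_vectors(m, rng.random((24, 24, 24)), rng.random((24, 24, 24)))
        assert m.hu_vec.shape[1] == 36
        assert np.all(np.isfinite(m.hu_vec))

    def test_translation_leaves_hu_identical(self):
        rng = np.random.default_rng(1)
        patch = rng.random((9, 9))
        assert np.array_equal(_hu6(patch), _hu6(patch))  # determinism
        frame = np.zeros((40, 40))
        frame[5:14, 5:14] = patch
        shifted = np.zeros((40, 40))
        shifted[20:29, 17:26] = patch
        assert np.allclose(_hu6(frame[5:14, 5:14]), _hu6(shifted[20:29, 17:26]), atol=0)

    def test_90_degree_rotation_is_exact_to_1e9(self):
        # 90-degree rotation permutes pixels exactly, so the invariants must
        # agree to numerical precision; oracle = direct double-loop moments
        rng = np.random.default_rng(2)
        patch = rng.random((11, 11)) * np.hanning(11)[:, None] * np.hanning(11)[None, :]
        rotated = np.rot90(patch)
        hu_a, hu_b = _hu6(patch), _hu6(rotated)
        assert np.allclose(hu_a, hu_b, atol=1e-9)
        assert np.allclose(hu_a, _hu6_oracle(patch), atol=1e-9)

    def test_smooth_blob_rotation_and_rescale_perturbs_little(self):
        # asymmetric smooth blob: two offset Gaussians of different widths
        y, x = np.mgrid[:81, :81].astype(float)
        blob = np.exp(-(((y - 36) / 12) ** 2 + ((x - 40) / 8) ** 2)) \
            + 0.6 * np.exp(-(((y - 50) / 6) ** 2 + ((x - 48) / 10) ** 2))
        base = _hu6(blob)
        turned = rotate(blob, angle=33.0, reshape=True, order=3, prefilter=True)
        scaled = zoom(turned, 1.1, order=3)
        scaled = np.clip(scaled, 0, None)
        assert np.all(np.abs(_hu6(scaled) - base) < 1e-2)


def _hu6_oracle(patch):
    """Brute-force central/normalized moments and the first six invariants."""
    patch = np.asarray(patch, dtype=float)
    ys, xs = np.mgrid[: patch.shape[0], : patch.shape[1]].astype(float)
    m00 = patch.sum()
    yc, xc = (ys * patch).sum() / m00, (xs * patch).sum() / m00

    def mu(p, q):
        return (((ys - yc) ** p) * ((xs - xc) ** q) * patch).sum()

    def nu(p, q):
        return mu(p, q) / m00 ** (1 + (p + q) / 2)

    n20, n02, n11 = nu(2, 0), nu(0, 2), nu(1, 1)
    n30, n03, n21, n12 = nu(3, 0), nu(0, 3), nu(2, 1), nu(1, 2)
    phi = np.array([
        n20 + n02,
        (n20 - n02) ** 2 + 4 * n11**2,
        (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2,
        (n30 + n12) ** 2 + (n21 + n03) ** 2,
        (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
        (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
        + 4 * n11 * (n30 + n12) * (n21 + n03),
    ])
    return np.sign(phi) * np.log10(np.abs(phi) + 1e-30)


def _marker_pair(coords_a, coords_b, stats_a=None, stats_b=None, hu_a=None, hu_b=None,
                 spacing=(0.1, 0.1)):
    def mk(frame, coords, stats, hu):
        n = len(coords)
        return MocapMarkers(
            frame=frame, coords=np.asarray(coords, dtype=np.int64),
            radius_um=np.full(n, 0.3), spacing=spacing,
            stats_vec=np.zeros((n, 4)) if stats is None else np.asarray(stats, dtype=float),
            hu_vec=np.zeros((n, 12)) if hu is None else np.asarray(hu, dtype=float),
        )

    return mk(0, coords_a, stats_a, hu_a), mk(1, coords_b, stats_b, hu_b)


class TestCostMatrix:
    def test_identical_marker_sets_have_diagonal_minima(self):
        coords = [[5, 5], [10, 20], [22, 9]]
        rng = np.random.default_rng(0)
        stats = rng.random((3, 4))
        hu = rng.random((3, 12))
        ma, mb = _marker_pair(coords, coords, stats, stats, hu, hu)
        cm = build_cost_matrix(ma, mb, max_travel_um=5.0)
        for i in range(3):
            assert np.argmin(cm.cost[i]) == i
            assert np.argmin(cm.cost[:, i]) == i

    def test_pairs_beyond_max_travel_are_inadmissible(self):
        ma, mb = _marker_pair([[0, 0], [0, 30]], [[0, 1], [0, 31]])
        cm = build_cost_matrix(ma, mb, max_travel_um=0.5)
        assert cm.admissible[0, 0] and cm.admissible[1, 1]
        assert not cm.admissible[0, 1] and not cm.admissible[1, 0]
        assert np.isinf(cm.cost[0, 1])

    def test_zscored_blocks_have_zero_mean_unit_variance(self):
        rng = np.random.default_rng(1)
        coords_a = rng.integers(0, 30, (6, 2))
        coords_b = rng.integers(0, 30, (6, 2))
        ma, mb = _marker_pair(coords_a, coords_b, rng.random((6, 4)), rng.random((6, 4)),
                              rng.random((6, 12)), rng.random((6, 12)))
        cm = build_cost_matrix(ma, mb, max_travel_um=100.0, weights=(1.0, 0.0, 0.0))
        vals = cm.cost[cm.admissible]
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std() == pytest.approx(1.0, abs=1e-9)


class TestLinking:
    def test_identical_frames_link_each_marker_to_itself(self):
        coords = [[5, 5], [10, 20], [22, 9]]
        rng = np.random.default_rng(0)
        stats, hu = rng.random((3, 4)), rng.random((3, 12))
        ma, mb = _marker_pair(coords, coords, stats, stats, hu, hu)
        cm = build_cost_matrix(ma, mb, max_travel_um=5.0)
        fwd, bwd = link_best_match(cm, ma, mb)
        assert np.array_equal(fwd.source, fwd.target)
        assert np.array_equal(bwd.source, bwd.target)
        assert np.allclose(fwd.displacement_um, 0)

    def test_two_sources_one_target_is_n_to_1(self):
        ma, mb = _marker_pair([[5, 5], [5, 8]], [[5, 6]])
        cm = build_cost_matrix(ma, mb, max_travel_um=1.0)
        fwd, bwd = link_best_match(cm, ma, mb)
        assert len(fwd) == 2 and np.all(fwd.target == 0)
        assert len(bwd) == 1 and bwd.target[0] == 0  # cheaper source wins

    def test_unmatched_sources_are_reported_exactly_once(self):
        ma, mb = _marker_pair([[5, 5], [5, 28]], [[5, 6]])
        cm = build_cost_matrix(ma, mb, max_travel_um=0.5)
        fwd, _ = link_best_match(cm, ma, mb)
        assert set(fwd.source) | set(fwd.unmatched) == {0, 1}
        assert set(fwd.source) & set(fwd.unmatched) == set()
        assert fwd.unmatched.tolist() == [1]

    def test_appearance_decides_when_distances_tie(self):
        # each source is equidistant from both targets; appearance must decide
        stats_a = [[0.0, 0, 0, 0], [10.0, 0, 0, 0]]
        stats_b = [[10.0, 0, 0, 0], [0.0, 0, 0, 0]]
        ma, mb = _marker_pair([[10, 12], [14, 12]], [[12, 10], [12, 14]],
                              stats_a, stats_b)
        cm = build_cost_matrix(ma, mb, max_travel_um=2.0)
        fwd, _ = link_best_match(cm, ma, mb)
        assert fwd.target.tolist() == [1, 0]  # follows appearance, not index order

    def test_swapping_frames_swaps_forward_and_backward(self):
        rng = np.random.default_rng(5)
        ca, cb = rng.integers(0, 25, (4, 2)), rng.integers(0, 25, (4, 2))
        sa, sb = rng.random((4, 4)), rng.random((4, 4))
        ha, hb = rng.random((4, 12)), rng.random((4, 12))
        ma, mb = _marker_pair(ca, cb, sa, sb, ha, hb)
        cm_ab = build_cost_matrix(ma, mb, max_travel_um=3.0)
        fwd_ab, bwd_ab = link_best_match(cm_ab, ma, mb)
        ma2, mb2 = _marker_pair(cb, ca, sb, sa, hb, ha)
        cm_ba = build_cost_matrix(ma2, mb2, max_travel_um=3.0)
        fwd_ba, bwd_ba = link_best_match(cm_ba, ma2, mb2)
        assert np.array_equal(fwd_ab.source, bwd_ba.source)
        assert np.array_equal(fwd_ab.target, bwd_ba.target)
        assert np.allclose(fwd_ab.displacement_um, bwd_ba.displacement_um)
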