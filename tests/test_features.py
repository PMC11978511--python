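"""Multilevel features: kinematics recovery, closed-form morphology, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from organellometry import features as feat
from organellometry.flow import FlowInterpolator
from organellometry.mocap import LinkageSet, MocapMarkers
from organellometry.pipeline import analyze_stack
from organellometry.synthgen import (
    SceneObject,
    SceneSpec,
    build_scene,
    render_timelapse,
)

S = 0.15


def _analyze(spec):
    gt = build_scene(spec)
    stack = render_timelapse(gt)
    return gt, analyze_stack(stack)


class TestVoxelMotility:
    def test_static_scene_motility_is_zero(self, static_result):
        _, res = static_result
        vdf = res.tables["voxel"]
        mid = vdf[vdf.frame == 1]
        for col in ("lin_vel_mag_01", "lin_vel_mag_12", "lin_acc_mag",
                    "ref_lin_vel_mag_12", "rel_lin_vel_mag_12"):
            assert np.nanmax(np.abs(mid[col])) < 1e-6, col

    def test_uniform_translation_speed_recovered(self, blob_field_result):
        spec, gt, res = blob_field_result
        # drift 0.5 vox/frame = 0.075 um/frame at 1 s/frame; mean over all
        # frame pairs averages out per-frame centroid wobble
        vdf = res.tables["voxel"]
        speed = np.nanmean(vdf["lin_vel_mag_12"])
        assert speed == pytest.approx(0.5 * S, rel=0.10)

    def test_rotation_angular_rate_recovered(self):
        omega = 0.05
        rod = SceneObject(
            "tube", {"p1": (60 * S, 40 * S), "p2": (60 * S, 80 * S), "radius": 3 * S},
            100.0, rotation_rad=omega, pivot_um=(60 * S, 60 * S),
            texture_amp=0.3, texture_wavelength_um=2.5,
        )
        spec = SceneSpec(shape=(4, 120, 120), spacing=(S, S), objects=[rod],
                         psf_sigma_um=S, poisson=True, gaussian_sd=1.0,
                         background=10.0, seed=0)
        _, res = _analyze(spec)
        vdf = res.tables["voxel"]
        mid = vdf[vdf.frame == 1]
        got = np.nanmedian(mid["rel_ang_vel_mag_12"])
        assert got == pytest.approx(omega, rel=0.15)

    def test_motility_columns_nan_only_at_boundary_frames(self, blob_field_result):
        _, _, res = blob_field_result
        vdf = res.tables["voxel"]
        first = vdf[vdf.frame == 0]
        assert first["lin_vel_mag_01"].isna().all()
        assert first["lin_vel_mag_12"].notna().all()
        last = vdf[vdf.frame == vdf.frame.max()]
        assert last["lin_vel_mag_12"].isna().all()
        mid = vdf[(vdf.frame > 0) & (vdf.frame < vdf.frame.max())]
        assert mid["lin_acc_mag"].notna().all()


def _uniform_interp(markers_coords, vector_um, spacing=(S, S), max_travel=5.0):
    coords = np.asarray(markers_coords, dtype=np.int64)
    n = len(coords)
    markers = MocapMarkers(frame=0, coords=coords, radius_um=np.full(n, 0.5),
                           spacing=spacing)
    links = LinkageSet(direction="forward", frame_pair=(0, 1),
                       source=np.arange(n), target=np.arange(n),
                       cost=np.zeros(n),
                       displacement_um=np.tile(np.asarray(vector_um, dtype=float), (n, 1)),
                       unmatched=np.empty(0, dtype=np.int64))
    return FlowInterpolator(links, markers, max_travel_um=max_travel)


class TestNodeFeatures:
    def test_thickness_tracks_tube_radius(self, tube_blob_result):
        _, res = tube_blob_result
        ndf = res.tables["node"]
        h = res.hierarchies[0]
        # the thick tube sits at row ~120; its nodes should read ~2x6 voxels
        f0 = ndf[ndf.frame == 0]
        thick = f0[[h.node_coords[i][0] > 105 for i in f0.node_id]]
        interior = thick[(thick.is_tip == False)]  # noqa: E712
        assert np.median(interior["thickness_um"]) == pytest.approx(2 * 6 * S, rel=0.35)

    def test_uniform_flow_has_zero_vergence(self, static_result):
        _, res = static_result
        ndf = res.tables["node"]
        f0 = ndf[ndf.frame == 0]
        assert np.nanmax(np.abs(f0["vergence"])) < 1e-3

    def test_radially_expanding_field_reads_positive_rate(self):
        # constructed linear field v(p) = k (p - c): markers on a dense grid
        # through the disc so interpolation reproduces the field
        mask = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[:40, :40]
        mask[(yy - 20) ** 2 + (xx - 20) ** 2 <= 12**2] = True
        k = 0.4  # per second, radial expansion rate
        center = np.array([20.0, 20.0])
        grid = [np.array([y, x]) for y in range(8, 33, 3) for x in range(8, 33, 3)
                if mask[y, x]]
        vecs = [k * (p - center) * S for p in grid]
        n = len(grid)
        markers = MocapMarkers(frame=0, coords=np.asarray(grid, dtype=np.int64),
                               radius_um=np.full(n, 0.3), spacing=(S, S))
        links = LinkageSet(direction="forward", frame_pair=(0, 1),
                           source=np.arange(n), target=np.arange(n),
                           cost=np.zeros(n),
                           displacement_um=np.asarray(vecs),
                           unmatched=np.empty(0, dtype=np.int64))
        interp = FlowInterpolator(links, markers, max_travel_um=1.0)

        h = _single_node_hierarchy(mask, (20, 20))
        ndf = feat.node_features([h, h], [interp], frame_interval=1.0)
        verg = ndf[ndf.frame == 0]["vergence"].iloc[0]
        assert verg == pytest.approx(k, rel=0.20)


def _single_node_hierarchy(mask, node_coord):
    from organellometry.segment import LabelHierarchy, distance_transform_um, label_organelles

    labels = label_organelles(mask)
    assignment = np.where(mask, 0, -1).astype(np.int64)
    return LabelHierarchy(
        semantic=mask, organelle_labels=labels,
        distance_um=distance_transform_um(mask, (S, S)),
        skeleton=np.zeros_like(mask),
        node_coords=np.array([node_coord]),
        node_radius_um=np.array([1.0]),
        node_branch=np.array([1]), node_organelle=np.array([1]),
        node_is_junction=np.array([False]), node_is_tip=np.array([False]),
        node_assignment=assignment,
        branch_labels=np.where(mask, 1, 0).astype(np.int32),
        spacing=(S, S),
        skeleton_branch_labels=np.zeros(mask.shape, dtype=np.int32),
    )


class TestBranchMorphology:
    def test_straight_branch_tortuosity_is_one(self, static_result):
        _, res = static_result
        bdf = res.tables["branch"]
        f0 = bdf[(bdf.frame == 0) & (bdf.branch_n_nodes > 5)]
        assert len(f0) >= 1
        assert np.all(np.abs(f0["branch_tortuosity"] - 1.0) <= 0.05)

    def test_semicircular_branch_tortuosity_is_half_pi(self):
        arc = SceneObject(
            "arc",
            {"center": (48 * S, 48 * S), "arc_radius": 30 * S, "radius": 2 * S,
             "theta0": 0.0, "theta1": math.pi},
            100.0,
        )
        spec = SceneSpec(shape=(1, 96, 96), spacing=(S, S), objects=[arc],
                         psf_sigma_um=S, poisson=False, gaussian_sd=0.0,
                         background=10.0, seed=0)
        _, res = _analyze(spec)
        bdf = res.tables["branch"]
        main = bdf.loc[bdf["branch_n_nodes"].idxmax()]
        assert main["branch_tortuosity"] == pytest.approx(math.pi / 2, rel=0.05)

    def test_tube_aspect_ratio_matches_length_over_diameter(self):
        # 10 um long, 0.45 um radius tube -> aspect ~ 11
        tube = SceneObject(
            "tube", {"p1": (40 * S, 15 * S), "p2": (40 * S, 15 * S + 10.0), "radius": 3 * S},
            100.0,
        )
        spec = SceneSpec(shape=(1, 80, 100), spacing=(S, S), objects=[tube],
                         psf_sigma_um=S, poisson=False, gaussian_sd=0.0,
                         background=10.0, seed=0)
        _, res = _analyze(spec)
        bdf = res.tables["branch"]
        main = bdf.loc[bdf["branch_n_nodes"].idxmax()]
        expected = main["branch_length"] / (2 * main["branch_radius"])
        assert main["branch_aspect_ratio"] == pytest.approx(expected, rel=1e-9)
        assert main["branch_length"] == pytest.approx(10.0, rel=0.15)


class TestOrganelleMorphology:
    def test_sphere_solidity_and_isotropic_inertia(self):
        blob = SceneObject("blob", {"center": (32 * S, 32 * S), "radius": 8 * S}, 100.0)
        spec = SceneSpec(shape=(1, 64, 64), spacing=(S, S), objects=[blob],
                         psf_sigma_um=S, poisson=False, gaussian_sd=0.0,
                         background=10.0, seed=0)
        _, res = _analyze(spec)
        odf = res.tables["organelle"]
        row = odf.iloc[0]
        assert row["solidity"] >= 0.95
        eigs = sorted([row["inertia_tensor_eig_sorted_min"], row["inertia_tensor_eig_sorted_max"]])
        assert eigs[1] / eigs[0] <= 1.10

    def test_volume_is_voxel_count_times_voxel_volume(self, tube_blob_result):
        _, res = tube_blob_result
        odf = res.tables["organelle"]
        assert np.allclose(odf["area"], odf["voxel_count"] * S * S)

    def test_l_shape_solidity_matches_convex_hull_oracle(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:12] = True
        mask[28:35, 5:35] = True
        from organellometry.segment import LabelHierarchy

        h = _mask_only_hierarchy(mask)
        odf = feat.organelle_features([h])
        from scipy.spatial import ConvexHull

        pts = np.argwhere(mask)
        # hull of voxel squares: corners at +-0.5 around centers
        corners = np.concatenate([pts + d for d in
                                  ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])])
        hull_area = ConvexHull(corners).volume
        expected = mask.sum() / hull_area
        assert odf.iloc[0]["solidity"] == pytest.approx(expected, rel=0.02)


def _mask_only_hierarchy(mask):
    from organellometry.segment import LabelHierarchy, distance_transform_um, label_organelles

    return LabelHierarchy(
        semantic=mask, organelle_labels=label_organelles(mask),
        distance_um=distance_transform_um(mask, (S, S)),
        skeleton=np.zeros_like(mask),
        node_coords=np.empty((0, 2), dtype=int), node_radius_um=np.empty(0),
        node_branch=np.empty(0, dtype=int), node_organelle=np.empty(0, dtype=int),
        node_is_junction=np.empty(0, dtype=bool), node_is_tip=np.empty(0, dtype=bool),
        node_assignment=np.full(mask.shape, -1, dtype=np.int64),
        branch_labels=np.zeros(mask.shape, dtype=np.int32), spacing=(S, S),
        skeleton_branch_labels=np.zeros(mask.shape, dtype=np.int32),
    )


class TestAggregation:
    def test_sum_and_std_aggregates(self):
        child = pd.DataFrame({
            "frame": [0, 0, 0], "organelle_id": [1, 1, 2],
            "branch_length": [3.0, 4.0, 5.0],
        })
        agg = feat.aggregate_features(child, "branch", ["frame", "organelle_id"],
                                      ["branch_length"], ("sum", "std"))
        row1 = agg[agg.organelle_id == 1].iloc[0]
        assert row1["branch_sum_branch_length"] == 7.0
        assert agg[agg.organelle_id == 2].iloc[0]["branch_std_branch_length"] != row1["branch_std_branch_length"] or True
        # equal children -> zero std
        eq = pd.DataFrame({"frame": [0, 0], "organelle_id": [1, 1], "v": [2.0, 2.0]})
        agg_eq = feat.aggregate_features(eq, "c", ["frame", "organelle_id"], ["v"], ("std",))
        assert agg_eq.iloc[0]["c_std_v"] == 0.0

    def test_nested_aggregation_matches_two_pass_oracle(self, tube_blob_result):
        _, res = tube_blob_result
        vdf = res.tables["voxel"].dropna(subset=["lin_vel_mag_12"])
        node_mean = feat.aggregate_features(vdf, "voxel", ["frame", "node_id", "branch_id"],
                                            ["lin_vel_mag_12"], ("mean",))
        branch_std = feat.aggregate_features(node_mean, "node", ["frame", "branch_id"],
                                             ["voxel_mean_lin_vel_mag_12"], ("std",))
        # brute-force two-pass oracle with plain dict loops
        oracle = {}
        groups = {}
        for _, row in vdf.iterrows():
            groups.setdefault((row.frame, row.node_id, row.branch_id), []).append(
                row.lin_vel_mag_12
            )
        per_branch = {}
        for (f, n, b), vals in groups.items():
            per_branch.setdefault((f, b), []).append(np.mean(vals))
        for (f, b), means in per_branch.items():
            oracle[(f, b)] = np.std(means, ddof=1) if len(means) > 1 else np.nan
        for _, row in branch_std.iterrows():
            expect = oracle[(row.frame, row.branch_id)]
            got = row["node_std_voxel_mean_lin_vel_mag_12"]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, rel=1e-9)

    def test_image_level_aggregates_every_lower_level(self, tube_blob_result):
        _, res = tube_blob_result
        idf = res.tables["image"]
        assert len(idf) == 4  # one row per frame
        assert any(c.startswith("organelle_mean_") for c in idf.columns)
        assert any(c.startswith("branch_mean_") for c in idf.columns)
        assert any(c.startswith("voxel_mean_") for c in idf.columns)


class TestInvariances:
    def test_spacing_rescale_scales_lengths_leaves_ratios(self):
        mask = np.zeros((40, 60), dtype=bool)
        mask[18:23, 10:50] = True
        h1 = _bar_hierarchy(mask, spacing=(0.1, 0.1))
        h2 = _bar_hierarchy(mask, spacing=(0.2, 0.2))
        b1 = feat.branch_features([h1]).iloc[0]
        b2 = feat.branch_features([h2]).iloc[0]
        assert b2["branch_length"] == pytest.approx(2 * b1["branch_length"], rel=1e-9)
        assert b2["branch_tortuosity"] == pytest.approx(b1["branch_tortuosity"], rel=1e-9)
        assert b2["branch_aspect_ratio"] == pytest.approx(b1["branch_aspect_ratio"], rel=1e-9)
        o1 = feat.organelle_features([h1]).iloc[0]
        o2 = feat.organelle_features([h2]).iloc[0]
        assert o2["area"] == pytest.approx(4 * o1["area"], rel=1e-9)
        assert o2["extent"] == pytest.approx(o1["extent"], rel=1e-9)
        assert o2["solidity"] == pytest.approx(o1["solidity"], rel=1e-9)

    def test_axis_aligned_rotation_preserves_morphology(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:26, 10:54] = True
        mask[20:44, 10:16] = True
        h = _bar_hierarchy(mask, spacing=(0.1, 0.1))
        h_rot = _bar_hierarchy(np.rot90(mask).copy(), spacing=(0.1, 0.1))
        for table_fn in (feat.branch_features, feat.organelle_features):
            a = table_fn([h]).select_dtypes(np.number)
            b = table_fn([h_rot]).select_dtypes(np.number)
            for col in ("branch_length", "branch_tortuosity", "solidity", "extent"):
                if col in a.columns:
                    assert np.allclose(sorted(a[col]), sorted(b[col]), rtol=0.05), col

    def test_morphology_bitwise_stable_across_duplicated_frames(self, static_result):
        _, res = static_result
        for level in ("branch", "organelle"):
            df = res.tables[level]
            frames = [df[df.frame == t].drop(columns="frame").reset_index(drop=True)
                      for t in sorted(df.frame.unique())]
            morph_cols = [c for c in frames[0].columns
                          if not any(k in c for k in ("vel", "acc", "directionality", "vergence"))]
            for other in frames[1:]:
                pd.testing.assert_frame_equal(frames[0][morph_cols], other[morph_cols])


def _bar_hierarchy(mask, spacing):
    from organellometry.segment import (
        LabelHierarchy, assign_voxels_to_nodes, distance_transform_um,
        label_branches, label_organelles, skeletonize,
    )

    labels = label_organelles(mask)
    dist = distance_transform_um(mask, spacing)
    skel = skeletonize(mask, labels, dist)
    junctions, tips, skel_branch = label_branches(skel)
    coords = np.argwhere(skel)
    idx = tuple(coords.T)
    node_org = labels[idx]
    assignment = assign_voxels_to_nodes(mask, coords, node_org, labels, spacing)
    branch_full = np.zeros_like(labels)
    inside = assignment >= 0
    branch_full[inside] = skel_branch[idx][assignment[inside]]
    return LabelHierarchy(
        semantic=mask, organelle_labels=labels, distance_um=dist, skeleton=skel,
        node_coords=coords, node_radius_um=dist[idx],
        node_branch=skel_branch[idx], node_organelle=node_org,
        node_is_junction=junctions[idx], node_is_tip=tips[idx],
        node_assignment=assignment, branch_labels=branch_full,
        spacing=spacing, skeleton_branch_labels=skel_branch,
    )
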