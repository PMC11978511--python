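"""Hierarchical feature extraction: voxel, node, branch, organelle, image.

Units are micrometres, seconds and radians throughout. Motility features are
computed from interpolated flow at each voxel's position over the frame
triplet (t-1, t, t+1); the ``_01`` suffix denotes the (t-1, t) interval and
``_12`` the (t, t+1) interval, accelerations need both. Reference-adjusted
(``rel_``) kinematics subtract the motion of the branch's tracked pivot
point, separating a voxel's own motion from bulk branch motion; ``ref_``
features are the pivot's own kinematics. Rows at the first/last frame have
no adjacent frame on one side, so the affected columns are NaN there (and
absent entirely for single-frame runs).

Aggregate columns follow the ``{child_level}_{stat}_{feature}`` naming
scheme at every parent level, and aggregations nest (a branch's nodes' mean
voxel speed variability is just two applications).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from skimage.measure import regionprops

from .segment import LabelHierarchy

AGG_STATS = ("mean", "std", "min", "max", "median", "sum")


def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Elementwise angle between rows of u and v, radians; 0 for null rows."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    cos = np.zeros(u.shape[:-1])
    ok = denom > 0
    cos[ok] = np.sum(u * v, axis=-1)[ok] / denom[ok]
    return np.arccos(np.clip(cos, -1.0, 1.0))


def _branch_pivots(h: LabelHierarchy) -> Dict[int, np.ndarray]:
    """Pivot voxel (zyx) per branch: the skeleton node nearest the branch's
    mask-voxel centroid, in physical distance."""
    spacing = np.asarray(h.spacing, dtype=float)
    pivots: Dict[int, np.ndarray] = {}
    vox = np.argwhere(h.semantic)
    if not len(vox):
        return pivots
    vox_branch = h.branch_labels[tuple(vox.T)]
    for b in np.unique(vox_branch[vox_branch > 0]):
        centroid = vox[vox_branch == b].mean(axis=0) * spacing
        nodes = np.flatnonzero(h.node_branch == b)
        node_um = h.node_coords[nodes] * spacing
        pivots[int(b)] = h.node_coords[nodes[np.argmin(np.linalg.norm(node_um - centroid, axis=1))]].astype(float)
    return pivots


def voxel_features(
    hierarchies: Sequence[LabelHierarchy],
    raw_frames: Sequence[np.ndarray],
    enhanced_frames: Sequence[np.ndarray],
    forward_interps: Optional[Sequence] = None,
    backward_interps: Optional[Sequence] = None,
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Per-voxel intensity and motility table across all frames.

    ``forward_interps[t]`` interpolates displacement t -> t+1 at frame-t
    coordinates; ``backward_interps[t]`` interpolates t+1 -> t at frame-t+1
    coordinates (both um). With no interpolators (single frame) the table is
    morphology-only: intensities and lineage.
    """
    dt = float(frame_interval)
    n_frames = len(hierarchies)
    have_flow = forward_interps is not None and n_frames > 1
    rows: List[pd.DataFrame] = []
    for t, h in enumerate(hierarchies):
        spacing = np.asarray(h.spacing, dtype=float)
        vox = np.argwhere(h.semantic)
        n = len(vox)
        idx = tuple(vox.T)
        axis_names = "zyx"[-h.semantic.ndim :]
        df = pd.DataFrame(
            {
                "frame": t,
                "voxel_id": np.ravel_multi_index(idx, h.semantic.shape) if n else np.array([], dtype=int),
                **{ax: vox[:, a] for a, ax in enumerate(axis_names)},
            }
        )
        df["node_id"] = h.node_assignment[idx] if n else np.array([], dtype=int)
        df["branch_id"] = h.branch_labels[idx] if n else np.array([], dtype=int)
        df["organelle_id"] = h.organelle_labels[idx] if n else np.array([], dtype=int)
        df["intensity_raw"] = raw_frames[t][idx] if n else np.array([])
        df["intensity_enhanced"] = enhanced_frames[t][idx] if n else np.array([])

        if have_flow and n:
            p_t = vox * spacing
            fwd = forward_interps[t] if t < n_frames - 1 else None
            bwd = backward_interps[t - 1] if (backward_interps is not None and t > 0) else None
            p_next = p_t + fwd.query(vox.astype(float)).vectors_um if fwd is not None else None
            p_prev = p_t + bwd.query(vox.astype(float)).vectors_um if bwd is not None else None

            pivots = _branch_pivots(h)
            branch_ids = df["branch_id"].to_numpy()
            piv_t = np.full_like(p_t, np.nan)
            for b, pv in pivots.items():
                piv_t[branch_ids == b] = pv * spacing
            piv_coords = {b: pv for b, pv in pivots.items()}
            piv_vox = np.stack([piv_coords[b] for b in sorted(piv_coords)]) if piv_coords else np.empty((0, vox.shape[1]))
            b_sorted = sorted(piv_coords)
            piv_next_map, piv_prev_map = {}, {}
            if len(piv_vox):
                if fwd is not None:
                    d = fwd.query(piv_vox).vectors_um
                    for k, b in enumerate(b_sorted):
                        piv_next_map[b] = piv_vox[k] * spacing + d[k]
                if bwd is not None:
                    d = bwd.query(piv_vox).vectors_um
                    for k, b in enumerate(b_sorted):
                        piv_prev_map[b] = piv_vox[k] * spacing + d[k]
            piv_next = np.full_like(p_t, np.nan)
            piv_prev = np.full_like(p_t, np.nan)
            for b in b_sorted:
                sel = branch_ids == b
                if b in piv_next_map:
                    piv_next[sel] = piv_next_map[b]
                if b in piv_prev_map:
                    piv_prev[sel] = piv_prev_map[b]

            nan = np.full(n, np.nan)
            v01 = (p_t - p_prev) / dt if p_prev is not None else None
            v12 = (p_next - p_t) / dt if p_next is not None else None
            df["lin_vel_mag_01"] = np.linalg.norm(v01, axis=1) if v01 is not None else nan
            df["lin_vel_mag_12"] = np.linalg.norm(v12, axis=1) if v12 is not None else nan
            df["lin_acc_mag"] = (
                np.linalg.norm(v12 - v01, axis=1) / dt if v01 is not None and v12 is not None else nan
            )

            q_t = p_t - piv_t
            q_next = p_next - piv_next if p_next is not None else None
            q_prev = p_prev - piv_prev if p_prev is not None else None
            rv01 = (q_t - q_prev) / dt if q_prev is not None else None
            rv12 = (q_next - q_t) / dt if q_next is not None else None
            df["rel_lin_vel_mag_01"] = np.linalg.norm(rv01, axis=1) if rv01 is not None else nan
            df["rel_lin_vel_mag_12"] = np.linalg.norm(rv12, axis=1) if rv12 is not None else nan
            df["rel_lin_acc_mag"] = (
                np.linalg.norm(rv12 - rv01, axis=1) / dt if rv01 is not None and rv12 is not None else nan
            )
            w01 = _angle_between(q_prev, q_t) / dt if q_prev is not None else nan
            w12 = _angle_between(q_t, q_next) / dt if q_next is not None else nan
            df["rel_ang_vel_mag_01"] = w01
            df["rel_ang_vel_mag_12"] = w12
            df["rel_ang_acc_mag"] = (
                np.abs(w12 - w01) / dt
                if (q_prev is not None and q_next is not None)
                else nan
            )

            pv01 = (piv_t - piv_prev) / dt if p_prev is not None else None
            pv12 = (piv_next - piv_t) / dt if p_next is not None else None
            df["ref_lin_vel_mag_01"] = np.linalg.norm(pv01, axis=1) if pv01 is not None else nan
            df["ref_lin_vel_mag_12"] = np.linalg.norm(pv12, axis=1) if pv12 is not None else nan
            df["ref_lin_acc_mag"] = (
                np.linalg.norm(pv12 - pv01, axis=1) / dt if pv01 is not None and pv12 is not None else nan
            )

            # branch directionality w.r.t. the intensity centre of mass:
            # positive = branch voxels moving away from the CoM on average
            weights = raw_frames[t][idx].astype(float)
            wsum = weights.sum()
            com = (weights[:, None] * p_t).sum(axis=0) / wsum if wsum > 0 else p_t.mean(axis=0)
            for name, vel in (("com_directionality_01", v01), ("com_directionality_12", v12)):
                col = np.full(n, np.nan)
                if vel is not None:
                    radial = p_t - com
                    rn = np.linalg.norm(radial, axis=1)
                    vn = np.linalg.norm(vel, axis=1)
                    ok = (rn > 0) & (vn > 0)
                    cosang = np.zeros(n)
                    cosang[ok] = np.sum(radial * vel, axis=1)[ok] / (rn[ok] * vn[ok])
                    tmp = pd.Series(cosang).groupby(branch_ids).transform("mean").to_numpy()
                    col = np.where(branch_ids > 0, tmp, np.nan)
                df[name] = col
            df["com_directionality_acceleration"] = (
                (df["com_directionality_12"] - df["com_directionality_01"]) / dt
            )
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def node_features(
    hierarchies: Sequence[LabelHierarchy],
    forward_interps: Optional[Sequence] = None,
    voxel_table: Optional[pd.DataFrame] = None,
    frame_interval: float = 1.0,
    agg_features: Sequence[str] = ("lin_vel_mag_12", "intensity_raw", "intensity_enhanced"),
    stats: Sequence[str] = ("mean", "std"),
) -> pd.DataFrame:
    """Per-node table: thickness, flow vergence and voxel aggregates.

    Vergence is the local divergence rate of the surrounding flow: the mean,
    over a node's assigned voxels, of the radial component of the relative
    flow normalized by the radial distance,
    ``(flow(v) - flow(center)) . (v - center) / |v - center|^2`` per second,
    so a field expanding radially at rate k reads +k. Positive means the
    surrounding flow diverges from the node, negative converges.
    """
    dt = float(frame_interval)
    rows = []
    n_frames = len(hierarchies)
    for t, h in enumerate(hierarchies):
        spacing = np.asarray(h.spacing, dtype=float)
        n = h.n_nodes
        df = pd.DataFrame(
            {
                "frame": t,
                "node_id": np.arange(n),
                "branch_id": h.node_branch,
                "organelle_id": h.node_organelle,
                "is_junction": h.node_is_junction,
                "is_tip": h.node_is_tip,
                "radius_um": h.node_radius_um,
                "thickness_um": 2.0 * h.node_radius_um,
            }
        )
        verg = np.full(n, np.nan)
        fwd = forward_interps[t] if (forward_interps is not None and t < n_frames - 1) else None
        if fwd is not None and n:
            node_flow = fwd.query(h.node_coords.astype(float)).vectors_um
            vox = np.argwhere(h.semantic)
            assign = h.node_assignment[tuple(vox.T)]
            vox_flow = fwd.query(vox.astype(float)).vectors_um
            for i in range(n):
                sel = assign == i
                if not sel.any():
                    verg[i] = 0.0
                    continue
                rel = (vox[sel] - h.node_coords[i]) * spacing
                rn = np.linalg.norm(rel, axis=1)
                ok = rn > 0
                if not ok.any():
                    verg[i] = 0.0
                    continue
                radial = rel[ok] / rn[ok, None] ** 2
                verg[i] = float(np.mean(np.sum((vox_flow[sel][ok] - node_flow[i]) * radial, axis=1))) / dt
        df["vergence"] = verg
        rows.append(df)
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    if voxel_table is not None and len(voxel_table) and len(table):
        cols = [c for c in agg_features if c in voxel_table.columns]
        agg = aggregate_features(voxel_table, "voxel", ["frame", "node_id"], cols, stats)
        table = table.merge(agg, on=["frame", "node_id"], how="left")
    return table


def _branch_path_metrics(coords: np.ndarray, spacing: np.ndarray):
    """(path length, end-to-end distance) of one branch's skeleton voxels.

    The skeleton adjacency graph is reduced to its minimum spanning tree
    (physical edge weights), whose total weight is the path length without
    double-counting diagonal shortcuts; endpoints are the farthest-apart
    leaf pair found by double BFS.
    """
    n = len(coords)
    if n == 1:
        return 0.0, 0.0
    um = coords * spacing
    diff = coords[:, None, :] - coords[None, :, :]
    adj = np.all(np.abs(diff) <= 1, axis=-1) & ~np.eye(n, dtype=bool)
    w = np.linalg.norm(um[:, None, :] - um[None, :, :], axis=-1) * adj
    mst = minimum_spanning_tree(w)
    length = float(mst.sum())
    sym = mst + mst.T
    far, _ = breadth_first_order(sym, 0, directed=False)
    a = far[-1]
    far2, _ = breadth_first_order(sym, a, directed=False)
    b = far2[-1]
    end_to_end = float(np.linalg.norm(um[a] - um[b]))
    return length, end_to_end


def branch_features(hierarchies: Sequence[LabelHierarchy]) -> pd.DataFrame:
    """Per-branch skeleton morphology: length, radius, tortuosity, aspect ratio."""
    rows = []
    for t, h in enumerate(hierarchies):
        spacing = np.asarray(h.spacing, dtype=float)
        voxel_volume = float(np.prod(spacing))
        vox = np.argwhere(h.semantic)
        vox_branch = h.branch_labels[tuple(vox.T)] if len(vox) else np.array([], dtype=int)
        for b in np.unique(h.node_branch[h.node_branch > 0]) if h.n_nodes else []:
            nodes = np.flatnonzero(h.node_branch == b)
            coords = h.node_coords[nodes]
            length, end_to_end = _branch_path_metrics(coords, spacing)
            radius = float(h.node_radius_um[nodes].mean())
            tortuosity = 1.0 if end_to_end == 0 else max(1.0, length / end_to_end)
            n_vox = int(np.sum(vox_branch == b))
            rows.append(
                {
                    "frame": t,
                    "branch_id": int(b),
                    "organelle_id": int(h.node_organelle[nodes[0]]),
                    "branch_length": length,
                    "branch_radius": radius,
                    "branch_tortuosity": tortuosity,
                    "branch_aspect_ratio": length / (2.0 * radius) if radius > 0 else np.nan,
                    "branch_voxel_count": n_vox,
                    "branch_volume": n_vox * voxel_volume,
                    "branch_n_nodes": len(nodes),
                }
            )
    return pd.DataFrame(rows)


def organelle_features(hierarchies: Sequence[LabelHierarchy]) -> pd.DataFrame:
    """Per-organelle morphology: volume, extent, solidity, inertia eigenvalues."""
    rows = []
    for t, h in enumerate(hierarchies):
        spacing = tuple(float(s) for s in h.spacing)
        ndim = h.semantic.ndim
        for rp in regionprops(h.organelle_labels, spacing=spacing):
            try:
                solidity = float(rp.solidity)
            except Exception:  # degenerate hulls (collinear voxels)
                solidity = np.nan
            eigs = np.sort(np.asarray(rp.inertia_tensor_eigvals))
            try:
                major = float(rp.axis_major_length)
                minor = float(rp.axis_minor_length)
            except Exception:
                major = minor = 0.0
            row = {
                "frame": t,
                "organelle_id": int(rp.label),
                "area": float(rp.area),  # um^2 in 2D, um^3 in 3D
                "extent": float(rp.extent),
                "solidity": solidity,
                "inertia_tensor_eig_sorted_min": float(eigs[0]),
                "inertia_tensor_eig_sorted_max": float(eigs[-1]),
                "axis_major_length": major,
                "axis_minor_length": minor,
                "voxel_count": int(rp.num_pixels),
            }
            if ndim == 3:
                row["inertia_tensor_eig_sorted_mid"] = float(eigs[1])
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_features(
    child: pd.DataFrame,
    child_level: str,
    parent_keys: Sequence[str],
    feature_cols: Sequence[str],
    stats: Sequence[str] = AGG_STATS,
) -> pd.DataFrame:
    """Aggregate child features onto a parent level.

    Produces one row per unique parent key combination with columns named
    ``{child_level}_{stat}_{feature}``. Empty child sets simply yield no row
    (downstream joins flag them as missing). Nested aggregation is just a
    second call with this output as the child.
    """
    cols = [c for c in feature_cols if c in child.columns]
    if not cols or not len(child):
        return pd.DataFrame(columns=list(parent_keys))
    grouped = child.groupby(list(parent_keys))[cols].agg(list(stats))
    grouped.columns = [f"{child_level}_{stat}_{feat}" for feat, stat in grouped.columns]
    return grouped.reset_index()


def image_features(
    tables: Dict[str, pd.DataFrame],
    stats: Sequence[str] = ("mean", "std", "min", "max"),
) -> pd.DataFrame:
    """One row per frame aggregating every lower level's numeric features."""
    per_level = []
    for level, df in tables.items():
        if df is None or not len(df):
            continue
        skip = {"frame", "voxel_id", "node_id", "branch_id", "organelle_id", "z", "y", "x"}
        cols = [
            c
            for c in df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(df[c]) and df[c].dtype != bool
        ]
        if not cols:
            continue
        agg = aggregate_features(df, level, ["frame"], cols, stats)
        per_level.append(agg)
    if not per_level:
        return pd.DataFrame()
    out = per_level[0]
    for other in per_level[1:]:
        out = out.merge(other, on="frame", how="outer")
    return out.sort_values("frame").reset_index(drop=True)


def feature_dictionary() -> pd.DataFrame:
    """Data dictionary for the exported tables (name, level, unit, meaning)."""
    entries = [
        ("intensity_raw", "voxel", "counts", "raw image value at the voxel"),
        ("intensity_enhanced", "voxel", "a.u.", "structural enhancement response"),
        ("lin_vel_mag_01", "voxel", "um/s", "speed over (t-1, t)"),
        ("lin_vel_mag_12", "voxel", "um/s", "speed over (t, t+1)"),
        ("lin_acc_mag", "voxel", "um/s^2", "magnitude of velocity change"),
        ("rel_lin_vel_mag_01", "voxel", "um/s", "speed relative to the branch pivot, (t-1, t)"),
        ("rel_lin_vel_mag_12", "voxel", "um/s", "speed relative to the branch pivot, (t, t+1)"),
        ("rel_lin_acc_mag", "voxel", "um/s^2", "pivot-relative acceleration magnitude"),
        ("rel_ang_vel_mag_01", "voxel", "rad/s", "angular speed about the branch pivot, (t-1, t)"),
        ("rel_ang_vel_mag_12", "voxel", "rad/s", "angular speed about the branch pivot, (t, t+1)"),
        ("rel_ang_acc_mag", "voxel", "rad/s^2", "angular acceleration about the branch pivot"),
        ("ref_lin_vel_mag_01", "voxel", "um/s", "branch pivot's own speed, (t-1, t)"),
        ("ref_lin_vel_mag_12", "voxel", "um/s", "branch pivot's own speed, (t, t+1)"),
        ("ref_lin_acc_mag", "voxel", "um/s^2", "branch pivot's acceleration magnitude"),
        ("com_directionality_01", "voxel", "cosine", "branch-mean alignment of motion with the outward radial from the intensity centre of mass, (t-1, t)"),
        ("com_directionality_12", "voxel", "cosine", "same over (t, t+1); positive = moving away from the centre of mass"),
        ("com_directionality_acceleration", "voxel", "1/s", "rate of change of directionality"),
        ("radius_um", "node", "um", "distance-transform value at the skeleton node"),
        ("thickness_um", "node", "um", "2 x radius"),
        ("vergence", "node", "1/s", "mean radial component of surrounding flow; >0 divergence"),
        ("branch_length", "branch", "um", "skeleton path length (anisotropic steps)"),
        ("branch_radius", "branch", "um", "mean node radius"),
        ("branch_tortuosity", "branch", "ratio", "path length / end-to-end distance (1 = straight)"),
        ("branch_aspect_ratio", "branch", "ratio", "length / (2 x radius)"),
        ("branch_voxel_count", "branch", "voxels", "mask voxels assigned to the branch"),
        ("branch_volume", "branch", "um^3 (um^2 in 2D)", "voxel count x voxel volume"),
        ("area", "organelle", "um^3 (um^2 in 2D)", "physical volume/area"),
        ("extent", "organelle", "ratio", "volume / bounding-box volume"),
        ("solidity", "organelle", "ratio", "volume / convex-hull volume"),
        ("inertia_tensor_eig_sorted_min", "organelle", "um^2", "smallest inertia eigenvalue"),
        ("inertia_tensor_eig_sorted_mid", "organelle", "um^2", "middle inertia eigenvalue (3D)"),
        ("inertia_tensor_eig_sorted_max", "organelle", "um^2", "largest inertia eigenvalue"),
        ("axis_major_length", "organelle", "um", "major axis from the inertia tensor"),
        ("axis_minor_length", "organelle", "um", "minor axis from the inertia tensor"),
    ]
    return pd.DataFrame(entries, columns=["feature", "level", "unit", "description"])
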