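"""Dense sub-voxel flow interpolation from mocap-marker linkages.

Any coordinate of interest (CoI) — a voxel, a sub-voxel point, or a whole
object's voxel set — gets a displacement vector interpolated from nearby
marker links: each link within the maximum travel distance contributes its
vector with weight ``(1/(d+eps)) * (1/(c - c_min + eps))``, preferring links
that are close (small distance ``d`` to the CoI) and well-matched (cost ``c``
near the local minimum ``c_min``). Weights are normalized to sum to one, so
the interpolated vector is a convex combination of the contributing link
vectors; a CoI with no link in range keeps a zero vector (conservative:
unmoved rather than extrapolated).

Tracks accumulate these vectors at fractional (sub-voxel) precision;
rounding to the grid happens only when matching voxels between frames to
decide each voxel's fate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .mocap import DEFAULT_MAX_TRAVEL_UM, LinkageSet, MocapMarkers
from .segment import LabelHierarchy

EPS = 1e-6


@dataclass
class FlowField:
    """Interpolated displacements for a batch of query coordinates."""

    frame_pair: Tuple[int, int]
    direction: str
    coords: np.ndarray      # (M, ndim) query coordinates, fractional voxels
    vectors_um: np.ndarray  # (M, ndim)
    support: np.ndarray     # (M,) number of contributing links


@dataclass
class Track:
    """One seed followed through time at sub-voxel precision."""

    track_id: int
    start_frame: int
    frames: np.ndarray      # (K,) frame indices, consecutive
    coords: np.ndarray      # (K, ndim) fractional voxel coordinates
    origin_level: str = "voxel"
    terminated: bool = False  # left the image bounds


class FlowInterpolator:
    """Per-frame-pair interpolator over one direction's marker linkages."""

    def __init__(
        self,
        links: LinkageSet,
        source_markers: MocapMarkers,
        max_travel_um: float = DEFAULT_MAX_TRAVEL_UM,
    ):
        self.links = links
        self.max_travel_um = float(max_travel_um)
        self.spacing = np.asarray(source_markers.spacing, dtype=float)
        if len(links):
            src_coords_um = source_markers.coords_um[links.source]
            self._tree = cKDTree(src_coords_um)
            self._vectors = links.displacement_um
            self._costs = links.cost
            # variable-range support: a marker describes the motion of the
            # local region within its own radius, so it can inform CoIs up
            # to max_travel + radius away. Without this, structures thicker
            # than max_travel would have support gaps, since the detection
            # exclusion footprint scales with the same radius.
            self._radii = source_markers.radius_um[links.source]
            self._max_reach = self.max_travel_um + float(self._radii.max())
        else:
            self._tree = None

    def query(self, cois: np.ndarray) -> FlowField:
        """Interpolate displacement vectors at fractional voxel coordinates.

        Results are independent of query batch order: every CoI is handled
        from the same immutable link set.
        """
        cois = np.atleast_2d(np.asarray(cois, dtype=float))
        m, ndim = cois.shape
        vectors = np.zeros((m, ndim))
        support = np.zeros(m, dtype=np.int64)
        if self._tree is not None:
            cois_um = cois * self.spacing
            neighbor_lists = self._tree.query_ball_point(cois_um, self._max_reach)
            for i, idx in enumerate(neighbor_lists):
                if not idx:
                    continue
                idx = np.asarray(idx)
                d = np.linalg.norm(self._tree.data[idx] - cois_um[i], axis=1)
                keep = d <= self.max_travel_um + self._radii[idx]
                if not keep.any():
                    continue
                idx, d = idx[keep], d[keep]
                c = self._costs[idx]
                w = (1.0 / (d + EPS)) * (1.0 / (c - c.min() + EPS))
                w /= w.sum()
                vectors[i] = w @ self._vectors[idx]
                support[i] = len(idx)
        return FlowField(
            frame_pair=self.links.frame_pair,
            direction=self.links.direction,
            coords=cois,
            vectors_um=vectors,
            support=support,
        )


def interpolate_flow(
    cois: np.ndarray,
    links: LinkageSet,
    source_markers: MocapMarkers,
    max_travel_um: float = DEFAULT_MAX_TRAVEL_UM,
) -> FlowField:
    """One-shot convenience over :class:`FlowInterpolator`."""
    return FlowInterpolator(links, source_markers, max_travel_um).query(cois)


def propagate_tracks(
    seeds: np.ndarray,
    forward_flows: Sequence[FlowInterpolator],
    shape: Tuple[int, ...],
    t0: int = 0,
    backward_flows: Optional[Sequence[FlowInterpolator]] = None,
    origin_level: str = "voxel",
) -> List[Track]:
    """Advance seeds frame by frame along interpolated flow.

    ``forward_flows[t]`` maps frame t -> t+1; ``backward_flows[t]`` (optional,
    same indexing: pair (t, t+1), direction backward) extends tracks from
    ``t0`` back to frame 0. Positions are kept fractional; displacement is
    converted um -> voxels per axis. A seed stepping outside the image bounds
    terminates its track with a flag.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    ndim = seeds.shape[1]
    spacing = None
    for f in list(forward_flows) + list(backward_flows or []):
        if f is not None:
            spacing = f.spacing
            break
    if spacing is None:
        spacing = np.ones(ndim)
    bounds = np.asarray(shape, dtype=float)

    n_frames = len(forward_flows) + 1
    tracks: List[Track] = []
    for tid, seed in enumerate(seeds):
        frames = [t0]
        coords = [seed.copy()]
        terminated = False
        # backward from t0 to 0
        if backward_flows is not None:
            p = seed.copy()
            for t in range(t0 - 1, -1, -1):
                interp = backward_flows[t]
                if interp is None:
                    break
                v = interp.query(p[None, :]).vectors_um[0] / spacing
                p = p + v
                if np.any(p < 0) or np.any(p > bounds - 1):
                    terminated = True
                    break
                frames.insert(0, t)
                coords.insert(0, p.copy())
        # forward from t0
        p = seed.copy()
        for t in range(t0, n_frames - 1):
            interp = forward_flows[t]
            if interp is None:
                break
            v = interp.query(p[None, :]).vectors_um[0] / spacing
            p = p + v
            if np.any(p < 0) or np.any(p > bounds - 1):
                terminated = True
                break
            frames.append(t + 1)
            coords.append(p.copy())
        tracks.append(
            Track(
                track_id=tid,
                start_frame=frames[0],
                frames=np.asarray(frames),
                coords=np.asarray(coords),
                origin_level=origin_level,
                terminated=terminated,
            )
        )
    return tracks


def match_voxels(
    hierarchy_t: LabelHierarchy,
    hierarchy_t1: LabelHierarchy,
    forward_flow: FlowInterpolator,
) -> np.ndarray:
    """Determine each mask voxel's fate in the next frame.

    Each voxel at t is displaced by its interpolated vector and rounded to
    the grid. If it lands inside the t+1 mask it is matched to that voxel
    (and thereby to its node/branch/organelle labels); otherwise to the
    nearest t+1 mask voxel within one voxel on every axis; otherwise it is
    unmatched.

    Returns an ``(n_voxels_t, 2 + 2*ndim)`` int array with columns
    ``(matched_flag, unused, coord_t..., coord_t1...)``; unmatched rows carry
    -1 coordinates at t+1.
    """
    vox_t = np.argwhere(hierarchy_t.semantic)
    ndim = hierarchy_t.semantic.ndim
    n = len(vox_t)
    out = np.full((n, 2 + 2 * ndim), -1, dtype=np.int64)
    out[:, 2 : 2 + ndim] = vox_t
    out[:, 0] = 0
    if n == 0:
        return out
    spacing = np.asarray(hierarchy_t.spacing, dtype=float)
    field = forward_flow.query(vox_t.astype(float))
    dest = vox_t + field.vectors_um / spacing
    dest_round = np.rint(dest).astype(np.int64)

    mask_t1 = hierarchy_t1.semantic
    shape = np.asarray(mask_t1.shape)
    inb = np.all((dest_round >= 0) & (dest_round < shape), axis=1)
    hit = np.zeros(n, dtype=bool)
    hit[inb] = mask_t1[tuple(dest_round[inb].T)]
    out[hit, 0] = 1
    out[hit, 2 + ndim :] = dest_round[hit]

    miss = np.flatnonzero(~hit)
    if len(miss):
        vox_t1 = np.argwhere(mask_t1)
        if len(vox_t1):
            tree = cKDTree(vox_t1)
            dists, nearest = tree.query(dest[miss], k=1)
            cand = vox_t1[nearest]
            ok = np.all(np.abs(cand - dest[miss]) <= 1.0 + 1e-9, axis=1)
            rows = miss[ok]
            out[rows, 0] = 1
            out[rows, 2 + ndim :] = cand[ok]
    return out
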