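"""Label-independent motion-capture markers and frame-to-frame linkage.

Markers are local maxima of the distance transform inside the mask — centers
of locally thickest regions — detected with an exclusion footprint that
scales with the local radius, so thick regions yield sparse markers and thin
tubules dense ones. They carry no biological identity; they are beacons for
the downstream flow interpolation, deliberately independent of instance
labels so that segmentation instability between frames cannot corrupt
tracking.

Each marker gets a 'stats vector' (mean and variance of the raw and of the
enhanced image inside its radius-sized bounding box) and a 'Hu vector' (the
first six Hu moment invariants of the raw and enhanced patches; in 3D, of
the xy/xz/yz maximum-intensity projections of the box). Linking builds three
difference matrices — physical distance, stats distance, Hu distance —
z-scores each over the admissible (within max travel) pairs, sums them, and
assigns every marker to its best match in each direction independently
(no global assignment solve), so 1-to-1, 1-to-n and n-to-1 matches all
arise naturally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from skimage.measure import moments_central, moments_hu, moments_normalized

from .segment import LabelHierarchy

#: default admissible travel per frame, micrometres (~ one organelle radius
#: per second at 1 Hz); user-configurable
DEFAULT_MAX_TRAVEL_UM = 1.0

_LOG_EPS = 1e-30


@dataclass
class MocapMarkers:
    """All markers of one frame (parallel arrays, index = marker id)."""

    frame: int
    coords: np.ndarray          # (N, ndim) int voxel coordinates (grid peak)
    radius_um: np.ndarray       # (N,)
    spacing: tuple
    #: sub-voxel marker position: distance-weighted centroid of the medial
    #: peak within the exclusion footprint. Linking distances and link
    #: displacement vectors use this; feature bounding boxes use the
    #: integer ``coords``.
    coords_refined: Optional[np.ndarray] = None  # (N, ndim) float
    stats_vec: Optional[np.ndarray] = None  # (N, 4)
    hu_vec: Optional[np.ndarray] = None     # (N, 12) in 2D, (N, 36) in 3D

    def __len__(self) -> int:
        return len(self.radius_um)

    @property
    def coords_um(self) -> np.ndarray:
        pos = self.coords if self.coords_refined is None else self.coords_refined
        return pos * np.asarray(self.spacing)


@dataclass
class LinkageSet:
    """Directed best-match links for one frame pair.

    ``direction`` is "forward" (T -> T+1) or "backward" (T+1 -> T). Every
    source marker appears exactly once: either in ``source`` or in
    ``unmatched``.
    """

    direction: str
    frame_pair: Tuple[int, int]
    source: np.ndarray        # (L,) source marker ids
    target: np.ndarray        # (L,) target marker ids
    cost: np.ndarray          # (L,)
    displacement_um: np.ndarray  # (L, ndim) target - source, physical
    unmatched: np.ndarray     # source marker ids with no admissible target

    def __len__(self) -> int:
        return len(self.source)


def _refine_subvoxel(
    coords: np.ndarray,
    radii: np.ndarray,
    dist: np.ndarray,
    organelle_labels: np.ndarray,
    spacing: np.ndarray,
) -> np.ndarray:
    """Distance^2-weighted centroid of the medial peak around each marker.

    Pulls the grid peak to the structure's true medial centre, restricted to
    the marker's own organelle so contact with a neighbour cannot bias it.
    This is what makes link displacement vectors sub-voxel quantities.
    """
    refined = coords.astype(float).copy()
    shape = np.asarray(dist.shape)
    for i, (c, r) in enumerate(zip(coords, radii)):
        rad_vox = np.maximum(1, np.ceil(r / spacing).astype(int))
        lo = np.maximum(c - rad_vox, 0)
        hi = np.minimum(c + rad_vox + 1, shape)
        window = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub = dist[window]
        inside = (organelle_labels[window] == organelle_labels[tuple(c)]) & (sub > 0)
        idx = np.argwhere(inside)
        offs_um = (idx + lo - c) * spacing
        near = np.linalg.norm(offs_um, axis=1) <= max(r, float(spacing.min()))
        idx = idx[near]
        if len(idx) == 0:
            continue
        w = sub[tuple(idx.T)] ** 2
        refined[i] = lo + (w[:, None] * idx).sum(axis=0) / w.sum()
    return refined


def detect_markers(hierarchy: LabelHierarchy, frame: int = 0) -> MocapMarkers:
    """Adaptive local peak detection on the masked distance transform.

    Candidates are 3^d-neighborhood maxima of the distance transform (plateau
    maxima keep the lowest scan-order voxel). Candidates are then accepted
    greedily in decreasing-radius order; accepting a marker suppresses all
    remaining candidates within its exclusion radius
    ``max(min_spacing, radius_um)`` — the adaptive footprint. Every organelle
    is guaranteed at least one marker (fallback: its maximum-distance voxel).
    Accepted markers get a sub-voxel position from a distance-weighted
    centroid of their medial peak.
    """
    dist = hierarchy.distance_um
    mask = hierarchy.semantic
    spacing = np.asarray(hierarchy.spacing, dtype=float)
    if not mask.any():
        return MocapMarkers(
            frame=frame,
            coords=np.empty((0, mask.ndim), dtype=np.int64),
            radius_um=np.empty(0),
            spacing=tuple(spacing),
        )

    footprint = np.ones((3,) * mask.ndim, dtype=bool)
    local_max = ndimage.maximum_filter(dist, footprint=footprint, mode="constant")
    cand_mask = mask & (dist >= local_max) & (dist > 0)
    cand = np.argwhere(cand_mask)
    values = dist[tuple(cand.T)]
    # decreasing radius; scan order (argwhere order) breaks value ties, so
    # plateau maxima resolve to the lowest-index voxel
    order = np.argsort(-values, kind="stable")
    cand = cand[order]
    values = values[order]

    cand_um = cand * spacing
    tree = cKDTree(cand_um)
    suppressed = np.zeros(len(cand), dtype=bool)
    accepted = []
    min_sp = float(spacing.min())
    for i in range(len(cand)):
        if suppressed[i]:
            continue
        accepted.append(i)
        r_excl = max(min_sp, values[i])
        for j in tree.query_ball_point(cand_um[i], r_excl):
            if j != i:
                suppressed[j] = True

    coords = cand[accepted]
    radii = values[accepted]

    # fallback: every organelle contributes at least one marker
    olab = hierarchy.organelle_labels
    have = set(np.unique(olab[tuple(coords.T)])) if len(coords) else set()
    missing = [o for o in np.unique(olab[olab > 0]) if o not in have]
    extra_coords, extra_radii = [], []
    for oid in missing:
        d = np.where(olab == oid, dist, -1.0)
        c = np.unravel_index(np.argmax(d), d.shape)
        extra_coords.append(c)
        extra_radii.append(dist[c])
    if extra_coords:
        coords = np.vstack([coords, np.asarray(extra_coords)])
        radii = np.concatenate([radii, np.asarray(extra_radii)])

    coords = coords.astype(np.int64)
    refined = _refine_subvoxel(coords, radii, dist, olab, spacing)
    return MocapMarkers(
        frame=frame,
        coords=coords,
        radius_um=radii.astype(float),
        spacing=tuple(spacing),
        coords_refined=refined,
    )


# -- feature vectors -------------------------------------------------------

def _hu6(patch: np.ndarray) -> np.ndarray:
    """First six Hu invariants of a 2D patch, signed-log transformed.

    Raw Hu invariants span many orders of magnitude; storing
    ``sign(phi) * log10(|phi| + 1e-30)`` keeps them commensurable so no
    single invariant dominates the z-scored cost blocks.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.sum() <= 0:
        return np.zeros(6)
    mu = moments_central(patch)
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = moments_normalized(mu)
    phi = moments_hu(np.nan_to_num(nu))[:6]
    return np.sign(phi) * np.log10(np.abs(phi) + _LOG_EPS)


def _marker_patch(img: np.ndarray, coord, half_widths) -> np.ndarray:
    slices = tuple(
        slice(max(0, c - h), min(n, c + h + 1))
        for c, h, n in zip(coord, half_widths, img.shape)
    )
    return img[slices]


def marker_feature_vectors(
    markers: MocapMarkers,
    raw: np.ndarray,
    enhanced: np.ndarray,
) -> MocapMarkers:
    """Fill ``stats_vec`` and ``hu_vec`` from radius-sized bounding boxes.

    The bounding-box half-width per axis is the marker radius converted to
    voxels on that axis (box side = twice the radius), clipped to the frame.
    In 3D the Hu invariants come from maximum-intensity projections of the
    box along z, y and x (the xy, xz and yz planes).
    """
    ndim = raw.ndim
    spacing = np.asarray(markers.spacing, dtype=float)
    n = len(markers)
    stats = np.zeros((n, 4))
    hu_len = 12 if ndim == 2 else 36
    hu = np.zeros((n, hu_len))
    for i in range(n):
        half = np.maximum(1, np.ceil(markers.radius_um[i] / spacing).astype(int))
        patches = [_marker_patch(img, markers.coords[i], half) for img in (raw, enhanced)]
        for k, patch in enumerate(patches):
            stats[i, 2 * k] = patch.mean()
            stats[i, 2 * k + 1] = patch.var()
        vecs = []
        for patch in patches:
            if ndim == 2:
                vecs.append(_hu6(patch))
            else:
                for axis in range(3):  # projections: xy, xz, yz
                    vecs.append(_hu6(patch.max(axis=axis)))
        hu[i] = np.concatenate(vecs)
    markers.stats_vec = stats
    markers.hu_vec = hu
    return markers


# -- linking ---------------------------------------------------------------

@dataclass
class CostMatrix:
    """Summed z-scored cost with its admissibility mask."""

    cost: np.ndarray        # (n_t, n_t1), +inf where inadmissible
    admissible: np.ndarray  # bool
    displacement_um: np.ndarray  # (n_t, n_t1, ndim)


def _zscore_block(block: np.ndarray, admissible: np.ndarray) -> np.ndarray:
    """Z-score over admissible entries; zero-variance blocks go to all zeros."""
    out = np.zeros_like(block)
    vals = block[admissible]
    if vals.size:
        sd = vals.std()
        if sd > 0:
            out[admissible] = (vals - vals.mean()) / sd
    return out


def build_cost_matrix(
    markers_t: MocapMarkers,
    markers_t1: MocapMarkers,
    max_travel_um: float = DEFAULT_MAX_TRAVEL_UM,
    weights: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CostMatrix:
    """Distance + stats + Hu difference blocks, z-scored and summed.

    The z-scoring population is the admissible entries of this frame pair
    only, so the cost adapts to the local motion statistics.
    """
    if len(markers_t) == 0 or len(markers_t1) == 0:
        raise ValueError("both marker sets must be nonempty")
    p_t = markers_t.coords_um
    p_t1 = markers_t1.coords_um
    d_coord = cdist(p_t, p_t1)
    admissible = d_coord <= max_travel_um
    d_stats = cdist(markers_t.stats_vec, markers_t1.stats_vec)
    d_hu = cdist(markers_t.hu_vec, markers_t1.hu_vec)

    w_dist, w_stats, w_hu = weights
    cost = (
        w_dist * _zscore_block(d_coord, admissible)
        + w_stats * _zscore_block(d_stats, admissible)
        + w_hu * _zscore_block(d_hu, admissible)
    )
    cost = np.where(admissible, cost, np.inf)
    disp = p_t1[None, :, :] - p_t[:, None, :]
    return CostMatrix(cost=cost, admissible=admissible, displacement_um=disp)


def link_best_match(
    cm: CostMatrix,
    markers_t: MocapMarkers,
    markers_t1: MocapMarkers,
) -> Tuple[LinkageSet, LinkageSet]:
    """Row-wise and column-wise admissible minima -> forward/backward links.

    No global assignment solve: each marker independently takes its best
    admissible match (ties to the lowest index), and the two directions are
    computed separately.
    """
    pair = (markers_t.frame, markers_t1.frame)

    def _direction(cost, disp, n_src, direction):
        src, tgt, costs, disps, unmatched = [], [], [], [], []
        for i in range(n_src):
            row = cost[i]
            if np.isfinite(row).any():
                j = int(np.argmin(row))  # ties -> lowest index
                src.append(i)
                tgt.append(j)
                costs.append(row[j])
                disps.append(disp[i, j])
            else:
                unmatched.append(i)
        d = np.asarray(disps).reshape(len(src), -1) if src else np.empty((0, disp.shape[-1]))
        return LinkageSet(
            direction=direction,
            frame_pair=pair,
            source=np.asarray(src, dtype=np.int64),
            target=np.asarray(tgt, dtype=np.int64),
            cost=np.asarray(costs, dtype=float),
            displacement_um=d,
            unmatched=np.asarray(unmatched, dtype=np.int64),
        )

    forward = _direction(cm.cost, cm.displacement_um, len(markers_t), "forward")
    backward = _direction(
        cm.cost.T, -np.swapaxes(cm.displacement_um, 0, 1), len(markers_t1), "backward"
    )
    return forward, backward
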