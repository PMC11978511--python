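"""End-to-end orchestration: load -> enhance -> segment -> track -> features.

The analysis pipeline itself is fully deterministic — the only random draws
anywhere live in the synthetic scene generator's rendering, controlled by
its seed — so identical configuration yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import features as feat
from .flow import FlowInterpolator, propagate_tracks
from .imaging_io import ImageStack, load_stack, select_slices, write_outputs
from .mocap import (
    DEFAULT_MAX_TRAVEL_UM,
    build_cost_matrix,
    detect_markers,
    link_best_match,
    marker_feature_vectors,
)
from .preprocess import DEFAULT_R_MAX_UM, DEFAULT_R_MIN_UM, derive_scales, structure_enhance
from .segment import build_hierarchy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every parameter that affects pipeline outputs, with defaults.

    Serialized verbatim into the run manifest so a run is reproducible from
    its own outputs.
    """

    input_path: Optional[str] = None
    dim_order: Optional[str] = None
    spacing: Optional[Tuple[float, ...]] = None
    frame_interval: Optional[float] = None
    channel: Optional[int] = None
    t_start: Optional[int] = None
    t_end: Optional[int] = None
    r_min_um: float = DEFAULT_R_MIN_UM
    r_max_um: float = DEFAULT_R_MAX_UM
    n_scales: Optional[int] = None
    min_size_um: float = 0.0
    max_travel_um: float = DEFAULT_MAX_TRAVEL_UM
    cost_weights: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    aggregation_stats: Tuple[str, ...] = ("mean", "std", "min", "max", "median", "sum")
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


@dataclass
class PipelineResult:
    """In-memory products of a run (written to disk by ``run_pipeline``)."""

    stack: ImageStack
    enhanced: list
    hierarchies: list
    markers: list
    forward_links: list
    backward_links: list
    forward_interps: list
    backward_interps: list
    tables: dict
    tracks: list
    manifest: dict = field(default_factory=dict)


def _markers_dataframe(markers_list) -> pd.DataFrame:
    rows = []
    for m in markers_list:
        ndim = m.coords.shape[1]
        for i in range(len(m)):
            row = {"frame": m.frame, "marker_id": i}
            for a, ax in enumerate("zyx"[-ndim:]):
                row[ax] = int(m.coords[i, a])
            row["radius_um"] = float(m.radius_um[i])
            if m.stats_vec is not None:
                row.update({f"stats_{k}": m.stats_vec[i, k] for k in range(m.stats_vec.shape[1])})
            if m.hu_vec is not None:
                row.update({f"hu_{k}": m.hu_vec[i, k] for k in range(m.hu_vec.shape[1])})
            rows.append(row)
    return pd.DataFrame(rows)


def _links_dataframe(all_links, markers_list) -> pd.DataFrame:
    rows = []
    for links in all_links:
        t0, _ = links.frame_pair
        ndim = links.displacement_um.shape[1] if len(links) else 3
        for k in range(len(links)):
            row = {
                "frame": t0,
                "direction": links.direction,
                "source_id": int(links.source[k]),
                "target_id": int(links.target[k]),
                "cost": float(links.cost[k]),
            }
            for a, ax in enumerate("zyx"[-ndim:]):
                row[f"d{ax}"] = float(links.displacement_um[k, a])
            rows.append(row)
    return pd.DataFrame(rows)


def _tracks_dataframe(tracks, spacing) -> pd.DataFrame:
    spacing = np.asarray(spacing, dtype=float)
    ndim = len(spacing)
    rows = []
    for tr in tracks:
        for f, c in zip(tr.frames, tr.coords):
            row = {"track_id": tr.track_id, "frame": int(f)}
            for a, ax in enumerate("zyx"[-ndim:]):
                row[ax] = float(c[a])
                row[f"{ax}_um"] = float(c[a] * spacing[a])
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_stack(stack: ImageStack, config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full analysis on an in-memory stack."""
    config = config or PipelineConfig()
    t_total = time.perf_counter()
    scales = derive_scales(stack.spacing, config.r_min_um, config.r_max_um, config.n_scales)
    dt = stack.interval_or_default

    enhanced, hierarchies, markers = [], [], []
    for t, frame in enumerate(stack.frames()):
        t0 = time.perf_counter()
        ef = structure_enhance(np.asarray(frame, dtype=np.float64), scales)
        h = build_hierarchy(ef, stack.spacing, min_size_um=config.min_size_um)
        m = detect_markers(h, frame=t)
        m = marker_feature_vectors(m, np.asarray(frame, dtype=np.float64), ef.response)
        enhanced.append(ef)
        hierarchies.append(h)
        markers.append(m)
        logger.info(
            "frame %d: %d organelles, %d branches, %d nodes, %d markers (%.2fs)",
            t, h.n_organelles, h.n_branches, h.n_nodes, len(m), time.perf_counter() - t0,
        )

    fwd_links, bwd_links, fwd_interps, bwd_interps = [], [], [], []
    for t in range(stack.n_frames - 1):
        if len(markers[t]) and len(markers[t + 1]):
            cm = build_cost_matrix(
                markers[t], markers[t + 1], config.max_travel_um, config.cost_weights
            )
            f, b = link_best_match(cm, markers[t], markers[t + 1])
        else:
            from .mocap import LinkageSet

            ndim = stack.ndim_spatial
            empty = lambda d: LinkageSet(  # noqa: E731
                direction=d, frame_pair=(t, t + 1),
                source=np.empty(0, dtype=np.int64), target=np.empty(0, dtype=np.int64),
                cost=np.empty(0), displacement_um=np.empty((0, ndim)),
                unmatched=np.arange(len(markers[t] if d == "forward" else markers[t + 1])),
            )
            f, b = empty("forward"), empty("backward")
        fwd_links.append(f)
        bwd_links.append(b)
        fwd_interps.append(FlowInterpolator(f, markers[t], config.max_travel_um))
        bwd_interps.append(FlowInterpolator(b, markers[t + 1], config.max_travel_um))

    t0 = time.perf_counter()
    raw = [np.asarray(f, dtype=np.float64) for f in stack.frames()]
    enh = [e.response for e in enhanced]
    voxel_df = feat.voxel_features(
        hierarchies, raw, enh,
        fwd_interps if fwd_interps else None,
        bwd_interps if bwd_interps else None,
        frame_interval=dt,
    )
    node_df = feat.node_features(
        hierarchies, fwd_interps if fwd_interps else None, voxel_df, frame_interval=dt
    )
    branch_df = feat.branch_features(hierarchies)
    organelle_df = feat.organelle_features(hierarchies)
    # cross-level aggregates onto branch and organelle rows
    motility_cols = [c for c in voxel_df.columns if "vel" in c or "acc" in c or "directionality" in c]
    agg_cols = motility_cols + ["intensity_raw", "intensity_enhanced"]
    stats = config.aggregation_stats
    if len(branch_df):
        agg = feat.aggregate_features(voxel_df, "voxel", ["frame", "branch_id"], agg_cols, stats)
        branch_df = branch_df.merge(agg, on=["frame", "branch_id"], how="left")
    if len(organelle_df):
        agg = feat.aggregate_features(voxel_df, "voxel", ["frame", "organelle_id"], agg_cols, stats)
        organelle_df = organelle_df.merge(agg, on=["frame", "organelle_id"], how="left")
        if len(branch_df):
            bcols = ["branch_length", "branch_radius", "branch_tortuosity", "branch_aspect_ratio"]
            agg_b = feat.aggregate_features(branch_df, "branch", ["frame", "organelle_id"], bcols, stats)
            organelle_df = organelle_df.merge(agg_b, on=["frame", "organelle_id"], how="left")
    tables = {
        "voxel": voxel_df,
        "node": node_df,
        "branch": branch_df,
        "organelle": organelle_df,
    }
    tables["image"] = feat.image_features(tables)
    logger.info("feature extraction: %.2fs", time.perf_counter() - t0)

    tracks = []
    if fwd_interps and hierarchies[0].semantic.any():
        seeds = np.argwhere(hierarchies[0].semantic).astype(float)
        tracks = propagate_tracks(seeds, fwd_interps, hierarchies[0].semantic.shape, t0=0)

    logger.info("pipeline total: %.2fs", time.perf_counter() - t_total)
    return PipelineResult(
        stack=stack,
        enhanced=enhanced,
        hierarchies=hierarchies,
        markers=markers,
        forward_links=fwd_links,
        backward_links=bwd_links,
        forward_interps=fwd_interps,
        backward_interps=bwd_interps,
        tables=tables,
        tracks=tracks,
    )


def run_pipeline(config: PipelineConfig, stack: Optional[ImageStack] = None) -> dict:
    """Load (unless given), analyze and write everything; return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if stack is None:
        if config.input_path is None:
            raise ValueError("config.input_path or an in-memory stack is required")
        stack = load_stack(
            config.input_path,
            dim_order_override=config.dim_order,
            spacing_override=config.spacing,
            interval_override=config.frame_interval,
        )
    if stack.has_channels or config.t_start is not None or config.t_end is not None:
        stack = select_slices(stack, config.channel, config.t_start, config.t_end)

    result = analyze_stack(stack, config)
    out_dir = Path(config.output_dir or "organellometry_run")
    markers_df = _markers_dataframe(result.markers)
    links_df = _links_dataframe(result.forward_links + result.backward_links, result.markers)
    tracks_df = _tracks_dataframe(result.tracks, stack.spacing)
    manifest = write_outputs(
        out_dir,
        stack,
        result.hierarchies,
        markers_df=markers_df,
        links_df=links_df,
        tracks_df=tracks_df,
        tables=result.tables,
        config=config.to_dict(),
    )
    feat.feature_dictionary().to_csv(out_dir / "feature_dictionary.csv", index=False)
    result.manifest = manifest
    return manifest
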