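"""Reading and writing microscopy stacks with axis and voxel-size metadata.

Stacks are held in a canonical ``(T, Z, Y, X)`` order (singleton axes where a
dimension is absent) so every downstream stage can index frames uniformly.
Spacing is physical voxel size in micrometres, ``(dz, dy, dx)`` for volumetric
data and ``(dy, dx)`` for single-plane data; the frame interval is in seconds.

Metadata is inferred from OME-XML when present, falling back to ImageJ tags;
user overrides beat both. Spacing is mandatory — the structural enhancement
filter is spacing-adaptive, so a stack without a voxel size cannot be
processed meaningfully.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

CANONICAL_AXES = "TZYX"


class MetadataError(ValueError):
    """Raised when stack metadata is missing or inconsistent."""


@dataclass
class ImageStack:
    """An intensity stack in canonical (T, Z, Y, X) order.

    Parameters
    ----------
    data : ndarray
        Canonical array. Shape is ``(T, Z, Y, X)`` for channel-free data; if a
        channel axis is present (before :func:`select_slices`) the shape is
        ``(T, C, Z, Y, X)``.
    spacing : tuple of float
        ``(dz, dy, dx)`` in micrometres; ``(dy, dx)`` for 2D data.
    frame_interval : float or None
        Seconds per frame; ``None`` for single-frame data.
    axes : str
        Source axis-order string (e.g. ``"TZYX"``, ``"TYX"``, ``"YX"``),
        possibly containing ``"C"`` before channel selection.
    source_path : str
        Provenance of the data.
    validation : dict
        Report of inferred vs used metadata values and missing fields.
    """

    data: np.ndarray
    spacing: tuple
    frame_interval: Optional[float]
    axes: str
    source_path: str = ""
    validation: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be positive, got {self.spacing}")
        expected = 5 if "C" in self.axes else 4
        if self.data.ndim != expected:
            raise MetadataError(
                f"canonical data must be {expected}D for axes {self.axes!r}, "
                f"got shape {self.data.shape}"
            )
        if self.n_frames > 1 and self.frame_interval is not None and self.frame_interval <= 0:
            raise MetadataError("frame_interval must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def has_channels(self) -> bool:
        return "C" in self.axes

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def is_2d(self) -> bool:
        return len(self.spacing) == 2

    @property
    def ndim_spatial(self) -> int:
        return len(self.spacing)

    @property
    def interval_or_default(self) -> float:
        """Frame interval, defaulting to 1.0 s (velocities then per frame)."""
        return 1.0 if self.frame_interval is None else self.frame_interval

    def frame(self, t: int) -> np.ndarray:
        """Spatial array at frame ``t``: (Z, Y, X) in 3D, (Y, X) in 2D."""
        if self.has_channels:
            raise MetadataError("select a channel before per-frame access")
        vol = self.data[t]
        return vol[0] if self.is_2d else vol

    def frames(self) -> Iterator[np.ndarray]:
        for t in range(self.n_frames):
            yield self.frame(t)

    def to_source_order(self) -> np.ndarray:
        """Return the data permuted back to the source axis order."""
        canon = "T" + ("C" if self.has_channels else "") + "ZYX"
        arr = self.data
        # drop canonical singleton axes absent from the source
        keep = [i for i, ax in enumerate(canon) if ax in self.axes]
        arr = arr.reshape([arr.shape[i] for i in keep])
        present = "".join(ax for ax in canon if ax in self.axes)
        return np.transpose(arr, [present.index(ax) for ax in self.axes])


def _canonicalize(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute ``data`` with source ``axes`` into canonical order.

    The permutation is lossless and invertible (``to_source_order``).
    """
    axes = axes.upper()
    if len(axes) != data.ndim:
        raise MetadataError(
            f"axis string {axes!r} inconsistent with array rank {data.ndim}"
        )
    if len(set(axes)) != len(axes) or not set(axes) <= set("TCZYX"):
        raise MetadataError(f"invalid axis string {axes!r}")
    if "Y" not in axes or "X" not in axes:
        raise MetadataError(f"axis string {axes!r} must contain Y and X")
    canon = "T" + ("C" if "C" in axes else "") + "ZYX"
    order = [axes.index(ax) for ax in canon if ax in axes]
    arr = np.transpose(data, order)
    # insert singleton axes for missing dims
    for i, ax in enumerate(canon):
        if ax not in axes:
            arr = np.expand_dims(arr, i)
    return arr


def _infer_tiff_metadata(tif: tifffile.TiffFile) -> dict:
    """Pull axes / spacing / interval from OME-XML, then ImageJ tags."""
    inferred: dict = {"axes": None, "spacing": {}, "frame_interval": None, "source": None}
    series = tif.series[0] if tif.series else None
    if series is not None and series.axes:
        inferred["axes"] = "".join(ax for ax in series.axes if ax in "TCZYX")

    if tif.is_ome and tif.ome_metadata:
        try:
            meta = tifffile.xml2dict(tif.ome_metadata)
            image = meta.get("OME", {}).get("Image")
            if isinstance(image, list):
                image = image[0]
            pixels = (image or {}).get("Pixels", {})
            for key, tag in (("z", "PhysicalSizeZ"), ("y", "PhysicalSizeY"), ("x", "PhysicalSizeX")):
                if tag in pixels:
                    inferred["spacing"][key] = float(pixels[tag])
            if "TimeIncrement" in pixels:
                inferred["frame_interval"] = float(pixels["TimeIncrement"])
            inferred["source"] = "ome"
        except Exception:  # malformed OME block: fall through to ImageJ
            logger.warning("failed to parse OME metadata; trying ImageJ tags")

    if inferred["source"] is None and tif.is_imagej and tif.imagej_metadata:
        ij = tif.imagej_metadata
        page = tif.pages[0]
        for key, tag in (("y", "YResolution"), ("x", "XResolution")):
            if tag in page.tags:
                num, den = page.tags[tag].value
                if num:
                    inferred["spacing"][key] = den / num
        if "spacing" in ij:
            inferred["spacing"]["z"] = float(ij["spacing"])
        if ij.get("finterval"):
            inferred["frame_interval"] = float(ij["finterval"])
        inferred["source"] = "imagej"
    return inferred


def load_stack(
    path,
    dim_order_override: Optional[str] = None,
    spacing_override: Optional[Sequence[float]] = None,
    interval_override: Optional[float] = None,
) -> ImageStack:
    """Load a TIFF/OME-TIFF as a canonical :class:`ImageStack`.

    Metadata precedence: overrides > OME-XML > ImageJ tags. Missing spacing
    with no override is a hard error. Missing frame interval on a timelapse
    defaults to 1.0 s with a warning (velocities then read per frame).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            inferred = _infer_tiff_metadata(tif)
    except (FileNotFoundError, tifffile.TiffFileError, OSError) as exc:
        raise MetadataError(f"cannot read {path}: {exc}") from exc

    axes = (dim_order_override or inferred["axes"] or "").upper()
    if not axes:
        raise MetadataError(
            f"{path}: no axis order in metadata; pass dim_order_override"
        )
    data = _canonicalize(data, axes)

    is_2d = "Z" not in axes
    spacing_keys = ("y", "x") if is_2d else ("z", "y", "x")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
        if len(spacing) != len(spacing_keys):
            raise MetadataError(
                f"spacing_override needs {len(spacing_keys)} values for axes {axes!r}"
            )
    else:
        missing = [k for k in spacing_keys if k not in inferred["spacing"]]
        if missing:
            raise MetadataError(
                f"{path}: voxel spacing for axes {missing} missing from metadata "
                "and no spacing_override given; the structural filter is "
                "spacing-adaptive and cannot run without it"
            )
        spacing = tuple(inferred["spacing"][k] for k in spacing_keys)

    n_frames = data.shape[0]
    interval = interval_override if interval_override is not None else inferred["frame_interval"]
    if n_frames > 1 and interval is None:
        warnings.warn(
            f"{path}: timelapse without frame interval; defaulting to 1.0 s "
            "(velocities are then per frame)",
            stacklevel=2,
        )
        interval = 1.0
    if n_frames == 1:
        interval = None

    validation = {
        "inferred": inferred,
        "used": {"axes": axes, "spacing": spacing, "frame_interval": interval},
        "missing": [k for k in spacing_keys if k not in inferred["spacing"]],
        "overridden": {
            "axes": dim_order_override is not None,
            "spacing": spacing_override is not None,
            "frame_interval": interval_override is not None,
        },
    }
    return ImageStack(
        data=data,
        spacing=spacing,
        frame_interval=interval,
        axes=axes,
        source_path=str(path),
        validation=validation,
    )


def select_slices(
    stack: ImageStack,
    channel: Optional[int] = None,
    t_start: Optional[int] = None,
    t_end: Optional[int] = None,
) -> ImageStack:
    """Restrict to one channel and a half-open frame range ``[t_start, t_end)``."""
    if stack.has_channels:
        if channel is None:
            raise MetadataError("stack has a channel axis; a channel index is required")
        if not 0 <= channel < stack.data.shape[1]:
            raise IndexError(f"channel {channel} out of range")
        data = stack.data[:, channel]
        axes = stack.axes.replace("C", "")
    else:
        if channel is not None:
            raise MetadataError("channel given for channel-less data")
        data = stack.data
        axes = stack.axes

    t0 = 0 if t_start is None else t_start
    t1 = data.shape[0] if t_end is None else t_end
    if not (0 <= t0 < t1 <= data.shape[0]):
        raise IndexError(f"empty or out-of-range frame selection [{t0}, {t1})")
    data = data[t0:t1]
    interval = stack.frame_interval if data.shape[0] > 1 else None
    return ImageStack(
        data=data,
        spacing=stack.spacing,
        frame_interval=interval,
        axes=axes,
        source_path=stack.source_path,
        validation=stack.validation,
    )


# -- output writing --------------------------------------------------------

def write_label_image(path, array: np.ndarray, spacing, axes: str = "TZYX",
                      frame_interval: Optional[float] = None) -> None:
    """Write a label (or float) stack as OME-TIFF carrying voxel spacing."""
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) == 2:
        spacing = (1.0,) + spacing
    meta = {
        "axes": axes,
        "PhysicalSizeZ": spacing[0],
        "PhysicalSizeY": spacing[1],
        "PhysicalSizeX": spacing[2],
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
    }
    if frame_interval is not None:
        meta["TimeIncrement"] = float(frame_interval)
        meta["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, array, ome=True, metadata=meta)


def read_label_image(path) -> tuple:
    """Round-trip companion to :func:`write_label_image` -> (array, spacing)."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        inferred = _infer_tiff_metadata(tif)
    sp = inferred["spacing"]
    spacing = tuple(sp.get(k, 1.0) for k in ("z", "y", "x"))
    return arr, spacing


def write_outputs(
    run_dir,
    stack: ImageStack,
    hierarchies,
    markers_df=None,
    links_df=None,
    tracks_df=None,
    tables: Optional[dict] = None,
    config: Optional[dict] = None,
) -> dict:
    """Write all pipeline products under ``run_dir`` and return a manifest.

    Label images (semantic / organelle / branch / node-assignment) go out as
    OME-TIFF stacks with spacing metadata; markers, links, tracks and feature
    tables as CSV; the manifest (files, parameters, software version) as JSON.
    Writing is deterministic for a fixed config and seed.

    Single-frame runs get no links/tracks files (morphology-only analysis).
    """
    from . import __version__

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    files: dict = {}

    shapes = {h.semantic.shape for h in hierarchies}
    if len(shapes) > 1:
        raise ValueError(f"frames have mismatched shapes: {shapes}")

    def _stack4d(arrays, dtype):
        arr = np.stack([np.asarray(a, dtype=dtype) for a in arrays])
        if arr.ndim == 3:  # 2D frames
            arr = arr[:, None]
        return arr

    label_specs = {
        "semantic": (np.uint8, [h.semantic for h in hierarchies]),
        "organelle": (np.uint32, [h.organelle_labels for h in hierarchies]),
        "branch": (np.uint32, [h.branch_labels for h in hierarchies]),
        "node_assignment": (
            np.uint32,
            [np.where(h.node_assignment >= 0, h.node_assignment + 1, 0) for h in hierarchies],
        ),
    }
    for name, (dtype, arrays) in label_specs.items():
        p = run_dir / f"labels_{name}.ome.tif"
        write_label_image(p, _stack4d(arrays, dtype), stack.spacing)
        files[f"labels_{name}"] = p.name

    csvs = {}
    if markers_df is not None and len(markers_df):
        csvs["markers"] = markers_df
    if stack.n_frames > 1:
        if links_df is not None and len(links_df):
            csvs["links"] = links_df
        if tracks_df is not None and len(tracks_df):
            csvs["tracks"] = tracks_df
    for level, df in (tables or {}).items():
        if df is not None:
            csvs[f"features_{level}"] = df
    for name, df in csvs.items():
        p = run_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.9g")
        files[name] = p.name

    manifest = {
        "software": "organellometry",
        "version": __version__,
        "source": stack.source_path,
        "n_frames": stack.n_frames,
        "spacing_um": list(stack.spacing),
        "frame_interval_s": stack.frame_interval,
        "config": config or {},
        "files": files,
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = "manifest.json"
    return manifest
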