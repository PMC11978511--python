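"""Shared fixtures: small rendered scenes and analyzed pipeline results.

Everything is generated programmatically and seeded; session scope keeps the
expensive end-to-end runs to one apiece.
"""

from __future__ import annotations

import numpy as np
import pytest

from organellometry.pipeline import analyze_stack
from organellometry.synthgen import (
    SceneObject,
    SceneSpec,
    blob_field_scene,
    build_scene,
    default_tube_blob_scene,
    render_timelapse,
)

S = 0.15  # um, isotropic 2D spacing used by most fixtures


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def tube_blob_scene():
    """Mixed-size tube+blob segmentation scene, SNR 10, drifting 0.5 vox/frame."""
    spec = default_tube_blob_scene(snr=10.0, n_frames=4, translation_vox_per_frame=0.5)
    gt = build_scene(spec)
    stack = render_timelapse(gt)
    return spec, gt, stack


@pytest.fixture(scope="session")
def tube_blob_result(tube_blob_scene):
    _, gt, stack = tube_blob_scene
    return gt, analyze_stack(stack)


@pytest.fixture(scope="session")
def blob_field_result():
    """Blob tracking field, 0.5 vox/frame diagonal drift, 6 frames."""
    spec = blob_field_scene(snr=10.0, translation_vox_per_frame=0.5, n_frames=6)
    gt = build_scene(spec)
    stack = render_timelapse(gt)
    return spec, gt, analyze_stack(stack)


@pytest.fixture(scope="session")
def static_result():
    """A statically duplicated scene: all motion features must vanish."""
    spec = SceneSpec(
        shape=(3, 96, 96),
        spacing=(S, S),
        objects=[
            SceneObject("blob", {"center": (30 * S, 30 * S), "radius": 4 * S}, 100.0),
            SceneObject(
                "tube",
                {"p1": (65 * S, 20 * S), "p2": (65 * S, 70 * S), "radius": 2.5 * S},
                100.0,
            ),
        ],
        psf_sigma_um=S,
        poisson=False,
        gaussian_sd=0.0,
        background=10.0,
        seed=0,
    )
    gt = build_scene(spec)
    stack = render_timelapse(gt)
    return gt, analyze_stack(stack)


def make_plus_scene(n_frames: int = 1):
    """Two crossing tubes: one junction cluster, four tips, four branches."""
    objs = [
        SceneObject(
            "tube", {"p1": (48 * S, 12 * S), "p2": (48 * S, 84 * S), "radius": 2 * S}, 100.0
        ),
        SceneObject(
            "tube", {"p1": (12 * S, 48 * S), "p2": (84 * S, 48 * S), "radius": 2 * S}, 100.0
        ),
    ]
    return SceneSpec(
        shape=(n_frames, 96, 96), spacing=(S, S), objects=objs,
        psf_sigma_um=S, poisson=False, gaussian_sd=0.0, background=10.0, seed=0,
    )


def make_y_scene():
    """Three tubes meeting at a point: three branches, three tips."""
    c = (48 * S, 48 * S)
    import math

    objs = []
    for ang in (math.pi / 2, math.pi * 7 / 6, math.pi * 11 / 6):
        end = (48 * S + 30 * S * math.sin(ang), 48 * S + 30 * S * math.cos(ang))
        objs.append(SceneObject("tube", {"p1": c, "p2": end, "radius": 2 * S}, 100.0))
    return SceneSpec(
        shape=(1, 96, 96), spacing=(S, S), objects=objs,
        psf_sigma_um=S, poisson=False, gaussian_sd=0.0, background=10.0, seed=0,
    )


def analyze_scene(spec):
    gt = build_scene(spec)
    stack = render_timelapse(gt)
    return gt, stack, analyze_stack(stack)


@pytest.fixture(scope="session")
def plus_result():
    return analyze_scene(make_plus_scene())


@pytest.fixture(scope="session")
def y_result():
    return analyze_scene(make_y_scene())
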