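# organellometry

Organelle-agnostic segmentation, label-independent sub-voxel tracking and
hierarchical feature extraction for fluorescence microscopy timelapses —
2D (xy) or 3D (xyz) stacks with optional time and channel axes, read from
TIFF/OME-TIFF with voxel-size metadata.

Quantifying organelle dynamics (mitochondria, ER, Golgi, peroxisomes, ...)
runs into two coupled problems: per-frame instance segmentations are
unstable over time, so object-identity tracking is brittle; and a single
"object" is the wrong unit anyway — a membrane network is simultaneously a
set of disconnected components, their branches, their skeleton nodes and
their voxels. This package addresses both:

1. **Spacing-adaptive structural enhancement.** A multiscale Hessian filter
   with scales specified in micrometres and converted per axis to voxel
   sigmas (anisotropic sampling handled automatically). At each scale σ the
   response is `1 − exp(−S²/2γ²)` under a bright-structure eigenvalue sign
   condition, with `S` the Frobenius norm of the σ²-normalized Hessian
   eigenvalues and `γ` recomputed per scale as half the maximal `S` — so
   dim and bright, small and large, tubular and rounded structures are all
   enhanced to comparable strength, with zero manual parameters.
2. **Hierarchical deconstruction.** Combined Otsu/triangle thresholding,
   full-connectivity instance labels, topology-preserving skeletonization,
   junction detection, branch decomposition and a k-d-tree assignment of
   every mask voxel to its nearest same-organelle skeleton node — an exact
   partition at every level (organelle → branch → node → voxel).
3. **Motion-capture-marker tracking.** Markers are sub-voxel-refined local
   maxima of the distance transform (label independent). Each marker gets a
   stats vector (mean/variance of raw and enhanced intensity in a
   radius-sized box) and a Hu vector (first six Hu moment invariants; xy/xz/yz
   projections in 3D). Frame-to-frame links take the per-marker best match
   of a z-scored distance + stats + Hu cost (no global assignment), and a
   distance- and cost-weighted combination of nearby link vectors
   interpolates a displacement for *any* coordinate — whole organelles,
   branches, voxels or sub-voxel points.
4. **Multilevel features and graphs.** Per-voxel kinematics (speeds,
   pivot-relative linear/angular velocities and accelerations,
   centre-of-mass directionality), node thickness and flow vergence, branch
   length/tortuosity/aspect ratio, organelle volume/solidity/inertia
   eigenvalues, cross-level aggregates (`{child}_{stat}_{feature}`), skeleton
   graphs with degree/betweenness/cyclomatic topology metrics, and
   power-of-two multi-mesh adjacencies ready for graph learning.

A deterministic synthetic-scene generator (`organellometry.synthgen`) with
analytic ground truth — masks, skeletons, dense flow — underpins the test
suite and the acceptance metrics.

## Worked example

```python
import numpy as np
from organellometry.synthgen import blob_field_scene, build_scene, render_timelapse
from organellometry.pipeline import analyze_stack
from organellometry.flow import propagate_tracks

# a field of nine round organelles (radii 2-5 voxels) drifting rigidly at
# 0.5 voxel/frame, Poisson + read noise, SNR 10
spec = blob_field_scene(snr=10.0, translation_vox_per_frame=0.5, n_frames=6, seed=0)
gt = build_scene(spec)                  # analytic ground truth
stack = render_timelapse(gt)            # noisy ImageStack
result = analyze_stack(stack)           # full pipeline, defaults only

h = result.hierarchies[0]
print(f"frame 0: {h.n_organelles} organelles, {h.n_nodes} skeleton nodes, "
      f"{len(result.markers[0])} mocap markers")

organelle = result.tables["organelle"]
print(organelle[organelle.frame == 0][
    ["organelle_id", "area", "solidity", "extent"]].round(3).to_string(index=False))

voxel = result.tables["voxel"]
print(f"mean voxel speed: {np.nanmean(voxel['lin_vel_mag_12']):.4f} um/s")

seeds = np.argwhere(h.semantic).astype(float)[::10]
tracks = propagate_tracks(seeds, result.forward_interps, h.semantic.shape, t0=0)
step = 0.5 * 5 / np.sqrt(2)
errs = [np.linalg.norm(t.coords[-1] - (s + step))
        for t, s in zip(tracks, seeds) if t.frames[-1] == 5]
print(f"mean 5-frame track endpoint error: {np.mean(errs):.3f} voxels")
```

prints

```
frame 0: 9 organelles, 21 skeleton nodes, 10 mocap markers
 organelle_id  area  solidity  extent
            1 2.948     0.942   0.775
            2 1.012     1.000   0.918
            ...
mean voxel speed: 0.0767 um/s
mean 5-frame track endpoint error: 0.147 voxels
```

The nine blobs are recovered as nine organelles with near-unit solidity;
the mean per-voxel speed (0.0767 µm/s) matches the simulated drift
(0.5 voxel/frame × 0.15 µm/voxel = 0.075 µm/s at one frame per second), and
following every tenth mask voxel through five frames of interpolated flow
lands within 0.15 voxel of the analytic endpoint — sub-voxel tracking from
integer-grid images.

## Command line

```bash
organellometry validate image.ome.tif                 # metadata report only
organellometry run image.ome.tif --out results/       # full pipeline
organellometry simulate --spec scene.toml --out sim/  # synthetic scene + GT
organellometry graph image.ome.tif                    # topology summary
organellometry features results/ --level branch --stat mean --stat std
```

`run` writes per-frame label images (semantic, organelle, branch,
node-assignment) as OME-TIFF with spacing metadata, markers/links/tracks and
the five per-level feature tables as CSV, a data dictionary, and a JSON
manifest embedding the full configuration — reruns with the same
configuration are byte-identical.

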