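# Methods

This note documents the models and algorithms the package implements, the
choices made where the design was genuinely open, and the limits of what the
synthetic benchmarks demonstrate.

## Structural enhancement

The enhancement is a multiscale Hessian filter. For each scale σ (in
micrometres) the image is convolved with Gaussian derivative kernels whose
per-axis widths are σ divided by the voxel spacing on that axis, so physical
isotropy is preserved on anisotropic grids. Second derivatives are converted
to per-µm² units and multiplied by σ² (γ-normalized derivatives), making
responses comparable across scales. With eigenvalues λ₁ ≤ … sorted by
magnitude, the response at a voxel is

    R_σ = 1 − exp(−S² / 2γ²)   if λ₂ < 0 (2D), λ₂ < 0 and λ₃ < 0 (3D)
    R_σ = 0                    otherwise

where S = √Σλᵢ² is the Frobenius norm ("structureness") and γ is half the
maximum S over the frame *at this scale* — never shared across scales. The
final response is the voxel-wise maximum over scales.

Two classical vesselness ingredients are deliberately absent:

- the plate penalty R_a, and
- the blob penalty `exp(−R_b²/2β²)` with R_b = |λ₁|/√|λ₂λ₃|.

R_b ≈ 1 at the centre of any rounded structure, so retaining it multiplies
blob interiors by e⁻² and segments them as rings. Since the filter must be
organelle-agnostic — puncta and spheroids as well as tubules — both
geometric selectivity terms are dropped; the brightness condition and the
per-scale adaptive structureness do the discriminating. For users who want
classic curvilinear-only enhancement, `hessian_response_at_scale` accepts a
`blobness_beta` that restores the R_b factor.

The per-scale γ is a deliberate trade-off: it amplifies whichever scale is
locally strongest, which rescues dim or small structures, at the cost of a
halo around structures much smaller than the largest scale. The default
radius range (0.25–1.0 µm, log-spaced, one scale per octave,
`max(2, ceil(log2(r_max/r_min)) + 1)` scales) targets the size range of
typical organelles in diffraction-limited light microscopy; scales whose
smallest per-axis sigma falls below 0.25 voxel are unrepresentable on the
grid and dropped. Derivative filtering uses reflect padding; the frame mean
is subtracted first so that a uniform intensity offset changes nothing
(sampled derivative kernels do not sum exactly to zero).

## Thresholding and hierarchy

The semantic threshold is computed on a 256-bin histogram of the *nonzero*
response values, as the **larger** of the Otsu and triangle thresholds. The
two estimators guard each other: the response histogram is an L-shaped
spike-plus-tail on which the triangle threshold collapses into the noise
spike (accepting the halo and roughly halving the Dice), while Otsu can
fail when the foreground fraction is tiny. Components below `min_size_um`
(default: anything smaller than two voxels) are removed.

Organelles are full-connectivity connected components (8-connected in 2D,
26-connected in 3D), labeled deterministically in scan order. The mask is
thinned by topology-preserving medial-axis skeletonization; any organelle
the thinning erases contributes its maximum-distance voxel instead, so every
organelle owns at least one skeleton node. Skeleton voxels with more than
two neighbors are junctions, with exactly one are tips; branches are the
connected components of the skeleton minus junctions, and each junction
voxel is then attached to its lowest-labeled adjacent branch (iterating
into junction-cluster interiors) so that every skeleton voxel carries a
branch label. Every skeleton voxel is a node carrying the anisotropic
Euclidean distance transform value (µm) as its local radius. Finally, every
mask voxel is assigned to the nearest node of its own organelle through a
per-organelle k-d tree in physical coordinates — the levels partition the
mask exactly, which the tests assert voxel-for-voxel. Nothing in this module
is stochastic.

## Motion-capture markers

Markers are local maxima of the masked distance transform, accepted
greedily in decreasing-radius order with an exclusion radius of
`max(one voxel, local radius)` — thick regions yield sparse markers, thin
tubules dense ones. Accepted markers are refined to sub-voxel positions as
the distance²-weighted centroid of the medial peak within the footprint
(restricted to the marker's organelle). This refinement is what makes link
displacement vectors sub-voxel quantities: without it a track riding a
marker inherits an irreducible ~0.7-voxel quantization error.

Each marker's appearance is summarized by a 4-component stats vector (mean
and variance of raw and enhanced intensity inside a bounding box of
half-width = radius per axis) and a Hu vector: the first six Hu moment
invariants of the raw and the enhanced patch (12 values in 2D; in 3D the
invariants of the xy, xz and yz maximum-intensity projections, 36 values).
Invariants are stored as `sign(φ)·log₁₀(|φ| + 1e−30)`; the raw invariants
span ~15 orders of magnitude and would otherwise dominate or vanish in the
z-scored cost.

Linking computes three difference matrices over marker pairs within
`max_travel_um` (default 1.0 µm/frame, ~one organelle radius per second at
1 Hz): physical distance, stats-vector distance, Hu-vector distance. Each
block is z-scored over the admissible entries of the current frame pair
(adapting to local motion statistics) and summed with configurable weights
(default 1,1,1). Each marker then takes its row-wise (forward) or
column-wise (backward) admissible minimum — deliberately not a global
assignment solve, so 1-to-1, 1-to-n and n-to-1 matches all arise, and a
marker's link never depends on distant markers.

## Flow interpolation and tracks

A coordinate of interest (CoI) receives the weighted sum of nearby link
vectors with weights

    w_k ∝ 1/(d_k + ε) · 1/(c_k − c_min + ε),   ε = 1e−6,

normalized to 1 (so the result is a convex combination and identical link
vectors are reproduced exactly); c_min is the minimum cost among the
contributing links, keeping the best link's weight finite even for negative
z-scored costs. A link contributes to CoIs within `max_travel + its
marker's radius`: the marker speaks for the region within its own radius.
Without this variable range, structures thicker than the travel bound would
contain voxels with no support at all, because marker spacing scales with
the same radius. CoIs with no link in range keep a zero vector
(conservative: unmoved, never extrapolated) with support 0.

Tracks advance seeds frame by frame at fractional (sub-voxel) precision,
forward from their seed frame and optionally backward to frame 0; rounding
to the grid happens only in voxel-fate matching, where each voxel's
displaced position is matched to the containing next-frame mask voxel, else
to the nearest mask voxel within one voxel per axis, else flagged
unmatched.

## Features

All lengths are µm, times s, angles rad. Per voxel, positions at t−1, t,
t+1 come from backward and forward interpolated flow; `_01` and `_12`
suffix the two intervals and accelerations need both (boundary frames carry
NaN in the affected columns; single-frame runs omit motility columns
entirely). Pivot-relative (`rel_`) kinematics subtract the motion of the
branch's reference point — the skeleton node nearest the branch's voxel
centroid at frame t, advanced to t±1 by interpolated flow — separating
voxel-own motion from bulk branch motion; `ref_` features are the pivot's
own kinematics; `rel_ang_vel` is the angle swept by the pivot-relative
position vector per second. `com_directionality` is the branch-mean cosine
between each voxel's velocity and its outward radial from the
intensity-weighted centre of mass of the frame's mask (positive = moving
away).

Node thickness is twice the local radius. Vergence is the local divergence
rate of the surrounding flow: the mean over the node's assigned voxels of
the radial component of the relative flow divided by the radial distance
(1/s), so a field expanding at rate k reads +k.

Branch length is the total weight of the minimum spanning tree of the
branch's skeleton-voxel adjacency graph with physical edge lengths (this
avoids double-counting diagonal shortcuts); endpoints are the farthest leaf
pair (double BFS); tortuosity = length / end-to-end distance (1.0 for
single-node branches); aspect ratio = length / (2 × mean node radius) — a
definition choice, documented here because "aspect ratio" is ambiguous.
Organelle morphology (volume, extent, solidity, inertia-tensor eigenvalues
sorted ascending, axis lengths) comes from `skimage.measure.regionprops`
with physical spacing; degenerate convex hulls yield NaN solidity rather
than an error.

Aggregates are named `{child_level}_{stat}_{feature}` with stats from
{mean, std, min, max, median, sum}; they nest (a branch's nodes' mean voxel
speed variability is two applications), and the image level aggregates
every lower level into one row per frame.

## Graphs and multi-mesh

The skeleton graph contracts junction clusters to single nodes, keeps tips
as nodes, and adds one edge per branch — a multigraph, because collapsing
parallel edges or self-loops would corrupt the cyclomatic number of a
genuinely loopy membrane network. An isolated closed loop becomes one node
with one self-loop. Betweenness centrality is shortest-path betweenness
normalized by 2/((n−1)(n−2)); the cyclomatic number is E − N + C and its
normalized form divides by N (configurable to per-component counts).

The multi-mesh orders one organelle's skeleton nodes by depth-first
traversal from the lexicographically smallest degree-1 voxel (fallback: the
smallest-coordinate node), children visited in lexicographic order — fully
deterministic. Level 0 contains every consecutive-traversal pair plus every
skeleton-adjacency edge; level ℓ ≥ 1 connects stride-aligned indices k·2^ℓ
and (k+1)·2^ℓ; a path of 2^k+1 nodes therefore has levels with 2^k, …, 1
edges. Per-node feature vectors (z-scored per organelle-timelapse) export
alongside the sparse edge list for downstream graph-learning code.

## Synthetic scenes

The generator rasterizes capsules (tubes, optionally with sinusoidal
varicosity), circular arcs, ellipsoidal blobs and hexagonal tubular lattice
patches from analytic signed distance functions evaluated at voxel centres,
applies per-object rigid motion (translation and in-plane rotation about a
pivot) analytically, and renders with anti-aliased coverage, Gaussian PSF
blur, a Poisson photon draw and additive Gaussian read noise — photon-count
physics, so SNR = √intensity at object voxels. Objects can carry a
material-attached sinusoidal intensity texture (label heterogeneity /
varicosities) that co-moves rigidly. Ground truth — instance masks,
centreline points, dense displacement fields, kinematics — is computed
pre-noise and is exact. A single seed fixes every random draw; the analysis
pipeline itself contains no randomness, so identical configuration gives
byte-identical outputs.

Two canonical scenes serve as benchmarks. The *segmentation scene* mixes
tubes of radius 1.5–6 voxels with blobs, spanning the default filter range;
Dice against ground truth is ≥ 0.9 at SNR 5–20 with defaults only. The
*tracking scene* is a field of nine well-separated blobs of radii 2–5
voxels under rigid translation or rotation; translation endpoint error over
5 frames is ~0.1–0.2 voxel at 0.25–1 voxel/frame, rotation at 0.05
rad/frame tracks within ~0.7 voxel. Problem sizes (≈160² pixels, 4–6
frames) are chosen so the full benchmark battery completes in well under a
minute while leaving hundreds of objects/voxels per estimate.

### What the benchmarks do not show

- **Tracking along featureless tubes.** The motion of a homogeneous
  straight tube along its own axis is unobservable to any local tracker
  (the aperture problem), and even transverse to it, distance-transform
  markers on a flat medial ridge are not locked to material points — their
  frame-to-frame jitter puts medium/long textureless tubes at ~0.5–1.5
  voxel endpoint error regardless of weighting or footprint choices. Real
  tubules carry persistent intensity texture that mitigates this; the
  synthetic sinusoidal texture is a weaker cue than real varicosity
  patterns. Tracking accuracy is therefore certified on round/compact
  structures, where the medial peak is material-locked.
- **Speed floor.** Per-frame voxel speeds are magnitudes of noisy vectors
  and inherit a positive bias of roughly σ²/2v; at 0.2 voxel/frame this
  bias is ~10% at SNR 10, so the speed-recovery benchmark runs at SNR 20
  where it is ~2%. Angular-rate recovery uses the median over voxels more
  than 1.5 µm from the pivot (the lever arm vanishes near it), averaged
  over three simulated replicates.
- **Biology.** No fission/fusion, no photobleaching, no focus drift, no
  sheet-like (large-minor-axis) organelles — the filter segments the rims
  of structures much larger than `r_max`, a known limitation shared with
  the approach it implements.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `r_min_um`, `r_max_um` | 0.25, 1.0 | target structure radius range, µm |
| `n_scales` | per octave | `max(2, ceil(log2(r_max/r_min)) + 1)` |
| `min_size_um` | 0 | remove only single-voxel specks |
| `max_travel_um` | 1.0 | admissible marker travel per frame, µm |
| `cost_weights` | (1, 1, 1) | distance / stats / Hu block weights |
| frame interval fallback | 1.0 s | velocities read per frame if metadata lacks it (warned) |

All of these are exposed in `PipelineConfig`, serialized into the run
manifest, and testable in isolation through the module functions.
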