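# Methods

This note documents the models, conventions and numerical choices behind
`vesselnet`, in the spirit of a software methods section: what each stage
computes, which knobs matter, what the synthetic phantoms do and do not
emulate, and where genuinely open design points were fixed.

## Data model

A volume is a 3D intensity grid indexed `(z, y, x)` — page order of the
TIFF stack — with a physical voxel pitch `(dz, dy, dx)` in µm. Calibration
comes from ImageJ-style TIFF metadata (resolution tags for x/y, `spacing`
for z) and may be overridden by the caller; an image without either is
rejected rather than silently assumed isotropic, because lengths and
per-mm³ densities depend on it. Connectivity conventions are fixed
throughout: foreground 26-connected, background 6-connected — the standard
complementary pair that avoids topological paradoxes in 3D.

## Preprocessing

Stage order is fixed (downscale → brightness window → background
subtraction → blur) and deliberately not configurable, to remove a silent
source of irreproducibility between runs and labs.

- **Downscaling** (`scale_xy`, default 1.0): local-mean area resampling of
  x and y only; the voxel pitch is scaled inversely so physical extents
  are preserved. Halving x/y is a practical way to cut memory on large
  stacks at little cost to network topology.
- **Brightness window** (`brightness_min`/`max`, default 0/255): an
  explicit linear window with clipping, mapping `≤ low → 0` and
  `≥ high → full scale`, with round-half-to-even rounding (the 8-bit
  window (100, 200) maps 150 → 128). An explicit window was chosen over
  auto-contrast so that a parameter file fully determines the output.
  Lowering `high` boosts weakly fluorescing vessels at the risk of
  saturating (and fusing) bright ones.
- **Background subtraction** (`background_radius`, default off): classic
  per-slice 2D rolling-ball estimation, subtracted and clipped at zero.
  Useful when background fluorescence varies smoothly across the field;
  off by default because it is only conditionally beneficial.
- **Gaussian blur** (`gaussian_sigma`, default (2, 2, 2) voxels):
  separable convolution, reflective boundaries, kernel truncated at 4σ.
  σ is given per axis in voxels because z-stacks are commonly anisotropic;
  a scalar broadcasts. The blur is the main defense against falsely
  fragmented segmentation of vessels with heterogeneous fill; too large a
  σ fuses fine detail (fewer skeletons/segments), too small or absent a σ
  leaves fragments (more skeletons/segments). Both directions are
  exercised by the tests on the fragmented phantom.

## Binarization

- **Yen threshold**: a 256-bin histogram spans the observed min..max of
  the (already windowed) volume; the returned threshold is the bin
  boundary maximizing Yen's maximum-correlation criterion
  `TC(t) = −ln(Σ_{i≤t} p_i² · Σ_{i>t} p_i²) + 2 ln(P(t)(1−P(t)))`,
  ties broken toward the lowest cut; foreground is strictly above the
  threshold. A constant image has no threshold and is an error. The
  implementation (vectorized cumulative sums) is checked against a
  brute-force per-cut evaluation of the criterion on random histograms.
- **Particle removal** (`particle_min_size`, default 5 px): per-z-slice
  2D 8-connected components with area below the threshold are deleted —
  slice-wise semantics, because that is how the classic stack-based
  particle analyzer behaves; a `particles_3d` switch provides volumetric
  removal (26-connected) instead.
- **Closing** (`closing_max_radius`/`closing_min_radius`, default
  (1, 1, 1)/(1, 1, 1)): a 3D maximum filter then minimum filter, each
  with an ellipsoidal neighborhood of independent per-axis radii (equal
  radii = morphological closing). Both filters see background outside the
  canvas; consequently closing is idempotent, and extensive except for
  structures touching the canvas border. A gap of up to twice the radius
  between fragments is bridged.
- **Hole filling**: 6-connected background components not reaching the
  volume border become foreground. Without this step, an enclosed cavity
  in the mask survives thinning as a hollow remnant and pollutes the
  skeleton with spurious loops; with it, the skeleton is loop-free for
  simply connected objects (verified via cycle ranks, below).

## Skeletonization and graph analysis

Thinning is Lee-style 6-subiteration simple-point deletion (the standard
3D medial-axis algorithm, via scikit-image), which preserves the number of
26-connected components and the cycle rank while reducing the mask to a
one-voxel-thick centerline.

Skeleton voxels are classified by their 26-neighbor count within the
mask: ≤ 1 end point, 2 slab, ≥ 3 junction (an isolated voxel is an end
point). 26-adjacent junction voxels merge into a single junction node, so
a thick crossing counts once; the reported junction count is the number of
merged clusters, not raw junction voxels. Segments are slab chains walked
between terminal voxels; each segment ends in two junctions, two end
points, or one of each. Two conventions close gaps the definition leaves
open: a pure slab cycle (a closed loop with no terminal voxel) counts as
one closed segment, and an isolated voxel is one skeleton with one end
point and one zero-length segment. Segment length is the sum of Euclidean
steps between consecutive voxel centers in calibrated µm.

**Pruning** (`prune_length`, default 4 voxels): a single pass deletes
every segment that joins an end point to a junction and is shorter than
the threshold (voxel count by default; `prune_calibrated` switches to µm),
keeping the junction voxels; the volume is then re-classified and the
graph re-extracted. Free-floating segments (two end points) are never
pruned, so isolated small structures survive regardless of threshold.
Single-pass application mirrors one run of the classic prune-ends script;
`prune_iterative` repeats until stable for users who want full cleanup of
nested spurs. Pruning at a fixed threshold is idempotent in both modes.

**Cycle rank** appears in two distinct senses in the tests, and they are
not interchangeable. Topology preservation of thinning is verified with
the first Betti number computed independently from the Euler
characteristic of the closed cubical complex (b1 = b0 + b2 − χ, with b0
from 26-connected labeling and b2 from enclosed 6-connected cavities);
the naive cycle rank of the 26-adjacency graph is wrong for this purpose
because diagonal corner contacts create spurious triangles in thick
objects. The adjacency-graph cycle rank (edges − vertices + components)
is instead the right detector of loop artifacts in *thin* skeletons: it
is 0 for clean tree-shaped centerlines, 1 for a true ring, and large for
the hollow remnant left by an unfilled cavity.

## Measurements

Per image: volume fraction (foreground/total voxels of the mask); network
length as the skeleton voxel count, also divided by the imaged volume in
mm³ (`(nz·dz)(ny·dy)(nx·dx) × 10⁻⁹`); counts of skeletons, segments,
junctions, end points; and per-segment lengths in µm. The calibrated total
length (Σ segment lengths) is emitted as an additional clearly labeled
column — the primary length unit stays voxel-based. Densities are
computed against the full imaged bounding volume, not a hull of the
specimen; note this makes
densities sensitive to empty padding, which is intended. Count
normalization to per-mm³ for cross-image comparison is a separate explicit
step (`normalize_counts`).

## Validation and statistics

**Overlap scoring**: the fraction of produced-skeleton voxels inside the
ground-truth mask, in percent. Because both structures are one voxel
thick, the ground truth can be dilated `r` rounds (3×3×3 element by
default, configurable to the 6-neighborhood) to tolerate small
displacements; the ground truth's voxel-count increase is reported
alongside so the stringency of each round is visible. Overlap is monotone
non-decreasing in dilation rounds.

**Mann–Whitney U**: two-sided. When the smaller group has ≤ 8 values —
the regime of typical organoid experiments (n = 2–9) — the permutation
null distribution of U is computed exactly over all C(nₐ+n_b, nₐ)
labelings by dynamic programming on doubled midranks (integers even under
ties), and p = min(1, 2·min(P(U ≤ u), P(U ≥ u))). Larger samples use the
normal approximation with tie-corrected variance and continuity
correction. The exact branch is verified against full enumeration with
direct pair counting; the asymptotic branch against an independent
library implementation.

**Bonferroni**: the per-test level is α*/m with α* = 0.05 by default; the
family size m is supplied by the caller per analysis family rather than
guessed, because the correct family depends on the experimental design
(e.g. a parameter that provably cannot affect one measurement is dropped
from that measurement's family).

**Glass's Δ** = |x̄₁ − x̄₂| / σ₂ with σ₂ the *control* group's sample
standard deviation (n − 1 denominator, the conventional estimator for
Glass's Δ). Categories: Δ ≤ 0.2 low, 0.2 < Δ ≤ 0.5 medium, Δ > 0.5 high;
boundaries are inclusive on the low side. Δ is invariant to common shifts
and common positive scaling of both groups.

## Synthetic phantoms

A phantom is a set of centerline polylines (one per intended segment) with
per-path tube radii; tubes are all voxels within the radius of the
centerline (anisotropy-aware Euclidean distance; the radius is in units of
the x pitch). The intensity model emulates the image traits the pipeline
must cope with: foreground mean × a smooth low-frequency multiplicative
heterogeneity field (seeded 5³ noise upsampled by cubic spline, amplitude
±15 % by default), constant background mean, optional additive Gaussian
noise, a weak-vessel variant (low foreground mean), and fragmentation
(centerline spans cut before rendering — the visible gap is the cut span
minus two cap radii, since tube ends are rounded).

Ground-truth counts come from the generative centerline graph — nodes are
merged path endpoints, junctions are nodes of degree ≥ 3, end points
degree 1, segments are the paths — *not* from re-analysis of the rendered
volume, so generator and analyzer are independent and the truth is a
genuine oracle.

The fixed battery (`make_test_suite`) holds seven phantoms at 96³ voxels,
1 µm isotropic, 8-bit, foreground 200 / background 20: straight tube,
Y-bifurcation, H-network (two junctions), two disjoint networks, closed
loop (cycle rank 1), fragmented tube (radius-3 tube, two 9-voxel
centerline cuts ≈ 3-voxel visible gaps — wide enough that closing alone
cannot bridge them but the default blur can, narrow enough that an
oversized blur still does), and a weak tube (foreground 70). The canvas
size keeps every test at seconds scale while leaving room for distinct
junctions; radii ≥ 2.5 voxels and ~90° branch angles keep the thinned
junction a single merged cluster.

What the phantoms deliberately do **not** emulate: optical
point-spread-function anisotropy, depth-dependent attenuation,
autofluorescent debris, and touching non-vessel structures. Passing the
phantom battery therefore demonstrates correctness of the algorithms and
their composition under controlled corruption — not segmentation quality
on any particular microscope's data, which still requires per-dataset
parameter tuning and visual control of the returned binary and skeleton
images against the raw stack.

## Parameter diagnostics

When tuning on real data: check the binary image against the raw image for
the brightness window (all vessels present, small structures not fused);
check the skeleton for blur σ and the closing radii (no fragmented or
spurious segments in irregular regions); small disconnected artifacts in
the binary or skeleton indicate a too-low particle threshold; short
terminal stubs on the skeleton indicate a too-low prune length. The
shipped defaults segment the bundled phantoms exactly and are meant as a
starting point for screening, not as optimal for any real dataset.

## Determinism and degenerate inputs

Every stage is deterministic: fixed stage order, deterministic scan order
in graph walking, ties in the Yen criterion broken toward the lowest
threshold, seeded generators in the phantoms. Two identical batch runs
produce byte-identical CSVs. Degenerate inputs fail loudly where a result
would be meaningless (constant image at thresholding, empty skeleton at
overlap scoring, zero control variance at Glass's Δ) and are well-defined
elsewhere (empty mask through closing/filling/thinning, zero-length
segments, prune threshold 0 = identity).
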