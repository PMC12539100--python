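"""Synthetic 3D vessel phantoms with known ground-truth topology.

A phantom is described by centerline polylines (voxel coordinates, one
polyline per network segment), per-path tube radii, and an intensity model
emulating confocal stacks of stained vasculature: nonhomogeneous
within-vessel fluorescence (smooth low-frequency multiplicative field),
uniform background fluorescence, additive Gaussian noise, weakly
fluorescing vessels (low foreground mean), and fragmented vessels
(centerline spans cut out before tube rendering).

Ground truth — tube mask, centerline skeleton and the exact
skeleton/segment/junction/end-point counts — is derived from the centerline
graph *before* corruption, so the generator is an oracle independent of the
analysis code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import BinaryVolume, VolumeImage
from .io import write_volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "render_phantom",
    "make_test_suite",
    "write_phantom",
]

TRUTH_FIELDS = ("n_skeletons", "n_segments", "n_junctions", "n_endpoints")


@dataclass
class PhantomSpec:
    """Generative description of one synthetic vessel network."""

    centerlines: list  # list of (k, 3) float arrays, (z, y, x) voxel coords
    radii: list  # tube radius per path, in units of the x voxel pitch
    canvas_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    foreground_intensity: float = 200.0
    background_intensity: float = 20.0
    intensity_heterogeneity: float = 0.15
    noise_sd: float = 0.0
    fragmentation_gaps: list = field(default_factory=list)  # (path_id, start, length) voxels
    seed: int = 0
    bit_depth: int = 8
    name: str = "phantom"

    def __post_init__(self) -> None:
        self.centerlines = [np.asarray(c, dtype=np.float64) for c in self.centerlines]
        if len(self.radii) != len(self.centerlines):
            raise ValueError("need one radius per centerline path")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground mean must exceed background mean")
        if not (0.0 <= self.intensity_heterogeneity < 1.0):
            raise ValueError("intensity_heterogeneity must be in [0, 1)")
        shape = np.array(self.canvas_shape)
        for path, r in zip(self.centerlines, self.radii):
            if path.ndim != 2 or path.shape[1] != 3:
                raise ValueError("each centerline must be a (k, 3) array")
            if np.any(path < r) or np.any(path > shape - 1 - r):
                raise ValueError(
                    f"centerline must stay within the canvas with margin >= radius {r}"
                )


@dataclass
class PhantomTruth:
    """Exact ground truth of a phantom, from the generative graph."""

    mask: BinaryVolume  # rendered (unfragmented) tubes
    skeleton_gt: BinaryVolume  # rasterized centerline voxels
    n_skeletons: int
    n_segments: int
    n_junctions: int
    n_endpoints: int
    segment_lengths: list[float]  # µm


def _sample_polyline(path: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Dense points along a polyline plus their arc position (voxel units)."""
    pts = [path[0]]
    arc = [0.0]
    total = 0.0
    for a, b in zip(path[:-1], path[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        for i in range(1, n + 1):
            pts.append(a + (b - a) * (i / n))
            arc.append(total + seg * (i / n))
        total += seg
    out = np.array(pts)
    return np.column_stack([out, np.array(arc)])


def _rasterize(points: np.ndarray, shape) -> np.ndarray:
    """Boolean volume of the voxels nearest to the given points."""
    vol = np.zeros(shape, dtype=bool)
    idx = np.rint(points).astype(int)
    idx = np.clip(idx, 0, np.array(shape) - 1)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return vol


def _tube_from_centerline(centerline_mask: np.ndarray, radius: float, voxel_size) -> np.ndarray:
    if not centerline_mask.any():
        return np.zeros_like(centerline_mask)
    dist = ndimage.distance_transform_edt(~centerline_mask, sampling=voxel_size)
    return dist <= radius * voxel_size[2]


def _truth_from_graph(spec: PhantomSpec) -> tuple[int, int, int, int, list[float]]:
    """Counts from the centerline graph: nodes are path endpoints (merged when
    coincident), edges are the paths; a path whose ends coincide is a loop."""
    nodes: list[np.ndarray] = []

    def node_id(p: np.ndarray) -> int:
        for i, q in enumerate(nodes):
            if np.linalg.norm(p - q) < 0.5:
                return i
        nodes.append(p)
        return len(nodes) - 1

    edges = []
    lengths = []
    vs = np.asarray(spec.voxel_size)
    for path in spec.centerlines:
        a, b = node_id(path[0]), node_id(path[-1])
        edges.append((a, b))
        steps = np.diff(path, axis=0) * vs
        lengths.append(float(np.sqrt((steps**2).sum(axis=1)).sum()))

    degree = np.zeros(len(nodes), dtype=int)
    for a, b in edges:
        if a == b:
            degree[a] += 2
        else:
            degree[a] += 1
            degree[b] += 1

    # connected components over nodes (isolated loop edges connect a==b)
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    n_skeletons = len({find(i) for i in range(len(nodes))})

    # a pure loop path with both ends at a free node is a closed segment,
    # and its node is neither a junction nor an end point
    n_junctions = int((degree >= 3).sum())
    n_endpoints = int((degree == 1).sum())
    n_segments = len(edges)
    return n_skeletons, n_segments, n_junctions, n_endpoints, lengths


def _heterogeneity_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1 − a, 1 + a], low spatial frequency."""
    if amplitude == 0:
        return np.ones(shape)
    coarse = rng.standard_normal((5, 5, 5))
    zoom = [s / 5 for s in shape]
    fine = ndimage.zoom(coarse, zoom, order=3)
    fine = fine[: shape[0], : shape[1], : shape[2]]
    peak = np.abs(fine).max()
    if peak > 0:
        fine = fine / peak
    return 1.0 + amplitude * fine


def render_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Render a phantom to a calibrated intensity volume plus its truth."""
    shape = spec.canvas_shape
    rng = np.random.default_rng(spec.seed)

    gaps_by_path: dict[int, list[tuple[float, float]]] = {}
    for path_id, start, length in spec.fragmentation_gaps:
        gaps_by_path.setdefault(int(path_id), []).append((float(start), float(length)))

    clean_tube = np.zeros(shape, dtype=bool)
    corrupt_tube = np.zeros(shape, dtype=bool)
    skeleton_gt = np.zeros(shape, dtype=bool)
    for i, (path, radius) in enumerate(zip(spec.centerlines, spec.radii)):
        samples = _sample_polyline(path)
        pts, arc = samples[:, :3], samples[:, 3]
        cl_mask = _rasterize(pts, shape)
        skeleton_gt |= cl_mask
        tube = _tube_from_centerline(cl_mask, radius, spec.voxel_size)
        clean_tube |= tube
        keep = np.ones(len(pts), dtype=bool)
        for start, length in gaps_by_path.get(i, []):
            keep &= ~((arc >= start) & (arc <= start + length))
        if keep.all():
            corrupt_tube |= tube
        elif keep.any():
            corrupt_tube |= _tube_from_centerline(
                _rasterize(pts[keep], shape), radius, spec.voxel_size
            )

    field_arr = _heterogeneity_field(shape, spec.intensity_heterogeneity, rng)
    img = np.full(shape, spec.background_intensity, dtype=np.float64)
    img[corrupt_tube] = (spec.foreground_intensity * field_arr)[corrupt_tube]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)
    max_int = (1 << spec.bit_depth) - 1
    img = np.clip(np.rint(img), 0, max_int)
    voxels = img.astype(np.uint8 if spec.bit_depth == 8 else np.uint16)

    n_skel, n_seg, n_junc, n_end, lengths = _truth_from_graph(spec)
    truth = PhantomTruth(
        mask=BinaryVolume(clean_tube, voxel_size=spec.voxel_size),
        skeleton_gt=BinaryVolume(skeleton_gt, voxel_size=spec.voxel_size),
        n_skeletons=n_skel,
        n_segments=n_seg,
        n_junctions=n_junc,
        n_endpoints=n_end,
        segment_lengths=lengths,
    )
    image = VolumeImage(voxels, bit_depth=spec.bit_depth, voxel_size=spec.voxel_size)
    return image, truth


def _suite_specs(seed: int, noise_sd: float) -> list[PhantomSpec]:
    z = 48.0
    common = dict(noise_sd=noise_sd)
    specs = [
        PhantomSpec(
            name="straight_tube",
            centerlines=[[(z, 48, 8), (z, 48, 88)]],
            radii=[3.0],
            seed=seed + 1,
            **common,
        ),
        PhantomSpec(
            name="y_bifurcation",
            centerlines=[
                [(z, 48, 8), (z, 48, 48)],
                [(z, 48, 48), (z, 16, 80)],
                [(z, 48, 48), (z, 80, 80)],
            ],
            radii=[3.0, 3.0, 3.0],
            seed=seed + 2,
            **common,
        ),
        PhantomSpec(
            name="h_network",
            centerlines=[
                [(z, 28, 8), (z, 28, 48)],
                [(z, 28, 48), (z, 28, 88)],
                [(z, 68, 8), (z, 68, 48)],
                [(z, 68, 48), (z, 68, 88)],
                [(z, 28, 48), (z, 68, 48)],
            ],
            radii=[3.0] * 5,
            seed=seed + 3,
            **common,
        ),
        PhantomSpec(
            name="disjoint_pair",
            centerlines=[
                [(30.0, 30, 8), (30.0, 30, 88)],
                [(66.0, 8, 66), (66.0, 88, 66)],
            ],
            radii=[3.0, 3.0],
            seed=seed + 4,
            **common,
        ),
        PhantomSpec(
            name="loop",
            centerlines=[_circle_polyline(center=(z, 48, 48), radius=28.0, n=64)],
            radii=[2.5],
            seed=seed + 5,
            **common,
        ),
        PhantomSpec(
            name="fragmented_tube",
            centerlines=[[(z, 48, 8), (z, 48, 88)]],
            radii=[3.0],
            fragmentation_gaps=[(0, 22.0, 9.0), (0, 51.0, 9.0)],
            seed=seed + 6,
            **common,
        ),
        PhantomSpec(
            name="low_contrast_tube",
            centerlines=[[(z, 8, 48), (z, 88, 48)]],
            radii=[3.0],
            foreground_intensity=70.0,
            seed=seed + 7,
            **common,
        ),
    ]
    return specs


def _circle_polyline(center, radius: float, n: int) -> np.ndarray:
    cz, cy, cx = center
    theta = np.linspace(0.0, 2.0 * np.pi, n + 1)
    return np.column_stack(
        [np.full(n + 1, cz), cy + radius * np.sin(theta), cx + radius * np.cos(theta)]
    )


def make_test_suite(
    seed: int = 0, noise_sd: float = 0.0
) -> list[tuple[VolumeImage, PhantomTruth, PhantomSpec]]:
    """The fixed seven-phantom battery covering every pipeline stage.

    Straight tube, Y-bifurcation, H-network (2 junctions), two disjoint
    networks (2 skeletons), closed loop (cycle rank 1), fragmented tube,
    and a weakly fluorescing low-contrast tube — each on a 96³ canvas of
    1 µm voxels.  Noise-free by default; pass ``noise_sd`` to corrupt.
    """
    out = []
    for spec in _suite_specs(seed, noise_sd):
        image, truth = render_phantom(spec)
        out.append((image, truth, spec))
    return out


def write_phantom(
    pair: tuple[VolumeImage, PhantomTruth],
    directory,
    name: str = "phantom",
) -> dict[str, Path]:
    """Write raw TIFF, ground-truth skeleton TIFF and truth CSV to disk."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"directory not found: {directory}")
    image, truth = pair
    paths = {
        "raw": directory / f"{name}.tif",
        "skeleton_gt": directory / f"{name}_gt_skeleton.tif",
        "truth": directory / f"{name}_truth.csv",
    }
    write_volume(image, paths["raw"])
    write_volume(truth.skeleton_gt, paths["skeleton_gt"])
    with open(paths["truth"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", *TRUTH_FIELDS, "total_length_um"])
        writer.writerow(
            [
                name,
                *(getattr(truth, f) for f in TRUTH_FIELDS),
                sum(truth.segment_lengths),
            ]
        )
    return paths
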