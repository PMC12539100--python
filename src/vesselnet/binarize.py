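"""Binarization: Yen threshold, artifact removal, 3D closing, hole filling.

Connectivity conventions used throughout: foreground 26-connected,
background 6-connected (the standard complementary pair in 3D).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BinaryVolume, VolumeImage
from .params import PipelineParams

__all__ = [
    "yen_criterion",
    "yen_threshold",
    "remove_small_particles",
    "close_3d",
    "fill_holes_3d",
    "binarize_pipeline",
    "volume_fraction",
    "ellipsoid_footprint",
]

N_BINS = 256


def yen_criterion(hist: np.ndarray) -> np.ndarray:
    """Yen's maximum-correlation criterion for every cut of a histogram.

    For a normalized histogram ``p`` and a cut after bin ``t`` (foreground =
    bins > t) the criterion is

        TC(t) = -ln( Σ_{i≤t} p_i² · Σ_{i>t} p_i² ) + 2·ln( P(t) · (1 − P(t)) )

    with ``P(t) = Σ_{i≤t} p_i``.  Returns the criterion for t = 0 .. nbins−2;
    cuts with an empty side get −inf.
    """
    hist = np.asarray(hist, dtype=np.float64)
    p = hist / hist.sum()
    P = np.cumsum(p)
    P_sq = np.cumsum(p**2)
    total_sq = P_sq[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(P_sq[:-1] * (total_sq - P_sq[:-1])) + 2.0 * np.log(
            P[:-1] * (1.0 - P[:-1])
        )
    crit[~np.isfinite(crit)] = -np.inf
    return crit


def yen_threshold(image: VolumeImage) -> float:
    """Automatic threshold by Yen's criterion on a 256-bin histogram.

    The histogram spans the observed min..max of the volume; the returned
    value is the intensity at the bin boundary maximizing the criterion
    (ties broken toward the lowest threshold).  Foreground voxels are those
    strictly above the threshold.
    """
    v = image.voxels
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise ValueError("constant image: no threshold exists")
    hist, edges = np.histogram(v, bins=N_BINS, range=(vmin, vmax))
    crit = yen_criterion(hist)
    t = int(np.argmax(crit))  # argmax takes the first (lowest) maximizer
    return float(edges[t + 1])


def _drop_small_components(mask: np.ndarray, min_pixels: int, structure: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_pixels
    keep[0] = False
    return keep[labels]


def remove_small_particles(
    binary: BinaryVolume, min_pixels: int, three_d: bool = False
) -> BinaryVolume:
    """Delete small foreground components (area < ``min_pixels``).

    Default semantics are per z-slice with 2D 8-connectivity, matching the
    slice-wise behavior of ImageJ's Analyze Particles on stacks; with
    ``three_d=True`` volumetric 26-connected components are removed instead.
    """
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    if min_pixels == 0:
        return binary
    if three_d:
        out = _drop_small_components(binary.mask, min_pixels, np.ones((3, 3, 3), dtype=bool))
    else:
        eight = np.ones((3, 3), dtype=bool)
        out = np.empty_like(binary.mask)
        for z in range(binary.mask.shape[0]):
            out[z] = _drop_small_components(binary.mask[z], min_pixels, eight)
    return binary.with_mask(out)


def ellipsoid_footprint(radii) -> np.ndarray:
    """Boolean ellipsoid of per-axis radii ``(rz, ry, rx)`` (voxels).

    A zero radius collapses that axis; radii (0, 0, 0) give a single voxel.
    """
    rz, ry, rx = (int(r) for r in radii)
    if min(rz, ry, rx) < 0:
        raise ValueError(f"radii must be >= 0, got {(rz, ry, rx)}")
    zz, yy, xx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    with np.errstate(divide="ignore"):
        d2 = (
            (zz / max(rz, 1)) ** 2 * (rz > 0)
            + (yy / max(ry, 1)) ** 2 * (ry > 0)
            + (xx / max(rx, 1)) ** 2 * (rx > 0)
        )
    return d2 <= 1.0


def close_3d(binary: BinaryVolume, max_radius, min_radius) -> BinaryVolume:
    """3D maximum filter (dilation) then minimum filter (erosion).

    Each filter uses an ellipsoidal neighborhood with independent per-axis
    radii; equal radii realize a morphological closing.  Both filters see
    background outside the canvas, so closing with equal radii is idempotent
    and extensive for structures at least one radius away from the border
    (border-touching foreground can lose its outermost layer).
    """
    fp_max = ellipsoid_footprint(max_radius)
    fp_min = ellipsoid_footprint(min_radius)
    out = binary.mask
    if fp_max.sum() > 1:
        out = ndimage.binary_dilation(out, structure=fp_max, border_value=0)
    if fp_min.sum() > 1:
        out = ndimage.binary_erosion(out, structure=fp_min, border_value=0)
    return binary.with_mask(out)


def fill_holes_3d(binary: BinaryVolume) -> BinaryVolume:
    """Fill enclosed cavities: 6-connected background components that do not
    reach the volume border become foreground."""
    return binary.with_mask(ndimage.binary_fill_holes(binary.mask))


def binarize_pipeline(image: VolumeImage, params: PipelineParams) -> BinaryVolume:
    """Threshold → particle removal → 3D closing → hole filling."""
    t = yen_threshold(image)
    binary = BinaryVolume(image.voxels > t, voxel_size=image.voxel_size)
    binary = remove_small_particles(binary, params.particle_min_size, params.particles_3d)
    binary = close_3d(binary, params.closing_max_radius, params.closing_min_radius)
    binary = fill_holes_3d(binary)
    return binary


def volume_fraction(binary: BinaryVolume) -> float:
    """Foreground voxel count over total voxel count, in [0, 1]."""
    return float(binary.mask.sum() / binary.mask.size)
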