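"""Preprocessing of raw z-stacks before thresholding.

Fixed stage order: downscale → brightness window → background subtraction →
3D Gaussian blur.  The order is deliberately not configurable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball
from skimage.transform import downscale_local_mean

from .core import VolumeImage
from .params import PipelineParams

__all__ = [
    "downscale_xy",
    "rescale_brightness",
    "subtract_background",
    "gaussian_blur_3d",
    "preprocess_pipeline",
]


def downscale_xy(image: VolumeImage, factor: float) -> VolumeImage:
    """Downscale x and y by ``factor`` in (0, 1] with local-mean area resampling.

    The z axis is untouched; dy and dx are divided by ``factor`` so physical
    extents are preserved.  Output extents round down, minimum 1 voxel.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return image
    nz, ny, nx = image.shape
    block = int(round(1.0 / factor))
    out = downscale_local_mean(image.voxels.astype(np.float64), (1, block, block))
    # downscale_local_mean pads partial blocks with zeros; crop to full blocks
    out = out[:, : max(ny // block, 1), : max(nx // block, 1)]
    out = np.clip(np.rint(out), 0, image.max_intensity).astype(image.voxels.dtype)
    dz, dy, dx = image.voxel_size
    return VolumeImage(out, bit_depth=image.bit_depth, voxel_size=(dz, dy * block, dx * block))


def rescale_brightness(image: VolumeImage, low: float, high: float) -> VolumeImage:
    """Linear window map: clip((v - low)/(high - low)) × full scale.

    Values ≤ ``low`` map to 0, values ≥ ``high`` to the full intensity range.
    Rounding is round-half-to-even (numpy ``rint``), so for 8-bit data the
    window midpoint of (100, 200) maps to 128.
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    full = image.max_intensity
    v = image.voxels.astype(np.float64)
    scaled = np.clip((v - low) / (high - low), 0.0, 1.0) * full
    out = np.rint(scaled).astype(image.voxels.dtype)
    return image.with_voxels(out)


def subtract_background(image: VolumeImage, radius: float) -> VolumeImage:
    """Per-slice rolling-ball background subtraction, clipped at 0."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    out = np.empty_like(image.voxels)
    for z in range(image.shape[0]):
        plane = image.voxels[z]
        background = rolling_ball(plane, radius=radius)
        out[z] = np.clip(
            plane.astype(np.int64) - background.astype(np.int64), 0, image.max_intensity
        ).astype(image.voxels.dtype)
    return image.with_voxels(out)


def gaussian_blur_array(voxels: np.ndarray, sigma) -> np.ndarray:
    """Separable Gaussian convolution in float64, reflective boundaries.

    The kernel is normalized and truncated at 4σ; σ = 0 on an axis skips it.
    """
    sigma = tuple(float(s) for s in (sigma if np.iterable(sigma) else (sigma,) * 3))
    if len(sigma) != 3:
        raise ValueError("sigma must be a (σz, σy, σx) triple or a scalar")
    if any(s < 0 for s in sigma):
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    return ndimage.gaussian_filter(
        np.asarray(voxels, dtype=np.float64), sigma=sigma, mode="reflect", truncate=4.0
    )


def gaussian_blur_3d(image: VolumeImage, sigma) -> VolumeImage:
    """3D Gaussian blur of a volume; output rounded back to the input dtype.

    ``sigma`` is ``(σz, σy, σx)`` in voxels; 0 on an axis means no smoothing
    on that axis.
    """
    blurred = gaussian_blur_array(image.voxels, sigma)
    if np.array_equal(blurred, image.voxels):
        return image
    out = np.clip(np.rint(blurred), 0, image.max_intensity).astype(image.voxels.dtype)
    return image.with_voxels(out)


def preprocess_pipeline(image: VolumeImage, params: PipelineParams) -> VolumeImage:
    """Apply the full preprocessing chain in the fixed order."""
    out = downscale_xy(image, params.scale_xy)
    out = rescale_brightness(out, params.brightness_min, params.brightness_max)
    if params.background_radius is not None:
        out = subtract_background(out, params.background_radius)
    out = gaussian_blur_3d(out, params.gaussian_sigma)
    return out
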