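"""Core calibrated-volume containers.

All grids are indexed ``(z, y, x)``, 0-based — plane order matches TIFF page
order.  ``voxel_size`` is always the ``(dz, dy, dx)`` physical pitch in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeImage", "BinaryVolume"]


def _check_voxel_size(voxel_size: tuple[float, float, float]) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3:
        raise ValueError("voxel_size must be a (dz, dy, dx) triple")
    if any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size components must be > 0, got {vs}")
    return vs  # type: ignore[return-value]


@dataclass
class VolumeImage:
    """A calibrated 3D intensity grid (a fluorescence z-stack).

    Parameters
    ----------
    voxels:
        3D array of intensities, shape ``(nz, ny, nx)``.
    bit_depth:
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    voxel_size:
        ``(dz, dy, dx)`` in µm per voxel, all > 0.
    """

    voxels: np.ndarray
    bit_depth: int = 8
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D (z, y, x) array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        self.voxel_size = _check_voxel_size(self.voxel_size)
        vmin, vmax = float(self.voxels.min()), float(self.voxels.max())
        if vmin < 0 or vmax > self.max_intensity:
            raise ValueError(
                f"intensities [{vmin}, {vmax}] outside [0, {self.max_intensity}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        """New image sharing bit depth and calibration."""
        return VolumeImage(voxels, bit_depth=self.bit_depth, voxel_size=self.voxel_size)

    def volume_mm3(self) -> float:
        """Imaged bounding volume in mm³ (µm³ × 1e-9)."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.voxel_size
        return nz * dz * ny * dy * nx * dx * 1e-9


@dataclass
class BinaryVolume:
    """A calibrated 3D boolean mask of vessel voxels."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 3D (z, y, x) array")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def with_mask(self, mask: np.ndarray) -> "BinaryVolume":
        return BinaryVolume(mask, voxel_size=self.voxel_size)

    def count(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self) -> float:
        nz, ny, nx = self.shape
        dz, dy, dx = self.voxel_size
        return nz * dz * ny * dy * nx * dx * 1e-9
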