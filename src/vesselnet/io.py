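"""Reading and writing calibrated TIFF volumes; batch discovery.

Volumes are stored as ImageJ-style multi-page TIFFs: the x/y pitch lives in
the resolution tags and the z spacing in the ImageJ metadata, all in µm.
Binary masks are written as 8-bit 0/255 stacks.
"""

from __future__ import annotations

import fnmatch
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .core import BinaryVolume, VolumeImage

__all__ = ["read_volume", "write_volume", "discover_batch"]

_MICRON_UNITS = {"um", "µm", "\\u00b5m", "micron", "microns", "micrometer"}


def _calibration_from_tiff(tif: tifffile.TiffFile) -> Optional[tuple[float, float, float]]:
    """Extract (dz, dy, dx) in µm from ImageJ metadata + resolution tags."""
    meta = tif.imagej_metadata or {}
    unit = str(meta.get("unit", "")).lower()
    if unit and unit not in _MICRON_UNITS:
        return None
    dz = meta.get("spacing")
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    dx = xres[1] / xres[0] if xres[0] else None
    dy = yres[1] / yres[0] if yres[0] else None
    if dz is None or dx is None or dy is None:
        return None
    if dz <= 0 or dy <= 0 or dx <= 0:
        return None
    return (float(dz), float(dy), float(dx))


def read_volume(
    path: Union[str, Path],
    calibration_override: Optional[tuple[float, float, float]] = None,
) -> VolumeImage:
    """Read a single-channel multi-page TIFF as a :class:`VolumeImage`.

    Calibration precedence: explicit ``calibration_override`` (dz, dy, dx in
    µm) > TIFF metadata > error.  Multi-channel files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        if "C" in axes or "S" in axes:
            raise ValueError(f"multi-channel TIFF not supported: {path} (axes={axes})")
        voxels = series.asarray()
        if voxels.ndim == 2:
            voxels = voxels[np.newaxis]
        if voxels.ndim != 3:
            raise ValueError(f"expected a 3D single-channel stack, got axes {axes}")
        calibration = calibration_override or _calibration_from_tiff(tif)
    if calibration is None:
        raise ValueError(
            f"no voxel calibration in TIFF metadata of {path}; "
            "pass calibration_override=(dz, dy, dx) in µm"
        )
    if voxels.dtype == np.uint8:
        bit_depth = 8
    elif voxels.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported TIFF dtype {voxels.dtype}; expected uint8/uint16")
    return VolumeImage(voxels, bit_depth=bit_depth, voxel_size=calibration)


def write_volume(image: Union[VolumeImage, BinaryVolume], path: Union[str, Path]) -> None:
    """Write a volume or mask to a calibrated ImageJ-style TIFF.

    Binary volumes are stored as 8-bit 0/255.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    if isinstance(image, BinaryVolume):
        data = np.where(image.mask, 255, 0).astype(np.uint8)
    else:
        data = image.voxels.astype(np.uint8 if image.bit_depth == 8 else np.uint16)
    dz, dy, dx = image.voxel_size
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def discover_batch(directory: Union[str, Path], pattern: str = "*.tif") -> list[Path]:
    """List files in ``directory`` matching ``pattern``, lexicographically sorted."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"directory not found: {directory}")
    matches = [
        p for p in directory.iterdir()
        if p.is_file() and fnmatch.fnmatch(p.name, pattern)
    ]
    return sorted(matches, key=lambda p: p.name)
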