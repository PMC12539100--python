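"""Pipeline parameters and their YAML serialization.

The parameters mirror the knobs of the vessel-network pipeline: brightness
window, optional per-slice rolling-ball background subtraction, 3D Gaussian
blur, small-particle removal, 3D max/min (closing) filters, skeleton-end
pruning, and an optional x/y downscale factor.

The shipped defaults are this package's own choices that segment the bundled
synthetic phantoms cleanly; real microscopy data will usually need tuning
(see docs/methods.md for the diagnostic guidance per parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["PipelineParams", "load_params", "save_params"]

Triple = tuple[float, float, float]
IntTriple = tuple[int, int, int]


def _as_triple(value, name: str, cast=float) -> tuple:
    """Broadcast a scalar to (z, y, x) or validate a length-3 sequence."""
    if isinstance(value, (int, float)):
        value = (value, value, value)
    value = tuple(cast(v) for v in value)
    if len(value) != 3:
        raise ValueError(f"{name} must be a scalar or a (z, y, x) triple")
    if any(v < 0 for v in value):
        raise ValueError(f"{name} components must be >= 0, got {value}")
    return value


@dataclass
class PipelineParams:
    """Full parameter set for one pipeline run.

    Attributes
    ----------
    brightness_min, brightness_max:
        Intensity window for linear brightness rescaling; ``min < max``.
    background_radius:
        Rolling-ball radius in pixels for per-slice background subtraction;
        ``None`` skips the step (the default).
    gaussian_sigma:
        Blur σ per axis ``(σz, σy, σx)`` in voxels; a scalar broadcasts.
    particle_min_size:
        Per-slice 2D components smaller than this pixel count are removed.
    closing_max_radius, closing_min_radius:
        Per-axis ellipsoid radii (voxels) of the 3D maximum (dilation) and
        minimum (erosion) filters; equal radii realize a morphological closing.
    prune_length:
        Terminal skeleton segments shorter than this many voxels are pruned.
    prune_calibrated:
        If True, ``prune_length`` is interpreted in µm instead of voxels.
    prune_iterative:
        If True, pruning repeats until stable instead of the default single pass.
    particles_3d:
        If True, particle removal uses 3D 26-connected components instead of
        the default per-slice 2D semantics.
    scale_xy:
        Area-resampling downscale factor in (0, 1] applied to x and y first.
    """

    brightness_min: float = 0.0
    brightness_max: float = 255.0
    background_radius: Optional[float] = None
    gaussian_sigma: Triple = (2.0, 2.0, 2.0)
    particle_min_size: int = 5
    closing_max_radius: IntTriple = (1, 1, 1)
    closing_min_radius: IntTriple = (1, 1, 1)
    prune_length: float = 4.0
    prune_calibrated: bool = False
    prune_iterative: bool = False
    particles_3d: bool = False
    scale_xy: float = 1.0

    def __post_init__(self) -> None:
        if self.brightness_min >= self.brightness_max:
            raise ValueError(
                f"brightness_min ({self.brightness_min}) must be < "
                f"brightness_max ({self.brightness_max})"
            )
        if self.background_radius is not None and self.background_radius <= 0:
            raise ValueError("background_radius must be > 0 (or None to skip)")
        self.gaussian_sigma = _as_triple(self.gaussian_sigma, "gaussian_sigma")
        self.closing_max_radius = _as_triple(self.closing_max_radius, "closing_max_radius", int)
        self.closing_min_radius = _as_triple(self.closing_min_radius, "closing_min_radius", int)
        if self.particle_min_size < 0:
            raise ValueError("particle_min_size must be >= 0")
        if self.prune_length < 0:
            raise ValueError("prune_length must be >= 0")
        if not (0.0 < self.scale_xy <= 1.0):
            raise ValueError(f"scale_xy must be in (0, 1], got {self.scale_xy}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gaussian_sigma"] = list(self.gaussian_sigma)
        d["closing_max_radius"] = list(self.closing_max_radius)
        d["closing_min_radius"] = list(self.closing_min_radius)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


def load_params(path: Union[str, Path]) -> PipelineParams:
    """Load :class:`PipelineParams` from a YAML file; missing keys use defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"parameter file must contain a mapping: {path}")
    return PipelineParams.from_dict(data)


def save_params(params: PipelineParams, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
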