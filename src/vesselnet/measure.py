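"""The seven per-image network measurements.

Volume fraction comes from the binary mask; everything else from the
skeleton: total network length in voxels (skeleton voxel count) and in
voxels per mm³ of imaged volume, counts of skeletons / segments / junctions
/ end points, and the calibrated per-segment lengths in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .binarize import volume_fraction
from .core import BinaryVolume
from .skeleton import SkeletonGraph, SkeletonVolume

__all__ = ["NetworkMeasurements", "measure_network", "normalize_counts"]

_COUNT_FIELDS = ("n_skeletons", "n_segments", "n_junctions", "n_endpoints")


@dataclass
class NetworkMeasurements:
    volume_fraction: float
    network_length_voxels: int
    network_length_density: float  # voxels per mm³
    n_skeletons: int
    n_segments: int
    n_junctions: int
    n_endpoints: int
    segment_lengths: list[float] = field(default_factory=list)
    total_length_um: float = 0.0  # Σ segment lengths; extra, clearly-labeled column
    image_volume_mm3: float = 0.0

    def scalar_row(self) -> dict:
        """Flat dict for one CSV row (segment lengths go to their own table)."""
        return {
            "volume_fraction": self.volume_fraction,
            "network_length_voxels": self.network_length_voxels,
            "network_length_per_mm3": self.network_length_density,
            "n_skeletons": self.n_skeletons,
            "n_segments": self.n_segments,
            "n_junctions": self.n_junctions,
            "n_endpoints": self.n_endpoints,
            "total_length_um": self.total_length_um,
            "image_volume_mm3": self.image_volume_mm3,
        }


def measure_network(
    binary: BinaryVolume, graph: SkeletonGraph, skeleton: SkeletonVolume
) -> NetworkMeasurements:
    """Populate all measurements from one image's binary mask and skeleton."""
    if binary.shape != skeleton.shape:
        raise ValueError(f"shape mismatch: binary {binary.shape} vs skeleton {skeleton.shape}")
    if binary.voxel_size != skeleton.voxel_size:
        raise ValueError(
            f"calibration mismatch: {binary.voxel_size} vs {skeleton.voxel_size}"
        )
    vol_mm3 = binary.volume_mm3()
    n_voxels = skeleton.count()
    lengths = graph.segment_lengths
    return NetworkMeasurements(
        volume_fraction=volume_fraction(binary),
        network_length_voxels=n_voxels,
        network_length_density=n_voxels / vol_mm3,
        n_skeletons=graph.n_skeletons,
        n_segments=graph.n_segments,
        n_junctions=graph.n_junctions,
        n_endpoints=graph.n_endpoints,
        segment_lengths=lengths,
        total_length_um=float(sum(lengths)),
        image_volume_mm3=vol_mm3,
    )


def normalize_counts(measurements: NetworkMeasurements, image_volume_mm3: float) -> dict:
    """Counts per mm³ of imaged volume (for cross-image comparison)."""
    if image_volume_mm3 <= 0:
        raise ValueError("image volume must be > 0")
    return {
        f"{name}_per_mm3": getattr(measurements, name) / image_volume_mm3
        for name in _COUNT_FIELDS
    }
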