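"""The end-to-end image-processing pipeline and batch orchestration.

One image goes through three stages — preprocessing, binarization,
skeletonization — and comes out as a binary mask, a pruned skeleton with
its graph decomposition, and the seven network measurements.  Batch runs
apply the same parameters to many images, write the binary and skeleton
TIFFs plus two CSV tables, and skip (with a logged reason) images that
fail rather than aborting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .binarize import binarize_pipeline
from .core import BinaryVolume, VolumeImage
from .io import read_volume, write_volume
from .measure import NetworkMeasurements, measure_network
from .params import PipelineParams
from .preprocess import preprocess_pipeline
from .skeleton import SkeletonGraph, SkeletonVolume, extract_graph, prune_short_end_segments, thin_3d

logger = logging.getLogger("vesselnet")

__all__ = ["PipelineResult", "BatchResultTable", "process_image", "run_batch"]


@dataclass
class PipelineResult:
    binary: BinaryVolume
    skeleton: SkeletonVolume
    graph: SkeletonGraph
    measurements: NetworkMeasurements


@dataclass
class BatchResultTable:
    """Aggregate results of a batch run.

    ``measurements``: one row per successfully processed image;
    ``segment_lengths``: long table of (image_id, segment_id, length_um);
    ``failed``: image identifiers that were skipped, with reasons.
    """

    measurements: pd.DataFrame
    segment_lengths: pd.DataFrame
    failed: dict[str, str]


def process_image(image: VolumeImage, params: Optional[PipelineParams] = None) -> PipelineResult:
    """Run preprocessing, binarization and skeletonization on one volume."""
    params = params or PipelineParams()
    pre = preprocess_pipeline(image, params)
    binary = binarize_pipeline(pre, params)
    skeleton = thin_3d(binary)
    graph = extract_graph(skeleton)
    graph, skeleton = prune_short_end_segments(
        graph,
        skeleton,
        params.prune_length,
        calibrated=params.prune_calibrated,
        iterative=params.prune_iterative,
    )
    measurements = measure_network(binary, graph, skeleton)
    return PipelineResult(binary=binary, skeleton=skeleton, graph=graph, measurements=measurements)


def run_batch(
    paths: Sequence[Union[str, Path]],
    params: Optional[PipelineParams] = None,
    output_dir: Union[str, Path, None] = None,
    calibration_override: Optional[tuple[float, float, float]] = None,
) -> BatchResultTable:
    """Process every image and aggregate the measurement tables.

    For each input ``<stem>.tif`` writes ``<stem>_binary.tif`` and
    ``<stem>_skeleton.tif`` into ``output_dir`` (if given), plus
    ``measurements.csv`` and ``segment_lengths.csv``.  A failing image is
    logged and skipped; only an unwritable output directory is fatal.
    """
    params = params or PipelineParams()
    out_dir = None
    if output_dir is not None:
        out_dir = Path(output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if not out_dir.is_dir():
            raise NotADirectoryError(f"cannot use output directory: {out_dir}")

    rows = []
    length_rows = []
    failed: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        image_id = path.stem
        try:
            image = read_volume(path, calibration_override=calibration_override)
            result = process_image(image, params)
        except Exception as exc:  # per-image isolation: log and continue
            logger.warning("skipping %s: %s", path, exc)
            failed[image_id] = str(exc)
            continue
        if out_dir is not None:
            write_volume(result.binary, out_dir / f"{image_id}_binary.tif")
            write_volume(result.skeleton.as_binary(), out_dir / f"{image_id}_skeleton.tif")
        rows.append({"image_id": image_id, **result.measurements.scalar_row()})
        for seg_id, length in enumerate(result.measurements.segment_lengths):
            length_rows.append(
                {"image_id": image_id, "segment_id": seg_id, "length_um": length}
            )

    measurements = pd.DataFrame(
        rows,
        columns=[
            "image_id",
            "volume_fraction",
            "network_length_voxels",
            "network_length_per_mm3",
            "n_skeletons",
            "n_segments",
            "n_junctions",
            "n_endpoints",
            "total_length_um",
            "image_volume_mm3",
        ],
    )
    segment_lengths = pd.DataFrame(
        length_rows, columns=["image_id", "segment_id", "length_um"]
    )
    if out_dir is not None:
        measurements.to_csv(out_dir / "measurements.csv", index=False)
        segment_lengths.to_csv(out_dir / "segment_lengths.csv", index=False)
    return BatchResultTable(
        measurements=measurements, segment_lengths=segment_lengths, failed=failed
    )
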