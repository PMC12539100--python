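"""Segmentation-quality evaluation against a ground-truth skeleton.

A manually drawn (or synthetic) ground-truth skeleton is compared with the
pipeline's skeleton by the fraction of produced skeleton voxels falling
inside the ground truth.  Because both are thin structures, the ground
truth is optionally dilated a few rounds to tolerate one-voxel
displacements; the overlap is reported alongside the ground truth's area
increase so the stringency of each round is visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryVolume
from .skeleton import SkeletonVolume

__all__ = ["OverlapReport", "dilate_ground_truth", "skeleton_overlap", "overlap_table"]

_CUBE27 = np.ones((3, 3, 3), dtype=bool)
_CROSS7 = ndimage.generate_binary_structure(3, 1)


@dataclass
class OverlapReport:
    dilation_rounds: int
    overlap_percent: float
    gt_area_increase_percent: float


def dilate_ground_truth(
    gt: BinaryVolume, rounds: int, connectivity: int = 26
) -> tuple[BinaryVolume, float]:
    """Dilate a ground-truth mask ``rounds`` times with a 3×3×3 element.

    Returns the dilated mask and the voxel-count increase vs. the original
    in percent.  ``connectivity`` 26 (default) uses the full cube, 6 the
    face-neighbor cross.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    structure = _CUBE27 if connectivity == 26 else _CROSS7
    original = gt.count()
    if rounds == 0:
        return gt, 0.0
    dilated = ndimage.binary_dilation(gt.mask, structure=structure, iterations=rounds)
    increase = 100.0 * (int(dilated.sum()) - original) / original if original else 0.0
    return gt.with_mask(dilated), increase


def skeleton_overlap(
    skeleton: Union[SkeletonVolume, BinaryVolume], gt: BinaryVolume
) -> float:
    """Percentage of skeleton voxels lying inside the ground truth."""
    mask = skeleton.mask
    if mask.shape != gt.mask.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {gt.mask.shape}")
    n_skel = int(mask.sum())
    if n_skel == 0:
        raise ValueError("empty skeleton: overlap undefined")
    return 100.0 * int((mask & gt.mask).sum()) / n_skel


def overlap_table(
    skeleton: Union[SkeletonVolume, BinaryVolume],
    gt: BinaryVolume,
    rounds: Sequence[int] = (0, 1, 2),
    connectivity: int = 26,
) -> pd.DataFrame:
    """Overlap vs. ground truth at several dilation rounds, as a table."""
    rows = []
    for r in rounds:
        gt_r, increase = dilate_ground_truth(gt, r, connectivity=connectivity)
        rows.append(
            OverlapReport(
                dilation_rounds=int(r),
                overlap_percent=skeleton_overlap(skeleton, gt_r),
                gt_area_increase_percent=increase,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
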