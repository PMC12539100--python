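import numpy as np
import pytest

from vesselnet import BinaryVolume
from vesselnet.skeleton import (
    END,
    JUNCTION,
    SLAB,
    SkeletonVolume,
    classify_skeleton_voxels,
    extract_graph,
    prune_short_end_segments,
    segment_length,
    thin_3d,
)

from _oracles import betti_numbers, graph_cycle_rank


def skeleton_from_mask(mask, voxel_size=(1.0, 1.0, 1.0)):
    mask = np.asarray(mask, dtype=bool)
    return SkeletonVolume(mask, classify_skeleton_voxels(mask), voxel_size)


def straight_line_mask(n=10, canvas=(3, 3, 12)):
    mask = np.zeros(canvas, dtype=bool)
    mask[1, 1, 1 : 1 + n] = True
    return mask


def y_mask(arm=4, canvas=(3, 13, 13)):
    """Y-shape: three arms of `arm` voxels meeting at one center voxel."""
    mask = np.zeros(canvas, dtype=bool)
    cz, cy, cx = 1, 6, 6
    mask[cz, cy, cx] = True
    for i in range(1, arm + 1):
        mask[cz, cy, cx - i] = True  # west arm
        mask[cz, cy - i, cx + i] = True  # north-east diagonal arm
        mask[cz, cy + i, cx + i] = True  # south-east diagonal arm
    return mask


def torus_mask(n=40, ring_r=12, tube_r=4):
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = n // 2
    return (np.sqrt((yy - c) ** 2 + (xx - c) ** 2) - ring_r) ** 2 + (zz - c) ** 2 <= tube_r**2


class TestThin3D:
    def test_one_voxel_line_unchanged(self):
        mask = straight_line_mask()
        out = thin_3d(BinaryVolume(mask))
        np.testing.assert_array_equal(out.mask, mask)

    def test_output_subset_of_input(self, rng):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[5:15, 5:15, 5:15] = True
        out = thin_3d(BinaryVolume(mask))
        assert np.all(mask[out.mask])

    def test_solid_cube_topology(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[1:8, 1:8, 1:8] = True
        out = thin_3d(BinaryVolume(mask))
        b0, b1, _ = betti_numbers(out.mask)
        assert (b0, b1) == (1, 0)

    def test_torus_keeps_its_loop(self):
        mask = torus_mask()
        out = thin_3d(BinaryVolume(mask))
        assert betti_numbers(mask)[:2] == (1, 1)
        assert betti_numbers(out.mask)[:2] == (1, 1)


class TestClassify:
    def test_straight_line_classes(self):
        classes = classify_skeleton_voxels(straight_line_mask(n=5))
        assert (classes == END).sum() == 2
        assert (classes == SLAB).sum() == 3
        assert (classes == JUNCTION).sum() == 0

    def test_y_center_is_junction(self):
        classes = classify_skeleton_voxels(y_mask(arm=4))
        assert classes[1, 6, 6] == JUNCTION
        assert (classes == END).sum() == 3

    def test_isolated_voxel_is_end(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        assert classify_skeleton_voxels(mask)[1, 1, 1] == END


class TestSegmentLength:
    def test_collinear_and_diagonal_closed_forms(self):
        line = [(0, 0, i) for i in range(5)]
        assert segment_length(np.array(line), (1, 1, 1)) == pytest.approx(4.0)
        diag = [(0, 0, 0), (0, 1, 1), (0, 2, 2)]
        assert segment_length(np.array(diag), (1, 1, 1)) == pytest.approx(2 * np.sqrt(2))

    def test_anisotropic_calibration(self):
        # steps: one along z (dz=2), one along x (dx=1): 2 + 1 = 3 µm
        path = np.array([(0, 0, 0), (1, 0, 0), (1, 0, 1)])
        assert segment_length(path, (2.0, 1.0, 1.0)) == pytest.approx(3.0)
        diag = np.array([(0, 0, 0), (1, 0, 1)])
        assert segment_length(diag, (2.0, 1.0, 1.0)) == pytest.approx(np.sqrt(5))

    def test_non_adjacent_path_rejected(self):
        with pytest.raises(ValueError):
            segment_length(np.array([(0, 0, 0), (0, 0, 3)]), (1, 1, 1))


class TestExtractGraph:
    def test_straight_line(self):
        g = extract_graph(skeleton_from_mask(straight_line_mask(n=5)))
        assert (g.n_skeletons, g.n_segments, g.n_junctions, g.n_endpoints) == (1, 1, 0, 2)
        assert g.segment_lengths[0] == pytest.approx(4.0)

    def test_y_shape(self):
        g = extract_graph(skeleton_from_mask(y_mask(arm=4)))
        assert (g.n_skeletons, g.n_segments, g.n_junctions, g.n_endpoints) == (1, 3, 1, 3)
        # two diagonal arms of length 4√2, one straight arm of length 4
        assert sorted(g.segment_lengths) == pytest.approx([4.0, 4 * np.sqrt(2), 4 * np.sqrt(2)])

    def test_two_disjoint_structures_are_two_skeletons(self):
        mask = np.zeros((3, 8, 12), dtype=bool)
        mask[1, 1, 1:9] = True
        mask[1, 5, 2:10] = True
        g = extract_graph(skeleton_from_mask(mask))
        assert g.n_skeletons == 2
        assert g.n_segments == 2

    def test_closed_loop_is_one_closed_segment(self):
        # diamond contour |dy| + |dx| = 3: twelve voxels, all diagonal steps,
        # every voxel has exactly two neighbors
        mask = np.zeros((3, 9, 9), dtype=bool)
        for dy in range(-3, 4):
            dx = 3 - abs(dy)
            mask[1, 4 + dy, 4 + dx] = True
            mask[1, 4 + dy, 4 - dx] = True
        g = extract_graph(skeleton_from_mask(mask))
        assert (g.n_skeletons, g.n_segments, g.n_junctions, g.n_endpoints) == (1, 1, 0, 0)
        assert g.segments[0].closed
        assert g.segment_lengths[0] == pytest.approx(12 * np.sqrt(2))

    def test_two_voxel_and_isolated_components(self):
        mask = np.zeros((3, 5, 5), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True  # 2-voxel free segment
        mask[1, 3, 3] = True  # isolated voxel
        g = extract_graph(skeleton_from_mask(mask))
        assert g.n_skeletons == 2
        assert g.n_segments == 2
        assert g.n_endpoints == 3
        assert sorted(s.n_voxels for s in g.segments) == [1, 2]

    def test_every_end_voxel_is_exactly_one_terminus(self):
        for mask in [straight_line_mask(), y_mask(), y_mask(arm=6)]:
            g = extract_graph(skeleton_from_mask(mask))
            end_termini = []
            for seg in g.segments:
                for v in (seg.path[0], seg.path[-1]):
                    if not seg.closed and g.voxel_size:
                        end_termini.append(tuple(v))
            for ep in map(tuple, g.endpoints):
                assert end_termini.count(ep) == 1

    def test_terminal_attachment_count(self):
        # every open segment contributes exactly two terminal attachments
        g = extract_graph(skeleton_from_mask(y_mask(arm=5)))
        attachments = sum(2 for s in g.segments if not s.closed)
        assert attachments == 2 * g.n_segments


class TestPrune:
    def test_zero_prune_is_identity(self):
        skel = skeleton_from_mask(y_mask(arm=4))
        g = extract_graph(skel)
        g2, s2 = prune_short_end_segments(g, skel, 0)
        assert g2 is g and s2 is skel

    def test_y_with_short_arm_loses_exactly_that_arm(self):
        # arms 5, 5, 2: pruning below 3 removes the 2-arm; the junction
        # dissolves and the two long arms fuse into one segment
        mask = np.zeros((3, 13, 13), dtype=bool)
        cz, cy, cx = 1, 6, 6
        mask[cz, cy, cx] = True
        for i in range(1, 6):  # two long diagonal arms, 5 voxels each
            mask[cz, cy - i, cx + i] = True
            mask[cz, cy + i, cx + i] = True
        mask[cz, cy, cx - 1] = mask[cz, cy, cx - 2] = True  # short west arm
        skel = skeleton_from_mask(mask)
        g = extract_graph(skel)
        assert (g.n_segments, g.n_junctions, g.n_endpoints) == (3, 1, 3)
        g2, s2 = prune_short_end_segments(g, skel, 3)
        assert (g2.n_segments, g2.n_junctions, g2.n_endpoints) == (1, 0, 2)
        assert s2.count() == 11

    def test_free_floating_segment_never_pruned(self):
        mask = np.zeros((3, 4, 4), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        skel = skeleton_from_mask(mask)
        g2, s2 = prune_short_end_segments(extract_graph(skel), skel, 5)
        assert s2.count() == 2
        assert g2.n_segments == 1

    def test_prune_is_idempotent(self):
        mask = y_mask(arm=4)
        mask[1, 5, 5] = False  # make one arm shorter than the others
        skel = skeleton_from_mask(y_mask(arm=4))
        g = extract_graph(skel)
        g1, s1 = prune_short_end_segments(g, skel, 3)
        g2, s2 = prune_short_end_segments(g1, s1, 3)
        np.testing.assert_array_equal(s1.mask, s2.mask)
        assert g1.n_segments == g2.n_segments

    def test_pruning_never_increases_segments_or_junctions(self):
        for arm, prune in [(4, 2), (4, 5), (6, 4)]:
            skel = skeleton_from_mask(y_mask(arm=arm))
            g = extract_graph(skel)
            g2, _ = prune_short_end_segments(g, skel, prune)
            assert g2.n_segments <= g.n_segments
            assert g2.n_junctions <= g.n_junctions

    def test_negative_prune_rejected(self):
        skel = skeleton_from_mask(straight_line_mask())
        with pytest.raises(ValueError):
            prune_short_end_segments(extract_graph(skel), skel, -1)


class TestGraphCycleRankOracle:
    def test_clean_tree_skeletons_have_rank_zero(self):
        assert graph_cycle_rank(straight_line_mask()) == 0
        assert graph_cycle_rank(y_mask()) == 0
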