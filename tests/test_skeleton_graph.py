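"""Skeletonization, branch graph construction, pruning, partition, TAC."""

import numpy as np
import pytest
from scipy import ndimage

from awvct.errors import (
    EmptyInputError,
    InvalidPartitionError,
    MissingLabelsError,
    MultipleComponentsError,
)
from awvct.imaging_io import BinaryMask
from awvct.skeleton_graph import (
    AirwayGraph,
    build_branch_graph,
    main_bifurcation_children,
    partition_subtrees,
    prune_spurs,
    skeletonize_mask,
    total_airway_count,
)

SP = (0.5, 0.5, 0.5)


def mask_from(shape, voxels):
    m = np.zeros(shape, bool)
    for v in voxels:
        m[v] = True
    return BinaryMask(m, SP)


def line(p0, p1):
    """Integer voxel line from p0 to p1 (26-connected steps)."""
    p0, p1 = np.asarray(p0), np.asarray(p1)
    n = int(np.max(np.abs(p1 - p0)))
    return [tuple(np.round(p0 + (p1 - p0) * t / n).astype(int)) for t in range(n + 1)]


def y_skeleton(shape=(40, 40, 40)):
    """A Y: stem down the middle, two arms — returned as a voxel mask."""
    stem = line((20, 20, 35), (20, 20, 20))
    arm1 = line((20, 20, 20), (10, 20, 8))
    arm2 = line((20, 20, 20), (30, 20, 8))
    return mask_from(shape, stem + arm1 + arm2)


class TestSkeletonize:
    def test_solid_cylinder_gives_single_path(self):
        x, y, z = np.mgrid[0:30, 0:30, 0:40]
        cyl = ((x - 15) ** 2 + (y - 15) ** 2 <= 25) & (z >= 4) & (z <= 36)
        sk = skeletonize_mask(BinaryMask(cyl, SP))
        g = build_branch_graph(sk, SP)
        g = prune_spurs(g, 2.0)
        assert len(g.branches) == 1
        kinds = {n.kind for n in g.nodes.values()}
        assert "bifurcation" not in kinds

    def test_single_voxel_is_its_own_skeleton(self):
        m = mask_from((10, 10, 10), [(5, 5, 5)])
        sk = skeletonize_mask(m)
        assert sk.sum() == 1 and sk[5, 5, 5]

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyInputError):
            skeletonize_mask(BinaryMask(np.zeros((5, 5, 5), bool), SP))

    def test_y_mask_has_one_trifurcation_voxel(self):
        # dilate the Y skeleton into a solid mask, then re-skeletonize
        solid = ndimage.binary_dilation(y_skeleton().values, iterations=2)
        sk = skeletonize_mask(BinaryMask(solid, SP))
        g = prune_spurs(build_branch_graph(sk, SP), 2.0)
        bifs = [n for n in g.nodes.values() if n.kind == "bifurcation"]
        assert len(bifs) == 1
        assert len(g.branches) == 3


class TestBranchGraph:
    def test_straight_path_single_branch_length(self):
        vox = [(5, 5, k) for k in range(10, 31)]  # 21 voxels, 20 steps of 0.5 mm
        g = build_branch_graph(mask_from((20, 20, 40), vox).values, SP)
        assert len(g.branches) == 1
        b = next(iter(g.branches.values()))
        assert b.length_mm == pytest.approx(10.0)

    def test_y_three_branches_node_kinds(self):
        g = build_branch_graph(y_skeleton().values, SP)
        assert len(g.branches) == 3
        kinds = sorted(n.kind for n in g.nodes.values())
        assert kinds.count("bifurcation") == 1
        assert kinds.count("endpoint") == 2
        assert kinds.count("root") == 1

    def test_phantom_depth3_has_seven_branches(self, crisp_graph):
        assert len(crisp_graph.branches) == 7

    def test_generations_increment_from_root(self, crisp_graph):
        root = crisp_graph.root_branch()
        assert root.generation == 0
        for b in crisp_graph.branches.values():
            parent = crisp_graph.parent(b.id)
            if parent is not None:
                assert b.generation == parent.generation + 1

    def test_disconnected_centerline_rejected_unless_flagged(self):
        vox = [(5, 5, k) for k in range(5, 15)] + [(10, 10, k) for k in range(25, 30)]
        m = mask_from((20, 20, 40), vox).values
        with pytest.raises(MultipleComponentsError):
            build_branch_graph(m, SP)
        g = build_branch_graph(m, SP, keep_largest=True)
        assert len(g.branches) == 1

    def test_branch_count_robust_to_one_voxel_dilation(self, crisp_phantom, crisp_graph):
        lumen = crisp_phantom[1]
        dil = ndimage.binary_dilation(lumen.values, structure=ndimage.generate_binary_structure(3, 3))
        g = prune_spurs(build_branch_graph(skeletonize_mask(BinaryMask(dil, SP)), SP), 2.0)
        assert len(g.branches) == len(crisp_graph.branches)

    def test_json_round_trip_preserves_structure(self, crisp_graph):
        back = AirwayGraph.from_json(crisp_graph.to_json())
        assert len(back.branches) == len(crisp_graph.branches)
        assert back.root_node == crisp_graph.root_node
        assert {b.label for b in back.branches.values()} == {b.label for b in crisp_graph.branches.values()}


class TestPruneSpurs:
    def test_zero_min_length_is_identity(self, crisp_graph):
        g = prune_spurs(crisp_graph, 0.0)
        assert len(g.branches) == len(crisp_graph.branches)

    def test_short_twig_removed_and_merged(self):
        stem = line((20, 20, 35), (20, 20, 5))
        twig = [(21, 21, 20), (22, 22, 19)]
        g = build_branch_graph(mask_from((40, 40, 40), stem + twig).values, SP)
        assert len(g.branches) == 3
        pruned = prune_spurs(g, 2.0)
        assert len(pruned.branches) == 1

    def test_idempotent(self):
        solid = ndimage.binary_dilation(y_skeleton().values, iterations=2)
        g = build_branch_graph(skeletonize_mask(BinaryMask(solid, SP)), SP)
        once = prune_spurs(g, 2.0)
        twice = prune_spurs(once, 2.0)
        assert len(once.branches) == len(twice.branches)
        assert sorted(b.length_mm for b in once.branches.values()) == pytest.approx(
            sorted(b.length_mm for b in twice.branches.values())
        )


class TestPartitionAndTac:
    def test_depth2_partition_splits_children(self):
        from awvct.phantom import PhantomSpec, build_tree_spec, rasterize_phantom

        spec = PhantomSpec(shape=(160, 160, 144), blur_sigma_mm=0.0, noise_sd_hu=0.0)
        _, lumen, _, _ = rasterize_phantom(build_tree_spec(2), spec)
        g = prune_spurs(build_branch_graph(skeletonize_mask(lumen), SP), 2.0)
        rul, rmll = main_bifurcation_children(g)
        partition_subtrees(g, rul, rmll)
        labels = [b.label for b in g.branches.values()]
        assert labels.count("RUL") == 1 and labels.count("RMLL") == 1
        assert total_airway_count(g) == 2

    def test_ancestor_pair_rejected(self, crisp_graph):
        rul, _ = main_bifurcation_children(crisp_graph)
        child_of_rul = crisp_graph.children(rul)[0].id
        with pytest.raises(InvalidPartitionError):
            partition_subtrees(crisp_graph, rul, child_of_rul)

    def test_unpartitioned_graph_rejected(self):
        g = build_branch_graph(y_skeleton().values, SP)
        with pytest.raises(MissingLabelsError):
            total_airway_count(g)

    def test_tac_is_rul_plus_rmll(self, crisp_graph):
        labels = [b.label for b in crisp_graph.branches.values()]
        assert total_airway_count(crisp_graph) == labels.count("RUL") + labels.count("RMLL") == 6

    def test_label_conservation(self, crisp_graph):
        labels = [b.label for b in crisp_graph.branches.values()]
        assert len(labels) == labels.count("RUL") + labels.count("RMLL") + labels.count(
            "trachea"
        ) + labels.count("other")

    def test_empty_rul_side_counts_rmll_alone(self):
        g = build_branch_graph(y_skeleton().values, SP)
        kids = g.children(g.root_branch().id)
        # label one arm RMLL by hand; leave the other unlabeled
        for b in g.branches.values():
            b.label = "other"
        g.branches[kids[0].id].label = "RMLL"
        assert total_airway_count(g) == 1
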