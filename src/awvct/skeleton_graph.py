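"""Skeletonization, branch graphs, airway counting and lobar partition.

The segmented lumen mask is thinned to a one-voxel-wide centerline
(topology-preserving 3-D thinning), which is then parsed into a labelled
branch graph: nodes at skeleton voxels of degree != 2 (26-neighbourhood;
adjacent voxels of degree >= 3 are merged into a single bifurcation node at
their centroid), one branch per maximal degree-2 chain.  Short terminal
spurs — voxelization artefacts, not genuine branches — are pruned and the
adjacent chains re-merged.  The tree is rooted at the most cranial endpoint
(the trachea) and partitioned into right-upper-lobe (RUL) and
right-middle-lower-lobe (RMLL) subtrees from caller-supplied lobar root
branches; the total airway count (TAC) is the number of RUL plus RMLL
branches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import (
    EmptyInputError,
    GraphTopologyError,
    InvalidParameterError,
    InvalidPartitionError,
    MissingLabelsError,
    MultipleComponentsError,
)
from .imaging_io import BinaryMask

_OFFSETS = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
)


@dataclass
class GraphNode:
    id: int
    #: centroid of the member skeleton voxels, in (possibly fractional) voxel indices
    voxel: tuple[float, float, float]
    voxels: list[tuple[int, int, int]]
    degree: int
    kind: str  # "endpoint" | "bifurcation" | "root" | "isolated"


@dataclass
class GraphBranch:
    id: int
    #: (proximal node id, distal node id) after rooting; unordered before
    nodes: tuple[int, int]
    #: ordered centerline voxels from proximal to distal, shape (N, 3)
    points: np.ndarray
    length_mm: float
    generation: int | None = None
    label: str | None = None  # "RUL" | "RMLL" | "other" | "trachea"


@dataclass
class AirwayGraph:
    """Skeleton-derived airway tree with labelled branches."""

    nodes: dict[int, GraphNode]
    branches: dict[int, GraphBranch]
    spacing: tuple[float, float, float]
    root_node: int | None = None

    # -- topology helpers ---------------------------------------------------
    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for b in self.branches.values():
            g.add_edge(b.nodes[0], b.nodes[1], key=b.id)
        return g

    def node_branches(self, node_id: int) -> list[GraphBranch]:
        return [b for b in self.branches.values() if node_id in b.nodes]

    def root_branch(self) -> GraphBranch:
        if self.root_node is None:
            raise GraphTopologyError("graph has no root")
        incident = self.node_branches(self.root_node)
        if len(incident) != 1:
            raise GraphTopologyError("root node must be an endpoint with one incident branch")
        return incident[0]

    def children(self, branch_id: int) -> list[GraphBranch]:
        b = self.branches[branch_id]
        distal = b.nodes[1]
        return [c for c in self.branches.values() if c.id != branch_id and c.nodes[0] == distal]

    def parent(self, branch_id: int) -> GraphBranch | None:
        b = self.branches[branch_id]
        for c in self.branches.values():
            if c.id != branch_id and c.nodes[1] == b.nodes[0]:
                return c
        return None

    def descendants(self, branch_id: int) -> list[int]:
        """Branch ids of the subtree rooted at ``branch_id`` (inclusive)."""
        out, queue = [], [branch_id]
        while queue:
            cur = queue.pop(0)
            out.append(cur)
            queue.extend(c.id for c in self.children(cur))
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        cur = self.branches.get(b)
        while cur is not None:
            if cur.id == a:
                return True
            cur = self.parent(cur.id)
        return False

    def centerline_points_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """All branch centerline points in mm and their branch ids."""
        pts, ids = [], []
        for b in self.branches.values():
            pts.append(b.points * np.asarray(self.spacing))
            ids.append(np.full(len(b.points), b.id))
        return np.concatenate(pts), np.concatenate(ids)

    # -- serialization ------------------------------------------------------
    @staticmethod
    def _json_default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "spacing_mm": list(self.spacing),
                "root_node": self.root_node,
                "nodes": [
                    {
                        "id": n.id,
                        "voxel": list(n.voxel),
                        "voxels": [list(v) for v in n.voxels],
                        "degree": n.degree,
                        "kind": n.kind,
                    }
                    for n in self.nodes.values()
                ],
                "branches": [
                    {
                        "id": b.id,
                        "nodes": list(b.nodes),
                        "points": b.points.tolist(),
                        "length_mm": b.length_mm,
                        "generation": b.generation,
                        "label": b.label,
                    }
                    for b in self.branches.values()
                ],
            },
            indent=2,
            default=self._json_default,
        )

    @classmethod
    def from_json(cls, text: str) -> "AirwayGraph":
        d = json.loads(text)
        nodes = {
            n["id"]: GraphNode(n["id"], tuple(n["voxel"]), [tuple(v) for v in n["voxels"]], n["degree"], n["kind"])
            for n in d["nodes"]
        }
        branches = {
            b["id"]: GraphBranch(
                b["id"],
                tuple(b["nodes"]),
                np.asarray(b["points"], dtype=int),
                b["length_mm"],
                b["generation"],
                b["label"],
            )
            for b in d["branches"]
        }
        return cls(nodes, branches, tuple(d["spacing_mm"]), d["root_node"])

    def to_graphml(self, path) -> None:
        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, voxel=json.dumps(list(n.voxel)), kind=n.kind, degree=n.degree)
        for b in self.branches.values():
            g.add_edge(
                b.nodes[0],
                b.nodes[1],
                key=b.id,
                length_mm=b.length_mm,
                generation=-1 if b.generation is None else b.generation,
                label=b.label or "",
                points=json.dumps(b.points.tolist()),
            )
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Thinning
# ---------------------------------------------------------------------------

def skeletonize_mask(mask: BinaryMask) -> np.ndarray:
    """Topology-preserving 3-D thinning to a one-voxel-wide centerline."""
    if not mask.values.any():
        raise EmptyInputError("cannot skeletonize an empty mask")
    if int(mask.values.sum()) == 1:
        return mask.values.copy()
    out = _sk_skeletonize(mask.values).astype(bool)
    if not out.any():
        # perfectly even-symmetric tubes are a degenerate thinning input
        # (every voxel is deleted); break the tie with a one-sided
        # one-voxel dilation before retrying
        footprint = np.zeros((3, 3, 3), dtype=bool)
        footprint[1, 1, 1] = footprint[2, 1, 1] = True
        from scipy import ndimage

        nudged = ndimage.binary_dilation(mask.values, structure=footprint)
        out = _sk_skeletonize(nudged).astype(bool)
    return out


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_branch_graph(
    centerline: np.ndarray,
    spacing: tuple[float, float, float],
    keep_largest: bool = False,
) -> AirwayGraph:
    """Parse a skeleton voxel set into a rooted branch graph.

    Nodes sit at voxels of 26-degree != 2 (bifurcation clusters merged);
    branches are maximal degree-2 chains with polyline length in mm.  The
    root is the most cranial endpoint.  A disconnected centerline raises
    :class:`MultipleComponentsError` unless ``keep_largest`` is set.
    """
    centerline = np.asarray(centerline).astype(bool)
    coords = np.argwhere(centerline)
    if len(coords) == 0:
        raise EmptyInputError("empty centerline")

    index_of = {tuple(c): i for i, c in enumerate(coords)}
    neighbors: list[list[int]] = [[] for _ in coords]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            j = index_of.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None and j > i:
                neighbors[i].append(j)
                neighbors[j].append(i)
    degree = np.array([len(nb) for nb in neighbors])

    # connectivity check on the voxel graph
    comp = _voxel_components(len(coords), neighbors)
    if comp.max() > 0:
        if not keep_largest:
            raise MultipleComponentsError(
                f"centerline has {comp.max() + 1} connected components; "
                "pass keep_largest=True to keep the largest"
            )
        sizes = np.bincount(comp)
        keep = comp == int(np.argmax(sizes))
        sub = centerline.copy()
        sub[tuple(coords[~keep].T)] = False
        return build_branch_graph(sub, spacing)

    # node voxels: endpoints (degree <= 1) and junction clusters (degree >= 3)
    node_of_voxel = np.full(len(coords), -1)
    nodes: dict[int, GraphNode] = {}
    nid = 0
    junction = degree >= 3
    visited = np.zeros(len(coords), dtype=bool)
    for i in np.flatnonzero(junction):
        if visited[i]:
            continue
        stack, members = [i], []
        visited[i] = True
        while stack:
            cur = stack.pop()
            members.append(cur)
            for j in neighbors[cur]:
                if junction[j] and not visited[j]:
                    visited[j] = True
                    stack.append(j)
        centroid = coords[members].mean(axis=0)
        nodes[nid] = GraphNode(
            nid, tuple(centroid), [tuple(coords[m]) for m in members], 0, "bifurcation"
        )
        node_of_voxel[members] = nid
        nid += 1
    for i in np.flatnonzero(degree <= 1):
        kind = "isolated" if degree[i] == 0 else "endpoint"
        nodes[nid] = GraphNode(nid, tuple(coords[i].astype(float)), [tuple(coords[i])], 0, kind)
        node_of_voxel[i] = nid
        nid += 1

    if not nodes:
        # a pure cycle has every voxel at degree 2
        raise GraphTopologyError("centerline is a closed loop; no endpoints or bifurcations")

    # walk degree-2 chains between node voxels
    branches: dict[int, GraphBranch] = {}
    bid = 0
    used_steps: set[tuple[int, int]] = set()
    sp = np.asarray(spacing)
    for i in range(len(coords)):
        if node_of_voxel[i] < 0:
            continue
        for j in neighbors[i]:
            if (i, j) in used_steps:
                continue
            path = [i]
            prev, cur = i, j
            while node_of_voxel[cur] < 0:
                path.append(cur)
                nxt = [k for k in neighbors[cur] if k != prev]
                if len(nxt) != 1:  # should not happen for degree-2 voxels
                    raise GraphTopologyError("inconsistent chain while walking skeleton")
                prev, cur = cur, nxt[0]
            path.append(cur)
            used_steps.add((i, j))
            used_steps.add((cur, prev))
            u, v = int(node_of_voxel[i]), int(node_of_voxel[cur])
            if u == v and len(path) <= 2:
                continue  # internal adjacency within one junction cluster
            pts = coords[path]
            length = float(np.linalg.norm(np.diff(pts * sp, axis=0), axis=1).sum())
            branches[bid] = GraphBranch(bid, (u, v), pts, length)
            bid += 1

    for n in nodes.values():
        n.degree = sum(1 for b in branches.values() if n.id in b.nodes)

    graph = AirwayGraph(nodes, branches, tuple(spacing))
    _check_tree(graph)
    _root_and_orient(graph)
    return graph


def _voxel_components(n: int, neighbors: list[list[int]]) -> np.ndarray:
    comp = np.full(n, -1)
    c = 0
    for i in range(n):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = c
        while stack:
            cur = stack.pop()
            for j in neighbors[cur]:
                if comp[j] < 0:
                    comp[j] = c
                    stack.append(j)
        c += 1
    return comp


def _check_tree(graph: AirwayGraph) -> None:
    n_nodes, n_edges = len(graph.nodes), len(graph.branches)
    if n_edges != n_nodes - 1:
        raise GraphTopologyError(
            f"skeleton graph is not a tree: {n_nodes} nodes, {n_edges} branches"
        )


def _root_and_orient(graph: AirwayGraph) -> None:
    """Root at the most cranial (max z) endpoint and orient every branch
    proximal->distal; assign generations (root branch = 0)."""
    if not graph.branches:
        graph.root_node = next(iter(graph.nodes)) if graph.nodes else None
        return
    candidates = [n for n in graph.nodes.values() if n.kind in ("endpoint", "root")]
    if not candidates:
        raise GraphTopologyError("no endpoint available to root the tree")
    root = max(candidates, key=lambda n: n.voxel[2])
    root.kind = "root"
    graph.root_node = root.id
    # BFS over nodes, flipping branches so nodes[0] is proximal
    node_depth = {root.id: 0}
    queue = [root.id]
    oriented: set[int] = set()
    while queue:
        cur = queue.pop(0)
        for b in graph.node_branches(cur):
            if b.id in oriented:
                continue
            other = b.nodes[1] if b.nodes[0] == cur else b.nodes[0]
            if b.nodes[0] != cur:
                graph.branches[b.id] = replace(b, nodes=(cur, other), points=b.points[::-1].copy())
            graph.branches[b.id].generation = node_depth[cur]
            oriented.add(b.id)
            if other not in node_depth:
                node_depth[other] = node_depth[cur] + 1
                queue.append(other)


# ---------------------------------------------------------------------------
# Spur pruning
# ---------------------------------------------------------------------------

def prune_spurs(graph: AirwayGraph, min_length: float = 2.0) -> AirwayGraph:
    """Remove terminal branches shorter than ``min_length`` mm and re-merge
    the adjacent degree-2 chains.  The trachea (root branch) is never
    pruned.  Idempotent: a second application changes nothing."""
    if min_length < 0:
        raise InvalidParameterError("min_length must be >= 0")
    if min_length == 0 or not graph.branches:
        return graph
    nodes = {k: replace(v, voxels=list(v.voxels)) for k, v in graph.nodes.items()}
    branches = {k: replace(v, points=v.points.copy()) for k, v in graph.branches.items()}
    g = AirwayGraph(nodes, branches, graph.spacing, graph.root_node)

    def leaf_node(b: GraphBranch) -> int | None:
        for n_id in b.nodes:
            incident = [c for c in g.branches.values() if n_id in c.nodes]
            if len(incident) == 1 and n_id != g.root_node:
                return n_id
        return None

    removed = True
    while removed:
        removed = False
        for b in list(g.branches.values()):
            leaf = leaf_node(b)
            if leaf is not None and b.length_mm < min_length and len(g.branches) > 1:
                del g.branches[b.id]
                del g.nodes[leaf]
                removed = True
        # merge pass: interior nodes with exactly two incident branches
        for n in list(g.nodes.values()):
            incident = [c for c in g.branches.values() if n.id in c.nodes]
            if len(incident) == 2 and n.id != g.root_node and incident[0].id != incident[1].id:
                _merge_pair(g, n.id, incident[0], incident[1])
    _root_and_orient(g)
    return g


def _merge_pair(g: AirwayGraph, node_id: int, a: GraphBranch, b: GraphBranch) -> None:
    sp = np.asarray(g.spacing)

    def oriented(br: GraphBranch, end_at: int) -> np.ndarray:
        # return points ordered so the last point is at the node `end_at`
        return br.points if br.nodes[1] == end_at else br.points[::-1]

    pts_a = oriented(a, node_id)
    pts_b = oriented(b, node_id)[::-1]  # starts at node
    far_a = a.nodes[0] if a.nodes[1] == node_id else a.nodes[1]
    far_b = b.nodes[0] if b.nodes[1] == node_id else b.nodes[1]
    merged_pts = np.vstack([pts_a, pts_b[1:]])
    length = float(np.linalg.norm(np.diff(merged_pts * sp, axis=0), axis=1).sum())
    del g.branches[b.id]
    g.branches[a.id] = replace(a, nodes=(far_a, far_b), points=merged_pts, length_mm=length)
    del g.nodes[node_id]


# ---------------------------------------------------------------------------
# Lobar partition and counting
# ---------------------------------------------------------------------------

def partition_subtrees(graph: AirwayGraph, rul_root: int, rmll_root: int) -> AirwayGraph:
    """Label every branch: descendants (inclusive) of ``rul_root`` as RUL,
    of ``rmll_root`` as RMLL, the path above them as trachea, the rest as
    other.  Labels are written back onto the branches."""
    if rul_root not in graph.branches or rmll_root not in graph.branches:
        raise InvalidPartitionError("lobar root branch id not present in graph")
    if rul_root == rmll_root:
        raise InvalidPartitionError("lobar roots must be distinct branches")
    if graph.is_ancestor(rul_root, rmll_root) or graph.is_ancestor(rmll_root, rul_root):
        raise InvalidPartitionError("lobar roots must not be ancestor and descendant")
    rul = set(graph.descendants(rul_root))
    rmll = set(graph.descendants(rmll_root))
    trachea = set()
    for lobar in (rul_root, rmll_root):
        cur = graph.parent(lobar)
        while cur is not None:
            trachea.add(cur.id)
            cur = graph.parent(cur.id)
    for b in graph.branches.values():
        if b.id in rul:
            b.label = "RUL"
        elif b.id in rmll:
            b.label = "RMLL"
        elif b.id in trachea:
            b.label = "trachea"
        else:
            b.label = "other"
    return graph


def main_bifurcation_children(graph: AirwayGraph) -> tuple[int, int]:
    """Branch ids of the two children of the root branch — the default
    lobar roots for phantoms whose first bifurcation splits the tree."""
    kids = graph.children(graph.root_branch().id)
    if len(kids) < 2:
        raise InvalidPartitionError("root branch has fewer than two children")
    kids = sorted(kids, key=lambda b: b.id)
    return kids[0].id, kids[1].id


def total_airway_count(graph: AirwayGraph) -> int:
    """TAC: the number of branches labelled RUL plus those labelled RMLL."""
    labels = [b.label for b in graph.branches.values()]
    if all(lab is None for lab in labels):
        raise MissingLabelsError("graph is not partitioned; run partition_subtrees first")
    return sum(1 for lab in labels if lab in ("RUL", "RMLL"))
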