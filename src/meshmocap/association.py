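"""Cross-view association of unordered detections into animal identities.

At the first frame there is no temporal information, so instances detected in
different views are matched purely spatially: every (view, instance) pair
becomes a node of a multipartite graph whose edge weights are mean epipolar
distances between the two instances' mutually visible keypoints.  The graph is
partitioned into identity groups by enumerating cliques (node sets spanning
distinct views with all pairwise edges present) and greedily selecting
disjoint cliques; leftover nodes land in a junk group.  At later frames the
previous frame's regressed 3D keypoints are projected into every view and a
per-view Hungarian assignment carries identities forward.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import CameraModel, epipolar_distance, project

__all__ = [
    "Instance",
    "FrameDetections",
    "AssociationGraph",
    "IdentityGrouping",
    "build_association_graph",
    "partition_graph",
    "brute_force_partition",
    "track_frame",
    "DEFAULT_EDGE_CUTOFF",
    "DEFAULT_TRACK_GATE",
]

DEFAULT_EDGE_CUTOFF = 25.0   # px: admit an edge only below this epipolar distance
DEFAULT_TRACK_GATE = 50.0    # px: Hungarian assignments above this go to junk


@dataclass
class Instance:
    """One detected animal in one view."""

    bbox: np.ndarray                      # (4,) x, y, w, h pixels
    keypoints: np.ndarray                 # (N_K, 3) x, y, sigma
    mask: np.ndarray | None = None        # binary (H, W) or None

    def __post_init__(self):
        self.bbox = np.asarray(self.bbox, float).ravel()
        self.keypoints = np.asarray(self.keypoints, float)


@dataclass
class FrameDetections:
    """Unordered per-view instances for one frame: ``views[c]`` is a list.

    Keypoints and bounding boxes are in full camera resolution; silhouette
    masks may be stored at a reduced working resolution, recorded by
    ``mask_scale`` (mask pixel = full pixel * mask_scale).
    """

    views: dict[int, list[Instance]] = field(default_factory=dict)
    mask_scale: float = 1.0

    def nodes(self) -> list[tuple[int, int]]:
        return [(c, q) for c in sorted(self.views)
                for q in range(len(self.views[c]))]

    def instance(self, node: tuple[int, int]) -> Instance:
        return self.views[node[0]][node[1]]


@dataclass
class AssociationGraph:
    """Sparse multipartite graph over (view, instance) nodes."""

    nodes: list[tuple[int, int]]
    edges: dict[frozenset, float]        # {frozenset({node_a, node_b}): weight}

    def weight(self, a, b) -> float | None:
        return self.edges.get(frozenset((a, b)))


@dataclass
class IdentityGrouping:
    """Partition of detection nodes into identity groups plus a junk group."""

    groups: list[list[tuple[int, int]]]
    junk: list[tuple[int, int]] = field(default_factory=list)
    padded: bool = False                 # True when groups were singleton-padded

    def validate(self) -> None:
        seen = set()
        for g in self.groups:
            views = [n[0] for n in g]
            if len(views) != len(set(views)):
                raise ValueError("group repeats a view")
            seen.update(g)
        overlap = seen & set(self.junk)
        if overlap:
            raise ValueError(f"nodes in both a group and junk: {overlap}")


def build_association_graph(frame: FrameDetections,
                            cameras: list[CameraModel],
                            edge_cutoff: float = DEFAULT_EDGE_CUTOFF
                            ) -> AssociationGraph:
    """Weight every cross-view instance pair by mean epipolar distance.

    Edges with no mutually visible keypoint, or with weight above
    ``edge_cutoff``, are omitted.
    """
    nodes = frame.nodes()
    edges: dict[frozenset, float] = {}
    for (ca, qa), (cb, qb) in itertools.combinations(nodes, 2):
        if ca == cb:
            continue
        w = epipolar_distance(cameras[ca], cameras[cb],
                              frame.views[ca][qa].keypoints,
                              frame.views[cb][qb].keypoints)
        if w is not None and w <= edge_cutoff:
            edges[frozenset(((ca, qa), (cb, qb)))] = w
    return AssociationGraph(nodes, edges)


# ---------------------------------------------------------------------------
# clique partitioning
# ---------------------------------------------------------------------------

def _clique_mean_weight(graph: AssociationGraph, clique) -> float:
    if len(clique) < 2:
        return float("inf")
    ws = [graph.weight(a, b) for a, b in itertools.combinations(clique, 2)]
    return float(np.mean(ws))


def _enumerate_cliques(graph: AssociationGraph) -> list[tuple]:
    """All cliques of size >= 2 spanning distinct views (plus singletons)."""
    adj: dict[tuple, set] = {n: set() for n in graph.nodes}
    for pair in graph.edges:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)
    cliques: list[tuple] = []
    order = sorted(graph.nodes)

    def extend(clique: tuple, candidates: list):
        cliques.append(clique)
        for i, n in enumerate(candidates):
            if all(n in adj[m] for m in clique):
                extend(clique + (n,), [c for c in candidates[i + 1:]
                                       if c[0] != n[0]])

    for i, n in enumerate(order):
        extend((n,), [c for c in order[i + 1:] if c[0] != n[0]])
    return cliques


def partition_graph(graph: AssociationGraph, n_individuals: int
                    ) -> IdentityGrouping:
    """Greedy disjoint-clique selection into identity groups.

    Candidate cliques are ranked by (more covered nodes first is implicit in
    clique size) mean edge weight, ties broken by larger size then
    lexicographic node order; ``n_individuals`` mutually disjoint cliques are
    selected in rank order.  If fewer multi-node cliques exist than
    individuals, groups are padded with leftover singletons and the result is
    flagged.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    cliques = [c for c in _enumerate_cliques(graph) if len(c) >= 2]
    # prefer larger cliques, then smaller mean weight, then lexicographic
    cliques.sort(key=lambda c: (-len(c), _clique_mean_weight(graph, c),
                                tuple(sorted(c))))
    chosen: list[tuple] = []
    used: set = set()
    for c in cliques:
        if len(chosen) == n_individuals:
            break
        if not used.intersection(c):
            chosen.append(c)
            used.update(c)
    padded = False
    leftovers = [n for n in sorted(graph.nodes) if n not in used]
    while len(chosen) < n_individuals:
        padded = True
        if leftovers:
            n = leftovers.pop(0)
            chosen.append((n,))
            used.add(n)
        else:
            chosen.append(())
    junk = [n for n in sorted(graph.nodes) if n not in used]
    grouping = IdentityGrouping([sorted(c) for c in chosen], junk, padded)
    grouping.validate()
    return grouping


def grouping_cost(graph: AssociationGraph, grouping: IdentityGrouping
                  ) -> tuple[int, float]:
    """(covered node count, summed mean clique weight) — lower weight better."""
    covered = sum(len(g) for g in grouping.groups)
    weight = sum(_clique_mean_weight(graph, g) for g in grouping.groups
                 if len(g) >= 2)
    return covered, weight


def brute_force_partition(graph: AssociationGraph, n_individuals: int
                          ) -> IdentityGrouping:
    """Exhaustive optimum partition; test oracle for :func:`partition_graph`.

    Searches all assignments of nodes to ``n_individuals`` groups plus junk,
    subject to one-node-per-view and to every group being a clique of the
    graph, maximizing covered nodes then minimizing summed mean clique
    weight.  Branch and bound over views keeps it exact but fast on small
    inputs; refuses more than 16 nodes.
    """
    nodes = sorted(graph.nodes)
    if len(nodes) > 16:
        raise ValueError("brute force limited to 16 nodes")
    views = sorted({n[0] for n in nodes})
    by_view = {v: [n for n in nodes if n[0] == v] for v in views}
    best = {"cover": -1, "weight": float("inf"), "groups": None}

    def pair_ok(a, b):
        return graph.weight(a, b) is not None

    def recurse(vi: int, groups: list[list], covered: int):
        remaining = sum(len(by_view[v]) for v in views[vi:])
        if covered + remaining < best["cover"]:
            return
        if vi == len(views):
            weight = sum(_clique_mean_weight(graph, g) for g in groups
                         if len(g) >= 2)
            if (covered > best["cover"]
                    or (covered == best["cover"] and weight < best["weight"])):
                best.update(cover=covered, weight=weight,
                            groups=[list(g) for g in groups])
            return
        v = views[vi]
        insts = by_view[v]
        slots = list(range(len(groups)))

        def assign(ii: int, used_slots: set, add: int):
            if ii == len(insts):
                recurse(vi + 1, groups, covered + add)
                return
            node = insts[ii]
            assign(ii + 1, used_slots, add)          # node -> junk
            for g in slots:
                if g in used_slots:
                    continue
                if all(pair_ok(node, m) for m in groups[g]):
                    groups[g].append(node)
                    assign(ii + 1, used_slots | {g}, add + 1)
                    groups[g].pop()

        assign(0, set(), 0)

    recurse(0, [[] for _ in range(n_individuals)], 0)
    groups = best["groups"] or [[] for _ in range(n_individuals)]
    used = {n for g in groups for n in g}
    junk = [n for n in nodes if n not in used]
    grouping = IdentityGrouping([sorted(g) for g in groups], junk)
    grouping.validate()
    return grouping


# ---------------------------------------------------------------------------
# temporal tracking
# ---------------------------------------------------------------------------

def track_frame(prev_keypoints: list[np.ndarray],
                frame: FrameDetections,
                cameras: list[CameraModel],
                track_gate: float = DEFAULT_TRACK_GATE) -> IdentityGrouping:
    """Carry identities forward by per-view Hungarian assignment.

    ``prev_keypoints[i]`` is the (N_K, 3) regressed 3D keypoint set of
    identity ``i`` at the previous frame.  In each view, the cost between an
    identity and a detected instance is the mean 2D Euclidean distance over
    the instance's visible keypoints; optimal per-view assignment is solved
    with the Hungarian algorithm and assignments above ``track_gate`` pixels
    are discarded to junk.
    """
    n_ids = len(prev_keypoints)
    groups: list[list[tuple[int, int]]] = [[] for _ in range(n_ids)]
    junk: list[tuple[int, int]] = []
    for c in sorted(frame.views):
        insts = frame.views[c]
        if not insts:
            continue
        proj = [project(cameras[c], kp) for kp in prev_keypoints]
        cost = np.full((n_ids, len(insts)), 1e9)
        for i in range(n_ids):
            for q, inst in enumerate(insts):
                vis = inst.keypoints[:, 2] > 0
                if not np.any(vis):
                    continue
                d = np.linalg.norm(proj[i][vis] - inst.keypoints[vis, :2],
                                   axis=1)
                d = d[np.isfinite(d)]
                if d.size:
                    cost[i, q] = float(np.mean(d))
        rows, cols = linear_sum_assignment(cost)
        assigned = set()
        for i, q in zip(rows, cols):
            if cost[i, q] <= track_gate:
                groups[i].append((c, q))
                assigned.add(q)
        junk.extend((c, q) for q in range(len(insts)) if q not in assigned)
    grouping = IdentityGrouping(groups, junk)
    grouping.validate()
    return grouping
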