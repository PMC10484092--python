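"""Centerline graph extraction from binary vessel masks.

The ROI-restricted vessel mask is thinned to a one-pixel-wide skeleton and
reduced to a graph whose nodes are endpoints (degree 1), bifurcations
(degree 3) and crossings (degree >= 4), and whose edges carry the ordered
8-connected centerline path between nodes.  This graph is the substrate for
the bifurcation-angle and tortuosity measurements.

Conventions: 8-connectivity throughout; diagonal steps contribute sqrt(2) to
arc length; pixel coordinates are (x, y) with x rightward and y downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = ["Node", "CenterlinePath", "VesselGraph", "skeletonize", "build_graph", "prune_spurs"]

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px-wide, 8-connected skeleton."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m)
    return _sk_skeletonize(m)


def path_arc_length(points: np.ndarray) -> float:
    """Sum of per-step Euclidean lengths along a polyline (1 or sqrt(2) on a pixel chain)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


@dataclass
class Node:
    """A skeleton node: cluster of adjacent pixels with != 2 skeleton neighbors."""

    id: int
    pixels: list[tuple[int, int]]
    position: tuple[float, float] = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=float)
        self.position = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


@dataclass
class CenterlinePath:
    """An ordered centerline between two nodes.

    ``points`` runs from a pixel of node_a's cluster to one of node_b's;
    interior points belong exclusively to this edge.
    """

    id: int
    points: np.ndarray  # (n, 2) float, (x, y)
    node_a: int
    node_b: int

    @property
    def arc_length(self) -> float:
        return path_arc_length(self.points)

    def oriented_from(self, node_id: int) -> np.ndarray:
        """Path points ordered so index 0 is at the given node's end."""
        if node_id == self.node_a:
            return self.points
        if node_id == self.node_b:
            return self.points[::-1]
        raise ValueError(f"edge {self.id} is not incident to node {node_id}")


class VesselGraph:
    """Skeleton-derived vessel graph: nodes, edges, adjacency."""

    def __init__(self):
        self.nodes: dict[int, Node] = {}
        self.edges: dict[int, CenterlinePath] = {}
        self.adjacency: dict[int, list[int]] = {}
        self._next_node = 0
        self._next_edge = 0

    # -- construction -----------------------------------------------------
    def add_node(self, pixels) -> int:
        nid = self._next_node
        self._next_node += 1
        self.nodes[nid] = Node(nid, [tuple(p) for p in pixels])
        self.adjacency[nid] = []
        return nid

    def add_edge(self, points: np.ndarray, node_a: int, node_b: int) -> int:
        eid = self._next_edge
        self._next_edge += 1
        self.edges[eid] = CenterlinePath(eid, np.asarray(points, dtype=float), node_a, node_b)
        self.adjacency[node_a].append(eid)
        self.adjacency[node_b].append(eid)
        return eid

    def remove_edge(self, eid: int) -> None:
        e = self.edges.pop(eid)
        self.adjacency[e.node_a].remove(eid)
        if e.node_b != e.node_a:
            self.adjacency[e.node_b].remove(eid)
        else:
            self.adjacency[e.node_a].remove(eid)

    def remove_node(self, nid: int) -> None:
        if self.adjacency[nid]:
            raise ValueError("cannot remove a node with incident edges")
        del self.nodes[nid]
        del self.adjacency[nid]

    # -- queries ----------------------------------------------------------
    def degree(self, nid: int) -> int:
        return len(self.adjacency[nid])

    def kind(self, nid: int) -> str:
        d = self.degree(nid)
        if d == 1:
            return "endpoint"
        if d == 3:
            return "bifurcation"
        if d >= 4:
            return "crossing"
        return "other"  # isolated pixel (0) or artificial cycle anchor (2)

    def bifurcations(self) -> list[int]:
        return [n for n in self.nodes if self.kind(n) == "bifurcation"]

    def endpoints(self) -> list[int]:
        return [n for n in self.nodes if self.kind(n) == "endpoint"]

    def skeleton_pixels(self) -> set[tuple[int, int]]:
        """All pixels accounted for: node clusters plus edge interiors."""
        pix: set[tuple[int, int]] = set()
        for node in self.nodes.values():
            pix.update(node.pixels)
        for e in self.edges.values():
            for p in e.points[1:-1]:
                pix.add((int(round(p[0])), int(round(p[1]))))
        return pix

    def to_json(self) -> str:
        obj = {
            "nodes": [
                {"id": n.id, "x": n.position[0], "y": n.position[1],
                 "kind": self.kind(n.id), "pixels": [list(p) for p in n.pixels]}
                for n in self.nodes.values()
            ],
            "edges": [
                {"id": e.id, "node_a": e.node_a, "node_b": e.node_b,
                 "arc_length": e.arc_length, "points": e.points.tolist()}
                for e in self.edges.values()
            ],
        }
        return json.dumps(obj)


def _neighbors(p: tuple[int, int], skel_set: set[tuple[int, int]]):
    x, y = p
    return [(x + dx, y + dy) for dy, dx in _NEIGH if (x + dx, y + dy) in skel_set]


def build_graph(skeleton: np.ndarray) -> VesselGraph:
    """Reduce a 1-px skeleton to a node/edge graph.

    Node pixels are skeleton pixels with a neighbor count other than 2;
    adjacent node pixels merge into one node cluster positioned at the
    cluster centroid.  Edges are traced along the chains of degree-2 pixels
    between clusters.  Isolated cycles receive one artificial degree-2
    anchor node and become a self-loop edge.
    """
    skel = np.asarray(skeleton, dtype=bool)
    g = VesselGraph()
    if not skel.any():
        return g
    ys, xs = np.nonzero(skel)
    skel_set = set(zip(xs.tolist(), ys.tolist()))

    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    ncount = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    node_mask = skel & (ncount != 2)

    labels, nlab = ndimage.label(node_mask, structure=np.ones((3, 3), dtype=int))
    pixel_to_node: dict[tuple[int, int], int] = {}
    for lab in range(1, nlab + 1):
        lys, lxs = np.nonzero(labels == lab)
        nid = g.add_node(list(zip(lxs.tolist(), lys.tolist())))
        for x, y in zip(lxs.tolist(), lys.tolist()):
            pixel_to_node[(x, y)] = nid

    visited: set[tuple[int, int]] = set()        # consumed interior pixels
    used_starts: set[tuple[tuple[int, int], tuple[int, int]]] = set()

    for start_pix, nid_a in sorted(pixel_to_node.items()):
        for q in sorted(_neighbors(start_pix, skel_set)):
            if q in pixel_to_node:
                if pixel_to_node[q] == nid_a:
                    continue  # same cluster, not an edge
                if (start_pix, q) in used_starts:
                    continue
                # direct node-node adjacency: zero-interior edge
                used_starts.add((q, start_pix))
                g.add_edge(np.array([start_pix, q], dtype=float), nid_a, pixel_to_node[q])
                continue
            if q in visited or (start_pix, q) in used_starts:
                continue
            # walk the degree-2 chain
            path = [start_pix, q]
            prev, cur = start_pix, q
            while cur not in pixel_to_node:
                visited.add(cur)
                nxt = [p for p in _neighbors(cur, skel_set) if p != prev]
                if not nxt:
                    break  # dangling chain end (shouldn't happen: endpoints are nodes)
                prev, cur = cur, nxt[0]
                path.append(cur)
            if cur in pixel_to_node:
                used_starts.add((cur, prev))
                g.add_edge(np.array(path, dtype=float), nid_a, pixel_to_node[cur])

    # isolated cycles: every pixel has exactly 2 neighbors, no node pixel
    remaining = skel_set - visited - set(pixel_to_node)
    while remaining:
        anchor = sorted(remaining)[0]
        nid = g.add_node([anchor])
        pixel_to_node[anchor] = nid
        nbrs = sorted(_neighbors(anchor, skel_set))
        path = [anchor, nbrs[0]]
        prev, cur = anchor, nbrs[0]
        while cur != anchor:
            remaining.discard(cur)
            nxt = [p for p in _neighbors(cur, skel_set) if p != prev]
            prev, cur = cur, nxt[0]
            path.append(cur)
        remaining.discard(anchor)
        g.add_edge(np.array(path, dtype=float), nid, nid)

    return g


def _bridge_through_cluster(p: tuple[int, int], q: tuple[int, int],
                            cluster: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Shortest 8-connected pixel path from p to q via cluster pixels (BFS)."""
    if p == q:
        return [p]
    allowed = cluster | {p, q}
    frontier = [[p]]
    seen = {p}
    while frontier:
        new_frontier = []
        for path in frontier:
            x, y = path[-1]
            for dy, dx in _NEIGH:
                nb = (x + dx, y + dy)
                if nb == q:
                    return path + [q]
                if nb in allowed and nb not in seen:
                    seen.add(nb)
                    new_frontier.append(path + [nb])
        frontier = new_frontier
    return [p, q]  # disconnected cluster; fall back to direct jump


def _merge_degree2(g: VesselGraph) -> bool:
    """Merge one degree-2 node by concatenating its two edges; True if merged."""
    for nid in list(g.nodes):
        if g.degree(nid) != 2:
            continue
        e1_id, e2_id = g.adjacency[nid]
        if e1_id == e2_id:
            continue  # self-loop anchor; keep
        e1, e2 = g.edges[e1_id], g.edges[e2_id]
        p1 = e1.oriented_from(nid)[::-1]     # ends at node nid
        p2 = e2.oriented_from(nid)           # starts at node nid
        other_a = e1.node_a if e1.node_b == nid else e1.node_b
        other_b = e2.node_a if e2.node_b == nid else e2.node_b
        cluster = set(g.nodes[nid].pixels)
        u = (int(round(p1[-1][0])), int(round(p1[-1][1])))
        v = (int(round(p2[0][0])), int(round(p2[0][1])))
        bridge = _bridge_through_cluster(u, v, cluster)
        mid = np.asarray(bridge[1:-1], dtype=float).reshape(-1, 2)
        merged = np.vstack([p1, mid, p2]) if v != u else np.vstack([p1, p2[1:]])
        g.remove_edge(e1_id)
        g.remove_edge(e2_id)
        g.remove_node(nid)
        g.add_edge(merged, other_a, other_b)
        return True
    return False


def prune_spurs(graph: VesselGraph, min_len: float = 10.0) -> VesselGraph:
    """Remove endpoint-terminated edges shorter than ``min_len``, to fixpoint.

    After each removal pass, orphaned nodes are dropped and degree-2 nodes
    are merged by concatenating their two incident edges.  The operation is
    idempotent; ``min_len == 0`` leaves the graph unchanged.  The input
    graph is modified in place and returned.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    g = graph
    changed = True
    while changed:
        changed = False
        for eid in sorted(g.edges):
            e = g.edges[eid]
            if e.node_a == e.node_b:
                continue
            if (g.degree(e.node_a) == 1 or g.degree(e.node_b) == 1) and e.arc_length < min_len:
                g.remove_edge(eid)
                changed = True
        for nid in list(g.nodes):
            if g.degree(nid) == 0:
                g.remove_node(nid)
        while _merge_degree2(g):
            changed = True
    return g
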