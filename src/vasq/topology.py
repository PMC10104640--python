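"""Vessel-graph construction and five-level branch classification.

A single-pixel skeleton is converted into a graph of nodes (root,
bifurcations, leaves) and edges (ordered pixel paths between nodes).  Branch
length is the number of pixels in an edge's path; branch diameter at a
skeleton pixel is obtained from the Euclidean distance transform of the
vessel mask.  Every branch is then classified into hierarchical levels
P1..P5: the main paths from the Root to the farthest reachable leaf through
each Root-incident branch are P1, branches stemming from P1 paths are P2,
and so on, with every branch beyond level 5 capped at P5.

Hepatic portal trees are assumed acyclic; a skeleton containing a loop is
rejected with :class:`CycleError`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .skeleton import _transitions, has_2x2_block, neighbor_count

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Edge",
    "VesselGraph",
    "CycleError",
    "build_graph",
    "pixel_diameter",
    "detect_root",
    "classify_levels",
    "summarize_levels",
    "shortest_path_lengths",
    "match_edges",
]


class CycleError(ValueError):
    """Raised when the skeleton contains a loop (anastomosis), which the
    branch-level classification does not support."""


@dataclass
class Node:
    id: int
    rc: tuple[int, int]  # (row, col) representative pixel
    kind: str  # "root" | "bifurcation" | "leaf"


@dataclass
class Edge:
    id: int
    u: int  # node id
    v: int  # node id
    path: list[tuple[int, int]]  # ordered pixels, endpoints included
    length_px: int
    mean_diameter_px: float
    level: int | None = None  # 1..5 once classified


@dataclass
class VesselGraph:
    """Vessel topology: nodes, edges, and the raster geometry they live in."""

    nodes: dict[int, Node] = field(default_factory=dict)
    edges: dict[int, Edge] = field(default_factory=dict)
    shape: tuple[int, int] = (0, 0)
    pixel_pitch_um: float = 1.0

    def incident(self, node_id: int) -> list[Edge]:
        return [e for e in self.edges.values() if node_id in (e.u, e.v)]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, rc=n.rc, kind=n.kind)
        for e in self.edges.values():
            g.add_edge(e.u, e.v, key=e.id, weight=e.length_px, edge_id=e.id)
        return g

    @property
    def root_id(self) -> int | None:
        for n in self.nodes.values():
            if n.kind == "root":
                return n.id
        return None


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=np.uint8)


def pixel_diameter(pixel: tuple[int, int], mask: np.ndarray, _edt: np.ndarray | None = None) -> float:
    """Vessel diameter at a skeleton pixel, from the mask distance transform.

    The minimum Euclidean distance from the pixel center to the nearest
    background pixel, doubled and reduced by one (``2 * d_bg - 1``), which is
    exact for ideal odd-width bands: the center pixel of a width-5 band has
    ``d_bg = 3`` and diameter 5.
    """
    r, c = pixel
    if not mask[r, c]:
        raise ValueError(f"pixel {pixel} lies outside the vessel mask")
    edt = _edt if _edt is not None else ndimage.distance_transform_edt(mask != 0)
    return float(2.0 * edt[r, c] - 1.0)


def _neighbors8(r: int, c: int, shape: tuple[int, int]):
    h, w = shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc


def build_graph(
    skeleton: np.ndarray,
    mask: np.ndarray,
    pixel_pitch_um: float = 1.0,
    include_satellites: bool = False,
    simplify: bool = True,
    spur_min_px: int = 5,
) -> VesselGraph:
    """Convert a single-pixel skeleton into a :class:`VesselGraph`.

    Node typing follows the skeleton-neighbor count (1 neighbor -> leaf,
    >= 3 -> bifurcation); 8-adjacent bifurcation pixels are merged into one
    node cluster represented by the member pixel nearest the cluster
    centroid.  Per-pixel diameters come from the distance transform of
    ``mask``.

    If the skeleton has several 8-connected components, only the largest is
    analyzed by default (a warning is emitted); with
    ``include_satellites=True`` disconnected fragments are kept and their
    edges are later classified as level-5 satellites.
    """
    skel = (np.asarray(skeleton) != 0).astype(np.uint8)
    mask = (np.asarray(mask) != 0).astype(np.uint8)
    if skel.shape != mask.shape:
        raise ValueError("skeleton and mask shapes differ")
    if has_2x2_block(skel):
        raise ValueError("skeleton violates the single-pixel-width invariant (2x2 block)")

    labels, ncomp = ndimage.label(skel, structure=_EIGHT)
    if ncomp > 1 and not include_satellites:
        sizes = ndimage.sum_labels(skel, labels, index=range(1, ncomp + 1))
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(
            f"skeleton has {ncomp} components; analyzing the largest "
            f"({int(sizes[keep - 1])} px)",
            stacklevel=2,
        )
        skel = (labels == keep).astype(np.uint8)

    counts = neighbor_count(skel)
    edt = ndimage.distance_transform_edt(mask != 0)

    # junction pixels: >= 3 distinct branch arcs around the pixel (ring
    # transition count).  The surrounding "bushy" pixels -- 3-neighbor
    # pixels 8-adjacent to a junction -- are absorbed into the junction
    # cluster; without this, short chains looping through them sever real
    # links.  Lone 3-neighbor corner pixels of plain 8-connected lines
    # (diagonal shortcut) stay ordinary path pixels.
    arcs = _transitions(skel)
    core = (skel == 1) & (arcs >= 3)
    bushy = (skel == 1) & (counts >= 3)
    junction = core.copy()
    while True:
        grown = junction | (bushy & ndimage.binary_dilation(junction, structure=_EIGHT))
        if np.array_equal(grown, junction):
            break
        junction = grown
    # growth can occasionally chain along corner pixels of a thin wiggly
    # path and swallow a whole branch between two nearby junctions: demote
    # clusters that extend far beyond the local vessel radius back to their
    # true-junction cores
    jl, nj = ndimage.label(junction, structure=_EIGHT)
    for lab in range(1, nj + 1):
        pix = np.argwhere(jl == lab)
        if len(pix) < 4:
            continue
        span = max(np.ptp(pix[:, 0]), np.ptp(pix[:, 1]))
        local_radius = float(edt[pix[:, 0], pix[:, 1]].max())
        if span > max(2.0 * local_radius + 4.0, 8.0):
            keep = core[pix[:, 0], pix[:, 1]]
            junction[pix[:, 0], pix[:, 1]] = keep
    jlabels, njunc = ndimage.label(junction, structure=_EIGHT)
    node_of_pixel: dict[tuple[int, int], int] = {}
    graph = VesselGraph(shape=skel.shape, pixel_pitch_um=pixel_pitch_um)
    next_node = 0
    for lab in range(1, njunc + 1):
        pix = np.argwhere(jlabels == lab)
        centroid = pix.mean(axis=0)
        rep = pix[np.argmin(((pix - centroid) ** 2).sum(axis=1))]
        graph.nodes[next_node] = Node(next_node, (int(rep[0]), int(rep[1])), "bifurcation")
        for r, c in pix:
            node_of_pixel[(int(r), int(c))] = next_node
        next_node += 1
    for r, c in np.argwhere((skel == 1) & (counts == 1)):
        graph.nodes[next_node] = Node(next_node, (int(r), int(c)), "leaf")
        node_of_pixel[(int(r), int(c))] = next_node
        next_node += 1
    # isolated pixels form single-node components
    for r, c in np.argwhere((skel == 1) & (counts == 0)):
        graph.nodes[next_node] = Node(next_node, (int(r), int(c)), "leaf")
        node_of_pixel[(int(r), int(c))] = next_node
        next_node += 1

    # trace edges between node pixels through plain (2-neighbor) pixels
    visited = np.zeros_like(skel, dtype=bool)
    next_edge = 0
    seen_pairs: set[tuple[int, int]] = set()
    # ownership of consumed plain pixels, for resolving ambiguous corners:
    # pixel -> ("edge", edge id) or ("node", node id)
    owner: dict[tuple[int, int], tuple[str, int]] = {}

    def _cheb(p, q):
        return max(abs(p[0] - q[0]), abs(p[1] - q[1]))

    def _edge_length(ra, chain, rb):
        # pixel count of an ideal 8-connected path through the chain; the
        # gaps between cluster representatives and the chain are counted so
        # that pixels absorbed into junction clusters still contribute
        if chain:
            return _cheb(ra, chain[0]) + len(chain) + _cheb(chain[-1], rb)
        return _cheb(ra, rb) + 1

    def add_edge(nid_a: int, nid_b: int, chain: list[tuple[int, int]]) -> int | None:
        nonlocal next_edge
        if nid_a == nid_b:
            # short chain looping back into its own junction cluster: a
            # thinning artifact around the cluster, not a real branch
            for p in chain:
                owner[p] = ("node", nid_a)
            return None
        ra, rb = graph.nodes[nid_a].rc, graph.nodes[nid_b].rc
        path = [ra] + chain + [rb]
        diam = float(np.mean([2.0 * edt[r, c] - 1.0 for r, c in path]))
        graph.edges[next_edge] = Edge(
            next_edge, nid_a, nid_b, path, _edge_length(ra, chain, rb), diam
        )
        for p in chain:
            owner[p] = ("edge", next_edge)
        next_edge += 1
        return next_edge - 1

    def split_edge_at(pix: tuple[int, int]) -> int:
        """Turn a consumed chain pixel into a node, splitting its edge."""
        nonlocal next_edge, next_node
        kind, eid = owner[pix]
        assert kind == "edge"
        e = graph.edges.pop(eid)
        idx = e.path.index(pix)
        nid_new = next_node
        graph.nodes[nid_new] = Node(nid_new, pix, "bifurcation")
        node_of_pixel[pix] = nid_new
        next_node += 1
        for half_u, half_path in ((e.u, e.path[: idx + 1]), (e.v, e.path[idx:][::-1])):
            chain = half_path[1:-1]
            ra = graph.nodes[half_u].rc
            graph.edges[next_edge] = Edge(
                next_edge,
                half_u,
                nid_new,
                half_path if half_u == e.u else half_path[::-1],
                _edge_length(ra, chain, pix),
                float(np.mean([2.0 * edt[r, c] - 1.0 for r, c in half_path])),
            )
            for p in chain:
                owner[p] = ("edge", next_edge)
            next_edge += 1
        return nid_new

    for (pr, pc), nid in sorted(node_of_pixel.items()):
        starts = sorted(
            _neighbors8(pr, pc, skel.shape),
            key=lambda p: (abs(p[0] - pr) + abs(p[1] - pc), p),
        )
        for rr, cc in starts:
            if not skel[rr, cc]:
                continue
            if (rr, cc) in node_of_pixel:
                other = node_of_pixel[(rr, cc)]
                if other != nid:  # directly adjacent node clusters
                    pair = (min(nid, other), max(nid, other))
                    if pair not in seen_pairs:
                        seen_pairs.add(pair)
                        add_edge(nid, other, [])
                continue
            if visited[rr, cc]:
                # a pixel consumed by a chain that looped back into another
                # cluster still carries a real link to that cluster
                own = owner.get((rr, cc))
                if own is not None and own[0] == "node" and own[1] != nid:
                    pair = (min(nid, own[1]), max(nid, own[1]))
                    if pair not in seen_pairs:
                        seen_pairs.add(pair)
                        add_edge(nid, own[1], [])
                continue
            chain = []
            prev = (pr, pc)
            cur = (rr, cc)
            while True:
                visited[cur] = True
                chain.append(cur)
                nxt = [
                    p
                    for p in _neighbors8(*cur, skel.shape)
                    if skel[p] and p != prev and (p in node_of_pixel or not visited[p])
                ]
                # prefer a node pixel to terminate on; otherwise prefer a
                # 4-adjacent continuation so corner pixels are not skipped
                # through their diagonal shortcut
                term = [p for p in nxt if p in node_of_pixel]
                if term:
                    # a bridge pixel can touch both its own cluster and a
                    # neighboring one; connecting back to the start would
                    # silently sever the real link
                    other = [p for p in term if node_of_pixel[p] != nid]
                    add_edge(nid, node_of_pixel[(other or term)[0]], chain)
                    break
                nxt.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1]), p))
                if not nxt:
                    # all continuations already consumed: an ambiguous corner
                    # sent an earlier trace through part of this line.
                    # Reattach to whatever consumed the adjacent pixel,
                    # splitting its edge if necessary.
                    resolved = False
                    for p in sorted(
                        _neighbors8(*cur, skel.shape),
                        key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q),
                    ):
                        if p == prev or p not in owner:
                            continue
                        kind, ref = owner[p]
                        nid_b = ref if kind == "node" else split_edge_at(p)
                        add_edge(nid, nid_b, chain)
                        resolved = True
                        break
                    if not resolved:
                        # genuinely hanging line end inside the cluster halo
                        graph.nodes[next_node] = Node(next_node, cur, "leaf")
                        node_of_pixel[cur] = next_node
                        add_edge(nid, next_node, chain[:-1])
                        next_node += 1
                    break
                prev, cur = cur, nxt[0]

    # completeness sweep: a branch whose tip ends in a 2-neighbor hook has
    # no endpoint pixel, and its junction-side entry may have been consumed
    # by a cluster self-chain -- such lines are never traced above.  Collect
    # every remaining unvisited plain-pixel component and attach it through
    # whatever it touches.
    from collections import deque

    def anchor_of(p: tuple[int, int]) -> int:
        if p in node_of_pixel:
            return node_of_pixel[p]
        own = owner[p]
        return own[1] if own[0] == "node" else split_edge_at(p)

    for r0, c0 in map(tuple, np.argwhere(skel == 1)):
        if visited[r0, c0] or (r0, c0) in node_of_pixel:
            continue
        comp = []
        contacts = []
        dq = deque([(r0, c0)])
        visited[r0, c0] = True
        while dq:
            p = dq.popleft()
            comp.append(p)
            for q in _neighbors8(*p, skel.shape):
                if not skel[q]:
                    continue
                if q in node_of_pixel or q in owner:
                    if (p, q) not in contacts:
                        contacts.append((p, q))
                elif not visited[q]:
                    visited[q] = True
                    dq.append(q)

        if not contacts:
            if len(comp) > 2:
                # an untouched component with no endpoints and no junctions
                # is a closed ring of pixels
                raise CycleError(
                    "skeleton contains a loop; branch classification supports trees only"
                )
            graph.nodes[next_node] = Node(next_node, (r0, c0), "leaf")
            node_of_pixel[(r0, c0)] = next_node
            next_node += 1
            continue

        # BFS again, rooted at the first contact pixel, to order the chain
        p_in, q_out = contacts[0]
        parent_px: dict[tuple[int, int], tuple[int, int] | None] = {p_in: None}
        order = [p_in]
        dq = deque([p_in])
        comp_set = set(comp)
        while dq:
            p = dq.popleft()
            for q in _neighbors8(*p, skel.shape):
                if q in comp_set and q not in parent_px:
                    parent_px[q] = p
                    order.append(q)
                    dq.append(q)

        def chain_to(p):
            out = []
            while p is not None:
                out.append(p)
                p = parent_px[p]
            return out[::-1]  # p_in first

        nid_a = anchor_of(q_out)
        second = next((c for c in contacts[1:] if c[1] != q_out), None)
        if second is not None:
            add_edge(nid_a, anchor_of(second[1]), chain_to(second[0]))
        else:
            far = order[-1]  # farthest pixel from the contact
            graph.nodes[next_node] = Node(next_node, far, "leaf")
            node_of_pixel[far] = next_node
            add_edge(nid_a, next_node, chain_to(far)[:-1])
            next_node += 1

    # connectivity restoration: sparse staircase junctions where three lines
    # meet without any single 3-arc pixel can leave the traced graph with
    # more components than the skeleton; stitch such components back
    # together across adjacent pixel pairs
    for _ in range(20):
        comps = list(nx.connected_components(graph.to_networkx()))
        if len(comps) <= 1:
            break
        comp_of_node = {}
        for ci, comp in enumerate(comps):
            for n in comp:
                comp_of_node[n] = ci

        def pixel_comp(p):
            if p in node_of_pixel:
                return comp_of_node.get(node_of_pixel[p])
            own = owner.get(p)
            if own is None:
                return None
            return comp_of_node.get(own[1] if own[0] == "node" else graph.edges[own[1]].u)

        # BFS from every owned pixel; a few pixels (dead-end tips) may be
        # unowned, so allow the search to pass through them
        link = None
        from collections import deque

        queue = deque()
        origin: dict[tuple[int, int], tuple[int, int]] = {}
        comp_px: dict[tuple[int, int], int] = {}
        for p in sorted(set(node_of_pixel) | set(owner)):
            cp = pixel_comp(p)
            if cp is not None:
                comp_px[p] = cp
                origin[p] = p
                queue.append(p)
        while queue and link is None:
            p = queue.popleft()
            for q in _neighbors8(*p, skel.shape):
                if not skel[q]:
                    continue
                if q in comp_px:
                    if comp_px[q] != comp_px[p]:
                        link = (origin[p], origin[q])
                        break
                    continue
                comp_px[q] = comp_px[p]
                origin[q] = origin[p]
                queue.append(q)
        if link is None:
            break

        def anchor(p):
            if p in node_of_pixel:
                return node_of_pixel[p]
            own = owner[p]
            return own[1] if own[0] == "node" else split_edge_at(p)

        add_edge(anchor(link[0]), anchor(link[1]), [])

    if simplify:
        _simplify(graph, edt, spur_min_px)
    g = graph.to_networkx()
    if g.number_of_nodes() and nx.number_of_edges(g) >= g.number_of_nodes() - nx.number_connected_components(g) + 1:
        raise CycleError("skeleton contains a loop; branch classification supports trees only")
    return graph


def _simplify(graph: VesselGraph, edt: np.ndarray, spur_min_px: int) -> None:
    """Remove thinning artifacts from the raw traced graph, in place.

    Thinning a junction of a vessel of diameter D perturbs the skeleton over
    a region of roughly D/2 around the junction: it emits short terminal
    spurs and can split one anatomical junction into two nearby nodes joined
    by a micro-edge.  Both artifact classes scale with the local diameter,
    so: (1) terminal edges shorter than ``max(spur_min_px,
    0.75 * node_diameter + 3)`` are deleted; (2) junction-junction edges
    shorter than the same bound are contracted; (3) nodes left with exactly
    two incident edges are dissolved by concatenating their edges.  Repeats
    until stable.
    """

    def node_diam(nid: int) -> float:
        return max((e.mean_diameter_px for e in graph.incident(nid)), default=0.0)

    def threshold(nid: int) -> float:
        return max(float(spur_min_px), 0.75 * node_diam(nid) + 3.0)

    changed = True
    while changed:
        changed = False
        # (1) dissolve pass-through nodes so fragmented chains consolidate
        # before any length-based decision
        for nid in sorted(graph.nodes):
            node = graph.nodes.get(nid)
            if node is None or node.kind not in ("bifurcation", "root"):
                continue
            inc = graph.incident(nid)
            if len(inc) != 2 or inc[0].id == inc[1].id or any(e.u == e.v for e in inc):
                continue
            a, b = inc
            far_a = a.u if a.v == nid else a.v
            far_b = b.v if b.u == nid else b.u
            path_a = a.path if a.v == nid else a.path[::-1]  # far_a -> nid
            path_b = b.path if b.u == nid else b.path[::-1]  # nid -> far_b
            new_path = path_a + path_b[1:]
            a.u, a.v = far_a, far_b
            a.path = new_path
            a.length_px = a.length_px + b.length_px - 1  # shared node pixel
            a.mean_diameter_px = float(np.mean([2.0 * edt[r, c] - 1.0 for r, c in new_path]))
            del graph.edges[b.id]
            del graph.nodes[nid]
            changed = True
        # (2) contract short junction-junction micro-edges
        for eid in sorted(graph.edges):
            e = graph.edges.get(eid)
            if e is None:
                continue
            ku, kv = graph.nodes[e.u].kind, graph.nodes[e.v].kind
            if ku in ("bifurcation", "root") and kv in ("bifurcation", "root"):
                if e.length_px < max(threshold(e.u), threshold(e.v)):
                    keep, drop = (e.u, e.v) if node_diam(e.u) >= node_diam(e.v) else (e.v, e.u)
                    if graph.nodes[drop].kind == "root":
                        keep, drop = drop, keep
                    del graph.edges[eid]
                    for other in graph.incident(drop):
                        if other.u == drop:
                            other.u = keep
                        if other.v == drop:
                            other.v = keep
                    del graph.nodes[drop]
                    # parallel junction-junction artifacts become self-loops
                    for other in list(graph.incident(keep)):
                        if other.u == other.v:
                            del graph.edges[other.id]
                    changed = True
        # (3) diameter-aware spur removal (only after consolidation, so a
        # long terminal branch fragmented by artifact nodes is not peeled
        # away piecewise)
        for eid in sorted(graph.edges):
            e = graph.edges[eid]
            ku, kv = graph.nodes[e.u].kind, graph.nodes[e.v].kind
            if {ku, kv} == {"leaf", "bifurcation"} or (
                "leaf" in (ku, kv) and "root" in (ku, kv)
            ):
                leaf, junc = (e.u, e.v) if ku == "leaf" else (e.v, e.u)
                if e.length_px < threshold(junc) and len(graph.incident(junc)) >= 3:
                    del graph.edges[eid]
                    del graph.nodes[leaf]
                    changed = True


# ---------------------------------------------------------------------------
# root detection
# ---------------------------------------------------------------------------


def _node_diameter(graph: VesselGraph, node_id: int) -> float:
    inc = graph.incident(node_id)
    return max((e.mean_diameter_px for e in inc), default=0.0)


def _border_distance(rc: tuple[int, int], shape: tuple[int, int]) -> int:
    r, c = rc
    h, w = shape
    return min(r, c, h - 1 - r, w - 1 - c)


def detect_root(graph: VesselGraph) -> int:
    """Identify the Root: the first main bifurcation of the injected tree.

    The three bifurcation nodes with the largest diameters (diameter of a
    node = maximum mean diameter of its incident edges) are candidate Roots;
    among them the one farthest from the image border wins.  Ties are broken
    by larger diameter, then by row-major pixel order.
    """
    bifs = [n for n in graph.nodes.values() if n.kind in ("bifurcation", "root")]
    if not bifs:
        leaves = [n for n in graph.nodes.values() if n.kind == "leaf"]
        if not leaves:
            raise ValueError("graph has no nodes")
        warnings.warn("no bifurcation node; returning the thickest leaf", stacklevel=2)
        return max(leaves, key=lambda n: (_node_diameter(graph, n.id), -n.rc[0], -n.rc[1])).id
    ranked = sorted(bifs, key=lambda n: (-_node_diameter(graph, n.id), n.rc))
    top = ranked[:3]
    top.sort(
        key=lambda n: (
            -_border_distance(n.rc, graph.shape),
            -_node_diameter(graph, n.id),
            n.rc,
        )
    )
    return top[0].id


# ---------------------------------------------------------------------------
# level classification
# ---------------------------------------------------------------------------


def shortest_path_lengths(graph: VesselGraph, source: int) -> dict[int, float]:
    """Dijkstra shortest-path distances (edge weight = length_px) from a node."""
    return dict(nx.single_source_dijkstra_path_length(graph.to_networkx(), source, weight="weight"))


def classify_levels(graph: VesselGraph, root: int, max_level: int = 5) -> VesselGraph:
    """Assign branch levels P1..P5 in place and return the graph.

    From the Root, each incident branch defines a main path to the leaf with
    the largest shortest-path distance reached through that branch: those
    edges are level 1.  Bifurcation nodes on level-L paths become level-(L+1)
    roots for the branches not yet claimed; an edge keeps the level of the
    first path that claims it.  Levels beyond ``max_level`` are recorded as
    ``max_level``.  Satellite components (disconnected from the Root) are
    assigned ``max_level``.
    """
    if root not in graph.nodes:
        raise ValueError(f"root node {root} not in graph")
    for e in graph.edges.values():
        e.level = None

    adjacency: dict[int, list[Edge]] = {n: [] for n in graph.nodes}
    for e in graph.edges.values():
        adjacency[e.u].append(e)
        adjacency[e.v].append(e)

    def farthest_leaf_path(start: int, first: Edge) -> list[Edge]:
        """DFS over unassigned edges; return the edge path to the farthest leaf."""
        best_key: tuple = (-1.0, ())
        best_path: tuple[Edge, ...] = (first,)
        other0 = first.v if first.u == start else first.u
        stack = [(other0, float(first.length_px), (first,), frozenset({start}))]
        while stack:
            node, dist, path, seen = stack.pop()
            moved = False
            for e in adjacency[node]:
                if e.level is not None or e in path:
                    continue
                other = e.v if e.u == node else e.u
                if other in seen:
                    continue
                stack.append((other, dist + e.length_px, path + (e,), seen | {node}))
                moved = True
            if not moved:
                key = (dist, tuple(-e.id for e in path))  # ties -> smaller edge ids
                if key > best_key:
                    best_key, best_path = key, path
        return list(best_path)

    queue: list[tuple[int, int]] = [(root, 1)]
    while queue:
        node, level = queue.pop(0)
        lvl = min(level, max_level)
        for branch in sorted(adjacency[node], key=lambda e: e.id):
            if branch.level is not None:
                continue
            path = farthest_leaf_path(node, branch)
            cur = node
            for e in path:
                e.level = lvl
                cur = e.v if e.u == cur else e.u
                if graph.nodes[cur].kind in ("bifurcation", "root") and any(
                    x.level is None for x in adjacency[cur]
                ):
                    queue.append((cur, level + 1))
    # disconnected satellites (no path from root) are distal fragments
    for e in graph.edges.values():
        if e.level is None:
            e.level = max_level
    return graph


# ---------------------------------------------------------------------------
# summaries and ground-truth matching
# ---------------------------------------------------------------------------


def summarize_levels(graphs: list[VesselGraph], times=None, max_level: int = 5):
    """Tidy per-level, per-time-point branch statistics.

    Returns a :class:`pandas.DataFrame` with branch count, accumulated length
    (px and µm), mean diameter (px and µm) per level, plus count and length
    ratios normalized to the first time point.
    """
    import pandas as pd

    if not graphs:
        raise ValueError("empty graph sequence")
    if times is None:
        times = list(range(len(graphs)))
    rows = []
    for t, g in zip(times, graphs):
        for lvl in range(1, max_level + 1):
            edges = [e for e in g.edges.values() if e.level == lvl]
            total_px = sum(e.length_px for e in edges)
            diam = float(np.mean([e.mean_diameter_px for e in edges])) if edges else 0.0
            rows.append(
                {
                    "time": t,
                    "level": lvl,
                    "n_branches": len(edges),
                    "total_length_px": total_px,
                    "total_length_um": total_px * g.pixel_pitch_um,
                    "mean_diameter_px": diam,
                    "mean_diameter_um": diam * g.pixel_pitch_um,
                }
            )
    df = pd.DataFrame(rows)
    ref = df[df.time == times[0]].set_index("level")
    df["count_ratio"] = [
        (row.n_branches / ref.loc[row.level, "n_branches"]) if ref.loc[row.level, "n_branches"] else 0.0
        for row in df.itertuples()
    ]
    df["length_ratio"] = [
        (row.total_length_px / ref.loc[row.level, "total_length_px"])
        if ref.loc[row.level, "total_length_px"]
        else 0.0
        for row in df.itertuples()
    ]
    return df


def match_edges(pred: VesselGraph, truth: VesselGraph) -> dict[int, int]:
    """Match each predicted edge to the nearest ground-truth edge.

    Uses the mean distance from the predicted edge's path pixels to each
    truth edge's path (KD-tree per truth edge); returns a mapping
    ``pred_edge_id -> truth_edge_id``.
    """
    from scipy.spatial import cKDTree

    trees = {eid: cKDTree(np.asarray(e.path, dtype=float)) for eid, e in truth.edges.items()}
    mapping: dict[int, int] = {}
    for eid, e in pred.edges.items():
        pts = np.asarray(e.path, dtype=float)
        best, best_d = None, np.inf
        for tid, tree in trees.items():
            d = float(tree.query(pts)[0].mean())
            if d < best_d:
                best, best_d = tid, d
        mapping[eid] = best
    return mapping
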