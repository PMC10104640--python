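"""Graph building, root detection, and P1-P5 branch classification."""

import numpy as np
import pytest

from vasq.topology import (
    CycleError,
    Edge,
    Node,
    VesselGraph,
    build_graph,
    classify_levels,
    detect_root,
    match_edges,
    pixel_diameter,
    shortest_path_lengths,
    summarize_levels,
)

from conftest import analyzed_graph, phantom_bundle


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def make_graph(nodes, edges, shape=(100, 100)):
    """nodes: (id, rc, kind); edges: (id, u, v, length, diam)."""
    g = VesselGraph(shape=shape)
    for nid, rc, kind in nodes:
        g.nodes[nid] = Node(nid, rc, kind)
    for eid, u, v, length, diam in edges:
        g.edges[eid] = Edge(eid, u, v, [g.nodes[u].rc, g.nodes[v].rc], length, diam)
    return g


def skeleton_canvas(pixels, shape=(40, 60)):
    skel = np.zeros(shape, np.uint8)
    for p in pixels:
        skel[p] = 1
    return skel


# ---------------------------------------------------------------------------
# graph construction from pixels
# ---------------------------------------------------------------------------


def test_straight_path_two_leaves_one_edge():
    pix = [(20, c) for c in range(5, 35)]
    skel = skeleton_canvas(pix)
    g = build_graph(skel, skel)
    kinds = sorted(n.kind for n in g.nodes.values())
    assert kinds == ["leaf", "leaf"]
    assert len(g.edges) == 1
    assert g.edges[0].length_px == 30


def test_y_junction_three_edges():
    trunk = [(20, c) for c in range(4, 24)]
    arm_up = [(20 - i, 24 + i) for i in range(1, 16)]
    arm_dn = [(20 + i, 24 + i) for i in range(1, 16)]
    skel = skeleton_canvas(trunk + [(20, 24)] + arm_up + arm_dn)
    g = build_graph(skel, skel)
    kinds = sorted(n.kind for n in g.nodes.values())
    assert kinds == ["bifurcation", "leaf", "leaf", "leaf"]
    assert len(g.edges) == 3
    lengths = sorted(e.length_px for e in g.edges.values())
    assert lengths[0] in (15, 16) and lengths[1] in (15, 16)
    assert lengths[2] in (20, 21, 22)


def test_plus_sign_single_four_way_node():
    c = (20, 30)
    pix = [c]
    for d in range(1, 9):
        pix += [(20 - d, 30), (20 + d, 30), (20, 30 - d), (20, 30 + d)]
    skel = skeleton_canvas(pix)
    g = build_graph(skel, skel)
    bifs = [n for n in g.nodes.values() if n.kind == "bifurcation"]
    assert len(bifs) == 1 and bifs[0].rc == c
    assert len(g.edges) == 4


def test_two_by_two_block_rejected():
    skel = np.zeros((10, 10), np.uint8)
    skel[4:6, 4:6] = 1
    with pytest.raises(ValueError, match="2x2"):
        build_graph(skel, skel)


def test_cycle_rejected():
    ring = np.zeros((20, 20), np.uint8)
    ring[5, 5:15] = 1
    ring[14, 5:15] = 1
    ring[5:15, 5] = 1
    ring[5:15, 14] = 1
    with pytest.raises(CycleError):
        build_graph(ring, ring)


def test_disconnected_components_largest_kept_with_warning():
    skel = np.zeros((40, 60), np.uint8)
    skel[10, 5:45] = 1
    skel[30, 5:12] = 1
    with pytest.warns(UserWarning, match="components"):
        g = build_graph(skel, skel)
    assert len(g.edges) == 1 and g.edges[0].length_px == 40


# ---------------------------------------------------------------------------
# per-pixel diameter
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("width,expected", [(3, 3.0), (5, 5.0)])
def test_pixel_diameter_exact_on_odd_bands(width, expected):
    mask = np.zeros((width + 10, 30), np.uint8)
    mask[5 : 5 + width] = 1
    center = 5 + width // 2
    assert pixel_diameter((center, 15), mask) == pytest.approx(expected)


def test_pixel_diameter_isolated_pixel_and_outside_error():
    mask = np.zeros((10, 10), np.uint8)
    mask[4, 4] = 1
    assert pixel_diameter((4, 4), mask) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        pixel_diameter((0, 0), mask)


# ---------------------------------------------------------------------------
# root detection
# ---------------------------------------------------------------------------


def test_root_is_thickest_interior_candidate():
    # two equal-diameter bifurcations; the one next to the border loses
    g = make_graph(
        [(0, (50, 50), "bifurcation"), (1, (2, 50), "bifurcation"),
         (2, (50, 10), "leaf"), (3, (50, 90), "leaf"), (4, (2, 90), "leaf"), (5, (90, 50), "leaf")],
        [(0, 0, 2, 40, 20.0), (1, 0, 1, 48, 20.0), (2, 1, 4, 40, 20.0),
         (3, 0, 3, 40, 6.0), (4, 0, 5, 40, 6.0)],
    )
    assert detect_root(g) == 0


def test_single_bifurcation_is_root_regardless_of_position():
    g = make_graph(
        [(0, (1, 1), "bifurcation"), (1, (10, 10), "leaf"), (2, (1, 20), "leaf"), (3, (20, 1), "leaf")],
        [(0, 0, 1, 13, 4.0), (1, 0, 2, 19, 3.0), (2, 0, 3, 19, 2.0)],
    )
    assert detect_root(g) == 0


def test_no_bifurcation_returns_thickest_leaf_with_warning():
    g = make_graph(
        [(0, (10, 10), "leaf"), (1, (10, 40), "leaf")],
        [(0, 0, 1, 31, 8.0)],
    )
    with pytest.warns(UserWarning, match="bifurcation"):
        assert detect_root(g) in (0, 1)


def test_root_matches_phantom_injection_site():
    b = phantom_bundle(seed=3, noise_sd_gray=0.0)
    graph, root = analyzed_graph(b)
    truth_rc = next(n.rc for n in b.truth_graph.nodes.values() if n.kind == "root")
    rc = graph.nodes[root].rc
    assert np.hypot(rc[0] - truth_rc[0], rc[1] - truth_rc[1]) < 25


# ---------------------------------------------------------------------------
# level classification
# ---------------------------------------------------------------------------


def test_single_chain_is_entirely_p1():
    g = make_graph(
        [(0, (50, 10), "bifurcation"), (1, (50, 40), "leaf"), (2, (50, 80), "leaf")],
        [(0, 0, 1, 31, 4.0), (1, 0, 2, 41, 4.0)],
    )
    classify_levels(g, 0)
    assert all(e.level == 1 for e in g.edges.values())


def test_depth_seven_binary_tree_caps_at_level_five():
    nodes = [(0, (0, 0), "bifurcation")]
    edges = []
    next_node, next_edge = 1, 0
    frontier = [(0, 0)]  # (node id, depth)
    for depth in range(1, 8):
        new = []
        for parent, _ in frontier:
            for _ in range(2):
                kind = "leaf" if depth == 7 else "bifurcation"
                nodes.append((next_node, (depth, next_node), kind))
                edges.append((next_edge, parent, next_node, 10 + depth, 3.0))
                new.append((next_node, depth))
                next_node += 1
                next_edge += 1
        frontier = new
    g = make_graph(nodes, edges, shape=(300, 300))
    classify_levels(g, 0)
    levels = {e.level for e in g.edges.values()}
    assert max(levels) == 5
    assert min(levels) == 1
    assert sum(1 for e in g.edges.values() if e.level == 5) > 0


def test_hand_tree_oracle():
    """Trunk splits into a long arm A and a short arm B; B splits again.

    Exhaustive enumeration on this tiny tree: every Root-incident branch
    extends into a P1 path through its farthest leaf, so A, the trunk, and
    B's longer continuation are P1, while B's shorter side branch is the
    only P2 edge.
    """
    g = make_graph(
        [(0, (50, 30), "bifurcation"),  # Root
         (1, (50, 10), "leaf"),        # trunk entry
         (2, (30, 60), "leaf"),        # A end
         (3, (60, 38), "bifurcation"),  # B end, splits again
         (4, (70, 50), "leaf"), (5, (65, 30), "leaf")],
        [(0, 0, 1, 20, 8.0),   # trunk
         (1, 0, 2, 40, 5.0),   # arm A
         (2, 0, 3, 10, 5.0),   # arm B
         (3, 3, 4, 18, 3.0),   # B child, longer
         (4, 3, 5, 9, 3.0)],   # B child, shorter
    )
    classify_levels(g, 0)
    assert [g.edges[i].level for i in range(5)] == [1, 1, 1, 1, 2]


def test_level_partition_covers_all_edges(clean_bundle):
    graph, _ = analyzed_graph(clean_bundle)
    assert all(e.level in range(1, 6) for e in graph.edges.values())
    counts = {lvl: sum(1 for e in graph.edges.values() if e.level == lvl) for lvl in range(1, 6)}
    assert sum(counts.values()) == len(graph.edges)


def test_levels_match_phantom_ground_truth(clean_bundle):
    graph, _ = analyzed_graph(clean_bundle)
    mapping = match_edges(graph, clean_bundle.truth_graph)
    truth = clean_bundle.truth_graph
    assert all(graph.edges[pe].level == truth.edges[te].level for pe, te in mapping.items())


def test_level_assignment_invariant_under_90_degree_rotation(clean_bundle):
    import warnings
    from collections import Counter

    from vasq.skeleton import prune_spurs, skeletonize

    base, _ = analyzed_graph(clean_bundle)
    rotated_mask = np.rot90(clean_bundle.truth_mask).copy()
    skel = prune_spurs(skeletonize(rotated_mask), 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = build_graph(skel, rotated_mask, clean_bundle.spec.pixel_pitch_um)
    root = detect_root(g)
    classify_levels(g, root)
    assert Counter(e.level for e in g.edges.values()) == Counter(e.level for e in base.edges.values())


# ---------------------------------------------------------------------------
# Dijkstra vs brute force
# ---------------------------------------------------------------------------


def random_weighted_graph(rng, n_nodes):
    g = VesselGraph(shape=(100, 100))
    for i in range(n_nodes):
        g.nodes[i] = Node(i, (int(rng.integers(100)), int(rng.integers(100))), "bifurcation")
    eid = 0
    for i in range(1, n_nodes):  # random spanning tree
        j = int(rng.integers(i))
        g.edges[eid] = Edge(eid, i, j, [g.nodes[i].rc, g.nodes[j].rc], int(rng.integers(1, 50)), 1.0)
        eid += 1
    for _ in range(int(rng.integers(0, 3))):  # extra edges (may close cycles)
        i, j = rng.integers(n_nodes, size=2)
        if i != j:
            g.edges[eid] = Edge(eid, int(i), int(j), [g.nodes[i].rc, g.nodes[j].rc], int(rng.integers(1, 50)), 1.0)
            eid += 1
    return g


def brute_force_distances(g, source):
    best = {source: 0}
    adjacency = {}
    for e in g.edges.values():
        adjacency.setdefault(e.u, []).append(e)
        adjacency.setdefault(e.v, []).append(e)

    def explore(node, dist, seen):
        for e in adjacency.get(node, []):
            other = e.v if e.u == node else e.u
            if other in seen:
                continue
            nd = dist + e.length_px
            if nd < best.get(other, float("inf")):
                best[other] = nd
            explore(other, nd, seen | {other})

    explore(source, 0, {source})
    return best


@pytest.mark.parametrize("trial", range(20))
def test_dijkstra_matches_exhaustive_enumeration(trial):
    rng = np.random.default_rng(trial)
    g = random_weighted_graph(rng, int(rng.integers(3, 11)))
    dj = shortest_path_lengths(g, 0)
    bf = brute_force_distances(g, 0)
    assert set(dj) == set(bf)
    for node in bf:
        assert dj[node] == pytest.approx(bf[node])


# ---------------------------------------------------------------------------
# level summaries
# ---------------------------------------------------------------------------


def two_level_graph(p3_edges):
    nodes = [(0, (10, 10), "root"), (1, (10, 30), "leaf")]
    edges = [(0, 0, 1, 21, 8.0)]
    g = make_graph(nodes, edges)
    g.edges[0].level = 1
    for k in range(p3_edges):
        nid = 2 + k
        g.nodes[nid] = Node(nid, (20 + k, 10), "leaf")
        eid = 1 + k
        g.edges[eid] = Edge(eid, 0, nid, [(10, 10), (20 + k, 10)], 10, 3.0, level=3)
    return g


def test_summarize_single_time_point_normalizes_to_one():
    df = summarize_levels([two_level_graph(4)])
    row = df[(df.level == 1)].iloc[0]
    assert row.count_ratio == 1.0 and row.length_ratio == 1.0


def test_summarize_tracks_level_loss_over_time():
    df = summarize_levels([two_level_graph(4), two_level_graph(2)])
    p3 = df[(df.level == 3) & (df.time == 1)].iloc[0]
    assert p3.length_ratio == pytest.approx(0.5)
    absent = df[(df.level == 2) & (df.time == 1)].iloc[0]
    assert absent.n_branches == 0 and absent.count_ratio == 0.0


def test_summarize_rejects_empty_sequence():
    with pytest.raises(ValueError):
        summarize_levels([])
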