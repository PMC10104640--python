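"""Synthetic vascular phantoms with complete ground truth.

The generator draws a branching vessel tree entering the canvas from the
left border, rasterizes it into a binary mask, renders a bright-field
channel whose intravascular grayscale follows the modified Beer-Lambert
attenuation ``A = epsilon * log10(c * d) + k`` (``c`` in mg/mL, optical path
``d`` in µm), and renders a fluorescent channel as a uniform intravascular
signal plus an extravascular halo decaying as ``G(x) = G_wall *
exp(-x / halo_scale)`` with ``x`` the distance to the vessel wall.  The
bundle carries the ground-truth mask, vessel graph (with branch levels and
per-edge concentrations), so every downstream pipeline stage can be tested
without external microscopy data.

Branch levels in the ground truth follow the same path-based semantics the
classifier uses: every Root-incident branch extends into a level-1 main path
to its farthest leaf (pixel-count metric), side branches are level 2, and so
on, capped at level 5.  The generator enforces a minimum length margin
between the farthest and second-farthest leaf of every subtree so that the
level assignment is robust to the few pixels of jitter that mask
skeletonization introduces.

Geometry conventions: row-major arrays, origin top-left, 0-based; public
distances in µm, converted through ``pixel_pitch_um``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .topology import Edge, Node, VesselGraph

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "PhantomBundle", "PhantomGeometryError", "generate_phantom", "rasterize_tube"]

# Geometry of the synthetic tree (fractions of min(height, width) unless noted).
_TRUNK_FRAC = 0.45  # trunk length
_TRUNK_ANGLE_JITTER_DEG = 8.0
_BASE2_FRAC = 0.12  # base segment length at generation 2
_LENGTH_DECAY = 0.75  # per-generation shrink of the base length
_MINOR_LEN_FACTOR = 0.5  # side branches are half as long as main continuations
_LEN_JITTER = (0.95, 1.05)
_MAJOR_ANGLE_DEG = 5.0  # main continuation stays within +/-5 deg of parent
_MINOR_ANGLE_DEG = (55.0, 70.0)  # wide forks keep sibling tubes from fusing
_MIN_ANGLE_SEP_DEG = 25.0
_MAX_FAN_DEG = 80.0  # branches never deviate more than this from the trunk axis
_MIN_LEVEL_MARGIN_PX = 12.0  # farthest-leaf margin guaranteeing stable levels
_MAX_TREE_TRIES = 200
_MAX_SEGMENT_TRIES = 40


class PhantomGeometryError(RuntimeError):
    """Raised when a valid tree cannot be laid out for the requested spec."""


_DEFAULT_DIAMETERS = ((600.0, 80.0), (250.0, 30.0), (100.0, 15.0), (64.0, 8.0), (55.0, 7.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic vascular phantom.

    ``diameter_by_level_um`` holds (mean, spread) pairs for levels P1..Pn;
    the defaults emulate a hepatic portal tree imaged at stereomicroscope
    scale (P3 = 100 +/- 15 µm, P4 = 64 +/- 8 µm, P5 = 55 +/- 7 µm).  The
    default pitch of 20 µm/px on a 1024x1024 canvas gives a ~2 cm field in
    which branch lengths are realistically large (8-20x) relative to the
    printed vessel diameters, while the ~600 µm trunk still spans ~30 px.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_pitch_um: float = 20.0
    n_levels: int = 5
    branching_factor: int = 2
    diameter_by_level_um: tuple[tuple[float, float], ...] = _DEFAULT_DIAMETERS
    trunk_concentration_mg_ml: float = 5.0
    concentration_decay_per_level: float = 0.8
    halo_scale_um: float = 100.0
    fluor_wall_gray: float = 180.0
    noise_sd_gray: float = 6.0
    background_gray: float = 220.0
    epsilon: float = 0.249
    k: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if not (0 <= self.n_levels <= 7):
            raise ValueError("n_levels must be in 0..7")
        if self.branching_factor < 1:
            raise ValueError("branching_factor must be >= 1")
        if len(self.diameter_by_level_um) < max(self.n_levels, 1) and self.n_levels > 0:
            raise ValueError("diameter_by_level_um must cover every level")
        means = [m for m, _ in self.diameter_by_level_um]
        if any(m <= 0 for m in means):
            raise ValueError("zero or negative vessel diameter requested")
        if any(a <= b for a, b in zip(means, means[1:])):
            raise ValueError("diameters must strictly decrease with level")
        if self.trunk_concentration_mg_ml < 0:
            raise ValueError("concentrations must be >= 0")
        if not (0 < self.concentration_decay_per_level <= 1):
            raise ValueError("concentration_decay_per_level must be in (0, 1]")
        if self.halo_scale_um <= 0:
            raise ValueError("halo_scale_um must be positive")
        if self.noise_sd_gray < 0:
            raise ValueError("noise_sd_gray must be >= 0")
        if not (0 < self.background_gray <= 255):
            raise ValueError("background_gray must be in (0, 255]")


@dataclass
class PhantomBundle:
    """Synthetic image pair plus the ground truth that produced it."""

    bright_field: np.ndarray  # float64 grayscale in [0, 255]
    fluorescent: np.ndarray
    truth_mask: np.ndarray  # uint8 binary
    truth_graph: VesselGraph
    truth_concentration: dict[int, float]  # edge id -> mg/mL
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# low-level raster helpers
# ---------------------------------------------------------------------------


def _line_pixels(p0: tuple[int, int], p1: tuple[int, int]) -> list[tuple[int, int]]:
    """8-connected, duplicate-free pixel path from p0 to p1 (inclusive)."""
    r0, c0 = p0
    r1, c1 = p1
    n = max(abs(r1 - r0), abs(c1 - c0)) + 1
    rr = np.rint(np.linspace(r0, r1, n)).astype(int)
    cc = np.rint(np.linspace(c0, c1, n)).astype(int)
    return list(zip(rr.tolist(), cc.tolist()))


def _segment_distance_field(p0, p1, shape, radius_pad: float):
    """(slice, distance) of pixels within radius_pad of segment p0-p1."""
    (r0, c0), (r1, c1) = p0, p1
    pad = int(np.ceil(radius_pad)) + 1
    rmin = max(0, int(np.floor(min(r0, r1))) - pad)
    rmax = min(shape[0], int(np.ceil(max(r0, r1))) + pad + 1)
    cmin = max(0, int(np.floor(min(c0, c1))) - pad)
    cmax = min(shape[1], int(np.ceil(max(c0, c1))) + pad + 1)
    if rmin >= rmax or cmin >= cmax:
        return None, None
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dr, dc = r1 - r0, c1 - c0
    seg2 = dr * dr + dc * dc
    if seg2 == 0:
        dist = np.hypot(rr - r0, cc - c0)
    else:
        t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / seg2, 0.0, 1.0)
        dist = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
    return (slice(rmin, rmax), slice(cmin, cmax)), dist


def rasterize_tube(
    p0: tuple[float, float],
    p1: tuple[float, float],
    diameter_px: float,
    canvas: np.ndarray,
) -> np.ndarray:
    """Stamp a tube (segment dilated by diameter/2) onto a binary canvas.

    All pixels whose centers lie within ``diameter_px / 2`` of the segment
    are set to foreground; the operation is idempotent and the union of
    repeated calls.  Parts of the tube falling outside the canvas are
    clipped (a warning is logged when the segment itself leaves the canvas).
    """
    if diameter_px < 1:
        raise ValueError("diameter_px must be >= 1")
    h, w = canvas.shape
    for r, c in (p0, p1):
        if not (0 <= r < h and 0 <= c < w):
            logger.warning("tube segment endpoint %s outside canvas %s; clipping", (r, c), canvas.shape)
    window, dist = _segment_distance_field(p0, p1, canvas.shape, diameter_px / 2)
    if window is not None:
        canvas[window] |= (dist <= diameter_px / 2).astype(canvas.dtype)
    return canvas


# ---------------------------------------------------------------------------
# abstract tree construction
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    id: int
    parent: int | None  # parent segment id
    generation: int  # 1 = trunk
    p0: tuple[float, float]
    p1: tuple[float, float]
    angle: float  # radians
    diameter_px: float
    major: bool
    level: int | None = None
    children: list[int] = field(default_factory=list)


def _seg_seg_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2D segments."""

    def pt_seg(p, q0, q1):
        q0, q1, p = np.asarray(q0, float), np.asarray(q1, float), np.asarray(p, float)
        d = q1 - q0
        seg2 = float(d @ d)
        t = 0.0 if seg2 == 0 else float(np.clip((p - q0) @ d / seg2, 0, 1))
        return float(np.linalg.norm(p - (q0 + t * d)))

    # segments are short relative to curvature of interest; endpoint checks
    # plus midpoints are sufficient for collision rejection
    cands = [pt_seg(a0, b0, b1), pt_seg(a1, b0, b1), pt_seg(b0, a0, a1), pt_seg(b1, a0, a1)]
    am = ((a0[0] + a1[0]) / 2, (a0[1] + a1[1]) / 2)
    bm = ((b0[0] + b1[0]) / 2, (b0[1] + b1[1]) / 2)
    cands += [pt_seg(am, b0, b1), pt_seg(bm, a0, a1)]
    return min(cands)


def _draw_diameter(rng: np.random.Generator, spec: PhantomSpec, level: int, parent_px: float | None) -> float:
    mean, sd = spec.diameter_by_level_um[min(level, len(spec.diameter_by_level_um)) - 1]
    d_um = float(rng.normal(mean, sd))
    d_px = max(1.0, d_um / spec.pixel_pitch_um)
    if parent_px is not None:
        d_px = min(d_px, parent_px * 0.98)  # diameters taper monotonically
    return max(1.0, d_px)


def _build_tree(spec: PhantomSpec, rng: np.random.Generator) -> list[_Segment]:
    h, w = spec.image_height_px, spec.image_width_px
    scale = min(h, w)
    segs: list[_Segment] = []

    def in_bounds(p, radius):
        margin = radius + 2
        return margin <= p[0] < h - margin and margin <= p[1] < w - margin

    def collides(cand: _Segment) -> bool:
        for s in segs:
            if s.id == cand.parent or (cand.parent is not None and s.parent == cand.parent):
                continue  # sharing a junction node
            if _seg_seg_distance(cand.p0, cand.p1, s.p0, s.p1) < (cand.diameter_px + s.diameter_px) / 2 + 3:
                return True
        return False

    # trunk: enters from the left border and ends near the canvas center,
    # mimicking an acquisition centered on the injected root region (this
    # also guarantees the root junction is the most interior thick node,
    # which the farthest-from-border root-detection rule relies on)
    trunk_d = _draw_diameter(rng, spec, 1, None)
    for attempt in range(_MAX_SEGMENT_TRIES):
        p1 = (
            h / 2 + rng.uniform(-0.02, 0.02) * scale,
            w / 2 + rng.uniform(-0.02, 0.02) * scale,
        )
        ang = np.deg2rad(rng.uniform(-_TRUNK_ANGLE_JITTER_DEG, _TRUNK_ANGLE_JITTER_DEG))
        p0 = (p1[0] - p1[1] * np.tan(ang), 0.0)
        if in_bounds(p1, trunk_d / 2) and 0 <= p0[0] < h:
            break
    else:
        raise PhantomGeometryError("level 1 trunk does not fit the canvas")
    segs.append(_Segment(0, None, 1, p0, p1, ang, trunk_d, True))

    frontier = [0]
    base_len = _BASE2_FRAC * scale
    for gen in range(2, spec.n_levels + 1):
        new_frontier = []
        for pid in frontier:
            parent = segs[pid]
            # angular offsets: one major continuation plus alternating minors
            for attempt in range(_MAX_SEGMENT_TRIES):
                offs = [np.deg2rad(rng.uniform(-_MAJOR_ANGLE_DEG, _MAJOR_ANGLE_DEG))]
                side = 1 if rng.random() < 0.5 else -1
                for j in range(spec.branching_factor - 1):
                    mag = rng.uniform(*_MINOR_ANGLE_DEG) + 25.0 * (j // 2)
                    offs.append(np.deg2rad(side * mag))
                    side = -side
                sep_ok = all(
                    abs(a - b) >= np.deg2rad(_MIN_ANGLE_SEP_DEG)
                    for i, a in enumerate(offs)
                    for b in offs[i + 1 :]
                )
                if sep_ok:
                    break
            else:
                raise PhantomGeometryError(f"cannot separate branches at level {gen}")
            trunk_ang = segs[0].angle
            placed_angles: list[float] = []
            sep = np.deg2rad(_MIN_ANGLE_SEP_DEG)
            for j, off in enumerate(offs):
                is_major = j == 0
                for attempt in range(_MAX_SEGMENT_TRIES):
                    jit = 0.0 if attempt == 0 else np.deg2rad(rng.uniform(-12, 12))
                    fan = np.deg2rad(_MAX_FAN_DEG)
                    ang = parent.angle + off + jit
                    if abs(ang - trunk_ang) > fan:  # mirror the fork inward
                        ang = parent.angle - off + jit
                    ang = float(np.clip(ang, trunk_ang - fan, trunk_ang + fan))
                    if any(abs(ang - pa) < sep for pa in placed_angles):
                        continue
                    factor = 1.0 if is_major else _MINOR_LEN_FACTOR
                    length = base_len * factor * rng.uniform(*_LEN_JITTER)
                    d_px = _draw_diameter(rng, spec, gen, parent.diameter_px)
                    # sibling tubes fuse over ~(r_i + r_j)/sin(dtheta) from
                    # the junction; keep that zone well short of the branch
                    fused = False
                    for sid in parent.children:
                        sib = segs[sid]
                        dth = abs(ang - sib.angle)
                        zone = (d_px + sib.diameter_px + 4) / (2 * max(np.sin(dth), 1e-6))
                        if zone > 0.35 * min(length, np.hypot(sib.p1[0] - sib.p0[0], sib.p1[1] - sib.p0[1])):
                            fused = True
                            break
                    if fused:
                        continue
                    p1 = (
                        parent.p1[0] + length * np.sin(ang),
                        parent.p1[1] + length * np.cos(ang),
                    )
                    cand = _Segment(len(segs), pid, gen, parent.p1, p1, ang, d_px, is_major)
                    if in_bounds(p1, d_px / 2) and not collides(cand):
                        segs.append(cand)
                        parent.children.append(cand.id)
                        new_frontier.append(cand.id)
                        placed_angles.append(ang)
                        break
                else:
                    raise PhantomGeometryError(
                        f"cannot place a level-{gen} branch inside the canvas"
                    )
        frontier = new_frontier
        base_len *= _LENGTH_DECAY
    _check_overlap(spec, segs)
    return segs


def _check_overlap(spec: PhantomSpec, segs: list[_Segment]) -> None:
    """Reject trees whose tubes fuse: pairwise collision tests exempt
    segments sharing a junction, so a deeply zig-zagging tree can still
    collapse onto itself.  Every tube must own a clear majority of its
    pixels exclusively (junction neighborhoods aside)."""
    h, w = spec.image_height_px, spec.image_width_px
    coverage = np.zeros((h, w), dtype=np.uint8)
    stamps = []
    for s in segs:
        window, dist = _segment_distance_field(s.p0, s.p1, (h, w), s.diameter_px / 2)
        inside = dist <= s.diameter_px / 2
        stamps.append((window, inside))
        coverage[window] += inside
    for s, (window, inside) in zip(segs, stamps):
        area = int(inside.sum())
        if area == 0:
            raise PhantomGeometryError(f"level-{s.generation} branch rasterizes to nothing")
        unique = int((inside & (coverage[window] == 1)).sum())
        # overlap at the two junctions is expected: about one parent radius
        # (resp. child radius) of tube length at each end
        allowed = 2.0 * s.diameter_px
        if s.parent is not None:
            allowed += 1.5 * s.diameter_px * segs[s.parent].diameter_px / 2
        for c in s.children:
            allowed += 1.5 * s.diameter_px * segs[c].diameter_px / 2
        if area - unique > allowed:
            raise PhantomGeometryError(f"level-{s.generation} branch fuses with its neighbors")


# ---------------------------------------------------------------------------
# path-based ground-truth levels
# ---------------------------------------------------------------------------


def _pixel_length(seg: _Segment) -> int:
    p0 = (int(round(seg.p0[0])), int(round(seg.p0[1])))
    p1 = (int(round(seg.p1[0])), int(round(seg.p1[1])))
    return len(_line_pixels(p0, p1))


def _assign_levels(segs: list[_Segment], max_level: int = 5) -> float:
    """Assign path-based levels in place; return the smallest leaf margin.

    The trunk's inner end is the Root.  Each Root-incident branch (the trunk
    itself plus the trunk's children) extends into a level-1 path to its
    farthest leaf; bifurcations on a level-L path spawn level-(L+1) paths.
    Distances use rasterized pixel counts, the same metric the pixel-level
    classifier uses.  The returned margin is the minimum gap between the
    best and second-best leaf distance over all selections (infinity when
    no selection is ambiguous).
    """
    if not segs:
        return np.inf
    lengths = {s.id: _pixel_length(s) for s in segs}
    min_margin = np.inf

    def farthest(seg_id: int) -> tuple[float, list[int]]:
        """Farthest-leaf distance down-tree through segment seg_id."""
        s = segs[seg_id]
        if not s.children:
            return lengths[seg_id], [seg_id]
        best = sorted(
            ((farthest(c)) for c in s.children), key=lambda t: t[0], reverse=True
        )
        nonlocal min_margin
        if len(best) > 1:
            min_margin = min(min_margin, best[0][0] - best[1][0])
        d, path = best[0]
        return lengths[seg_id] + d, [seg_id] + path

    trunk = segs[0]
    # Root-incident branches: trunk (leaf at the border) and its children
    queue: list[tuple[int, int]] = []  # (segment id starting a path, level)
    trunk.level = 1
    for c in trunk.children:
        queue.append((c, 1))
    while queue:
        sid, level = queue.pop(0)
        _, path = farthest(sid)
        for k in path:
            segs[k].level = min(level, max_level)
        for k in path:
            for c in segs[k].children:
                if segs[c].level is None:
                    queue.append((c, level + 1))
    return min_margin


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render(spec: PhantomSpec, segs: list[_Segment], rng: np.random.Generator):
    h, w = spec.image_height_px, spec.image_width_px
    mask = np.zeros((h, w), dtype=np.uint8)
    atten = np.zeros((h, w), dtype=np.float64)
    conc = {
        s.id: spec.trunk_concentration_mg_ml * spec.concentration_decay_per_level ** (s.level - 1)
        for s in segs
    }
    for s in segs:
        window, dist = _segment_distance_field(s.p0, s.p1, (h, w), s.diameter_px / 2)
        if window is None:
            continue
        r = s.diameter_px / 2
        inside = dist <= r
        # optical path = the vessel diameter (flat interior): the grayscale
        # along the centerline then satisfies the attenuation model exactly,
        # independent of sub-pixel centerline offsets
        d_um = s.diameter_px * spec.pixel_pitch_um
        a_val = max(spec.epsilon * np.log10(max(conc[s.id] * d_um, 1e-12)) + spec.k, 0.0)
        a = np.where(inside, a_val, 0.0)
        atten[window] = np.maximum(atten[window], a)
        mask[window] |= inside.astype(np.uint8)

    # discrete radius tests can leave pinholes in the wedge between two
    # diverging tubes; a vessel lumen has no holes, so fill them and carry
    # the neighborhood attenuation over
    filled = ndimage.binary_fill_holes(mask == 1)
    holes = filled & (mask == 0)
    if holes.any():
        atten[holes] = ndimage.grey_dilation(atten, size=3)[holes]
        mask[holes] = 1

    bright = spec.background_gray * np.power(10.0, -atten)

    fluor = np.empty((h, w), dtype=np.float64)
    fluor[mask == 1] = spec.fluor_wall_gray
    dist_px = ndimage.distance_transform_edt(mask == 0)
    outside = mask == 0
    fluor[outside] = spec.fluor_wall_gray * np.exp(
        -dist_px[outside] * spec.pixel_pitch_um / spec.halo_scale_um
    )
    if spec.noise_sd_gray > 0:
        bright = bright + rng.normal(0.0, spec.noise_sd_gray, size=bright.shape)
        fluor = fluor + rng.normal(0.0, spec.noise_sd_gray, size=fluor.shape)
    return np.clip(bright, 0, 255), np.clip(fluor, 0, 255), mask, conc


def _truth_graph(spec: PhantomSpec, segs: list[_Segment], mask: np.ndarray) -> VesselGraph:
    g = VesselGraph(shape=mask.shape, pixel_pitch_um=spec.pixel_pitch_um)
    if not segs:
        return g

    def rc(p):
        return (int(round(p[0])), int(round(p[1])))

    node_ids: dict[tuple[int, int], int] = {}

    def node_for(p, kind):
        key = rc(p)
        if key not in node_ids:
            nid = len(node_ids)
            node_ids[key] = nid
            g.nodes[nid] = Node(nid, key, kind)
        return node_ids[key]

    trunk = segs[0]
    root_id = node_for(trunk.p1, "root")
    node_for(trunk.p0, "leaf")
    for s in segs:
        kind = "bifurcation" if s.children else "leaf"
        if rc(s.p1) not in node_ids:
            node_for(s.p1, kind)
    for s in segs:
        path = _line_pixels(rc(s.p0), rc(s.p1))
        g.edges[s.id] = Edge(
            s.id,
            node_ids[rc(s.p0)],
            node_ids[rc(s.p1)],
            path,
            len(path),
            s.diameter_px,
            level=s.level,
        )
    assert g.nodes[root_id].kind == "root"
    return g


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate a deterministic phantom bundle for the given spec.

    The same spec (including seed) always yields a bit-identical bundle.
    Raises :class:`PhantomGeometryError` when the requested tree cannot be
    placed on the canvas (the offending level is named).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_levels == 0:
        h, w = spec.image_height_px, spec.image_width_px
        bright = np.full((h, w), spec.background_gray, dtype=np.float64)
        fluor = np.zeros((h, w), dtype=np.float64)
        if spec.noise_sd_gray > 0:
            bright += rng.normal(0, spec.noise_sd_gray, (h, w))
            fluor += rng.normal(0, spec.noise_sd_gray, (h, w))
        return PhantomBundle(
            np.clip(bright, 0, 255),
            np.clip(fluor, 0, 255),
            np.zeros((h, w), np.uint8),
            VesselGraph(shape=(h, w), pixel_pitch_um=spec.pixel_pitch_um),
            {},
            spec,
        )

    last_err: Exception | None = None
    for _ in range(_MAX_TREE_TRIES):
        try:
            segs = _build_tree(spec, rng)
        except PhantomGeometryError as err:
            last_err = err
            continue
        margin = _assign_levels(segs)
        if margin >= _MIN_LEVEL_MARGIN_PX:
            break
        last_err = PhantomGeometryError(
            f"ambiguous farthest-leaf margin {margin:.1f} px"
        )
    else:
        raise PhantomGeometryError(
            f"no valid tree after {_MAX_TREE_TRIES} attempts: {last_err}"
        )

    bright, fluor, mask, conc = _render(spec, segs, rng)
    graph = _truth_graph(spec, segs, mask)
    return PhantomBundle(bright, fluor, mask, graph, conc, spec)
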