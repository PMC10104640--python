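"""Intravascular drug-concentration estimation from bright-field grayscale.

The model is an empirical modification of the Beer-Lambert law: the light
attenuation at a point inside a drug-filled vessel,

    A = log10(G_B / G) = epsilon * log10(c * d) + k,

relates the grayscale ``G`` (against the background grayscale ``G_B``) to
the local drug concentration ``c`` (mg/mL) and the optical path length
``d`` -- the vessel diameter when sampled on the centerline (µm).
``epsilon`` is the light-attenuation coefficient of the dye and ``k`` an
attenuation-independent offset (scattering losses).

Calibration fits ``epsilon`` and ``k`` by ordinary least squares on
measurements from channels of known concentration and depth.  Mapping then
works edge-to-edge on a classified vessel graph: with the Root-incident
"source" edges assigned the injected concentration ``c0``, the ratio form

    log10(G_t / G_s) = epsilon * [log10(c_s / c_t) + log10(d_s / d_t)]

(in which ``k`` cancels) is solved for each target edge's concentration
``c_t``.  Base-10 logarithms are used throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .topology import VesselGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationModel",
    "EdgePhotometry",
    "ConcentrationMap",
    "fit_calibration",
    "estimate_background",
    "edge_photometry",
    "propagate_concentration",
    "concentration_timecourse",
    "DEFAULT_EPSILON",
]

# light-attenuation coefficient of doxorubicin in bright-field stereoscopy,
# used when no calibration data are supplied
DEFAULT_EPSILON = 0.249


@dataclass
class CalibrationModel:
    epsilon: float  # slope of A on log10(c*d)
    k: float  # intercept (attenuation-independent offset)
    r_squared: float = float("nan")
    slope_se: float = float("nan")
    g_background: float = float("nan")
    n_samples: int = 0


@dataclass
class EdgePhotometry:
    """Mean grayscale / diameter per edge, plus the source-edge aggregates."""

    g_t: dict[int, float]  # edge id -> mean grayscale along skeleton pixels
    d_t: dict[int, float]  # edge id -> mean diameter (px)
    source_edges: list[int] = field(default_factory=list)
    g_s: float = float("nan")
    d_s: float = float("nan")
    c_s: float = float("nan")


@dataclass
class ConcentrationMap:
    concentration: dict[int, float]  # edge id -> c_t (mg/mL)
    normalized: dict[int, float]  # edge id -> c_t / c0
    clipped: set[int] = field(default_factory=set)
    skipped: set[int] = field(default_factory=set)
    c0: float = float("nan")


def fit_calibration(samples, g_background: float) -> CalibrationModel:
    """Least-squares fit of the attenuation model to calibration channels.

    Parameters
    ----------
    samples
        Iterable of ``(c, d, G)`` triples: concentration (mg/mL), optical
        path (µm or px -- the unit only shifts ``k``), mean grayscale.
    g_background
        Grayscale of the drug-free background, ``G_B``.

    Returns
    -------
    CalibrationModel with ``epsilon`` (slope), ``k`` (intercept) and fit
    diagnostics.  Saturated-dark samples (G <= 0) are excluded with a
    warning; fewer than 3 usable samples or rank-deficient ``c*d`` raise
    ``ValueError``.
    """
    usable = []
    for c, d, g in samples:
        if g <= 0:
            warnings.warn(f"excluding saturated sample (c={c}, d={d}, G={g})", stacklevel=2)
            continue
        if c <= 0 or d <= 0:
            raise ValueError("concentration and depth must be positive")
        usable.append((float(c), float(d), float(g)))
    if len(usable) < 3:
        raise ValueError("need at least 3 usable calibration samples")
    x = np.log10([c * d for c, d, _ in usable])
    y = np.log10([g_background / g for _, _, g in usable])
    if np.ptp(x) < 1e-12:
        raise ValueError("calibration samples are rank-deficient (all c*d equal)")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        epsilon=float(fit.slope),
        k=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_se=float(fit.stderr),
        g_background=float(g_background),
        n_samples=len(usable),
    )


def estimate_background(image: np.ndarray, mask: np.ndarray, dilation_px: int = 5) -> float:
    """Background grayscale G_B: median outside a dilated vessel mask."""
    grown = ndimage.binary_dilation(mask != 0, iterations=dilation_px)
    outside = np.asarray(image)[~grown]
    if outside.size == 0:
        raise ValueError("no background pixels outside the dilated mask")
    return float(np.median(outside))


def _junction_trim(graph: VesselGraph, edge) -> list[tuple[int, int]]:
    """Edge path with pixels near the endpoint junctions removed.

    Within about one incident-vessel radius of a junction the tube overlaps
    its neighbors and the grayscale is contaminated by the thicker vessel,
    so those pixels are excluded from the edge mean.  At least the middle
    third of the path is always kept.
    """
    path = edge.path
    trims = []
    for nid in (edge.u, edge.v):
        inc = graph.incident(nid)
        radius = max((e.mean_diameter_px for e in inc), default=0.0) / 2.0
        trims.append(int(np.ceil(radius)) + 1)
    lo, hi = trims[0], len(path) - trims[1]
    if hi - lo < max(3, len(path) // 3):
        third = len(path) // 3
        lo, hi = third, max(third + 1, len(path) - third)
    return path[lo:hi]


def edge_photometry(
    graph: VesselGraph,
    bright: np.ndarray,
    root: int | None = None,
    c0: float = float("nan"),
) -> EdgePhotometry:
    """Measure mean grayscale and diameter for every edge of the graph.

    Grayscale is averaged over the edge's skeleton pixels after trimming
    one junction radius at each end.  Source edges are the edges incident
    to the Root and get ``c_s = c0``.
    """
    img = np.asarray(bright, dtype=float)
    g_t: dict[int, float] = {}
    d_t: dict[int, float] = {}
    for eid, e in graph.edges.items():
        pixels = _junction_trim(graph, e)
        g_t[eid] = float(np.mean([img[p] for p in pixels]))
        d_t[eid] = float(e.mean_diameter_px)
    phot = EdgePhotometry(g_t=g_t, d_t=d_t)
    if root is not None:
        src = [e.id for e in graph.incident(root)]
        phot.source_edges = src
        # geometric means: the attenuation model is linear in log10(G) and
        # log10(d), so only log-space averaging keeps the aggregated source
        # quantities on the model when source diameters differ
        phot.g_s = float(10 ** np.mean([np.log10(g_t[i]) for i in src]))
        phot.d_s = float(10 ** np.mean([np.log10(d_t[i]) for i in src]))
        phot.c_s = c0
    return phot


def propagate_concentration(
    graph: VesselGraph,
    bright: np.ndarray,
    calib: CalibrationModel,
    c0: float,
    max_level: int = 2,
    clip_factor: float = 2.0,
    root: int | None = None,
) -> ConcentrationMap:
    """Estimate per-edge drug concentration on the P1..P{max_level} vessels.

    Solves the ratio form of the attenuation model for each target edge:

        log10(c_t) = log10(c_s) + log10(d_s/d_t) - log10(G_t/G_s)/epsilon

    with source quantities averaged over the Root-incident edges and
    ``c_s = c0``.  Edges deeper than ``max_level`` are skipped (distal
    vessels are noise-dominated); estimates above ``clip_factor * c0`` are
    clipped and flagged, negatives cannot arise (the solution is an
    exponential).
    """
    if calib.epsilon <= 0:
        raise ValueError("calibration epsilon must be positive")
    root = root if root is not None else graph.root_id
    if root is None:
        raise ValueError("graph has no root; run detect_root/classify_levels first")
    phot = edge_photometry(graph, bright, root=root, c0=c0)
    if not phot.source_edges:
        raise ValueError("root has no incident (source) edges")
    conc: dict[int, float] = {}
    norm: dict[int, float] = {}
    clipped: set[int] = set()
    skipped: set[int] = set()
    for eid, e in graph.edges.items():
        if e.level is None or e.level > max_level:
            skipped.add(eid)
            continue
        g_t = phot.g_t[eid]
        if g_t <= 0:
            logger.warning("edge %d has zero grayscale; skipped", eid)
            skipped.add(eid)
            continue
        log_ct = (
            np.log10(c0)
            + np.log10(phot.d_s / phot.d_t[eid])
            - np.log10(g_t / phot.g_s) / calib.epsilon
        )
        c_t = float(10.0**log_ct)
        if c_t > clip_factor * c0:
            c_t = clip_factor * c0
            clipped.add(eid)
        conc[eid] = c_t
        norm[eid] = c_t / c0 if c0 > 0 else float("nan")
    return ConcentrationMap(conc, norm, clipped, skipped, c0=c0)


def concentration_timecourse(maps, times=None, edges=None):
    """Mean and SEM of edge concentrations over a registered time series.

    Parameters
    ----------
    maps
        Sequence of :class:`ConcentrationMap`, one per time point, sharing a
        graph lineage (same edge ids).
    times
        Optional time labels; defaults to 0..n-1.
    edges
        Edge ids to average; defaults to all edges present in the first map.

    Returns
    -------
    pandas.DataFrame with columns time, mean_c, sem_c, pct_of_c0.
    """
    import pandas as pd

    maps = list(maps)
    if not maps:
        raise ValueError("empty map sequence")
    if times is None:
        times = list(range(len(maps)))
    if edges is None:
        edges = sorted(maps[0].concentration)
    if not edges:
        raise ValueError("empty edge selection")
    rows = []
    for t, m in zip(times, maps):
        vals = np.array([m.concentration[e] for e in edges if e in m.concentration])
        if vals.size == 0:
            rows.append({"time": t, "mean_c": 0.0, "sem_c": 0.0, "pct_of_c0": 0.0})
            continue
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {
                "time": t,
                "mean_c": float(vals.mean()),
                "sem_c": sem,
                "pct_of_c0": float(100.0 * vals.mean() / m.c0) if m.c0 > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
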