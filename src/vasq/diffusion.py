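"""Extravascular drug spread from fluorescent images.

Quantifies how far drug has diffused out of a vessel: a ray is cast from a
skeleton anchor perpendicular to the local vessel direction, the
fluorescence profile along the ray is sampled starting at the vessel wall,
and the diffusion depth D(n%) is the largest distance at which the
(smoothed) grayscale still reaches n% of the intensity adjacent to the
wall.  Coverage metrics split fluorescence-positive area into
intravascular and extravascular parts, and an in vitro-in vivo correlation
(IVIVC) is a least-squares line through paired normalized intensity ratios
(G_n/G_0 in vitro) and concentration ratios (C_n/C_0 in vivo).

Vessel-diameter location classes follow the convention L1: 800-1000 µm,
L2: 600-800 µm, L3: 400-600 µm, L4: 200-400 µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionProfile",
    "CoverageRecord",
    "IvivcFit",
    "LOCATION_CLASSES_UM",
    "location_class",
    "extract_profile",
    "diffusion_depth",
    "coverage",
    "coverage_overlay",
    "ivivc_fit",
]

LOCATION_CLASSES_UM = {
    "L1": (800.0, 1000.0),
    "L2": (600.0, 800.0),
    "L3": (400.0, 600.0),
    "L4": (200.0, 400.0),
}


def location_class(diameter_um: float) -> str | None:
    """Map a vessel diameter to its L1..L4 location class (None if outside)."""
    for label, (lo, hi) in LOCATION_CLASSES_UM.items():
        if lo <= diameter_um < hi:
            return label
    return None


@dataclass
class DiffusionProfile:
    distances_um: np.ndarray  # increasing, measured from the vessel wall
    grayscale: np.ndarray  # raw samples
    smoothed: np.ndarray  # 3-sample moving average
    g0: float  # grayscale adjacent to the wall
    location: str | None = None
    truncated: bool = False  # ray left the image
    anchor: tuple[int, int] | None = None


@dataclass
class CoverageRecord:
    time: object = None
    total_px: int = 0
    intra_px: int = 0
    extra_px: int = 0
    pixel_pitch_um: float = 1.0
    normalized_total: float = float("nan")

    @property
    def total_um2(self) -> float:
        return self.total_px * self.pixel_pitch_um**2

    @property
    def intra_um2(self) -> float:
        return self.intra_px * self.pixel_pitch_um**2

    @property
    def extra_um2(self) -> float:
        return self.extra_px * self.pixel_pitch_um**2

    @property
    def extra_intra_ratio(self) -> float:
        return self.extra_px / self.intra_px if self.intra_px else 0.0


@dataclass
class IvivcFit:
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    n: int = 0


# ---------------------------------------------------------------------------
# profiles and depths
# ---------------------------------------------------------------------------


def _local_direction(skeleton: np.ndarray, anchor: tuple[int, int], window: int = 10):
    """Unit tangent of the skeleton near the anchor (PCA over a window)."""
    r, c = anchor
    h, w = skeleton.shape
    r0, r1 = max(0, r - window), min(h, r + window + 1)
    c0, c1 = max(0, c - window), min(w, c + window + 1)
    pts = np.argwhere(skeleton[r0:r1, c0:c1] != 0) + (r0, c0)
    if len(pts) < 2:
        raise ValueError("local vessel direction not estimable at anchor")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered.astype(float), full_matrices=False)
    tangent = vt[0]
    return tangent / np.linalg.norm(tangent)


def extract_profile(
    fluor: np.ndarray,
    mask: np.ndarray,
    skeleton: np.ndarray,
    anchor: tuple[int, int],
    ray_length_um: float,
    pixel_pitch_um: float = 1.0,
    step_px: float = 0.25,
    side: int = +1,
    noise_floor: float = 1.0,
) -> DiffusionProfile:
    """Sample a fluorescence profile perpendicular to the vessel.

    The ray starts at the first background pixel beyond the vessel wall and
    extends ``ray_length_um`` outward; intensities are sampled by bilinear
    interpolation every ``step_px`` pixels.  ``g0`` is the mean of the
    first 3 samples outside the wall, and the profile is smoothed by a
    3-sample moving average before any threshold search.
    """
    fluor = np.asarray(fluor, dtype=float)
    mask = np.asarray(mask) != 0
    if not skeleton[anchor]:
        raise ValueError("anchor must lie on the skeleton")
    tangent = _local_direction(skeleton, anchor)
    normal = np.array([-tangent[1], tangent[0]]) * side

    # march from the anchor to the vessel wall; the ray starts at the first
    # background position whose bilinear support is fully extravascular, so
    # the wall-adjacent samples are not diluted by the intravascular plateau
    h, w = fluor.shape
    edt_bg = ndimage.distance_transform_edt(~mask)
    pos = np.array(anchor, dtype=float)
    max_march = int((4 * max(1.0, _wall_radius(mask, anchor)) + 8) / step_px) + 8
    for _ in range(max_march):
        pos = pos + normal * step_px
        ri, ci = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= ri < h and 0 <= ci < w):
            raise ValueError("ray left the image before reaching the vessel wall")
        if edt_bg[ri, ci] >= 1.5:
            break
    else:
        raise ValueError("vessel wall not found along the ray")

    n_samples = int(ray_length_um / (step_px * pixel_pitch_um)) + 1
    offsets = np.arange(n_samples) * step_px
    rows = pos[0] + normal[0] * offsets
    cols = pos[1] + normal[1] * offsets
    inside = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    truncated = not bool(inside.all())
    if truncated:
        logger.warning("profile ray truncated at the image border")
        rows, cols, offsets = rows[inside], cols[inside], offsets[inside]
    values = ndimage.map_coordinates(fluor, [rows, cols], order=1)
    if len(values) < 3:
        raise ValueError("profile too short")
    # the profile abscissa is the distance from the vessel wall, taken from
    # the background distance transform at each sample (robust to the
    # staircase jaggedness of a rasterized wall); enforced non-decreasing
    wall_dist = ndimage.map_coordinates(edt_bg, [rows, cols], order=1)
    wall_dist = np.maximum.accumulate(wall_dist)
    offsets = wall_dist - wall_dist[0]
    g0 = float(np.mean(values[:3]))
    if g0 < noise_floor:
        raise ValueError(f"wall-adjacent grayscale {g0:.2f} below noise floor")
    kernel = np.ones(3) / 3.0
    smoothed = np.convolve(values, kernel, mode="same")
    # edge samples of the moving average use fewer points
    smoothed[0] = np.mean(values[:2])
    smoothed[-1] = np.mean(values[-2:])
    return DiffusionProfile(
        distances_um=offsets * pixel_pitch_um,
        grayscale=np.asarray(values, dtype=float),
        smoothed=smoothed,
        g0=g0,
        truncated=truncated,
        anchor=anchor,
    )


def _wall_radius(mask: np.ndarray, anchor: tuple[int, int]) -> float:
    edt = ndimage.distance_transform_edt(mask)
    return float(edt[anchor])


def diffusion_depth(profile: DiffusionProfile, n_percent: float) -> tuple[float, bool]:
    """Depth D(n%): the largest distance where the smoothed grayscale still
    reaches ``n_percent`` of the wall-adjacent intensity.

    Returns ``(depth_um, censored)``; ``censored`` is True when the profile
    never falls below the threshold, in which case the ray length is
    returned.  The crossing is linearly interpolated between samples.
    """
    if not (0 < n_percent <= 100):
        raise ValueError("n_percent must be in (0, 100]")
    y = profile.smoothed
    x = profile.distances_um
    thr = (n_percent / 100.0) * profile.g0
    above = y >= thr
    if not above.any():
        return 0.0, False
    last = int(np.flatnonzero(above)[-1])
    if last == len(y) - 1:
        return float(x[-1]), True
    # interpolate the crossing between the last above-threshold sample and
    # its successor
    y0, y1 = y[last], y[last + 1]
    frac = (y0 - thr) / (y0 - y1) if y0 != y1 else 0.0
    return float(x[last] + frac * (x[last + 1] - x[last])), False


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def coverage(
    fluor: np.ndarray,
    mask: np.ndarray,
    background: np.ndarray | float | None = None,
    pixel_pitch_um: float = 1.0,
    time=None,
) -> CoverageRecord:
    """Signal-area split into intra- and extravascular parts.

    ``background`` is subtracted first (a pre-injection frame when
    available, else the modal grayscale, else 0); signal pixels are those
    with corrected grayscale >= 1 on the 0-255 scale.
    """
    img = np.asarray(fluor, dtype=float)
    if background is None:
        vals, counts = np.unique(np.round(img).astype(int), return_counts=True)
        background = float(vals[np.argmax(counts)])
    corrected = img - background
    signal = corrected >= 1.0
    mask = np.asarray(mask) != 0
    intra = int(np.count_nonzero(signal & mask))
    extra = int(np.count_nonzero(signal & ~mask))
    return CoverageRecord(
        time=time,
        total_px=intra + extra,
        intra_px=intra,
        extra_px=extra,
        pixel_pitch_um=pixel_pitch_um,
    )


def coverage_overlay(signals: list[np.ndarray], times=None):
    """Label image of drug presence over a registered time series.

    Returns ``(first_seen, last_seen, table)``: per-pixel indices (1-based)
    of the earliest and latest time point with signal (0 = never), plus a
    table of total signal areas normalized to the first time point.
    """
    import pandas as pd

    if not signals:
        raise ValueError("empty time series")
    shape = signals[0].shape
    if any(s.shape != shape for s in signals):
        raise ValueError("time points differ in shape")
    if times is None:
        times = list(range(len(signals)))
    first = np.zeros(shape, dtype=np.int32)
    last = np.zeros(shape, dtype=np.int32)
    areas = []
    for i, s in enumerate(signals, start=1):
        sig = np.asarray(s) != 0
        newly = sig & (first == 0)
        first[newly] = i
        last[sig] = i
        areas.append(int(sig.sum()))
    ref = areas[0] if areas[0] else 1
    table = pd.DataFrame(
        {"time": times, "signal_px": areas, "normalized_area": [a / ref for a in areas]}
    )
    return first, last, table


# ---------------------------------------------------------------------------
# IVIVC
# ---------------------------------------------------------------------------


def ivivc_fit(pairs) -> IvivcFit:
    """Least-squares line through (in vitro G_n/G_0, in vivo C_n/C_0) pairs."""
    pairs = [(float(g), float(c)) for g, c in pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 ratio pairs")
    x = np.array([g for g, _ in pairs])
    y = np.array([c for _, c in pairs])
    if np.ptp(x) < 1e-12:
        raise ValueError("zero variance in G ratios")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return IvivcFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residuals=resid,
        n=len(pairs),
    )
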