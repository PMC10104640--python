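"""Binary-mask centerline extraction by two-subiteration thinning.

The vessel mask is reduced to a single-pixel-wide, 8-connected skeleton by
iteratively deleting boundary pixels in two alternating passes: one pass
removes redundant pixels on north-west corners / south-east boundaries, the
other on south-east corners / north-west boundaries (the classic
Zhang-Suen rule set).  Deletion stops when a full double pass removes
nothing.  A final cleanup pass removes simple pixels from any residual
2x2 foreground block so the width-1 invariant holds exactly.

Conventions: foreground is 8-connected, background 4-connected; arrays are
row-major with origin at the top-left.
"""

from __future__ import annotations

import numpy as np

__all__ = ["skeletonize", "prune_spurs", "has_2x2_block", "neighbor_count"]


def _neighbors(img: np.ndarray) -> tuple[np.ndarray, ...]:
    """Return the 8 shifted neighbor planes P2..P9 (N, NE, E, SE, S, SW, W, NW)."""
    p = np.pad(img, 1, mode="constant")
    n = p[:-2, 1:-1]
    ne = p[:-2, 2:]
    e = p[1:-1, 2:]
    se = p[2:, 2:]
    s = p[2:, 1:-1]
    sw = p[2:, :-2]
    w = p[1:-1, :-2]
    nw = p[:-2, :-2]
    return n, ne, e, se, s, sw, w, nw


def neighbor_count(img: np.ndarray) -> np.ndarray:
    """Number of foreground pixels among the 8 neighbors of every pixel."""
    stack = _neighbors(img.astype(np.uint8))
    return np.sum(stack, axis=0, dtype=np.int16)


def _transitions(img: np.ndarray) -> np.ndarray:
    """Count 0->1 transitions in the circular sequence P2,P3,...,P9,P2."""
    seq = _neighbors(img.astype(np.uint8))
    total = np.zeros(img.shape, dtype=np.int16)
    for a, b in zip(seq, seq[1:] + seq[:1]):
        total += ((a == 0) & (b == 1)).astype(np.int16)
    return total


def _thin_pass(img: np.ndarray, second: bool) -> np.ndarray:
    n, ne, e, se, s, sw, w, nw = _neighbors(img)
    b = n + ne + e + se + s + sw + w + nw
    a = _transitions(img)
    cond = (img == 1) & (b >= 2) & (b <= 6) & (a == 1)
    if not second:
        cond &= (n * e * s == 0) & (e * s * w == 0)
    else:
        cond &= (n * e * w == 0) & (n * s * w == 0)
    out = img.copy()
    out[cond] = 0
    return out


def _is_simple(img: np.ndarray, r: int, c: int) -> bool:
    """True if deleting (r, c) preserves local 8-connectivity of foreground."""
    h, wd = img.shape
    ring = []
    for dr, dc in ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)):
        rr, cc = r + dr, c + dc
        ring.append(int(img[rr, cc]) if 0 <= rr < h and 0 <= cc < wd else 0)
    b = sum(ring)
    a = sum(1 for x, y in zip(ring, ring[1:] + ring[:1]) if x == 0 and y == 1)
    return a == 1 and b >= 2


def _cleanup_blocks(img: np.ndarray) -> np.ndarray:
    """Remove simple pixels from residual 2x2 all-foreground blocks.

    Deletability is first decided by the local crossing number; when a block
    sits in diagonal-dense surroundings where the local test is too
    conservative, a global component-count check decides instead.
    """
    from scipy import ndimage

    eight = np.ones((3, 3), dtype=np.uint8)
    out = img.copy()
    for _ in range(64):  # residual blocks are rare; bounded fixpoint loop
        blocks = (out[:-1, :-1] & out[:-1, 1:] & out[1:, :-1] & out[1:, 1:]) == 1
        if not blocks.any():
            break
        changed = False
        for r, c in np.argwhere(blocks):
            members = ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1))
            for rr, cc in members:
                if out[rr, cc] and _is_simple(out, rr, cc):
                    out[rr, cc] = 0
                    changed = True
                    break
            else:
                n_before = ndimage.label(out, structure=eight)[1]
                for rr, cc in members:
                    if not out[rr, cc]:
                        continue
                    out[rr, cc] = 0
                    if ndimage.label(out, structure=eight)[1] == n_before:
                        changed = True
                        break
                    out[rr, cc] = 1
        if not changed:
            break
    return out


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary vessel mask to its single-pixel-wide skeleton.

    Parameters
    ----------
    mask
        2D binary array (anything nonzero is foreground).

    Returns
    -------
    numpy.ndarray
        uint8 skeleton matrix, 1 = skeleton pixel, 0 = background.  The
        skeleton is a subset of the mask foreground, has the same number of
        8-connected components, and contains no fully set 2x2 block.
        The operation is idempotent: the skeleton of a skeleton is itself.
    """
    img = (np.asarray(mask) != 0).astype(np.uint8)
    if img.ndim != 2:
        raise ValueError("mask must be 2D")
    original = img
    while True:
        nxt = _thin_pass(img, second=False)
        nxt = _thin_pass(nxt, second=True)
        if np.array_equal(nxt, img):
            break
        img = nxt
    img = _cleanup_blocks(img)
    return _restore_vanished(original, img)


def _restore_vanished(mask: np.ndarray, skel: np.ndarray) -> np.ndarray:
    """Re-seed one pixel for any mask component the parallel passes erased.

    Tiny compact components (e.g. an isolated 2x2 square) satisfy both
    deletion rules simultaneously and would otherwise vanish entirely; they
    are represented by their pixel closest to the component centroid.
    """
    from scipy import ndimage

    eight = np.ones((3, 3), dtype=np.uint8)
    labels, n = ndimage.label(mask, structure=eight)
    if n == 0:
        return skel
    survived = np.zeros(n + 1, dtype=bool)
    survived[labels[skel == 1]] = True
    out = skel.copy()
    for lab in range(1, n + 1):
        if survived[lab]:
            continue
        pix = np.argwhere(labels == lab)
        centroid = pix.mean(axis=0)
        r, c = pix[np.argmin(((pix - centroid) ** 2).sum(axis=1))]
        out[r, c] = 1
    return out


def _neighbor_coords(skel: np.ndarray, r: int, c: int) -> list[tuple[int, int]]:
    h, w = skel.shape
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                out.append((rr, cc))
    return out


def prune_spurs(skel: np.ndarray, min_length: int = 5) -> np.ndarray:
    """Remove terminal branches (spurs) shorter than ``min_length`` pixels.

    A spur is a path from an endpoint (one skeleton neighbor) to the nearest
    junction (three or more neighbors).  Spurs that end at another endpoint
    (isolated segments) are kept regardless of length.  Pruning repeats until
    no short spur remains.
    """
    out = (np.asarray(skel) != 0).astype(np.uint8)
    while True:
        counts = neighbor_count(out)
        endpoints = np.argwhere((out == 1) & (counts == 1))
        removed_any = False
        for r0, c0 in endpoints:
            if not out[r0, c0]:
                continue
            path = [(int(r0), int(c0))]
            prev = None
            cur = (int(r0), int(c0))
            hit_junction = False
            while len(path) <= min_length:
                nbrs = [p for p in _neighbor_coords(out, *cur) if p != prev]
                if len(nbrs) != 1:
                    hit_junction = len(nbrs) > 1
                    break
                nxt = nbrs[0]
                if len(_neighbor_coords(out, *nxt)) > 2:
                    hit_junction = True
                    break
                prev, cur = cur, nxt
                path.append(cur)
            if hit_junction and len(path) < min_length:
                for r, c in path:
                    out[r, c] = 0
                removed_any = True
        if not removed_any:
            return out


def has_2x2_block(skel: np.ndarray) -> bool:
    """True if any 2x2 window of the array is entirely foreground."""
    s = (np.asarray(skel) != 0).astype(np.uint8)
    return bool(((s[:-1, :-1] & s[:-1, 1:] & s[1:, :-1] & s[1:, 1:]) == 1).any())
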