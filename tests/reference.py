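"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit per-pixel loops, straight from the
mathematical definitions, and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

# centred (dr, dc) offsets of the four classic 3-pixel segments
K3_SEGMENTS = [
    [(0, -1), (0, 0), (0, 1)],  # 0 deg
    [(1, -1), (0, 0), (-1, 1)],  # 45 deg
    [(-1, 0), (0, 0), (1, 0)],  # 90 deg
    [(-1, -1), (0, 0), (1, 1)],  # 135 deg
]


def _in(shape, r, c):
    return 0 <= r < shape[0] and 0 <= c < shape[1]


def brute_gray_morph(img: np.ndarray, selem: np.ndarray, op: str) -> np.ndarray:
    """Grayscale erosion/dilation by sliding min/max, ignoring out-of-grid."""
    h, w = img.shape
    sh, sw = selem.shape
    ar, ac = sh // 2, sw // 2
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = []
            for i in range(sh):
                for j in range(sw):
                    if selem[i, j] and _in(img.shape, r + i - ar, c + j - ac):
                        vals.append(img[r + i - ar, c + j - ac])
            out[r, c] = min(vals) if op == "min" else max(vals)
    return out


def brute_open_close(img: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Opening (min then max) followed by closing (max then min)."""
    opened = brute_gray_morph(brute_gray_morph(img, selem, "min"), selem, "max")
    return brute_gray_morph(brute_gray_morph(opened, selem, "max"), selem, "min")


def brute_region_means(img: np.ndarray, u: np.ndarray):
    ins = [img[r, c] for r in range(u.shape[0]) for c in range(u.shape[1]) if u[r, c]]
    outs = [img[r, c] for r in range(u.shape[0]) for c in range(u.shape[1]) if not u[r, c]]
    eps = 1e-8
    return sum(ins) / (len(ins) + eps), sum(outs) / (len(outs) + eps)


def brute_balloon(u: np.ndarray, nu: int) -> np.ndarray:
    """Dilation/erosion over the in-grid 4-neighbourhood cross."""
    if nu == 0:
        return u.copy()
    h, w = u.shape
    out = np.empty_like(u)
    for r in range(h):
        for c in range(w):
            vals = [u[r, c]]
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if _in(u.shape, r + dr, c + dc):
                    vals.append(u[r + dr, c + dc])
            out[r, c] = max(vals) if nu > 0 else min(vals)
    return out


def brute_gradient_contour(u: np.ndarray) -> np.ndarray:
    """Nonzero-gradient pixels: central differences inside, one-sided at the
    border (the np.gradient convention, written out by hand)."""
    h, w = u.shape
    out = np.zeros((h, w), dtype=bool)
    uf = u.astype(float)
    for r in range(h):
        for c in range(w):
            if r == 0:
                gr = uf[1, c] - uf[0, c]
            elif r == h - 1:
                gr = uf[h - 1, c] - uf[h - 2, c]
            else:
                gr = (uf[r + 1, c] - uf[r - 1, c]) / 2.0
            if c == 0:
                gc = uf[r, 1] - uf[r, 0]
            elif c == w - 1:
                gc = uf[r, w - 1] - uf[r, w - 2]
            else:
                gc = (uf[r, c + 1] - uf[r, c - 1]) / 2.0
            out[r, c] = gr != 0 or gc != 0
    return out


def brute_si(u: np.ndarray, segments=K3_SEGMENTS) -> np.ndarray:
    """Sup-inf: max over segments of the min of u over the centred segment,
    out-of-grid pixels ignored."""
    h, w = u.shape
    out = np.zeros_like(u)
    for r in range(h):
        for c in range(w):
            best = 0
            for seg in segments:
                m = 1
                for dr, dc in seg:
                    if _in(u.shape, r + dr, c + dc):
                        m = min(m, int(u[r + dr, c + dc]))
                best = max(best, m)
            out[r, c] = best
    return out


def brute_is(u: np.ndarray, segments=K3_SEGMENTS) -> np.ndarray:
    """Inf-sup: min over segments of the max of u over the centred segment."""
    h, w = u.shape
    out = np.zeros_like(u)
    for r in range(h):
        for c in range(w):
            best = 1
            for seg in segments:
                m = 0
                for dr, dc in seg:
                    if _in(u.shape, r + dr, c + dc):
                        m = max(m, int(u[r + dr, c + dc]))
                best = min(best, m)
            out[r, c] = best
    return out


def segments_from_angles(length: int, angles_deg) -> list:
    """Centred digital line segments (matches Bresenham lines through the
    origin for the canonical angles)."""
    segs = []
    half = (length - 1) // 2
    for deg in angles_deg:
        th = math.radians(deg)
        er, ec = round(-half * math.sin(th)), round(half * math.cos(th))
        n = max(abs(er), abs(ec))
        seg = []
        for i in range(-n, n + 1):
            seg.append((round(er * i / n), round(ec * i / n)))
        segs.append(seg)
    return segs


def brute_macwe_iteration(
    u: np.ndarray,
    img: np.ndarray,
    segments=K3_SEGMENTS,
    nu: int = 1,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    tau: float = 0.5,
    phase: int = 0,
) -> np.ndarray:
    """One full tracking update, from the definitions: region means, balloon,
    sign test on the pre-balloon contour, compound smoothing (alternating
    parity), then the border overflow guard."""
    c1, c2 = brute_region_means(img, u)
    contour = brute_gradient_contour(u)
    cand = brute_balloon(u, nu)
    for r in range(u.shape[0]):
        for c in range(u.shape[1]):
            if contour[r, c]:
                force = lambda1 * (img[r, c] - c1) ** 2 - lambda2 * (img[r, c] - c2) ** 2
                if force < 0:
                    cand[r, c] = 1
                elif force > 0:
                    cand[r, c] = 0
    if phase % 2 == 0:
        cand = brute_si(brute_is(cand, segments), segments)
    else:
        cand = brute_is(brute_si(cand, segments), segments)
    # overflow guard
    n = 0
    pos = 0
    for r in range(u.shape[0]):
        for c in range(u.shape[1]):
            if contour[r, c]:
                n += 1
                force = lambda1 * (img[r, c] - c1) ** 2 - lambda2 * (img[r, c] - c2) ** 2
                if force < 0:
                    pos += 1
    touches = (
        cand[0, :].any() or cand[-1, :].any() or cand[:, 0].any() or cand[:, -1].any()
    )
    if n > 0 and pos / n > tau and touches:
        cand = cand & u
    return cand


def brute_hausdorff(pa: np.ndarray, pb: np.ndarray) -> float:
    """Symmetric max-min Euclidean distance between two point sets."""

    def directed(xs, ys):
        worst = 0.0
        for x in xs:
            best = min(math.dist(x, y) for y in ys)
            worst = max(worst, best)
        return worst

    return max(directed(pa, pb), directed(pb, pa))


def boundary_points(mask: np.ndarray) -> list:
    """Mask pixels with at least one 4-neighbour outside the mask."""
    pts = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            on_edge = False
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if not _in(mask.shape, r + dr, c + dc) or not mask[r + dr, c + dc]:
                    on_edge = True
            if on_edge:
                pts.append((r, c))
    return pts


def brute_focus_grid(radius_mm: float, spacing_mm: float) -> set:
    """Grid points (i, j) with centre distance <= radius."""
    n = int(radius_mm // spacing_mm) + 1
    pts = set()
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            if (i * spacing_mm) ** 2 + (j * spacing_mm) ** 2 <= radius_mm**2:
                pts.add((i, j))
    return pts
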