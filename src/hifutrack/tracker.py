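"""Improved morphological active contours without edges (MACWE).

The tracked contour is the boundary of the 1-region of a binary embedding
function ``u: grid -> {0, 1}`` (the contour is its level set 1/2).  One
tracking iteration, with the Chan-Vese parameters fixed at unit values,
composes four steps:

1. **balloon** — one binary dilation (``nu=+1``) or erosion (``nu=-1``) with
   a 3x3 cross, a uniform inflation/deflation force;
2. **attachment** — the region-competition sign test: every pixel on the
   discrete contour of ``u`` switches to the region whose mean intensity it
   is closer to, i.e. ``u=1`` where ``lambda1*(I-c1)^2 < lambda2*(I-c2)^2``
   and ``u=0`` for the opposite strict inequality (ties keep the pixel);
3. **SI∘IS smoothing** — the sup-inf/inf-sup compound operator over a set
   of discrete line structuring segments, a morphological surrogate of
   mean-curvature flow.  The classic operator set K3 uses four 3-pixel
   segments (0/45/90/135 degrees); the improved tracker replaces them with
   15-pixel segments (K15), which cannot bend around structures shorter than
   15 px and therefore ignores the bright internal sub-structures of a
   fibroid, tracking its outer contour only;
4. **overflow guard** — incomplete-area processing: when the lesion is cut
   by the field of view the contour can "overflow" along the border; if the
   fraction of contour pixels with outward (growth) attachment force exceeds
   ``overflow_tau`` while the candidate contour touches the image border,
   the growth of that iteration is rejected and only non-growing changes are
   kept.

Line segments are clipped at the image border (out-of-grid pixels are
ignored, not padded), so the guard - not padding - governs edge behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .preprocess import Frame

#: regularization of empty-region mean denominators
EPS_REGION = 1e-8

#: 3x3 cross (4-connectivity) used by the balloon force
CROSS = ndimage.generate_binary_structure(2, 1)


class TrackerError(ValueError):
    """Invalid tracker input or configuration."""


class EmptyInitializationError(TrackerError):
    """The rigid transform mapped the preoperative mask outside the grid."""


class TrackingLostError(RuntimeError):
    """The embedding degenerated (1-region vanished).

    Carries the last valid mask in ``last_valid``.
    """

    def __init__(self, message: str, last_valid: np.ndarray):
        super().__init__(message)
        self.last_valid = last_valid


# ---------------------------------------------------------------------------
# operator sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OperatorSet:
    """Discrete line structuring segments for the SI/IS extrema.

    Each segment is ``(length, orientation_deg)`` with odd length >= 3,
    centred on its midpoint.  Orientation 0 runs along columns, 90 along
    rows; 45/135 are the two diagonals.
    """

    segments: Tuple[Tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise TrackerError("operator set must contain at least one segment")
        for length, _ in self.segments:
            if length < 3 or length % 2 == 0:
                raise TrackerError("segment lengths must be odd and >= 3")

    def offsets(self) -> List[np.ndarray]:
        """Per-segment arrays of centred (dr, dc) pixel offsets."""
        out = []
        for length, deg in self.segments:
            half = (length - 1) // 2
            theta = math.radians(deg)
            er = int(round(-half * math.sin(theta)))
            ec = int(round(half * math.cos(theta)))
            rr, cc = draw_line(-er, -ec, er, ec)
            out.append(np.stack([rr, cc], axis=1))
        return out


def k3() -> OperatorSet:
    """Four 3-pixel segments at 0/45/90/135 degrees (classic operator set)."""
    return OperatorSet(tuple((3, a) for a in (0.0, 45.0, 90.0, 135.0)))


def k15(orientations: Sequence[float] = (0.0,)) -> OperatorSet:
    """The single large 15-pixel segment.

    With a one-element family the centred sup-inf/inf-sup compound
    degenerates to a directional closing (and, on the alternate repetition,
    opening) by the segment: structures thinner than 15 px along the segment
    are removed with no curvature shrinkage of the large region.  Additional
    orientations may be passed, but each added segment strengthens the
    curvature-flow component of the compound operator, which for 15-px
    segments shrinks lesion-sized regions faster than the unit balloon can
    re-inflate them; the single segment is the stable default.
    """
    return OperatorSet(tuple((15, float(a)) for a in orientations))


def operator_set(name: str, k15_orientations: Sequence[float] = (0.0,)) -> OperatorSet:
    name = name.lower()
    if name == "k3":
        return k3()
    if name == "k15":
        return k15(k15_orientations)
    raise TrackerError(f"unknown operator set {name!r} (expected 'k3' or 'k15')")


# ---------------------------------------------------------------------------
# parameters and statistics
# ---------------------------------------------------------------------------


@dataclass
class ACWEParams:
    """MACWE evolution parameters; defaults are the unit-parameter regime."""

    mu: int = 1
    nu: int = 1
    lambda1: float = 1.0
    lambda2: float = 1.0
    iters_per_frame: int = 5
    operator_set: OperatorSet = field(default_factory=k15)
    overflow_tau: float = 0.5
    overflow_scope: str = "border"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise TrackerError("mu must be >= 0")
        if abs(self.nu) > 1:
            raise TrackerError("|nu| must be <= 1 in the unit-parameter regime")
        if self.iters_per_frame < 1:
            raise TrackerError("iters_per_frame must be >= 1")
        if not 0.0 <= self.overflow_tau <= 1.0:
            raise TrackerError("overflow_tau must lie in [0, 1]")
        if self.overflow_scope not in ("border", "global"):
            raise TrackerError("overflow_scope must be 'border' or 'global'")


@dataclass
class RegionStats:
    """Mean intensity inside (c1) and outside (c2) the contour."""

    c1: float
    c2: float
    degenerate: bool = False


def _as_mask(u) -> np.ndarray:
    u = np.asarray(u)
    return (u > 0).astype(np.uint8)


def region_means(image: Frame, u: np.ndarray) -> RegionStats:
    """Region means of the Chan-Vese energy.

    Empty regions get an ``EPS_REGION``-regularized denominator and set the
    ``degenerate`` flag instead of raising.
    """
    pixels = image.pixels
    u = _as_mask(u)
    if u.shape != pixels.shape:
        raise TrackerError("mask shape does not match image")
    n1 = float(u.sum())
    n0 = float(u.size - n1)
    s1 = float(pixels[u == 1].sum())
    s0 = float(pixels[u == 0].sum())
    degenerate = n1 == 0 or n0 == 0
    return RegionStats(c1=s1 / (n1 + EPS_REGION), c2=s0 / (n0 + EPS_REGION), degenerate=degenerate)


# ---------------------------------------------------------------------------
# evolution steps
# ---------------------------------------------------------------------------


def balloon_step(u: np.ndarray, nu: int) -> np.ndarray:
    """Uniform inflation (dilation, nu>0) or deflation (erosion, nu<0).

    Out-of-grid neighbours are ignored (same clipping policy as the
    structuring segments), hence ``border_value=1`` for the erosion.
    """
    u = _as_mask(u)
    if nu > 0:
        return ndimage.binary_dilation(u, structure=CROSS).astype(np.uint8)
    if nu < 0:
        return ndimage.binary_erosion(u, structure=CROSS, border_value=1).astype(np.uint8)
    return u.copy()


def _contour_pixels(u: np.ndarray) -> np.ndarray:
    """Pixels with nonzero discrete gradient magnitude of u (both sides of
    the contour), using central differences / one-sided at the border."""
    gr, gc = np.gradient(u.astype(np.float64))
    return (gr != 0) | (gc != 0)


def attachment_step(
    u: np.ndarray,
    image: Frame,
    params: ACWEParams,
    stats: RegionStats,
    contour: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Region-competition sign test on contour pixels.

    Each contour pixel joins the region whose mean its intensity is closer
    to (weighted by lambda1/lambda2); exact ties leave the pixel unchanged.
    ``contour`` selects the pixels the test applies to; by default it is the
    nonzero-gradient set of ``u`` itself.  Within a full MACWE iteration the
    contour of the *pre-balloon* embedding is passed instead, so that the
    inflation of the balloon step and the recession of the sign test cannot
    cancel each other into a spurious fixed point.
    """
    u = _as_mask(u)
    pixels = image.pixels
    if u.shape != pixels.shape:
        raise TrackerError("mask shape does not match image")
    if contour is None:
        contour = _contour_pixels(u)
    force = params.lambda1 * (pixels - stats.c1) ** 2 - params.lambda2 * (pixels - stats.c2) ** 2
    out = u.copy()
    out[contour & (force < 0)] = 1
    out[contour & (force > 0)] = 0
    return out


def _shifted(u: np.ndarray, dr: int, dc: int, fill: int) -> np.ndarray:
    """u translated by (dr, dc): out[x] = u[x + (dr, dc)], out-of-grid = fill."""
    h, w = u.shape
    out = np.full_like(u, fill)
    rs_src = slice(max(dr, 0), min(h, h + dr))
    cs_src = slice(max(dc, 0), min(w, w + dc))
    rs_dst = slice(max(-dr, 0), min(h, h - dr))
    cs_dst = slice(max(-dc, 0), min(w, w - dc))
    out[rs_dst, cs_dst] = u[rs_src, cs_src]
    return out


def _segment_extremum(u: np.ndarray, offs: np.ndarray, minimum: bool) -> np.ndarray:
    """Min (or max) of u over the segment centred at each pixel, ignoring
    out-of-grid pixels (fill with the extremum's neutral element)."""
    fill = 1 if minimum else 0
    acc = np.full_like(u, fill)
    for dr, dc in offs:
        s = _shifted(u, int(dr), int(dc), fill)
        acc = np.minimum(acc, s) if minimum else np.maximum(acc, s)
    return acc


def _si(u: np.ndarray, offsets: List[np.ndarray]) -> np.ndarray:
    """Sup-inf: max over segments of the min of u along each segment."""
    acc = np.zeros_like(u)
    for offs in offsets:
        acc = np.maximum(acc, _segment_extremum(u, offs, minimum=True))
    return acc


def _is(u: np.ndarray, offsets: List[np.ndarray]) -> np.ndarray:
    """Inf-sup: min over segments of the max of u along each segment."""
    acc = np.ones_like(u)
    for offs in offsets:
        acc = np.minimum(acc, _segment_extremum(u, offs, minimum=False))
    return acc


def si_is_smooth(u: np.ndarray, operator_set: OperatorSet, mu: int, phase: int = 0) -> np.ndarray:
    """``mu`` repetitions of the compound sup-inf/inf-sup smoothing.

    Acts as a curvature-like smoothing on the binary embedding: features
    thinner than the segments are removed, and the operator is monotone on
    {0,1} grids.  Each single application of ``SI after IS`` is slightly
    shrink-biased (and ``IS after SI`` growth-biased) - noticeably so for
    long segments - so successive repetitions alternate the two orders,
    as in the classical morphological-snakes smoothing cycle.  ``phase``
    selects which order starts (even: IS then SI), letting a caller that
    applies one repetition per tracking iteration continue the alternation
    across iterations.
    """
    if mu < 0:
        raise TrackerError("mu must be >= 0")
    u = _as_mask(u)
    offsets = operator_set.offsets()
    for rep in range(int(mu)):
        if (rep + phase) % 2 == 0:
            u = _si(_is(u, offsets), offsets)
        else:
            u = _is(_si(u, offsets), offsets)
    return u


def _touches_border(u: np.ndarray) -> bool:
    return bool(u[0, :].any() or u[-1, :].any() or u[:, 0].any() or u[:, -1].any())


def overflow_guard(
    u_candidate: np.ndarray,
    u_prev: np.ndarray,
    image: Frame,
    stats: RegionStats,
    tau: float,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    scope: str = "border",
) -> Tuple[np.ndarray, bool]:
    """Incomplete-area processing.

    Evaluates the attachment force sign on the contour pixels of ``u_prev``;
    ``f`` is the fraction with outward (growth) force.  If ``f > tau`` and -
    under the default border scope - the candidate contour touches the image
    border, the iteration's growth is suppressed: only pixels that were
    already inside remain inside.  Returns ``(mask, guard_active)``.
    """
    u_candidate = _as_mask(u_candidate)
    u_prev = _as_mask(u_prev)
    if u_candidate.shape != u_prev.shape or u_candidate.shape != image.pixels.shape:
        raise TrackerError("shape mismatch in overflow_guard")
    contour = _contour_pixels(u_prev)
    n = int(contour.sum())
    if n == 0:
        return u_candidate, False
    force = lambda1 * (image.pixels - stats.c1) ** 2 - lambda2 * (image.pixels - stats.c2) ** 2
    f = float((force[contour] < 0).mean())
    at_border = _touches_border(u_candidate) if scope == "border" else True
    if f > tau and at_border:
        return (u_candidate & u_prev).astype(np.uint8), True
    return u_candidate, False


def evolve_iteration(
    u: np.ndarray, image: Frame, params: ACWEParams, guard: bool = True, phase: int = 0
) -> Tuple[np.ndarray, bool]:
    """One full MACWE update: stats, balloon, attachment, smoothing, guard.

    ``phase`` is the smoothing-alternation parity of this iteration.
    """
    u = _as_mask(u)
    stats = region_means(image, u)
    contour = _contour_pixels(u)
    cand = balloon_step(u, params.nu)
    cand = attachment_step(cand, image, params, stats, contour=contour)
    cand = si_is_smooth(cand, params.operator_set, params.mu, phase=phase)
    if guard:
        return overflow_guard(
            cand, u, image, stats, params.overflow_tau,
            params.lambda1, params.lambda2, params.overflow_scope,
        )
    return cand, False


def evolve_frame(
    u_prev: np.ndarray, frame_pre: Frame, params: ACWEParams, guard: bool = True
) -> Tuple[np.ndarray, dict]:
    """Track one frame: ``iters_per_frame`` MACWE iterations.

    Returns the evolved embedding and an info dict with the number of guard
    activations.  Raises :class:`TrackingLostError` (carrying the last valid
    mask) if the 1-region vanishes.
    """
    u = _as_mask(u_prev)
    if not u.any():
        raise TrackerError("u_prev is empty")
    guard_activations = 0
    for it in range(params.iters_per_frame):
        u_new, activated = evolve_iteration(u, frame_pre, params, guard=guard, phase=it)
        if not u_new.any():
            raise TrackingLostError("embedding degenerated: 1-region vanished", last_valid=u)
        guard_activations += int(activated)
        u = u_new
    return u, {"guard_activations": guard_activations}


# ---------------------------------------------------------------------------
# initialization from the preoperative frame
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform2D:
    """Rigid preop->intraop map: rotation about the grid centre, then a
    translation in mm, with an isotropic mm-per-pixel scale ratio between
    the source and target grids.

    The forward map of a source pixel ``p`` (row, col) is
    ``p' = scale * R(rotation) @ (p - c_src) + c_tgt + translation/spacing``
    where ``c_src``/``c_tgt`` are the grid centres and ``spacing`` the target
    pixel spacing.
    """

    rotation: float = 0.0
    translation_mm: Tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise TrackerError("scale must be positive")


def init_from_preop(
    mask_preop: np.ndarray,
    transform: RigidTransform2D,
    target_shape: Tuple[int, int],
    target_spacing_mm: float = 1.0,
) -> np.ndarray:
    """Resample the preoperative segmentation into the intraoperative grid.

    Nearest-neighbour resampling under the rigid map, then binarization; the
    result seeds the tracker as its initial contour.
    """
    mask_preop = _as_mask(mask_preop)
    if not mask_preop.any():
        raise TrackerError("preoperative mask is empty")
    phi = transform.rotation
    r = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
    c_src = (np.array(mask_preop.shape, dtype=float) - 1.0) / 2.0
    c_tgt = (np.array(target_shape, dtype=float) - 1.0) / 2.0
    t_px = np.asarray(transform.translation_mm, dtype=float) / target_spacing_mm
    # inverse map for ndimage.affine_transform: p_src = M @ p_tgt + offset
    m = r.T / transform.scale
    offset = c_src - m @ (c_tgt + t_px)
    out = ndimage.affine_transform(
        mask_preop, m, offset=offset, output_shape=tuple(target_shape), order=0,
        mode="constant", cval=0,
    ).astype(np.uint8)
    if not out.any():
        raise EmptyInitializationError("rigid transform maps the mask outside the target grid")
    return out
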