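"""Unexpected-movement monitoring and contour correction.

During sonication the patient must hold still; large movements shift the
HIFU focus and must interrupt treatment.  The monitor works purely on the
(preprocessed) image stream:

* every ``cadence`` frames (default 10, i.e. a third of a second at 30 FPS)
  the mutual information between the current frame and the reference frame
  is evaluated; a drop below ``mi_threshold`` times the baseline raises an
  alarm and clears the treatment-permission flag;
* on alarm, normalized cross-correlation (NCC) template matching relocates
  the initial-contour patch within a bounded search range, and the vector
  from the matched position to the current contour centroid becomes a
  *moving force* ``m`` applied as integer translations spread over the next
  ``alpha`` frames;
* the alarm stands down once the image is stable again - by default one
  checkpoint whose MI against the previous checkpoint frame is back above
  threshold - after which the reference frame refreshes and contour
  evolution resumes.

The reference is the last *stable* checkpoint frame, not frame 0, so slow
drift (which the tracker itself absorbs) does not accumulate into false
alarms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import Frame
from .tracker import TrackingLostError, _as_mask, _shifted


class MotionError(ValueError):
    """Invalid monitor input."""


class NoMatchError(MotionError):
    """NCC is undefined (zero-variance template or search window)."""


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def mutual_information(frame_a: Frame, frame_b: Frame, bins: int = 64) -> float:
    """Histogram mutual information between two frames, in nats.

    Uses ``bins`` equal-width bins over [0, 1] on both axes of the joint
    histogram; zero-probability cells contribute nothing.  Nonnegative and
    symmetric; equals the marginal histogram entropy when both frames are
    identical.
    """
    a, b = frame_a.pixels, frame_b.pixels
    if a.shape != b.shape:
        raise MotionError("frames must share a shape")
    if bins < 2:
        raise MotionError("bins must be >= 2")
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins, range=[[0, 1], [0, 1]])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    denom = np.outer(px, py)[nz]
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / denom)))


# ---------------------------------------------------------------------------
# monitor state machine
# ---------------------------------------------------------------------------


@dataclass
class MonitorState:
    """Rolling movement-monitor state.

    ``search_range=(a, b)`` bounds the per-axis NCC displacement magnitude,
    ``alpha`` is the number of frames over which a moving force is spread,
    and ``treatment_permitted`` mirrors ``not alarm`` for the planner gate.
    """

    reference_frame: Frame
    template: np.ndarray
    template_origin: Tuple[int, int]
    centroid_offset: Tuple[float, float]
    cadence: int = 10
    mi_threshold: float = 0.6
    bins: int = 64
    baseline_mi: Optional[float] = None
    search_range: Tuple[int, int] = (0, 30)
    alpha: int = 5
    stable_checkpoints_required: int = 1
    alarm: bool = False
    pending_force: Tuple[int, int] = (0, 0)
    force_frames_left: int = 0
    last_checkpoint_frame: Optional[Frame] = None
    stable_seen: int = 0
    n_checks: int = 0
    log: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cadence < 1:
            raise MotionError("cadence must be >= 1")
        if not 0 < self.mi_threshold <= 1:
            raise MotionError("mi_threshold must lie in (0, 1]")
        a, b = self.search_range
        if a > b:
            raise MotionError("search_range must satisfy a <= b")
        if self.alpha < 1:
            raise MotionError("alpha must be >= 1")

    @property
    def treatment_permitted(self) -> bool:
        return not self.alarm


def _mask_centroid(u: np.ndarray) -> np.ndarray:
    rr, cc = np.nonzero(u)
    return np.array([rr.mean(), cc.mean()])


def init_monitor(reference_frame: Frame, init_mask: np.ndarray, **kwargs) -> MonitorState:
    """Capture the initial-contour bounding-box template and build the state.

    The template is cut from the (preprocessed) reference frame at the
    bounding box of the initial lesion mask; the offset from the template
    centre to the contour centroid is stored so a match position converts
    directly into a target centroid.
    """
    u = _as_mask(init_mask)
    if not u.any():
        raise MotionError("initial mask is empty")
    rr, cc = np.nonzero(u)
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1
    template = reference_frame.pixels[r0:r1, c0:c1].copy()
    center = np.array([(r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0])
    offset = _mask_centroid(u) - center
    return MonitorState(
        reference_frame=reference_frame,
        template=template,
        template_origin=(r0, c0),
        centroid_offset=(float(offset[0]), float(offset[1])),
        **kwargs,
    )


def check_motion(state: MonitorState, frame: Frame, frame_index: int) -> str:
    """Cadence-gated MI checkpoint; returns 'not_checked', 'stable' or 'alarm'.

    The first checkpoint registers the reference; the second fixes the MI
    baseline (the first cross-frame measurement).  While alarmed, stability
    is judged between consecutive checkpoint frames: once it returns, the
    alarm clears and the reference refreshes to the current frame.
    """
    if frame_index % state.cadence != 0:
        return "not_checked"
    mi = mutual_information(state.reference_frame, frame, state.bins)
    state.n_checks += 1
    decision = "stable"
    if state.n_checks == 1:
        pass  # reference checkpoint: MI is the self-information of the scene
    elif state.baseline_mi is None:
        state.baseline_mi = mi
    elif state.alarm:
        mi_recent = mutual_information(state.last_checkpoint_frame, frame, state.bins)
        if mi_recent >= state.mi_threshold * state.baseline_mi:
            state.stable_seen += 1
        else:
            state.stable_seen = 0
        if state.stable_seen >= state.stable_checkpoints_required:
            state.alarm = False
            state.stable_seen = 0
            state.reference_frame = frame
            decision = "stable"
        else:
            decision = "alarm"
    elif mi < state.mi_threshold * state.baseline_mi:
        state.alarm = True
        state.stable_seen = 0
        decision = "alarm"
    state.log.append(
        {
            "frame": int(frame_index),
            "mi": float(mi),
            "baseline": None if state.baseline_mi is None else float(state.baseline_mi),
            "decision": decision,
        }
    )
    state.last_checkpoint_frame = frame
    return decision


# ---------------------------------------------------------------------------
# NCC template matching and the moving force
# ---------------------------------------------------------------------------


def _axis_displacements(a: int, b: int) -> np.ndarray:
    """Allowed per-axis displacements: magnitude in [a, b] (signed)."""
    d = np.arange(-b, b + 1)
    return d[np.abs(d) >= a]


def ncc_match(
    image: Frame,
    template: np.ndarray,
    search_range: Tuple[int, int],
    origin: Tuple[int, int],
) -> Tuple[Tuple[int, int], float]:
    """Best NCC placement of ``template`` near its original ``origin``.

    Candidate placements displace the template per axis by a magnitude in
    ``[a, b]``; ties break toward the smallest displacement, then row-major.
    Returns the top-left placement ``P`` and its score in [-1, 1].  Raises
    :class:`NoMatchError` when the template (or every candidate window) has
    zero variance.
    """
    pixels = image.pixels
    th, tw = template.shape
    if th > pixels.shape[0] or tw > pixels.shape[1]:
        raise MotionError("template larger than image")
    tmean = template.mean()
    tvar = template.var()
    if tvar == 0:
        raise NoMatchError("zero-variance template")
    a, b = search_range
    drs = _axis_displacements(a, b)
    dcs = _axis_displacements(a, b)
    cands = []
    for dr in drs:
        for dc in dcs:
            r, c = origin[0] + int(dr), origin[1] + int(dc)
            if 0 <= r <= pixels.shape[0] - th and 0 <= c <= pixels.shape[1] - tw:
                cands.append((int(dr) ** 2 + int(dc) ** 2, r, c))
    if not cands:
        raise NoMatchError("no candidate placement fits inside the image")
    cands.sort()  # smallest displacement first, then row-major
    windows = sliding_window_view(pixels, (th, tw))
    rows = np.array([r for _, r, c in cands])
    cols = np.array([c for _, r, c in cands])
    wins = windows[rows, cols]
    wmean = wins.mean(axis=(1, 2))
    wvar = wins.var(axis=(1, 2))
    cross = (wins * template).mean(axis=(1, 2)) - wmean * tmean
    valid = wvar > 0
    if not valid.any():
        raise NoMatchError("zero-variance search windows")
    scores = np.full(len(cands), -np.inf)
    scores[valid] = cross[valid] / np.sqrt(wvar[valid] * tvar)
    best = int(np.argmax(scores))  # first max in preference order
    return (int(rows[best]), int(cols[best])), float(scores[best])


def set_moving_force(state: MonitorState, u: np.ndarray, matched_origin: Tuple[int, int]) -> Tuple[int, int]:
    """Convert an NCC match into a pending moving force.

    ``m`` is the vector from the current contour centroid to the matched
    template centre plus the stored template-to-centroid offset; it is
    rounded to integers and spread over the next ``alpha`` frames.
    """
    th, tw = state.template.shape
    matched_center = np.array(
        [matched_origin[0] + (th - 1) / 2.0, matched_origin[1] + (tw - 1) / 2.0]
    )
    target = matched_center + np.asarray(state.centroid_offset)
    m = target - _mask_centroid(_as_mask(u))
    state.pending_force = (int(round(m[0])), int(round(m[1])))
    state.force_frames_left = state.alpha
    return state.pending_force


def apply_moving_force(u: np.ndarray, state: MonitorState) -> np.ndarray:
    """Translate the embedding by this frame's share of the pending force.

    The integer force is split over the remaining frames by repeated
    ceiling division (largest remainder first), so the per-frame shifts sum
    to ``m`` exactly: m=(5,0), alpha=2 gives (3,0) then (2,0).
    """
    u = _as_mask(u)
    if state.force_frames_left <= 0:
        return u
    left = state.force_frames_left
    shift = []
    pending = list(state.pending_force)
    for axis in range(2):
        p = pending[axis]
        s = int(np.sign(p)) * -(-abs(p) // left)  # ceil(|p|/left) with sign
        shift.append(s)
        pending[axis] = p - s
    out = _shifted(u, -shift[0], -shift[1], fill=0)
    if not out.any():
        raise TrackingLostError("moving force pushed the mask off the grid", last_valid=u)
    state.pending_force = (pending[0], pending[1])
    state.force_frames_left = left - 1
    return out
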