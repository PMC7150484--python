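"""Speckle phantom sequences with ground-truth lesion masks.

The generator emulates the salient features of intraoperative HIFU
ultrasound: a hypoechoic (dark) elliptical fibroid with brighter internal
sub-structures, an optional anechoic bladder-like distractor, multiplicative
fully-developed-speckle texture, and a motion schedule combining smooth
drift, respiration-like oscillation and rare large jumps.  Every frame comes
with the exact elliptical ground-truth mask (internal blobs count as lesion
interior: the clinical target is the outer fibroid contour, not its internal
structure).

Speckle is modelled as per-pixel multiplicative gamma noise with unit mean
(shape ``k``, scale ``1/k``); a single shape parameter controls the
signal-to-noise ratio.  Coordinates are (row, col), 0-based, origin at the
top-left pixel; this convention is shared by every module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import Frame

#: phase offset of the axis deformation relative to the oscillation term, so
#: that shape change and translation are in quadrature
DEFORM_PHASE = math.pi / 2.0


class PhantomConfigError(ValueError):
    """The phantom configuration is inconsistent."""


@dataclass
class PhantomConfig:
    """Phantom geometry, texture and motion schedule.

    ``internal_blobs`` entries are ``((dr, dc), radius_px, intensity)`` with
    the centre offset relative to the (moving) lesion centre, so blobs travel
    with the lesion.  ``bladder`` is ``((row, col), (a, b), intensity)`` in
    fixed image coordinates.  ``oscillation = (amplitude_px, period_frames)``
    displaces the lesion centre along the row (axial) axis.  ``jumps`` is a
    list of ``(frame_index, (dr, dc))`` step displacements that persist from
    their frame onward.  ``speckle_shape=None`` renders noiseless frames.

    ``allow_truncation`` disables the lesion-inside-image check and clips the
    truth masks at the image border; it exists to build phantoms whose lesion
    is deliberately cut by the field of view.
    """

    image_height: int = 128
    image_width: int = 128
    pixel_spacing_mm: float = 0.25
    n_frames: int = 120
    lesion_center0: Tuple[float, float] = (64.0, 64.0)
    lesion_axes0: Tuple[float, float] = (22.0, 17.0)
    lesion_intensity: float = 0.35
    background_intensity: float = 0.60
    internal_blobs: List[tuple] = field(
        default_factory=lambda: [((-4.0, 5.0), 5.0, 0.55)]
    )
    bladder: Optional[tuple] = None
    speckle_shape: Optional[float] = 9.0
    drift_px_per_frame: Tuple[float, float] = (0.0, 0.0)
    oscillation: Tuple[float, float] = (0.0, 40.0)
    jumps: List[tuple] = field(default_factory=list)
    deform_amplitude: float = 0.0
    seed: int = 0
    allow_truncation: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise PhantomConfigError("n_frames must be >= 1")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise PhantomConfigError("speckle_shape must be positive")
        for v in (self.lesion_intensity, self.background_intensity):
            if not 0.0 <= v <= 1.0:
                raise PhantomConfigError("intensities must lie in [0, 1]")
        if min(self.lesion_axes0) <= 0:
            raise PhantomConfigError("lesion axes must be positive")
        if not 0.0 <= self.deform_amplitude < 1.0:
            raise PhantomConfigError("deform_amplitude must lie in [0, 1)")
        for f, _ in self.jumps:
            if not 0 <= f < self.n_frames:
                raise PhantomConfigError("jump frame_index out of range")


@dataclass
class PhantomSequence:
    """Rendered frames, per-frame ground-truth masks and the jump event log."""

    frames: List[Frame]
    truth_masks: List[np.ndarray]
    events: List[tuple]
    config: PhantomConfig


def lesion_geometry(config: PhantomConfig, t: int) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Lesion centre and semi-axes at frame ``t`` under the motion schedule.

    centre = centre0 + drift*t + oscillation (row axis) + accumulated jumps;
    axes = axes0 * (1 + deform_amplitude * sin(2*pi*t/period + pi/2)).
    Deterministic given the config.
    """
    if not 0 <= t < config.n_frames:
        raise IndexError(f"frame index {t} out of range [0, {config.n_frames})")
    amp, period = config.oscillation
    phase = 2.0 * math.pi * t / period if period > 0 else 0.0
    dr, dc = config.drift_px_per_frame
    row = config.lesion_center0[0] + dr * t + amp * math.sin(phase)
    col = config.lesion_center0[1] + dc * t
    for f, (jr, jc) in config.jumps:
        if f <= t:
            row += jr
            col += jc
    scale = 1.0 + config.deform_amplitude * math.sin(phase + DEFORM_PHASE)
    axes = (config.lesion_axes0[0] * scale, config.lesion_axes0[1] * scale)
    return (row, col), axes


def _ellipse_mask(shape: tuple, center: tuple, axes: tuple) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = axes
    return (((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0).astype(np.uint8)


def _disk_mask(shape: tuple, center: tuple, radius: float) -> np.ndarray:
    return _ellipse_mask(shape, center, (radius, radius))


def _noiseless_template(config: PhantomConfig, t: int) -> np.ndarray:
    shape = (config.image_height, config.image_width)
    center, axes = lesion_geometry(config, t)
    img = np.full(shape, config.background_intensity, dtype=np.float64)
    img[_ellipse_mask(shape, center, axes).astype(bool)] = config.lesion_intensity
    for (dr, dc), radius, intensity in config.internal_blobs:
        blob = _disk_mask(shape, (center[0] + dr, center[1] + dc), radius)
        img[blob.astype(bool)] = intensity
    if config.bladder is not None:
        bcenter, baxes, bintensity = config.bladder
        img[_ellipse_mask(shape, bcenter, baxes).astype(bool)] = bintensity
    return img


def _check_bounds(config: PhantomConfig, t: int) -> None:
    center, axes = lesion_geometry(config, t)
    if (
        center[0] - axes[0] < 0
        or center[0] + axes[0] > config.image_height - 1
        or center[1] - axes[1] < 0
        or center[1] + axes[1] > config.image_width - 1
    ):
        raise PhantomConfigError(
            f"lesion leaves the image bounds at frame {t} "
            f"(center={center}, axes={axes}); set allow_truncation=True "
            "to build a deliberately truncated phantom"
        )


def render_frame(config: PhantomConfig, t: int, rng: Optional[np.random.Generator] = None) -> Frame:
    """Render one frame: noiseless template times unit-mean gamma speckle.

    The per-frame random generator is derived from ``(config.seed, t)`` when
    ``rng`` is not supplied, so any frame can be re-rendered independently and
    bit-identically.
    """
    if min(lesion_geometry(config, t)[1]) <= 0:
        raise PhantomConfigError("degenerate lesion axes")
    template = _noiseless_template(config, t)
    if config.speckle_shape is None:
        return Frame(template.copy(), config.pixel_spacing_mm)
    if rng is None:
        rng = np.random.default_rng([config.seed, t])
    k = config.speckle_shape
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=template.shape)
    return Frame(np.clip(template * speckle, 0.0, 1.0), config.pixel_spacing_mm)


def truth_mask(config: PhantomConfig, t: int) -> np.ndarray:
    """Exact ellipse-interior ground truth at frame ``t`` (blobs included)."""
    shape = (config.image_height, config.image_width)
    center, axes = lesion_geometry(config, t)
    return _ellipse_mask(shape, center, axes)


def generate_phantom_sequence(config: PhantomConfig) -> PhantomSequence:
    """Render the whole sequence with ground truth and the jump event log.

    Raises :class:`PhantomConfigError` naming the first frame at which the
    lesion would leave the image, unless ``allow_truncation`` is set.
    """
    frames: List[Frame] = []
    masks: List[np.ndarray] = []
    for t in range(config.n_frames):
        if not config.allow_truncation:
            _check_bounds(config, t)
        frames.append(render_frame(config, t))
        mask = truth_mask(config, t)
        if not mask.any():
            raise PhantomConfigError(f"truth mask empty at frame {t}")
        masks.append(mask)
    events = [(int(f), "jump", (float(d[0]), float(d[1]))) for f, d in sorted(config.jumps)]
    return PhantomSequence(frames=frames, truth_masks=masks, events=events, config=config)


# ---------------------------------------------------------------------------
# study phantoms
# ---------------------------------------------------------------------------


def standard_phantom(n_frames: int = 120, seed: int = 0) -> PhantomConfig:
    """The default tracking phantom: one fibroid-like lesion with an internal
    blob, slow lateral drift, respiration-like oscillation and mild pulsatile
    deformation."""
    return PhantomConfig(
        n_frames=n_frames,
        drift_px_per_frame=(0.0, 0.05),
        oscillation=(1.5, 40.0),
        deform_amplitude=0.03,
        seed=seed,
    )


def fine_structure_phantom(n_frames: int = 60, seed: int = 0) -> PhantomConfig:
    """Internal-fine-structure phantom: a background-intensity echogenic band
    (8 px thick, built from overlapping blobs) crosses the lesion vertically.

    Small structuring segments can carve the contour along the band; the
    15-px segment bridges it, which is the behaviour this phantom isolates.
    """
    band = [((float(dr), 5.0), 4.0, 0.60) for dr in range(-20, 21, 4)]
    return PhantomConfig(
        n_frames=n_frames,
        drift_px_per_frame=(0.0, 0.1),
        oscillation=(2.0, 40.0),
        deform_amplitude=0.05,
        internal_blobs=band,
        seed=seed,
    )


def jump_phantom(n_frames: int = 120, seed: int = 0, jump_frame: int = 40) -> PhantomConfig:
    """Large-movement phantom: a small lesion (so a 20 px jump de-overlaps it
    completely) that is static except for one 20 px downward jump."""
    return PhantomConfig(
        n_frames=n_frames,
        lesion_center0=(50.0, 64.0),
        lesion_axes0=(8.0, 13.0),
        internal_blobs=[],
        jumps=[(jump_frame, (20.0, 0.0))],
        seed=seed,
    )


def truncated_phantom(seed: int = 0) -> PhantomConfig:
    """Incomplete-lesion phantom: the lesion is cut by the bottom image
    border and an anechoic bladder sits beside it, the configuration in which
    an unguarded contour overflows along the border into the bladder."""
    return PhantomConfig(
        n_frames=1,
        lesion_center0=(120.0, 64.0),
        lesion_axes0=(22.0, 17.0),
        internal_blobs=[],
        bladder=((118.0, 28.0), (20.0, 24.0), 0.05),
        allow_truncation=True,
        seed=seed,
    )
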