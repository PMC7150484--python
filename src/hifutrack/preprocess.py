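"""Ultrasound frame preprocessing.

HIFU intraoperative ultrasound is acquired through a water bath rather than
direct skin contact, so frames carry structured echo speckle and contain a
bladder that is easily confused with a hypoechoic fibroid.  Preprocessing is
a two-stage pipeline applied to every frame before contour evolution:

1. :func:`denoise_morphological` — grayscale opening followed by closing with
   a disk, suppressing speckle grains smaller than the structuring element
   while preserving region boundaries;
2. :func:`linear_enhance` — an affine intensity window derived from the
   statistics of the initial lesion region, stretching the lesion's intensity
   band to [0, 1] and clipping the (much darker) bladder to 0.

:func:`preprocess_frame` is the composition of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from skimage.morphology import closing, disk, opening


class PreprocessError(ValueError):
    """Invalid input to the preprocessing stage."""


class DegenerateWindowError(PreprocessError):
    """The ROI statistics give a zero-width intensity window."""


@dataclass
class Frame:
    """One 2D grayscale ultrasound frame.

    Parameters
    ----------
    pixels
        2D float array with intensities in [0, 1].
    spacing_mm
        Isotropic physical pixel spacing in mm/pixel.
    """

    pixels: np.ndarray
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise PreprocessError("frame must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise PreprocessError("frame contains non-finite pixels")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise PreprocessError("frame intensities must lie in [0, 1]")
        if self.spacing_mm <= 0:
            raise PreprocessError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class PreprocessParams:
    """Preprocessing configuration.

    ``kappa_radius`` is the radius (pixels) of the disk structuring element of
    the morphological denoiser.  If ``window_low``/``window_high`` are unset
    the window is derived from the initial-ROI statistics as
    ``[m - k*s, m + k*s]`` with ``k = roi_stat_k``.
    """

    kappa_radius: int = 2
    window_low: Optional[float] = None
    window_high: Optional[float] = None
    roi_stat_k: float = 2.0

    def __post_init__(self) -> None:
        if self.kappa_radius < 1:
            raise PreprocessError("kappa_radius must be >= 1")
        explicit = self.window_low is not None and self.window_high is not None
        if explicit and not self.window_low < self.window_high:
            raise PreprocessError("window_low must be < window_high")


def denoise_morphological(frame: Frame, kappa_radius: int = 2) -> Frame:
    """Suppress speckle with a grayscale opening followed by a closing.

    Both operations use a disk of radius ``kappa_radius``; bright and dark
    grains smaller than the disk are removed while larger structures keep
    their boundaries (unlike linear filtering, which blurs them).
    """
    if kappa_radius < 1:
        raise PreprocessError("kappa_radius must be >= 1")
    selem = disk(int(kappa_radius))
    out = closing(opening(frame.pixels, selem), selem)
    return Frame(np.clip(out, 0.0, 1.0), frame.spacing_mm)


def resolve_window(frame: Frame, init_mask: np.ndarray, params: PreprocessParams) -> tuple:
    """Return the (low, high) intensity window for :func:`linear_enhance`.

    An explicit window in ``params`` wins; otherwise the window is centred on
    the mean of the pixels inside ``init_mask`` with half-width
    ``roi_stat_k`` standard deviations.
    """
    if params.window_low is not None and params.window_high is not None:
        return float(params.window_low), float(params.window_high)
    mask = np.asarray(init_mask).astype(bool)
    if mask.shape != frame.pixels.shape:
        raise PreprocessError("init_mask shape does not match frame")
    if not mask.any():
        raise PreprocessError("init_mask is empty")
    roi = frame.pixels[mask]
    m, s = float(roi.mean()), float(roi.std())
    if s == 0.0:
        raise DegenerateWindowError(
            "zero-variance ROI and no explicit window; set window_low/window_high"
        )
    k = params.roi_stat_k
    return m - k * s, m + k * s


def linear_enhance(frame: Frame, init_mask: np.ndarray, params: PreprocessParams) -> Frame:
    """Affine intensity windowing anchored on the initial lesion region.

    Maps ``low -> 0`` and ``high -> 1`` linearly with clipping.  With the
    window taken from lesion-ROI statistics, bladder-like regions far darker
    than the lesion clip to 0 (implicit distractor removal) while the lesion's
    own band is stretched across the full range.
    """
    low, high = resolve_window(frame, init_mask, params)
    out = np.clip((frame.pixels - low) / (high - low), 0.0, 1.0)
    return Frame(out, frame.spacing_mm)


def preprocess_frame(frame: Frame, init_mask: np.ndarray, params: PreprocessParams) -> Frame:
    """Full per-frame preprocessing: morphological denoise, then enhancement.

    Denoising runs first so that the windowing statistics are computed on the
    speckle-suppressed image.  Pure function of its inputs.
    """
    den = denoise_morphological(frame, params.kappa_radius)
    return linear_enhance(den, init_mask, params)


def frozen_window_params(frame: Frame, init_mask: np.ndarray, params: PreprocessParams) -> PreprocessParams:
    """Resolve the ROI-derived window on ``frame`` and freeze it.

    The tracking pipeline computes the window once on the first frame and
    applies the same fixed window to every subsequent frame, keeping the
    intensity mapping consistent while the lesion moves away from the initial
    ROI.
    """
    low, high = resolve_window(denoise_morphological(frame, params.kappa_radius), init_mask, params)
    return replace(params, window_low=low, window_high=high)
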