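"""HIFU sonication focus planning over the tracked lesion.

Per slice, the treatment area is the central quarter of the tracked lesion:
the lesion shape scaled by 1/2 in each linear dimension about its centroid
(area ratio 1/4 up to pixelization), intersected with the lesion itself.
Foci are laid on a square grid with pitch ``spacing_mm`` (default 5 mm, i.e.
0.5 cm) anchored at the region centroid, so the plan translates with the
lesion.  The per-slice 2D plans are stacked into a 3D plan with
``z = slice_index * slice_spacing_mm``.  Sonication of any focus is gated by
the movement monitor's alarm flag.

Focus coordinates are reported in mm as (x, y) = (col, row) with the origin
at the centre of the image's top-left pixel; conversion to device
coordinates is the caller's job.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .motion import MonitorState
from .tracker import _as_mask


class PlannerError(ValueError):
    """Invalid planner input."""


class MaskTooSmallError(PlannerError):
    """The lesion mask is too small to contain a treatment region."""


@dataclass
class FocusPlan:
    """Per-slice sonication foci in mm plus the per-slice treatment masks."""

    slices: List[dict]
    spacing_mm: float = 5.0
    treatment_masks: Dict[int, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "spacing_mm": self.spacing_mm,
            "slices": [
                {
                    "slice_index": s["slice_index"],
                    "z_mm": s["z_mm"],
                    "foci": [[round(float(x), 6), round(float(y), 6)] for x, y in s["foci"]],
                }
                for s in self.slices
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["slice_index", "z_mm", "x_mm", "y_mm"])
            for s in self.slices:
                for x, y in s["foci"]:
                    writer.writerow([s["slice_index"], s["z_mm"], round(float(x), 6), round(float(y), 6)])


def treatment_region(lesion_mask: np.ndarray) -> np.ndarray:
    """Central quarter-area treatment region of a lesion mask.

    A pixel belongs to the region iff the lesion contains the point twice as
    far from the centroid (nearest-neighbour sampling), i.e. the lesion
    scaled by 1/2 about its centroid; the result is intersected with the
    lesion so containment holds exactly.
    """
    u = _as_mask(lesion_mask)
    if not u.any():
        raise PlannerError("lesion mask is empty")
    if u.sum() < 16:
        # a quarter-area region of fewer than 16 px has no meaningful extent
        raise MaskTooSmallError("mask too small to contain a quarter-area treatment region")
    c = np.array(ndimage.center_of_mass(u))
    # inverse map p_src = 2*p_out - c for ndimage.affine_transform
    out = ndimage.affine_transform(
        u, 2.0 * np.eye(2), offset=-c, output_shape=u.shape, order=0, mode="constant", cval=0
    ).astype(np.uint8)
    out &= u
    if not out.any():
        raise MaskTooSmallError("mask too small to contain a quarter-area treatment region")
    return out


def distribute_foci_2d(
    region: np.ndarray, spacing_mm: float, pixel_spacing_mm: float
) -> List[Tuple[float, float]]:
    """Even square grid of foci over a treatment region.

    The grid has pitch ``spacing_mm`` and is anchored at the region
    centroid; a grid point is kept when its nearest pixel lies inside the
    region.  Returned as (x_mm, y_mm) sorted row-major; an empty region
    yields an empty list.
    """
    if spacing_mm <= 0 or pixel_spacing_mm <= 0:
        raise PlannerError("spacings must be positive")
    u = _as_mask(region)
    if not u.any():
        return []
    h, w = u.shape
    c = np.array(ndimage.center_of_mass(u))
    pitch_px = spacing_mm / pixel_spacing_mm
    i_min = int(np.ceil((0 - c[0]) / pitch_px))
    i_max = int(np.floor((h - 1 - c[0]) / pitch_px))
    j_min = int(np.ceil((0 - c[1]) / pitch_px))
    j_max = int(np.floor((w - 1 - c[1]) / pitch_px))
    foci: List[Tuple[float, float]] = []
    for i in range(i_min, i_max + 1):
        for j in range(j_min, j_max + 1):
            r = c[0] + i * pitch_px
            col = c[1] + j * pitch_px
            ri, ci = int(round(r)), int(round(col))
            if 0 <= ri < h and 0 <= ci < w and u[ri, ci]:
                foci.append((col * pixel_spacing_mm, r * pixel_spacing_mm))
    return foci


def assemble_3d(
    per_slice: Sequence[Tuple[int, np.ndarray]],
    slice_spacing_mm: float,
    spacing_mm: float,
    pixel_spacing_mm: float,
) -> FocusPlan:
    """Stack per-slice 2D focus distributions into a 3D plan.

    Each slice independently gets its quarter-area treatment region and
    focus grid; slices whose lesion is empty or too small for a treatment
    region contribute a layer with zero foci.  ``z = index * slice_spacing``.
    """
    indices = [i for i, _ in per_slice]
    if len(set(indices)) != len(indices):
        raise PlannerError("duplicate slice index in plan input")
    slices = []
    masks: Dict[int, np.ndarray] = {}
    for idx, lesion in sorted(per_slice, key=lambda p: p[0]):
        lesion = _as_mask(lesion)
        foci: List[Tuple[float, float]] = []
        if lesion.any():
            try:
                region = treatment_region(lesion)
            except MaskTooSmallError:
                region = None
            if region is not None:
                masks[int(idx)] = region
                foci = distribute_foci_2d(region, spacing_mm, pixel_spacing_mm)
        slices.append(
            {"slice_index": int(idx), "z_mm": float(idx * slice_spacing_mm), "foci": foci}
        )
    return FocusPlan(slices=slices, spacing_mm=float(spacing_mm), treatment_masks=masks)


def gate_by_alarm(monitor: MonitorState) -> str:
    """Sonication permission for the next focus: 'hold' while alarmed."""
    return "hold" if monitor.alarm else "fire"
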