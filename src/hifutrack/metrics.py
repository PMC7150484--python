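"""Segmentation/tracking evaluation: DSC, IoU and Hausdorff distance (mm).

DSC = 2|A∩B| / (|A|+|B|) and IoU = |A∩B| / |A∪B| operate on filled masks
(both defined as 1 for two empty masks, so reports stay total on degenerate
runs).  The Hausdorff distance is the symmetric max-min Euclidean distance
between *boundary* pixel sets, scaled by the isotropic pixel spacing into
mm; it is undefined (error) for empty masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .tracker import _as_mask


class MetricError(ValueError):
    """Invalid metric input."""


class UndefinedMetricError(MetricError):
    """The metric is undefined for this input (e.g. HD of an empty mask)."""


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise MetricError("masks must share a shape")


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks."""
    a, b = _as_mask(a), _as_mask(b)
    _check_shapes(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union (Jaccard index) of two binary masks."""
    a, b = _as_mask(a), _as_mask(b)
    _check_shapes(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels: mask minus its 4-connected erosion."""
    er = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1))
    return np.argwhere(mask.astype(bool) & ~er)


def hausdorff_mm(a: np.ndarray, b: np.ndarray, spacing_mm: float) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm.

    Requires nonempty masks and an isotropic (scalar) spacing.
    """
    if np.ndim(spacing_mm) != 0:
        raise MetricError("anisotropic spacing is not supported; pass a scalar")
    if spacing_mm <= 0:
        raise MetricError("spacing must be positive")
    a, b = _as_mask(a), _as_mask(b)
    _check_shapes(a, b)
    if not a.any() or not b.any():
        raise UndefinedMetricError("Hausdorff distance is undefined for an empty mask")
    pa, pb = _boundary(a), _boundary(b)
    d = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return float(d) * float(spacing_mm)


@dataclass
class TrackingReport:
    """Per-frame metric table plus mean/SD summary."""

    per_frame: pd.DataFrame
    summary: Dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "per_frame": [
                {k: (int(v) if k == "frame" else round(float(v), 9)) for k, v in rec.items()}
                for rec in self.per_frame.to_dict("records")
            ],
            "summary": {k: round(float(v), 9) for k, v in sorted(self.summary.items())},
        }


def evaluate_sequence(
    pred: Sequence[np.ndarray], truth: Sequence[np.ndarray], spacing_mm: float
) -> TrackingReport:
    """Per-frame DSC / HD(mm) / IoU against ground truth, with summaries.

    Frames where the Hausdorff distance is undefined (an empty mask) report
    ``hd_mm = nan`` and are excluded from the HD summary.
    """
    if len(pred) != len(truth):
        raise MetricError("prediction and truth sequences differ in length")
    rows: List[dict] = []
    for t, (p, g) in enumerate(zip(pred, truth)):
        try:
            hd = hausdorff_mm(p, g, spacing_mm)
        except UndefinedMetricError:
            hd = float("nan")
        rows.append({"frame": t, "dsc": dsc(p, g), "hd_mm": hd, "iou": iou(p, g)})
    table = pd.DataFrame(rows)
    summary = {}
    for col in ("dsc", "hd_mm", "iou"):
        vals = table[col].dropna()
        summary[f"{col}_mean"] = float(vals.mean()) if len(vals) else float("nan")
        summary[f"{col}_sd"] = float(vals.std(ddof=0)) if len(vals) else float("nan")
    return TrackingReport(per_frame=table, summary=summary)
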