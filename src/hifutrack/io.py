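"""File I/O, run configuration and the end-to-end pipeline.

The pipeline follows the intraoperative guidance loop: each incoming frame
is preprocessed, the movement monitor is consulted on its cadence, and the
contour is either evolved by the MACWE tracker (normal operation) or - while
the alarm stands - frozen except for the NCC moving-force translation.  At
the end of a run the tracked contour feeds the focus planner and, when
ground truth is available, the evaluation report.

Frames and masks are exchanged as zero-padded PNG stacks; configuration is
YAML with strict (unknown-key rejecting) parsing; run logs are JSON lines so
they are machine-checkable.  All randomness flows through the single seed in
the run configuration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import yaml
from skimage import measure

from .metrics import TrackingReport, evaluate_sequence
from .motion import (
    MonitorState,
    NoMatchError,
    apply_moving_force,
    check_motion,
    init_monitor,
    ncc_match,
    set_moving_force,
)
from .planner import FocusPlan, assemble_3d
from .preprocess import Frame, PreprocessParams, frozen_window_params, preprocess_frame
from .synth import PhantomConfig, PhantomSequence, generate_phantom_sequence
from .tracker import ACWEParams, TrackingLostError, evolve_frame, operator_set

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


class IOError_(ValueError):
    """Invalid file input."""


class ConfigError(ValueError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# frame and mask stacks
# ---------------------------------------------------------------------------


def _stack_paths(path) -> List[Path]:
    root = Path(path)
    if not root.is_dir():
        raise IOError_(f"not a directory: {root}")
    paths = sorted(p for p in root.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not paths:
        raise IOError_(f"no PNG/TIFF frames found in {root}")
    return paths


def read_frame_stack(path, spacing_mm: float = 1.0) -> List[Frame]:
    """Read a directory of numbered PNG/TIFF frames, rescaled to [0, 1].

    Frames are ordered by (zero-padded) filename; inconsistent shapes raise
    an error naming the first offending file.
    """
    frames: List[Frame] = []
    shape = None
    for p in _stack_paths(path):
        try:
            arr = iio.imread(p)
        except Exception as exc:  # pragma: no cover - imageio message varies
            raise IOError_(f"unreadable image {p}: {exc}") from exc
        if arr.ndim == 3:
            arr = arr[..., 0]
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise IOError_(f"frame {p.name} has shape {arr.shape}, expected {shape}")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
        else:
            arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
        frames.append(Frame(arr, spacing_mm))
    return frames


def write_frames(path, frames: Sequence[Frame], prefix: str = "frame") -> List[Path]:
    """Write frames as 8-bit zero-padded ``<prefix>_%05d.png``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    out = []
    for t, frame in enumerate(frames):
        p = root / f"{prefix}_{t:05d}.png"
        iio.imwrite(p, np.round(frame.pixels * 255).astype(np.uint8))
        out.append(p)
    return out


def write_masks(path, masks: Sequence[np.ndarray], prefix: str = "mask") -> List[Path]:
    """Write binary masks as 0/255 ``<prefix>_%05d.png``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    out = []
    for t, mask in enumerate(masks):
        p = root / f"{prefix}_{t:05d}.png"
        iio.imwrite(p, (np.asarray(mask) > 0).astype(np.uint8) * 255)
        out.append(p)
    return out


def read_masks(path) -> List[np.ndarray]:
    """Read a 0/255 PNG mask stack; gray values binarize at 128 with a warning."""
    masks = []
    for p in _stack_paths(path):
        arr = iio.imread(p)
        if arr.ndim == 3:
            arr = arr[..., 0]
        values = np.unique(arr)
        if not np.isin(values, (0, 255)).all():
            warnings.warn(f"non-binary mask {p.name}: thresholding at 128", stacklevel=2)
        masks.append((arr >= 128).astype(np.uint8))
    return masks


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class MonitorConfig:
    enabled: bool = True
    cadence: int = 10
    bins: int = 64
    mi_threshold: float = 0.6
    search_range: Tuple[int, int] = (0, 30)
    alpha: int = 5
    stable_checkpoints_required: int = 1


@dataclass
class TrackerConfig:
    operator_set: str = "k15"
    k15_orientations: Tuple[float, ...] = (0.0,)
    mu: int = 1
    nu: int = 1
    lambda1: float = 1.0
    lambda2: float = 1.0
    iters_per_frame: int = 5
    overflow_tau: float = 0.5
    overflow_scope: str = "border"

    def to_acwe_params(self) -> ACWEParams:
        return ACWEParams(
            mu=self.mu,
            nu=self.nu,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            iters_per_frame=self.iters_per_frame,
            operator_set=operator_set(self.operator_set, self.k15_orientations),
            overflow_tau=self.overflow_tau,
            overflow_scope=self.overflow_scope,
        )


@dataclass
class PlannerConfig:
    spacing_mm: float = 5.0
    slice_spacing_mm: float = 5.0


@dataclass
class RunConfig:
    """Top-level run configuration; YAML round-trips losslessly."""

    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    monitor: MonitorConfig = field(default_factory=MonitorConfig)
    planner: PlannerConfig = field(default_factory=PlannerConfig)


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list) and isinstance(f.default, tuple):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def _normalize_phantom(data: dict) -> dict:
    data = dict(data)
    for key in ("lesion_center0", "lesion_axes0", "drift_px_per_frame", "oscillation"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    if data.get("jumps"):
        data["jumps"] = [(int(f), (float(d[0]), float(d[1]))) for f, d in data["jumps"]]
    if data.get("internal_blobs"):
        data["internal_blobs"] = [
            ((float(c[0]), float(c[1])), float(r), float(v)) for c, r, v in data["internal_blobs"]
        ]
    if data.get("bladder"):
        c, ax, v = data["bladder"]
        data["bladder"] = ((float(c[0]), float(c[1])), (float(ax[0]), float(ax[1])), float(v))
    if "search_range" in data:
        data["search_range"] = tuple(data["search_range"])
    return data


def config_from_dict(data: dict) -> RunConfig:
    known = {"seed", "phantom", "preprocess", "tracker", "monitor", "planner"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = RunConfig(seed=int(data.get("seed", 0)))
    if "phantom" in data:
        cfg.phantom = _build(PhantomConfig, _normalize_phantom(data["phantom"]), "phantom")
    if "preprocess" in data:
        pp = dict(data["preprocess"])
        if "window" in pp:
            window = pp.pop("window")
            if window is not None:
                pp["window_low"], pp["window_high"] = float(window[0]), float(window[1])
        cfg.preprocess = _build(PreprocessParams, pp, "preprocess")
    if "tracker" in data:
        cfg.tracker = _build(TrackerConfig, dict(data["tracker"]), "tracker")
    if "monitor" in data:
        mon = dict(data["monitor"])
        if "search_range" in mon:
            mon["search_range"] = tuple(mon["search_range"])
        cfg.monitor = _build(MonitorConfig, mon, "monitor")
    if "planner" in data:
        cfg.planner = _build(PlannerConfig, dict(data["planner"]), "planner")
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            obj = dataclasses.asdict(obj)
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        return obj

    return {
        "seed": cfg.seed,
        "phantom": plain(cfg.phantom),
        "preprocess": plain(cfg.preprocess),
        "tracker": plain(cfg.tracker),
        "monitor": plain(cfg.monitor),
        "planner": plain(cfg.planner),
    }


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def contours_to_csv_rows(masks: Sequence[np.ndarray]) -> List[tuple]:
    """Contour polylines (frame, vertex_index, row, col) at level 1/2."""
    rows = []
    for t, mask in enumerate(masks):
        for contour in measure.find_contours(np.asarray(mask, dtype=float), 0.5):
            for k, (r, c) in enumerate(contour):
                rows.append((t, k, round(float(r), 3), round(float(c), 3)))
    return rows


@dataclass
class PipelineResult:
    masks: List[np.ndarray]
    plan: FocusPlan
    report: Optional[TrackingReport]
    log: List[dict]
    monitor: Optional[MonitorState]


def run_pipeline(
    config: RunConfig,
    out_dir=None,
    frames: Optional[Sequence[Frame]] = None,
    init_mask: Optional[np.ndarray] = None,
    truth: Optional[Sequence[np.ndarray]] = None,
) -> PipelineResult:
    """Run the full guidance loop on a frame sequence.

    Without explicit ``frames``, the phantom described by the configuration
    is generated (seeded by ``config.seed``) and its first truth mask seeds
    the tracker.  Per frame: preprocess, movement checkpoint on the monitor
    cadence, then either MACWE evolution or (while alarmed) the moving-force
    translation only.  The final mask feeds the focus planner.
    """
    phantom_cfg = dataclasses.replace(config.phantom, seed=config.seed)
    if frames is None:
        seq = generate_phantom_sequence(phantom_cfg)
        frames = seq.frames
        if truth is None:
            truth = seq.truth_masks
        if init_mask is None:
            init_mask = seq.truth_masks[0]
    if init_mask is None:
        raise ConfigError("init_mask is required when frames are supplied")
    init_mask = (np.asarray(init_mask) > 0).astype(np.uint8)

    acwe = config.tracker.to_acwe_params()
    log: List[dict] = []

    pp = frozen_window_params(frames[0], init_mask, config.preprocess)
    pre0 = preprocess_frame(frames[0], init_mask, pp)

    monitor: Optional[MonitorState] = None
    if config.monitor.enabled:
        monitor = init_monitor(
            pre0,
            init_mask,
            cadence=config.monitor.cadence,
            bins=config.monitor.bins,
            mi_threshold=config.monitor.mi_threshold,
            search_range=tuple(config.monitor.search_range),
            alpha=config.monitor.alpha,
            stable_checkpoints_required=config.monitor.stable_checkpoints_required,
        )

    u = init_mask.copy()
    masks: List[np.ndarray] = []
    tracking_lost = False
    for t, frame in enumerate(frames):
        try:
            pre = preprocess_frame(frame, init_mask, pp)
            if monitor is not None:
                decision = check_motion(monitor, pre, t)
                if decision != "not_checked":
                    log.append(dict(monitor.log[-1], kind="checkpoint"))
                if decision == "alarm":
                    try:
                        matched, score = ncc_match(
                            pre, monitor.template, monitor.search_range, monitor.template_origin
                        )
                        m = set_moving_force(monitor, u, matched)
                        log.append(
                            {
                                "kind": "correction",
                                "frame": t,
                                "P": [int(matched[0]), int(matched[1])],
                                "score": round(float(score), 6),
                                "m": [int(m[0]), int(m[1])],
                                "alpha": monitor.alpha,
                            }
                        )
                    except NoMatchError:
                        log.append({"kind": "correction_failed", "frame": t})
            if monitor is not None and monitor.alarm:
                if monitor.force_frames_left > 0:
                    u = apply_moving_force(u, monitor)
            elif not tracking_lost:
                if monitor is not None and monitor.force_frames_left > 0:
                    u = apply_moving_force(u, monitor)
                try:
                    u, info = evolve_frame(u, pre, acwe)
                except TrackingLostError as exc:
                    # clinical condition, not a crash: freeze the last valid
                    # contour and keep the report total
                    tracking_lost = True
                    u = exc.last_valid
                    log.append({"kind": "tracking_lost", "frame": t})
                    info = {"guard_activations": 0}
                if info["guard_activations"]:
                    log.append(
                        {"kind": "guard", "frame": t, "activations": info["guard_activations"]}
                    )
        except Exception as exc:
            log.append({"kind": "error", "frame": t, "stage": type(exc).__name__, "message": str(exc)})
            if out_dir is not None:
                _write_log(Path(out_dir), log)
            raise
        masks.append(u.copy())

    plan = assemble_3d(
        [(0, masks[-1])],
        slice_spacing_mm=config.planner.slice_spacing_mm,
        spacing_mm=config.planner.spacing_mm,
        pixel_spacing_mm=frames[0].spacing_mm,
    )
    report = evaluate_sequence(masks, truth, frames[0].spacing_mm) if truth is not None else None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_masks(out, masks, prefix="track")
        plan.write_json(out / "plan.json")
        plan.write_csv(out / "plan.csv")
        if report is not None:
            with open(out / "report.json", "w") as fh:
                json.dump(report.to_json_dict(), fh, sort_keys=True, indent=2)
                fh.write("\n")
        with open(out / "contours.csv", "w") as fh:
            fh.write("frame,vertex_index,row,col\n")
            for row in contours_to_csv_rows(masks):
                fh.write(",".join(str(v) for v in row) + "\n")
        _write_log(out, log)
    return PipelineResult(masks=masks, plan=plan, report=report, log=log, monitor=monitor)


def _write_log(out: Path, log: List[dict]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_log.jsonl", "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
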