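"""End-to-end pipeline: segmentation -> contour -> (normalize) -> centerline
-> kinematics -> (kymograph + band fits), with deterministic, fully logged
outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import tiptrace
from tiptrace import io as tio
from tiptrace.centerline import Centerline, contour_to_centerline
from tiptrace.kinematics import build_tip_trace
from tiptrace.register import SearchSpec, normalize_sequence
from tiptrace.segmentation import binarize_otsu, extract_contour, load_masks, smooth_contour
from tiptrace.signalprofile import build_kymograph, profile_along_centerline, track_band
from tiptrace.types import ImageSequence

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; hashable for provenance stamping."""

    input_path: str | None = None
    signal_path: str | None = None
    masks_path: str | None = None
    pixel_size: float = 1.0
    dt: float = 1.0
    time_unit: str = "min"
    normalize: bool = False
    reference_frame: int = 0
    register_strategy: str = "successive"
    register_on_mask: bool = False
    search_u: tuple[float, float] = (-15.0, 15.0)
    search_v: tuple[float, float] = (-15.0, 15.0)
    search_theta: tuple[float, float] = (-15.0, 15.0)
    segmentation: str = "otsu"            # or "external_masks"
    polarity: str = "bright_object"
    contour_smooth_frac: float | None = None
    centerline_smooth_frac: float | None = None
    k_extrapolation: int = 5
    min_branch_length: float | None = None
    bottom_anchor: tuple[float, float] | None = None
    bottom_first: bool | None = None
    kymo_anchor: str = "bottom"
    profile_step: float | None = None     # um; default pixel_size
    profile_halfwidth: float | None = None  # um; default 0.4 * local cell width
    band_end_multiplier: float = 1.0
    output_dir: str = "tiptrace_out"
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be positive")
        if self.segmentation not in ("otsu", "external_masks"):
            raise ValueError("segmentation must be 'otsu' or 'external_masks'")
        if self.segmentation == "external_masks" and not self.masks_path:
            raise ValueError("external_masks mode requires masks_path")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    contours: list = field(default_factory=list)
    centerlines: list = field(default_factory=list)
    transforms: list | None = None
    trace = None
    kymograph = None
    band_table = None
    run_log: dict = field(default_factory=dict)


def _estimate_cell_width_um(contour, centerline, pixel_size: float) -> float:
    from scipy.spatial import cKDTree
    interior = centerline.points[1:-1]
    d, _ = cKDTree(contour.points).query(interior)
    return 2.0 * float(np.median(d)) * pixel_size


def run_pipeline(config: RunConfig, seq: ImageSequence | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis. ``seq`` may be passed directly (in-memory);
    otherwise it is read from ``config.input_path``."""
    if seq is None:
        if not config.input_path:
            raise ValueError("no input: provide a sequence or config.input_path")
        seq = tio.read_sequence(config.input_path, config.pixel_size, config.dt,
                                signal_path=config.signal_path,
                                time_unit=config.time_unit)
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config)
    log: dict = {
        "software": "tiptrace",
        "version": tiptrace.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_frames": seq.n_frames,
        "stages": [],
    }

    def stage(name, fn, frame_index=None):
        try:
            return fn()
        except Exception as exc:
            where = f" (frame {frame_index})" if frame_index is not None else ""
            log["stages"].append({"stage": name, "status": f"error: {exc}"})
            tio.write_run_log(log, outdir / "runlog.json")
            raise RuntimeError(f"stage {name!r}{where}: {exc}") from exc

    # --- segmentation -------------------------------------------------
    if config.segmentation == "external_masks":
        masks = stage("load_masks", lambda: load_masks(
            config.masks_path, seq.n_frames, frame_shape=seq.frame_shape))
    else:
        masks = []
        for i in range(seq.n_frames):
            masks.append(stage("binarize_otsu",
                               lambda i=i: binarize_otsu(seq.frames[i],
                                                         polarity=config.polarity,
                                                         frame_index=i),
                               frame_index=i))
    log["stages"].append({"stage": "segmentation", "status": "ok",
                          "mode": config.segmentation})

    # --- registration -------------------------------------------------
    transforms = None
    work_seq = seq
    if config.normalize:
        search = SearchSpec(u_range=config.search_u, v_range=config.search_v,
                            theta_range=config.search_theta)
        work_seq, transforms = stage("normalize", lambda: normalize_sequence(
            seq, reference_index=config.reference_frame, search=search,
            strategy=config.register_strategy, use_mask=config.register_on_mask))
        result.transforms = transforms
        tio.write_csv(tio.transforms_table(transforms), outdir / "transforms.csv")
        # masks must follow the frames into the normalized coordinate system
        masks = []
        for i in range(work_seq.n_frames):
            masks.append(stage("binarize_otsu_aligned",
                               lambda i=i: binarize_otsu(work_seq.frames[i],
                                                         polarity=config.polarity,
                                                         frame_index=i),
                               frame_index=i))
        log["stages"].append({"stage": "normalize", "status": "ok",
                              "strategy": config.register_strategy})

    # --- contours and centerlines ------------------------------------
    contours = []
    centerlines: list[Centerline] = []
    prev: Centerline | None = None
    for i, m in enumerate(masks):
        c = stage("extract_contour", lambda m=m: extract_contour(m), frame_index=i)
        if config.contour_smooth_frac:
            c = stage("smooth_contour",
                      lambda c=c: smooth_contour(c, frac=config.contour_smooth_frac),
                      frame_index=i)
        contours.append(c)
        anchor = config.bottom_anchor if prev is None else None
        bottom_first = config.bottom_first if (prev is None and anchor is None) else None
        cl = stage("centerline", lambda c=c, prev=prev, anchor=anchor,
                   bottom_first=bottom_first, i=i: contour_to_centerline(
                       c, pixel_size=config.pixel_size,
                       min_branch_length=config.min_branch_length,
                       k=config.k_extrapolation,
                       smooth_frac=config.centerline_smooth_frac,
                       prev=prev, anchor=anchor, bottom_first=bottom_first,
                       frame_index=i), frame_index=i)
        centerlines.append(cl)
        prev = cl
    result.contours = contours
    result.centerlines = centerlines
    tio.write_csv(tio.contours_table(contours), outdir / "contours.csv")
    tio.write_csv(tio.centerlines_table(centerlines), outdir / "centerlines.csv")
    tio.write_csv(tio.tips_table(centerlines), outdir / "tips.csv")
    log["stages"].append({"stage": "centerline", "status": "ok",
                          "k": config.k_extrapolation,
                          "min_branch_length": config.min_branch_length})

    # --- kinematics ---------------------------------------------------
    trace = stage("kinematics", lambda: build_tip_trace(
        centerlines, transforms=None, dt=config.dt, pixel_size=config.pixel_size,
        time_unit=config.time_unit))
    result.trace = trace
    tio.write_csv(trace.table, outdir / "trace.csv")
    log["stages"].append({"stage": "kinematics", "status": "ok",
                          "reference_axis": trace.reference_axis.tolist()})

    # --- signal channel ----------------------------------------------
    if work_seq.signal is not None:
        step = config.profile_step or config.pixel_size
        profiles = []
        for i, cl in enumerate(centerlines):
            hw = config.profile_halfwidth
            if hw is None:
                hw = 0.4 * _estimate_cell_width_um(contours[i], cl, config.pixel_size)
            profiles.append(stage("profile", lambda i=i, cl=cl, hw=hw:
                                  profile_along_centerline(
                                      work_seq.signal[i], cl, halfwidth=hw, step=step,
                                      contour=contours[i], frame_index=i),
                                  frame_index=i))
        kymo = stage("kymograph", lambda: build_kymograph(
            profiles, dt=config.dt, anchor=config.kymo_anchor, step=step))
        result.kymograph = kymo
        tio.write_csv(tio.kymograph_tables(kymo), outdir / "kymograph.csv")
        tio.write_kymograph_tiff(kymo, outdir / "kymograph.tif")
        band = stage("band_fit", lambda: track_band(
            profiles, dt=config.dt, end_multiplier=config.band_end_multiplier))
        result.band_table = band
        tio.write_csv(band, outdir / "bands.csv")
        log["stages"].append({"stage": "signal", "status": "ok", "step_um": step,
                              "anchor": config.kymo_anchor,
                              "band_end_multiplier": config.band_end_multiplier})

    if config.make_plots:
        _make_plots(result, outdir)
    log["outputs"] = sorted(p.name for p in outdir.iterdir())
    result.run_log = log
    tio.write_run_log(log, outdir / "runlog.json")
    return result


def _make_plots(result: PipelineResult, outdir: Path) -> None:
    t = result.trace.table
    fig, axes = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    axes[0].plot(t["time"], t["dLdt"], "o-")
    axes[0].set_ylabel(f"dL/dt (um/{result.trace.time_unit})")
    axes[1].plot(t["time"], t["delta_theta_deg"], "o-")
    axes[1].set_ylabel("delta theta (deg; + is CCW, y flipped up)")
    axes[1].set_xlabel(f"time ({result.trace.time_unit})")
    fig.tight_layout()
    fig.savefig(outdir / "kinematics.png", dpi=120)
    plt.close(fig)

    if result.kymograph is not None:
        kymo = result.kymograph
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(kymo.matrix, aspect="auto", origin="lower",
                       extent=[kymo.t_axis[0], kymo.t_axis[-1],
                               kymo.s_axis[0], kymo.s_axis[-1]])
        ax.set_xlabel("time")
        ax.set_ylabel(f"s (um, from {kymo.anchor})")
        fig.colorbar(im, ax=ax, label="intensity")
        if result.band_table is not None:
            b = result.band_table
            ax.plot(b["time"], b["lower"], "m-", lw=1)
            ax.plot(b["time"], b["upper"], "m-", lw=1)
        fig.tight_layout()
        fig.savefig(outdir / "kymograph.png", dpi=120)
        plt.close(fig)
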