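"""Readers and writers for standard formats.

Image sequences come in as multi-page grayscale TIFF or a glob of per-frame
images (natural-sorted); tables go out as RFC-4180 CSV with '.' decimals and
a header row; kymographs are written both as 32-bit TIFF and long-format CSV.
"""

from __future__ import annotations

import glob as _glob
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from tiptrace.types import ImageSequence

_FLOAT_FMT = "%.6f"


def natural_sort(paths: list[str]) -> list[str]:
    def key(p: str):
        return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", p)]
    return sorted(paths, key=key)


def read_sequence(path, pixel_size: float, dt: float,
                  signal_path=None, time_unit: str = "min") -> ImageSequence:
    """Read a multi-page TIFF or a glob of single-page grayscale images."""
    frames = _read_stack(path)
    signal = _read_stack(signal_path) if signal_path is not None else None
    if signal is not None and signal.shape != frames.shape:
        raise ValueError(f"signal channel shape {signal.shape} != contour channel "
                         f"shape {frames.shape}")
    return ImageSequence(frames=frames, pixel_size=pixel_size, dt=dt,
                         signal=signal, time_unit=time_unit)


def _read_stack(path) -> np.ndarray:
    path = str(path)
    if any(ch in path for ch in "*?["):
        files = natural_sort(_glob.glob(path))
        if not files:
            raise FileNotFoundError(f"no files match pattern {path!r}")
        frames = []
        shape = dtype = None
        for f in files:
            img = _read_one(f)
            if shape is None:
                shape, dtype = img.shape, img.dtype
            elif img.shape != shape:
                raise ValueError(f"frame shape mismatch in file {f!r}: "
                                 f"{img.shape} != {shape}")
            elif img.dtype != dtype:
                raise ValueError(f"mixed dtypes in sequence: file {f!r} has "
                                 f"{img.dtype}, expected {dtype}")
            frames.append(img)
        return np.stack(frames)
    if not Path(path).exists():
        raise FileNotFoundError(f"no such file: {path!r}")
    arr = _read_one(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"cannot interpret {path!r} as a grayscale stack "
                         f"(shape {arr.shape})")
    return arr


def _read_one(path: str) -> np.ndarray:
    try:
        if path.lower().endswith((".tif", ".tiff")):
            return tifffile.imread(path)
        import imageio.v3 as iio
        img = iio.imread(path)
        if img.ndim == 3:
            img = img[..., 0]
        return img
    except Exception as exc:
        raise ValueError(f"unreadable image file {path!r}: {exc}") from exc


def write_sequence(seq: ImageSequence, path, channel: str = "frames") -> None:
    """Write one channel of a sequence as multi-page TIFF (lossless)."""
    data = seq.frames if channel == "frames" else seq.signal
    if data is None:
        raise ValueError(f"sequence has no {channel!r} channel")
    tifffile.imwrite(str(path), np.asarray(data))


def write_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV: RFC-4180, '.' decimal, fixed float format, LF endings."""
    df.to_csv(str(path), index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def contours_table(contours) -> pd.DataFrame:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.frame_index, i, x, y))
    return pd.DataFrame(rows, columns=["frame", "vertex_index", "x", "y"])


def centerlines_table(centerlines) -> pd.DataFrame:
    rows = []
    for c in centerlines:
        s = c.s_um
        for i, (x, y) in enumerate(c.points):
            rows.append((c.frame_index, i, x, y, s[i]))
    return pd.DataFrame(rows, columns=["frame", "s_index", "x", "y", "s_um"])


def tips_table(centerlines) -> pd.DataFrame:
    rows = []
    for c in centerlines:
        rows.append((c.frame_index, *c.tip_point, *c.bottom_point, c.length_um))
    return pd.DataFrame(rows, columns=["frame", "tip_x", "tip_y",
                                       "bottom_x", "bottom_y", "L_um"])


def transforms_table(transforms) -> pd.DataFrame:
    rows = [(t.frame_index if t.frame_index is not None else i, t.u, t.v, t.theta, t.gamma)
            for i, t in enumerate(transforms)]
    return pd.DataFrame(rows, columns=["frame", "u", "v", "theta_deg", "gamma"])


def kymograph_tables(kymo) -> pd.DataFrame:
    """Long-format kymograph; missing cells carried as empty fields (NaN), not 0."""
    s_idx, t_idx = np.meshgrid(np.arange(len(kymo.s_axis)),
                               np.arange(len(kymo.t_axis)), indexing="ij")
    return pd.DataFrame({
        "s_bin": s_idx.ravel(),
        "s_um": kymo.s_axis[s_idx.ravel()],
        "frame": t_idx.ravel(),
        "time": kymo.t_axis[t_idx.ravel()],
        "intensity": kymo.matrix.ravel(),
    })


def write_kymograph_tiff(kymo, path) -> None:
    tifffile.imwrite(str(path), kymo.matrix.astype(np.float32))


def write_ground_truth(gt, path, pixel_size: float) -> None:
    """Ground-truth table for a synthetic movie (frame, tip, bottom, L, jitter)."""
    rows = []
    for t in range(len(gt.lengths_um)):
        rows.append((t, *gt.tips[t], *gt.bottoms[t], gt.lengths_um[t], *gt.transforms[t]))
    df = pd.DataFrame(rows, columns=["frame", "tip_x", "tip_y", "bottom_x",
                                     "bottom_y", "L", "u", "v", "theta"])
    write_csv(df, path)


def write_run_log(log: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
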