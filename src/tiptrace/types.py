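"""Shared container types.

Coordinate convention used throughout: x = column, y = row, origin at the
top-left pixel centre, 0-based. Points are ``(x, y)`` float pairs; image
arrays are indexed ``[row, col]`` i.e. ``[y, x]``. All internal geometry is
in pixels; micrometres appear only at reporting boundaries via
``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSequence:
    """Ordered stack of 2-D grayscale frames with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Contour-channel intensities (the channel that defines the cell shape).
    pixel_size : float
        Micrometres per pixel.
    dt : float
        Time units per frame interval.
    signal : ndarray of shape (T, H, W), optional
        Second (intracellular signal) channel, same geometry as ``frames``.
    """

    frames: np.ndarray
    pixel_size: float
    dt: float
    signal: np.ndarray | None = None
    time_unit: str = "min"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (T, H, W); got shape {self.frames.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.signal is not None:
            self.signal = np.asarray(self.signal)
            if self.signal.shape != self.frames.shape:
                raise ValueError(
                    f"signal channel shape {self.signal.shape} != frames shape {self.frames.shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis: frame_index * dt."""
        return np.arange(self.n_frames) * self.dt


def frame_center(shape: tuple[int, int]) -> np.ndarray:
    """Geometric centre (x, y) of a (rows, cols) frame, in pixel coordinates."""
    rows, cols = shape
    return np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length (px) along an (N, 2) polyline; s[0] = 0."""
    pts = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])
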