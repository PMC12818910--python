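"""Binary segmentation and subpixel contour extraction.

Deep-learning segmentation is deliberately out of scope: the pipeline's
contract starts at binary masks, produced either by a baseline global Otsu
threshold or ingested from an external tool. Each validated mask yields a
single closed counterclockwise contour (iso-level 0.5 of the {0,1} grid),
resampled to uniform arc-length spacing before skeletonization.
"""

from __future__ import annotations

import glob as _glob
import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure
from skimage.filters import threshold_otsu
from statsmodels.nonparametric.smoothers_lowess import lowess

from tiptrace.types import polyline_arclength

logger = logging.getLogger(__name__)

MIN_CONTOUR_POINTS = 16
MIN_MASK_AREA_PX = 10


@dataclass
class BinaryMask:
    """Single-object boolean mask for one frame."""

    grid: np.ndarray
    frame_index: int = 0
    border_warning: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def area(self) -> int:
        return int(self.grid.sum())


@dataclass
class Contour:
    """Closed simple polygon of subpixel boundary points, counterclockwise.

    ``points`` is (N, 2) of (x, y); the closing edge from the last point back
    to the first is implied (the first point is not duplicated).
    """

    points: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be (N, 2)")

    @property
    def signed_area(self) -> float:
        x, y = self.points.T
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(polyline_arclength(closed)[-1])

    def as_polygon(self) -> Polygon:
        return Polygon(self.points)

    def validate(self) -> None:
        if len(self.points) < MIN_CONTOUR_POINTS:
            raise ValueError(f"contour has {len(self.points)} points; need >= {MIN_CONTOUR_POINTS}")
        if self.signed_area <= 0:
            raise ValueError("contour must be counterclockwise (positive signed area)")
        if not self.as_polygon().is_simple:
            raise ValueError("contour is self-intersecting")


def _cleanup(grid: np.ndarray, frame_index: int) -> BinaryMask:
    """Keep the largest connected component and fill holes; validate."""
    labels, n = ndimage.label(grid)
    if n == 0:
        raise ValueError(f"no foreground in mask for frame {frame_index}")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        logger.warning("frame %d: %d components; keeping largest (%d px)",
                       frame_index, n, int(sizes[keep - 1]))
        grid = labels == keep
    else:
        grid = labels == 1
    grid = ndimage.binary_fill_holes(grid)
    border = (grid[0, :].any() or grid[-1, :].any()
              or grid[:, 0].any() or grid[:, -1].any())
    if border:
        logger.warning("frame %d: foreground touches the image border", frame_index)
    return BinaryMask(grid=grid, frame_index=frame_index, border_warning=bool(border))


def binarize_otsu(frame: np.ndarray, polarity: str = "bright_object",
                  frame_index: int = 0) -> BinaryMask:
    """Global Otsu threshold of one frame, keeping the largest object.

    ``polarity`` selects which side of the threshold is foreground:
    ``bright_object`` (fluorescence) or ``dark_object`` (bright field).
    """
    frame = np.asarray(frame, dtype=float)
    if np.unique(frame).size < 2:
        raise ValueError("no threshold separates foreground: constant image")
    if polarity not in ("bright_object", "dark_object"):
        raise ValueError(f"unknown polarity {polarity!r}")
    thr = threshold_otsu(frame)
    grid = frame > thr if polarity == "bright_object" else frame < thr
    return _cleanup(grid, frame_index)


def _natural_key(path: str) -> list:
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", path)]


def load_masks(path_or_pattern, n_frames: int,
               frame_shape: tuple[int, int] | None = None) -> list[BinaryMask]:
    """Load externally generated masks: one multi-page TIFF or a filename glob.

    Values are interpreted as {0, nonzero}; each mask is cleaned up (largest
    component, holes filled) and checked against the expected frame count and
    shape.
    """
    import tifffile

    if isinstance(path_or_pattern, (list, tuple)):
        paths = list(path_or_pattern)
    else:
        paths = sorted(_glob.glob(str(path_or_pattern)), key=_natural_key)
    if len(paths) == 1:
        stack = tifffile.imread(paths[0])
        if stack.ndim == 2:
            stack = stack[None]
        arrays = [(paths[0], stack[i]) for i in range(stack.shape[0])]
    elif len(paths) > 1:
        import imageio.v3 as iio
        arrays = []
        for p in paths:
            img = tifffile.imread(p) if p.lower().endswith((".tif", ".tiff")) else iio.imread(p)
            if img.ndim == 3:
                img = img[..., 0]
            arrays.append((p, img))
    else:
        raise FileNotFoundError(f"no mask files match {path_or_pattern!r}")

    if len(arrays) != n_frames:
        raise ValueError(
            f"frame-count mismatch: {n_frames} frames declared but {len(arrays)} masks "
            f"found at {path_or_pattern!r}")
    masks = []
    for i, (name, arr) in enumerate(arrays):
        if frame_shape is not None and arr.shape != tuple(frame_shape):
            raise ValueError(f"mask shape {arr.shape} != frame shape {tuple(frame_shape)} "
                             f"in file {name!r} (frame {i})")
        if not np.any(arr):
            raise ValueError(f"no foreground in mask file {name!r} (frame {i})")
        masks.append(_cleanup(np.asarray(arr) != 0, i))
    return masks


def extract_contour(mask: BinaryMask, spacing: float = 1.0) -> Contour:
    """Subpixel outer boundary of the mask at iso-level 0.5, counterclockwise.

    The boundary is traced on the {0,1} grid with linear interpolation and
    resampled to uniform arc-length ``spacing`` (px).
    """
    if mask.area < MIN_MASK_AREA_PX:
        raise ValueError(f"degenerate mask (area {mask.area} px < {MIN_MASK_AREA_PX})")
    padded = np.pad(mask.grid.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour found")
    longest = max(contours, key=len)
    pts = np.column_stack([longest[:, 1], longest[:, 0]]) - 1.0  # (row,col)->(x,y), unpad
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    pts = resample_closed(pts, spacing)
    # one circular 3-point average: removes the half-pixel staircase of the
    # binary-grid iso-contour (which inflates perimeter and seeds Voronoi spurs)
    # while displacing true boundary points by well under half a pixel
    pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
    c = Contour(points=pts, frame_index=mask.frame_index)
    if c.signed_area < 0:
        c = Contour(points=pts[::-1], frame_index=mask.frame_index)
    c.validate()
    return c


def resample_closed(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polygon to (approximately) uniform arc-length spacing."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    s = polyline_arclength(closed)
    total = s[-1]
    n = max(int(round(total / spacing)), 8)
    s_new = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(s_new, s, closed[:, 0])
    y = np.interp(s_new, s, closed[:, 1])
    return np.column_stack([x, y])


_MIN_FRAC = 0.02


def smooth_contour(contour: Contour, frac: float = 0.05) -> Contour:
    """Lowess-smooth x(s) and y(s) against cumulative arc length.

    The contour is padded periodically so the closure point is not treated as
    a boundary. If smoothing yields a self-intersecting polygon the fraction
    is halved (with a warning) down to a floor, beyond which an error is
    raised.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    pts = contour.points
    n = len(pts)
    pad = max(int(np.ceil(frac * n)), 3)

    while True:
        ext = np.vstack([pts[-pad:], pts, pts[:pad]])
        s = polyline_arclength(ext)
        frac_ext = min(frac * n / len(ext), 1.0)
        xs = lowess(ext[:, 0], s, frac=frac_ext, it=0, return_sorted=False)
        ys = lowess(ext[:, 1], s, frac=frac_ext, it=0, return_sorted=False)
        sm = np.column_stack([xs, ys])[pad:pad + n]
        cand = Contour(points=sm, frame_index=contour.frame_index)
        if cand.signed_area < 0:
            cand = Contour(points=sm[::-1], frame_index=contour.frame_index)
        try:
            cand.validate()
            return cand
        except ValueError:
            if frac / 2 < _MIN_FRAC:
                raise ValueError(
                    f"smoothing failed down to frac floor {_MIN_FRAC}") from None
            logger.warning("smoothing at frac=%.3g self-intersects; retrying at %.3g",
                           frac, frac / 2)
            frac = frac / 2
            pad = max(int(np.ceil(frac * n)), 3)
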