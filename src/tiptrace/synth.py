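"""Synthetic tip-growing-cell movies with exact ground truth.

Renders a capsule (tube with semicircular caps) elongating along a possibly
curving axis, with optional per-frame rigid jitter, additive Gaussian noise
and a second channel carrying a Gaussian intensity band along the cell axis
(a nucleus / cytoskeletal-band stand-in). Every geometric quantity the
analysis pipeline estimates (tip, bottom, centerline, length, jitter
transform, band position) is recorded analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from tiptrace.types import ImageSequence, frame_center, polyline_arclength

_AXIS_STEP_PX = 0.25  # densification step of the true axis polyline


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of a synthetic growing-cell movie.

    Lengths (`width`, `initial_length`, `growth_rate`, `band_sigma`) are in
    micrometres; jitter and noise are in pixels / degrees / intensity units.
    `growth_rate` may be a scalar (um per time unit) or a per-frame sequence
    of length ``n_frames - 1``.
    """

    n_frames: int = 10
    frame_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.5
    dt: float = 1.0
    width: float = 6.0
    initial_length: float = 20.0
    growth_rate: float | tuple[float, ...] = 0.5
    bend_rate: float = 0.0
    initial_bend: float = 0.0  # total degrees of constant-curvature bend in the frame-0 axis
    jitter_translation_sd: float = 0.0
    jitter_rotation_sd: float = 0.0
    noise_sd: float = 0.0
    band_center_rel: float | None = None
    band_offset_from_tip: float | None = None
    band_sigma: float = 2.0
    band_amplitude: float = 150.0
    foreground: float = 200.0
    background: float = 10.0
    base_point: tuple[float, float] | None = None
    base_angle: float = -90.0  # degrees; -90 grows "up" the frame (toward row 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2 (two frames minimum for kinematics)")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.initial_length <= self.width:
            raise ValueError("initial_length must exceed width (elongated capsule)")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be positive")
        if self.band_center_rel is not None and self.band_offset_from_tip is not None:
            raise ValueError("give band_center_rel or band_offset_from_tip, not both")
        if self.band_center_rel is not None and not (0.0 <= self.band_center_rel <= 1.0):
            raise ValueError("band_center_rel must lie in [0, 1]")

    def growth_per_frame(self) -> np.ndarray:
        """Length increment (um) between frame t-1 and t, for t = 1..n-1."""
        g = self.growth_rate
        if np.isscalar(g):
            return np.full(self.n_frames - 1, float(g) * self.dt)
        g = np.asarray(g, dtype=float)
        if g.shape != (self.n_frames - 1,):
            raise ValueError(
                f"growth_rate sequence must have length n_frames-1={self.n_frames - 1}"
            )
        return g * self.dt

    def lengths_um(self) -> np.ndarray:
        """True bottom-to-tip length L(t), um, per frame."""
        return self.initial_length + np.concatenate([[0.0], np.cumsum(self.growth_per_frame())])


@dataclass
class GroundTruth:
    """Per-frame analytic truth for a generated movie (all geometry post-jitter, px)."""

    tips: np.ndarray            # (T, 2) true tip apex (x, y)
    bottoms: np.ndarray         # (T, 2) true bottom apex (x, y)
    centerlines: list           # per frame (N, 2) polyline bottom -> tip, incl. cap segments
    lengths_um: np.ndarray      # (T,) true L
    transforms: np.ndarray      # (T, 3) applied jitter (u, v, theta_deg), about frame centre
    band_center_um: np.ndarray | None = None  # (T,) band centre along s from bottom
    band_sigma_um: float | None = None
    pre_jitter_centerlines: list = field(default_factory=list)


def _rotation(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def apply_rigid(points: np.ndarray, u: float, v: float, theta_deg: float,
                center: np.ndarray) -> np.ndarray:
    """Rotate (x, y) points by theta about `center`, then translate by (u, v)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - center) @ _rotation(theta_deg).T + center + np.array([u, v])


def _build_axes(spec: SyntheticCellSpec) -> list[np.ndarray]:
    """Per-frame dense pre-jitter axis polylines (px), grown incrementally.

    The already-grown portion of the axis is frozen; new growth extends the
    far end in a direction rotated by ``bend_rate`` degrees each frame.
    """
    rows, cols = spec.frame_shape
    lengths_px = (spec.lengths_um() - spec.width) / spec.pixel_size  # axis (cap-to-cap) length
    if np.any(lengths_px <= 0):
        raise ValueError("cell length minus width must stay positive")
    if spec.base_point is not None:
        base = np.asarray(spec.base_point, dtype=float)
    else:
        # place the base so the fully grown cell plus caps fits comfortably
        base = np.array([(cols - 1) / 2.0, (rows - 1) * 0.78])
    angle = np.deg2rad(spec.base_angle)

    axes: list[np.ndarray] = []
    pts = [base.copy()]
    grown = 0.0
    for t in range(spec.n_frames):
        target = lengths_px[t]
        while grown < target - 1e-9:
            step = min(_AXIS_STEP_PX, target - grown)
            if t == 0 and spec.initial_bend:
                # constant-curvature arc along the initial axis
                frac = grown / lengths_px[0]
                ang = np.deg2rad(spec.base_angle + spec.initial_bend * frac)
            else:
                ang = np.deg2rad(spec.base_angle + spec.initial_bend
                                 + spec.bend_rate * t)
            d = np.array([np.cos(ang), np.sin(ang)])
            pts.append(pts[-1] + d * step)
            grown += step
        axes.append(np.array(pts))
    return axes


def _render_capsule(axis: np.ndarray, spec: SyntheticCellSpec,
                    rng: np.random.Generator | None,
                    band_center_um: float | None) -> tuple[np.ndarray, np.ndarray | None]:
    """Render one frame (and optional band channel) from a post-jitter axis."""
    rows, cols = spec.frame_shape
    half_w = spec.width / (2.0 * spec.pixel_size)

    yy, xx = np.mgrid[0:rows, 0:cols]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(axis)
    dist, idx = tree.query(pix, workers=-1)
    dist = dist.reshape(rows, cols)

    # soft half-pixel edge -> subpixel-consistent iso-contour at mid level
    cover = np.clip(0.5 + (half_w - dist), 0.0, 1.0)
    frame = spec.background + (spec.foreground - spec.background) * cover

    band = None
    if band_center_um is not None:
        s_axis = polyline_arclength(axis)
        # arc length from the *bottom contour apex*: axis coordinate + cap radius
        s_um = (s_axis[idx].reshape(rows, cols) + half_w) * spec.pixel_size
        gauss = np.exp(-((s_um - band_center_um) ** 2) / (2.0 * spec.band_sigma ** 2))
        band = spec.background + spec.band_amplitude * gauss * (cover > 0.5)

    if rng is not None and spec.noise_sd > 0:
        frame = frame + rng.normal(0.0, spec.noise_sd, frame.shape)
        if band is not None:
            band = band + rng.normal(0.0, spec.noise_sd, band.shape)
    return frame, band


def make_growing_cell(spec: SyntheticCellSpec) -> tuple[ImageSequence, GroundTruth]:
    """Generate a synthetic movie and its exact ground truth.

    Raises
    ------
    ValueError
        If the capsule (including its caps) leaves the frame in any frame;
        the message names the offending frame index.
    """
    rows, cols = spec.frame_shape
    center = frame_center((rows, cols))
    half_w_px = spec.width / (2.0 * spec.pixel_size)
    rng = np.random.default_rng(spec.seed)
    jit_rng = np.random.default_rng(rng.integers(2**63))
    noise_rng = np.random.default_rng(rng.integers(2**63))

    axes = _build_axes(spec)
    lengths = spec.lengths_um()
    want_band = spec.band_center_rel is not None or spec.band_offset_from_tip is not None
    band_centers = None
    if want_band:
        if spec.band_center_rel is not None:
            band_centers = spec.band_center_rel * lengths
        else:
            band_centers = lengths - spec.band_offset_from_tip

    frames = np.empty((spec.n_frames, rows, cols), dtype=np.float32)
    signal = np.empty_like(frames) if want_band else None
    tips = np.empty((spec.n_frames, 2))
    bottoms = np.empty((spec.n_frames, 2))
    centerlines: list[np.ndarray] = []
    pre_centerlines: list[np.ndarray] = []
    transforms = np.zeros((spec.n_frames, 3))

    for t in range(spec.n_frames):
        if spec.jitter_translation_sd > 0 or spec.jitter_rotation_sd > 0:
            u, v = jit_rng.normal(0.0, max(spec.jitter_translation_sd, 1e-12), 2)
            th = jit_rng.normal(0.0, max(spec.jitter_rotation_sd, 1e-12))
            if spec.jitter_translation_sd == 0:
                u = v = 0.0
            if spec.jitter_rotation_sd == 0:
                th = 0.0
        else:
            u = v = th = 0.0
        transforms[t] = (u, v, th)

        axis = axes[t]
        jaxis = apply_rigid(axis, u, v, th, center)
        d0 = jaxis[1] - jaxis[0]
        d0 /= np.linalg.norm(d0)
        d1 = jaxis[-1] - jaxis[-2]
        d1 /= np.linalg.norm(d1)
        bottom = jaxis[0] - d0 * half_w_px
        tip = jaxis[-1] + d1 * half_w_px

        lo = np.minimum(bottom, tip)
        hi = np.maximum(bottom, tip)
        pts_lo = jaxis.min(axis=0) - half_w_px
        pts_hi = jaxis.max(axis=0) + half_w_px
        if (min(lo[0], pts_lo[0]) < 1 or min(lo[1], pts_lo[1]) < 1
                or max(hi[0], pts_hi[0]) > cols - 2 or max(hi[1], pts_hi[1]) > rows - 2):
            raise ValueError(f"capsule exceeds frame bounds at frame {t}")

        bc = band_centers[t] if band_centers is not None else None
        frame, band = _render_capsule(jaxis, spec,
                                      noise_rng if spec.noise_sd > 0 else None, bc)
        frames[t] = frame
        if signal is not None:
            signal[t] = band

        tips[t] = tip
        bottoms[t] = bottom
        centerlines.append(np.vstack([bottom, jaxis, tip]))
        pre_axis = np.vstack([axis[0] - (axis[1] - axis[0]) / np.linalg.norm(axis[1] - axis[0]) * half_w_px,
                              axis,
                              axis[-1] + (axis[-1] - axis[-2]) / np.linalg.norm(axis[-1] - axis[-2]) * half_w_px])
        pre_centerlines.append(pre_axis)

    seq = ImageSequence(frames=frames, pixel_size=spec.pixel_size, dt=spec.dt, signal=signal)
    gt = GroundTruth(
        tips=tips,
        bottoms=bottoms,
        centerlines=centerlines,
        lengths_um=lengths,
        transforms=transforms,
        band_center_um=band_centers,
        band_sigma_um=spec.band_sigma if want_band else None,
        pre_jitter_centerlines=pre_centerlines,
    )
    return seq, gt


def make_band_profile(length_px: int, center: float, sigma: float, amplitude: float,
                      baseline: float, noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """1-D Gaussian band profile: baseline + amplitude*exp(-(s-center)^2/(2 sigma^2)) + noise."""
    if not (0 <= center < length_px):
        raise ValueError("center must lie in [0, length_px)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s = np.arange(length_px, dtype=float)
    prof = baseline + amplitude * np.exp(-((s - center) ** 2) / (2.0 * sigma ** 2))
    if noise_sd > 0:
        prof = prof + np.random.default_rng(seed).normal(0.0, noise_sd, length_px)
    return prof
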