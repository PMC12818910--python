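"""Coordinate normalization: rigid alignment by normalized correlation.

Each frame is aligned to a reference by the rigid transform (u, v, theta)
maximizing

    gamma(u, v, theta) = sum (f_ref - mean(f_ref)) (f_T - mean(f_T))
                         / sqrt(sum (f_ref - mean(f_ref))^2 * sum (f_T - mean(f_T))^2)

where f_T is the moving frame rotated by theta about the frame centre and
shifted by (u, v); pixels mapped from outside the original image are set to
0, and the means are spatial means over the full frame. Optimization is an
exhaustive integer grid over (u, v, theta) followed by local half-step
bisection refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from tiptrace.types import ImageSequence, frame_center

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """Rigid alignment: rotate by ``theta`` degrees about the frame centre, then
    translate by ``(u, v)`` px. ``gamma`` is the correlation achieved."""

    u: float = 0.0
    v: float = 0.0
    theta: float = 0.0
    gamma: float = float("nan")
    frame_index: int | None = None

    def is_identity(self, tol: float = 1e-9) -> bool:
        return abs(self.u) < tol and abs(self.v) < tol and abs(self.theta) < tol


def _rot(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``inner`` first, then ``outer``."""
    r = _rot(outer.theta)
    tau = r @ np.array([inner.u, inner.v]) + np.array([outer.u, outer.v])
    return RigidTransform(u=float(tau[0]), v=float(tau[1]),
                          theta=inner.theta + outer.theta)


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform: compose(t, invert(t)) is the identity."""
    r = _rot(-t.theta)
    tau = -(r @ np.array([t.u, t.v]))
    return RigidTransform(u=float(tau[0]), v=float(tau[1]), theta=-t.theta)


def transform_frame(img: np.ndarray, t: RigidTransform, order: int = 1) -> np.ndarray:
    """Warp an image by a rigid transform (bilinear by default, 0 outside)."""
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    cx, cy = frame_center((rows, cols))
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    # inverse map: p = R(-theta) (q - c - tau) + c
    qx = xx - cx - t.u
    qy = yy - cy - t.v
    th = np.deg2rad(-t.theta)
    c, s = np.cos(th), np.sin(th)
    px = c * qx - s * qy + cx
    py = s * qx + c * qy + cy
    return ndimage.map_coordinates(img, [py, px], order=order, cval=0.0,
                                   mode="constant", prefilter=(order > 1))


def transform_points(points: np.ndarray, t: RigidTransform,
                     shape: tuple[int, int]) -> np.ndarray:
    """Apply the same rigid transform to (x, y) points (forward mapping)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    center = frame_center(shape)
    return (pts - center) @ _rot(t.theta).T + center + np.array([t.u, t.v])


def normalized_correlation(ref: np.ndarray, moving: np.ndarray,
                           t: RigidTransform | None = None) -> float:
    """Pearson-type correlation between ``ref`` and the transformed ``moving``."""
    ref = np.asarray(ref, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if ref.shape != moving.shape:
        raise ValueError("frames must have the same shape")
    warped = moving if t is None or t.is_identity() else transform_frame(moving, t)
    a = ref - ref.mean()
    b = warped - warped.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("zero variance: constant frame")
    return float((a * b).sum() / denom)


@dataclass(frozen=True)
class SearchSpec:
    """Grid-search ranges (inclusive) and steps for the rigid registration."""

    u_range: tuple[float, float] = (-15.0, 15.0)
    v_range: tuple[float, float] = (-15.0, 15.0)
    theta_range: tuple[float, float] = (-15.0, 15.0)
    u_step: float = 1.0
    v_step: float = 1.0
    theta_step: float = 1.0
    refine_levels: int = 3
    gamma_floor: float = 0.5

    def grid(self, lo_hi: tuple[float, float], step: float) -> np.ndarray:
        lo, hi = lo_hi
        n = int(round((hi - lo) / step))
        return lo + step * np.arange(n + 1)


def _gamma_integer_shifts(ref: np.ndarray, rot: np.ndarray,
                          us: np.ndarray, vs: np.ndarray) -> np.ndarray:
    """gamma for all integer shifts (u, v) of ``rot``, zero-filled outside.

    Exploits that a pure integer shift needs no interpolation: sums over the
    full frame reduce to sums over the overlap window.
    """
    rows, cols = ref.shape
    n = rows * cols
    fbar = ref.mean()
    varf = ((ref - fbar) ** 2).sum()
    out = np.full((len(vs), len(us)), -np.inf)
    for i, v in enumerate(vs):
        v = int(v)
        r0, r1 = max(0, v), rows + min(0, v)
        if r1 <= r0:
            continue
        for j, u in enumerate(us):
            u = int(u)
            c0, c1 = max(0, u), cols + min(0, u)
            if c1 <= c0:
                continue
            g = rot[r0 - v:r1 - v, c0 - u:c1 - u]
            f = ref[r0:r1, c0:c1]
            sg = g.sum()
            varg = (g * g).sum() - sg * sg / n
            if varg <= 0:
                continue
            num = (f * g).sum() - fbar * sg
            out[i, j] = num / np.sqrt(varf * varg)
    return out


def register_frame(ref: np.ndarray, moving: np.ndarray,
                   search: SearchSpec | None = None,
                   frame_index: int | None = None) -> RigidTransform:
    """Find the rigid transform maximizing gamma.

    Coarse exhaustive grid over (u, v, theta) — with the translation layer
    evaluated exactly for integer shifts — then 3 levels of half-step
    bisection refinement around the best grid point.
    """
    if search is None:
        search = SearchSpec()
    ref = np.asarray(ref, dtype=float)
    moving = np.asarray(moving, dtype=float)
    us = search.grid(search.u_range, search.u_step)
    vs = search.grid(search.v_range, search.v_step)
    thetas = search.grid(search.theta_range, search.theta_step)

    integer_shifts = (float(search.u_step).is_integer() and float(search.v_step).is_integer()
                      and all(float(x).is_integer() for x in (*search.u_range, *search.v_range)))
    best = (-np.inf, 0.0, 0.0, 0.0)
    for th in thetas:
        rot = transform_frame(moving, RigidTransform(theta=float(th))) if th else moving
        if integer_shifts:
            g = _gamma_integer_shifts(ref, rot, us, vs)
            i, j = np.unravel_index(np.argmax(g), g.shape)
            if g[i, j] > best[0]:
                best = (float(g[i, j]), float(us[j]), float(vs[i]), float(th))
        else:
            for v in vs:
                for u in us:
                    gam = normalized_correlation(ref, rot, RigidTransform(u=u, v=v))
                    if gam > best[0]:
                        best = (gam, float(u), float(v), float(th))

    gbest, ubest, vbest, thbest = best
    step_u, step_v, step_th = search.u_step, search.v_step, search.theta_step
    for _ in range(search.refine_levels):
        step_u, step_v, step_th = step_u / 2, step_v / 2, step_th / 2
        for du in (-step_u, 0.0, step_u):
            for dv in (-step_v, 0.0, step_v):
                for dth in (-step_th, 0.0, step_th):
                    if du == dv == dth == 0.0:
                        continue
                    t = RigidTransform(u=ubest + du, v=vbest + dv, theta=thbest + dth)
                    gam = normalized_correlation(ref, moving, t)
                    if gam > gbest:
                        gbest, ubest, vbest, thbest = gam, t.u, t.v, t.theta

    if gbest < search.gamma_floor:
        logger.warning("poor alignment: best gamma %.3f below floor %.3f",
                       gbest, search.gamma_floor)
    return RigidTransform(u=ubest, v=vbest, theta=thbest, gamma=gbest,
                          frame_index=frame_index)


def normalize_sequence(seq: ImageSequence, reference_index: int = 0,
                       search: SearchSpec | None = None,
                       strategy: str = "successive",
                       use_mask: bool = False,
                       ) -> tuple[ImageSequence, list[RigidTransform]]:
    """Align every frame of a sequence to the reference frame.

    ``strategy='successive'`` registers each frame to its temporal neighbour
    toward the reference and composes the transforms (robust under growth);
    ``'direct'`` registers each frame straight to the reference. The same
    per-frame transform is applied to all channels. ``use_mask`` drives the
    registration with Otsu-binarized frames instead of raw intensities.
    """
    if not (0 <= reference_index < seq.n_frames):
        raise ValueError(f"reference_index {reference_index} out of range")
    if strategy not in ("successive", "direct"):
        raise ValueError(f"unknown strategy {strategy!r}")

    if use_mask:
        from tiptrace.segmentation import binarize_otsu
        driver = np.stack([binarize_otsu(f, frame_index=i).grid.astype(float)
                           for i, f in enumerate(seq.frames)])
    else:
        driver = seq.frames.astype(float)

    n = seq.n_frames
    transforms: list[RigidTransform | None] = [None] * n
    transforms[reference_index] = RigidTransform(gamma=1.0, frame_index=reference_index)

    order = list(range(reference_index + 1, n)) + list(range(reference_index - 1, -1, -1))
    for t_idx in order:
        neighbor = t_idx - 1 if t_idx > reference_index else t_idx + 1
        if strategy == "successive":
            pair = register_frame(driver[neighbor], driver[t_idx], search=search,
                                  frame_index=t_idx)
            cum = compose(transforms[neighbor], pair)
            cum = replace(cum, gamma=pair.gamma, frame_index=t_idx)
        else:
            cum = register_frame(driver[reference_index], driver[t_idx], search=search,
                                 frame_index=t_idx)
        transforms[t_idx] = cum

    aligned = np.stack([
        seq.frames[i] if transforms[i].is_identity()
        else transform_frame(seq.frames[i], transforms[i])
        for i in range(n)
    ]).astype(seq.frames.dtype if np.issubdtype(seq.frames.dtype, np.floating) else np.float32)
    aligned_signal = None
    if seq.signal is not None:
        aligned_signal = np.stack([
            seq.signal[i] if transforms[i].is_identity()
            else transform_frame(seq.signal[i], transforms[i])
            for i in range(n)
        ]).astype(aligned.dtype)
    out = ImageSequence(frames=aligned, pixel_size=seq.pixel_size, dt=seq.dt,
                        signal=aligned_signal, time_unit=seq.time_unit)
    return out, [t for t in transforms]
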