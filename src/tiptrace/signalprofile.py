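"""Intracellular signal quantification in the cell coordinate system.

Profiles are mean (or max) intensities across the cell cross-section,
sampled along normals to the centerline; kymographs stack per-frame profiles
on a common arc-length grid; the band (nucleus / cytoskeletal band) is
localized by least-squares fitting of baseline + Gaussian restricted to a
truncation window, with band "ends" reported as mu +/- k*sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from shapely import contains_xy

from tiptrace.centerline import Centerline
from tiptrace.segmentation import Contour
from tiptrace.types import ImageSequence


class NoBandError(ValueError):
    """Raised when no Gaussian band can be fitted to a profile."""


@dataclass
class AxialProfile:
    """Intensity along the centerline: s (um, from bottom) vs mean cross-section intensity."""

    s: np.ndarray
    intensity: np.ndarray
    frame_index: int = 0
    sampling_halfwidth: float = 0.0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.shape != self.intensity.shape:
            raise ValueError("s and intensity must have equal length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")

    @property
    def L(self) -> float:
        return float(self.s[-1])


@dataclass
class Kymograph:
    """rows = arc-length bins, cols = frames; missing cells (beyond L(t)) are NaN."""

    matrix: np.ndarray
    s_axis: np.ndarray
    t_axis: np.ndarray
    anchor: str = "bottom"

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class BandFit:
    """Gaussian band fit: I(s) ~ B + A exp(-(s-mu)^2 / (2 sigma^2)) over a window."""

    amplitude: float
    mu: float
    sigma: float
    baseline: float
    window: tuple[float, float]
    residual_rms: float
    end_multiplier: float = 1.0

    @property
    def lower(self) -> float:
        return self.mu - self.end_multiplier * self.sigma

    @property
    def upper(self) -> float:
        return self.mu + self.end_multiplier * self.sigma


def _resample_centerline(cl: Centerline, step_um: float) -> tuple[np.ndarray, np.ndarray]:
    """(s_um grid, (N, 2) px points) at uniform arc-length spacing ``step_um``."""
    s = cl.s_um
    if s[-1] < 2 * step_um:
        raise ValueError("centerline shorter than two steps")
    n = int(np.floor(s[-1] / step_um)) + 1
    s_new = np.minimum(np.arange(n) * step_um, s[-1])
    if s_new[-1] < s[-1]:
        s_new = np.append(s_new, s[-1])
    x = np.interp(s_new, s, cl.points[:, 0])
    y = np.interp(s_new, s, cl.points[:, 1])
    return s_new, np.column_stack([x, y])


def profile_along_centerline(frame: np.ndarray, cl: Centerline,
                             halfwidth: float, step: float,
                             contour: Contour | None = None,
                             stat: str = "mean",
                             frame_index: int = 0) -> AxialProfile:
    """Sample the image along normals to the centerline.

    At each arc-length position (spacing ``step`` um) intensities are sampled
    over [-halfwidth, +halfwidth] um along the local normal with bilinear
    interpolation; samples falling outside the contour (when given) are
    excluded; the mean (or max, ``stat='max'``) of the rest is recorded.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    frame = np.asarray(frame, dtype=float)
    s_um, pts = _resample_centerline(cl, step)
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    hw_px = halfwidth / cl.pixel_size
    n_off = max(int(np.ceil(2 * hw_px / 0.5)) + 1, 3)
    offsets = np.linspace(-hw_px, hw_px, n_off)
    sample_xy = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    vals = ndimage.map_coordinates(frame, [sample_xy[..., 1].ravel(),
                                           sample_xy[..., 0].ravel()],
                                   order=1, cval=np.nan, mode="constant")
    vals = vals.reshape(len(pts), n_off)
    if contour is not None:
        inside = contains_xy(contour.as_polygon(),
                             sample_xy[..., 0].ravel(), sample_xy[..., 1].ravel())
        vals[~inside.reshape(len(pts), n_off)] = np.nan

    valid = np.isfinite(vals)
    any_valid = valid.any(axis=1)
    intensity = np.zeros(len(pts))
    if stat == "mean":
        sums = np.where(valid, vals, 0.0).sum(axis=1)
        intensity[any_valid] = sums[any_valid] / valid.sum(axis=1)[any_valid]
    else:
        intensity[any_valid] = np.max(np.where(valid, vals, -np.inf),
                                      axis=1)[any_valid]
    return AxialProfile(s=s_um, intensity=intensity, frame_index=frame_index,
                        sampling_halfwidth=halfwidth)


def build_kymograph(profiles: list[AxialProfile], dt: float,
                    anchor: str = "bottom", step: float | None = None) -> Kymograph:
    """Stack per-frame axial profiles on a common arc-length grid.

    ``anchor='bottom'``: s measured from the cell bottom; ``'tip'``: s
    measured back from the tip. Grid extent is the maximum L over frames;
    bins beyond a frame's own L are NaN, never 0.
    """
    if anchor not in ("bottom", "tip"):
        raise ValueError("anchor must be 'bottom' or 'tip'")
    if not profiles:
        raise ValueError("no profiles")
    if step is None:
        step = float(np.median([np.median(np.diff(p.s)) for p in profiles]))
    L_max = max(p.L for p in profiles)
    s_axis = np.arange(0.0, L_max + step / 2, step)
    mat = np.full((len(s_axis), len(profiles)), np.nan)
    for j, p in enumerate(profiles):
        s = p.s if anchor == "bottom" else p.L - p.s[::-1]
        I = p.intensity if anchor == "bottom" else p.intensity[::-1]
        valid = s_axis <= p.L + 1e-9
        mat[valid, j] = np.interp(s_axis[valid], s, I)
    t_axis = np.arange(len(profiles)) * dt
    return Kymograph(matrix=mat, s_axis=s_axis, t_axis=t_axis, anchor=anchor)


def _gauss(s, A, mu, sigma, B):
    return B + A * np.exp(-((s - mu) ** 2) / (2.0 * sigma ** 2))


def fit_truncated_gaussian(profile: AxialProfile,
                           window: tuple[float, float] | None = None,
                           end_multiplier: float = 1.0,
                           max_iter: int = 2000) -> BandFit:
    """Least-squares Gaussian + baseline fit restricted to a truncation window.

    Auto window: [argmax - 3*sigma0, argmax + 3*sigma0] clipped to [0, L],
    with sigma0 from the full width at half maximum. Initialization:
    B = window minimum, A = max - min, mu = argmax,
    sigma = (FWHM / 2) / sqrt(2 ln 2).
    """
    s_all, I_all = profile.s, profile.intensity
    span_all = s_all[-1] - s_all[0]
    rng_I = I_all.max() - I_all.min()
    if rng_I <= 0 or not np.isfinite(rng_I):
        raise NoBandError("no band detected: flat profile")

    def fwhm_sigma(s, I):
        peak = np.argmax(I)
        half = I.min() + 0.5 * (I[peak] - I.min())
        above = I >= half
        idx = np.flatnonzero(above)
        lo = s[idx[0]] if idx.size else s[0]
        hi = s[idx[-1]] if idx.size else s[-1]
        width = max(hi - lo, np.median(np.diff(s)))
        return (width / 2.0) / np.sqrt(2.0 * np.log(2.0))

    if window is None:
        sig0_est = fwhm_sigma(s_all, I_all)
        mu0 = s_all[np.argmax(I_all)]
        window = (max(mu0 - 3 * sig0_est, s_all[0]), min(mu0 + 3 * sig0_est, s_all[-1]))
    sel = (s_all >= window[0]) & (s_all <= window[1])
    if sel.sum() < 8:
        raise NoBandError(f"no band detected: window holds {int(sel.sum())} samples (< 8)")
    s, I = s_all[sel], I_all[sel]
    if I.max() - I.min() <= 0:
        raise NoBandError("no band detected: flat profile in window")

    B0, A0 = float(I.min()), float(I.max() - I.min())
    mu0 = float(s[np.argmax(I)])
    sig0 = float(fwhm_sigma(s, I))
    span = window[1] - window[0]
    try:
        popt, _ = curve_fit(
            _gauss, s, I, p0=[A0, mu0, sig0, B0],
            bounds=([0.0, window[0], 1e-6, -np.inf],
                    [np.inf, window[1], 10 * max(span, span_all), np.inf]),
            maxfev=max_iter)
    except RuntimeError as exc:
        raise NoBandError(f"no band detected: fit did not converge ({exc})") from None
    A, mu, sigma, B = (float(v) for v in popt)
    if sigma > span:
        raise NoBandError(f"no band detected: fitted sigma {sigma:.3g} exceeds "
                          f"window span {span:.3g}")
    rms = float(np.sqrt(np.mean((I - _gauss(s, *popt)) ** 2)))
    return BandFit(amplitude=A, mu=mu, sigma=sigma, baseline=B,
                   window=(float(window[0]), float(window[1])),
                   residual_rms=rms, end_multiplier=end_multiplier)


def track_band(profiles: list[AxialProfile], dt: float = 1.0,
               end_multiplier: float = 1.0) -> pd.DataFrame:
    """Fit the band frame by frame, seeding each window from the previous fit.

    Frames that fail to fit get NaN rows; raises only if every frame fails.
    Columns: frame, time, mu, sigma, lower, upper, A, B, rms, L.
    """
    rows = []
    prev: BandFit | None = None
    n_ok = 0
    for j, p in enumerate(profiles):
        window = None
        if prev is not None:
            window = (max(prev.mu - 4 * prev.sigma, 0.0),
                      min(prev.mu + 4 * prev.sigma, p.L))
        try:
            fit = fit_truncated_gaussian(p, window=window, end_multiplier=end_multiplier)
        except NoBandError:
            if window is not None:
                try:
                    fit = fit_truncated_gaussian(p, window=None,
                                                 end_multiplier=end_multiplier)
                except NoBandError:
                    fit = None
            else:
                fit = None
        if fit is None:
            rows.append(dict(frame=j, time=j * dt, mu=np.nan, sigma=np.nan,
                             lower=np.nan, upper=np.nan, A=np.nan, B=np.nan,
                             rms=np.nan, L=p.L))
        else:
            n_ok += 1
            prev = fit
            rows.append(dict(frame=j, time=j * dt, mu=fit.mu, sigma=fit.sigma,
                             lower=fit.lower, upper=fit.upper, A=fit.amplitude,
                             B=fit.baseline, rms=fit.residual_rms, L=p.L))
    if n_ok == 0:
        raise NoBandError("no band detected in any frame")
    return pd.DataFrame(rows)
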