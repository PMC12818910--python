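"""Tip kinematics: velocity dL/dt and direction delta-theta time series.

Velocity is the forward difference of the centerline arc length L (not the
Euclidean tip displacement). Direction is the signed angle of the
frame-to-frame tip displacement relative to a reference axis, computed in
mathematical orientation (y flipped so counterclockwise on a screen-up
display is positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tiptrace.centerline import Centerline
from tiptrace.register import RigidTransform, transform_points


@dataclass
class TipTrace:
    """Tidy per-frame kinematics table.

    Columns: frame, time, tip_x, tip_y, bottom_x, bottom_y, L_um, dLdt,
    delta_theta_deg, zero_disp_flag. dLdt and delta_theta_deg are NaN at
    frame 0 (undefined).
    """

    table: pd.DataFrame
    dt: float
    pixel_size: float
    reference_axis: np.ndarray
    time_unit: str = "min"

    @property
    def L(self) -> np.ndarray:
        return self.table["L_um"].to_numpy()

    @property
    def dLdt(self) -> np.ndarray:
        return self.table["dLdt"].to_numpy()

    @property
    def delta_theta(self) -> np.ndarray:
        return self.table["delta_theta_deg"].to_numpy()


def tip_velocity(L_series: np.ndarray, dt: float, smooth_window: int | None = None
                 ) -> np.ndarray:
    """Forward-difference velocity: (L[t] - L[t-1]) / dt at frame t; NaN at frame 0."""
    L = np.asarray(L_series, dtype=float)
    if L.size < 2:
        raise ValueError("at least two frames are required")
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = np.empty_like(L)
    v[0] = np.nan
    v[1:] = np.diff(L) / dt
    if smooth_window and smooth_window > 1:
        sm = pd.Series(v).rolling(smooth_window, min_periods=1, center=True).mean()
        v = np.concatenate([[np.nan], sm.to_numpy()[1:]])
    return v


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-180, 180]."""
    return -(-(np.asarray(a) - 180.0) % 360.0) + 180.0


def velocity_direction(tip_series: np.ndarray, reference_axis: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Signed angle (degrees) of per-frame tip displacement vs a reference axis.

    Angles are measured after flipping y to mathematical orientation, so
    positive means counterclockwise on a screen-up display. Zero displacement
    carries the previous frame's angle forward and raises the flag.

    Returns
    -------
    delta_theta : ndarray
        Degrees in (-180, 180]; NaN at frame 0.
    zero_flag : ndarray of bool
        True where the displacement was exactly zero (value carried forward).
    """
    tips = np.asarray(tip_series, dtype=float)
    if tips.ndim != 2 or tips.shape[0] < 2:
        raise ValueError("need at least two tip points")
    ref = np.asarray(reference_axis, dtype=float)
    nrm = np.linalg.norm(ref)
    if nrm == 0:
        raise ValueError("reference_axis must be nonzero")
    ref = ref / nrm
    ref_angle = np.arctan2(-ref[1], ref[0])  # y flipped: math orientation

    n = tips.shape[0]
    dtheta = np.full(n, np.nan)
    zero = np.zeros(n, dtype=bool)
    for t in range(1, n):
        d = tips[t] - tips[t - 1]
        if np.allclose(d, 0.0):
            zero[t] = True
            dtheta[t] = dtheta[t - 1] if t > 1 else np.nan
            continue
        ang = np.arctan2(-d[1], d[0]) - ref_angle
        dtheta[t] = _wrap_deg(np.rad2deg(ang))
    return dtheta, zero


def build_tip_trace(centerlines: list[Centerline],
                    transforms: list[RigidTransform] | None = None,
                    dt: float = 1.0, pixel_size: float = 1.0,
                    reference_axis: np.ndarray | None = None,
                    frame_shape: tuple[int, int] | None = None,
                    time_unit: str = "min") -> TipTrace:
    """Compose per-frame centerlines (optionally mapped through rigid
    transforms into the normalized frame) into a TipTrace.

    ``reference_axis`` defaults to the bottom-to-tip direction of the first
    frame's centerline, so delta-theta ~ 0 means growth straight along the
    initial axis.
    """
    n = len(centerlines)
    if n < 2:
        raise ValueError("at least two frames are required")
    if transforms is not None and len(transforms) != n:
        raise ValueError(f"frame-count mismatch: {n} centerlines vs "
                         f"{len(transforms)} transforms")

    tips = np.array([c.tip_point for c in centerlines])
    bottoms = np.array([c.bottom_point for c in centerlines])
    if transforms is not None:
        if frame_shape is None:
            raise ValueError("frame_shape required to apply transforms")
        for i, t in enumerate(transforms):
            if t is None or t.is_identity():
                continue
            tips[i] = transform_points(tips[i], t, frame_shape)[0]
            bottoms[i] = transform_points(bottoms[i], t, frame_shape)[0]

    L = np.array([c.length_um for c in centerlines])
    if np.any(L <= 0):
        raise ValueError("cell length must stay positive")
    if reference_axis is None:
        reference_axis = tips[0] - bottoms[0]
    dLdt = tip_velocity(L, dt)
    dtheta, zero = velocity_direction(tips, reference_axis)

    table = pd.DataFrame({
        "frame": np.arange(n),
        "time": np.arange(n) * dt,
        "tip_x": tips[:, 0],
        "tip_y": tips[:, 1],
        "bottom_x": bottoms[:, 0],
        "bottom_y": bottoms[:, 1],
        "L_um": L,
        "dLdt": dLdt,
        "delta_theta_deg": dtheta,
        "zero_disp_flag": zero,
    })
    return TipTrace(table=table, dt=dt, pixel_size=pixel_size,
                    reference_axis=np.asarray(reference_axis, dtype=float),
                    time_unit=time_unit)
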