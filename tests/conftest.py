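import numpy as np
import pytest

from tiptrace import SyntheticCellSpec, make_growing_cell


@pytest.fixture(scope="session")
def capsule_factory():
    """Factory for small synthetic movies; results cached per parameter set."""
    cache = {}

    def make(**kwargs):
        key = tuple(sorted(kwargs.items()))
        if key not in cache:
            spec = SyntheticCellSpec(**kwargs)
            cache[key] = (spec, *make_growing_cell(spec))
        return cache[key]

    return make


@pytest.fixture(scope="session")
def basic_movie(capsule_factory):
    """6-frame straight capsule, growth 0.8 um per frame, no jitter/noise."""
    return capsule_factory(n_frames=6, width=6.0, initial_length=22.0,
                           growth_rate=0.8, seed=11, frame_shape=(128, 128))


def shoelace_area(points: np.ndarray) -> float:
    """Independent polygon-area oracle."""
    x, y = np.asarray(points, dtype=float).T
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def discrete_curvature(points: np.ndarray, closed: bool = True) -> np.ndarray:
    """Independent curvature oracle: turning angle / mean adjacent segment length."""
    pts = np.asarray(points, dtype=float)
    if closed:
        prv = np.roll(pts, 1, axis=0)
        nxt = np.roll(pts, -1, axis=0)
    else:
        prv, nxt = pts[:-2], pts[2:]
        pts = pts[1:-1]
    v1 = pts - prv
    v2 = nxt - pts
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    ang = np.arctan2(cross, np.einsum("ij,ij->i", v1, v2))
    seg = 0.5 * (np.hypot(*v1.T) + np.hypot(*v2.T))
    return np.abs(ang) / np.maximum(seg, 1e-12)
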