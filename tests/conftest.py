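import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def brute_force_mec(points: np.ndarray) -> tuple[np.ndarray, float]:
    """O(n^4) minimum enclosing circle: try every pair and triple.

    Independent oracle for the incremental construction; usable only at
    tiny n.
    """
    pts = np.asarray(points, dtype=float)
    best = None
    for i, j in itertools.combinations(range(len(pts)), 2):
        c = (pts[i] + pts[j]) / 2.0
        r = float(np.hypot(*(pts[i] - c)))
        if np.all(np.hypot(*(pts - c).T) <= r + 1e-9):
            if best is None or r < best[1]:
                best = (c, r)
    for i, j, k in itertools.combinations(range(len(pts)), 3):
        (ax, ay), (bx, by), (cx, cy) = pts[i], pts[j], pts[k]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
              + (cx ** 2 + cy ** 2) * (ay - by)) / d
        uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
              + (cx ** 2 + cy ** 2) * (bx - ax)) / d
        c = np.array([ux, uy])
        r = float(np.hypot(*(pts[i] - c)))
        if np.all(np.hypot(*(pts - c).T) <= r + 1e-9):
            if best is None or r < best[1]:
                best = (c, r)
    if best is None:  # all points identical
        best = (pts[0], 0.0)
    return best


def rasterize_curve(pts: np.ndarray) -> np.ndarray:
    """Densely sampled curve -> deduplicated 8-connected pixel chain."""
    ix = np.round(pts[:, 0]).astype(int)
    iy = np.round(pts[:, 1]).astype(int)
    out = [(ix[0], iy[0])]
    for x, y in zip(ix, iy):
        if (x, y) != out[-1]:
            out.append((x, y))
    return np.array(out, dtype=float)


@pytest.fixture
def pixel_chain():
    return rasterize_curve


@pytest.fixture
def mec_oracle():
    return brute_force_mec
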