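import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_convex_polygon(rng, n_points=12, scale=50.0):
    """Convex hull of random points — shared helper for Feret tests."""
    from scipy.spatial import ConvexHull

    pts = rng.uniform(0, scale, (n_points, 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def brute_force_min_feret(polygon, step_deg=0.01):
    """Orientation-scan oracle for the minimum caliper width."""
    pts = np.asarray(polygon, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = pts @ dirs.T  # (n_points, n_angles)
    return float((proj.max(axis=0) - proj.min(axis=0)).min())
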