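"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: the
polar-profile oracle densely resamples the boundary and interpolates
radius against angle (no ray-segment solve); the raster overlap oracle
counts grid points with matplotlib's point-in-path test (no shapely
clipping).
"""

from __future__ import annotations

import numpy as np
import pytest

from onh360.roi_io import Eye, Outline, Structure


def circle_polygon(center, radius, n=720, start=0.0):
    """Regular n-gon approximating a circle, clock-angle parametrized."""
    theta = np.radians(start + np.arange(n) * (360.0 / n))
    return np.column_stack(
        [center[0] + radius * np.sin(theta), center[1] - radius * np.cos(theta)]
    )


def star_polygon(rng, n_vertices=24, base=1.0, amp=0.35, center=(0.0, 0.0)):
    """Random star-shaped polygon about `center` (radius ~ base)."""
    # jittered regular angles keep edges well conditioned
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False) + rng.uniform(
        -np.pi / n_vertices * 0.8, np.pi / n_vertices * 0.8, n_vertices
    )
    r = base * (1 + rng.uniform(-amp, amp, n_vertices))
    return np.column_stack(
        [center[0] + r * np.sin(theta), center[1] - r * np.cos(theta)]
    )


def resampling_oracle_radii(ring, origin, step_deg=0.005):
    """Per-degree boundary distance via dense boundary resampling.

    Subdivides every edge finely, computes each sample's clock angle and
    distance from the origin, and linearly interpolates distance against
    angle at the 360 integer degrees.  Independent of the ray-segment
    intersection used by the implementation.
    """
    ring = np.asarray(ring, dtype=float)
    a = ring
    b = np.roll(ring, -1, axis=0)
    pts = []
    for p, q in zip(a, b):
        # subdivision count from the subtended angle at the origin
        ang_p = np.degrees(np.arctan2(p[0] - origin[0], -(p[1] - origin[1]))) % 360
        ang_q = np.degrees(np.arctan2(q[0] - origin[0], -(q[1] - origin[1]))) % 360
        span = abs((ang_q - ang_p + 180) % 360 - 180)
        k = max(8, int(np.ceil(span / step_deg)))
        t = np.linspace(0.0, 1.0, k, endpoint=False)
        pts.append(p[None, :] + t[:, None] * (q - p)[None, :])
    pts = np.vstack(pts)
    d = pts - np.asarray(origin, dtype=float)
    ang = np.degrees(np.arctan2(d[:, 0], -d[:, 1])) % 360.0
    rad = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(ang, kind="stable")
    ang_s, rad_s = ang[order], rad[order]
    # pad for circular interpolation
    ang_pad = np.concatenate([[ang_s[-1] - 360.0], ang_s, [ang_s[0] + 360.0]])
    rad_pad = np.concatenate([[rad_s[-1]], rad_s, [rad_s[0]]])
    return np.interp(np.arange(360, dtype=float), ang_pad, rad_pad)


def raster_overlap_oracle(poly_a, poly_b, step=0.005):
    """Intersection area by grid-point counting (matplotlib path test)."""
    from matplotlib.path import Path

    pa, pb = Path(poly_a), Path(poly_b)
    lo = np.minimum(poly_a.min(axis=0), poly_b.min(axis=0)) - step
    hi = np.maximum(poly_a.max(axis=0), poly_b.max(axis=0)) + step
    xs = np.arange(lo[0] + step / 2, hi[0], step)
    ys = np.arange(lo[1] + step / 2, hi[1], step)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    inside = pa.contains_points(grid) & pb.contains_points(grid)
    return inside.sum() * step * step


def make_outline(vertices, image_id="img1", eye=Eye.OD, structure=Structure.DISC,
                 grader="g1"):
    return Outline(image_id=image_id, eye=eye, structure=structure,
                   grader_id=grader, vertices=np.asarray(vertices, dtype=float))


def square(cx, cy, half):
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half],
         [cx + half, cy + half], [cx - half, cy + half]]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-eye synthetic cohort shared across cohort-level tests."""
    from onh360.synthetic import generate_cohort

    return generate_cohort(24, seed=11)
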