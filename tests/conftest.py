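import numpy as np
import pytest
from hypothesis import settings

import rootposture as rp

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def straight_trace():
    """Straight vertical 2 cm root, 5 points, base at origin, growing down."""
    pts = np.column_stack([np.zeros(5), -np.linspace(0.0, 2.0, 5)])
    return rp.RootTrace("straight", pts)


@pytest.fixture
def circle_trace():
    """Three-quarter circle of radius 0.1 cm, 150 digitized points."""
    theta = np.linspace(0.0, 1.5 * np.pi, 150)
    pts = np.column_stack([0.1 * np.cos(theta), 0.1 * np.sin(theta)])
    return rp.RootTrace("circle", pts)


def circle_arc_trace(radius, frac=0.75, n=150, root_id="arc"):
    theta = np.linspace(0.0, frac * 2.0 * np.pi, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    return rp.RootTrace(root_id, pts)


def uniform_centerline(points, root_id="manual"):
    """Build a ResampledCenterline directly from given points."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    density = 1.0 / seg.mean()
    return rp.ResampledCenterline(
        points=pts,
        arc_pos=arc,
        density=density,
        total_length_L=float(arc[-1]),
        root_id=root_id,
    )
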