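import numpy as np
import pytest

from barnestrat import ArenaSpec
from barnestrat.trajectory_io import Trajectory


@pytest.fixture
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture
def toy_arena() -> ArenaSpec:
    """Tiny 4-hole arena whose 2x2 coverage grid is enumerable by hand."""
    return ArenaSpec(
        arena_radius=2.0,
        hole_ring_radius=1.5,
        n_holes=4,
        hole_radius=0.2,
        visit_radius=0.5,
        target_hole=0,
    )


def make_traj(points, dt: float = 1.0, t0: float = 0.0) -> Trajectory:
    """Trajectory through the given (x, y) waypoints, one per dt."""
    pts = np.asarray(points, dtype=float)
    t = t0 + dt * np.arange(len(pts))
    return Trajectory(t, pts[:, 0], pts[:, 1])


@pytest.fixture
def traj_factory():
    return make_traj
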