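"""Shared fixtures: tiny hand-built trajectories and synthetic systems."""

import numpy as np
import pytest

from poreflux.permeation import PoreGeometry
from poreflux.trajio import AtomMeta, Selection, Trajectory


def make_trajectory(coords, box, atoms=None, dt=0.1):
    """Wrap a (frames, atoms, 3) array into a Trajectory of SOL/OW waters."""
    coords = np.asarray(coords, dtype=float)
    if atoms is None:
        atoms = [
            AtomMeta(name="OW", residue_name="SOL", residue_id=i + 1)
            for i in range(coords.shape[1])
        ]
    return Trajectory(
        coordinates=coords,
        box=np.asarray(box, dtype=float),
        times=np.arange(coords.shape[0]) * dt,
        atoms=atoms,
    )


def all_atoms(trajectory) -> Selection:
    return Selection(label="all", indices=np.arange(trajectory.n_atoms))


def build_crossing_fixture():
    """Hand-built 3-particle, 50-frame trajectory with planted crossings.

    Box 20×20×60 Å, pore: center (10, 10), radius 3, z in [15, 45].
    Planted attempts (hand-executed state machine):

    - particle 0: full +z transit (exit frame 6), then full −z transit
      (exit frame 12) → 2 events;
    - particle 1: full +z transit (exit frame 6), then a periodic z-wrap
      in the reservoir (frame 8→9) and two oscillations across the lower
      face only → 1 event;
    - particle 2: enters from the top, exits radially mid-pore at frame
      4 (x: 10→14, r = 4 > 3), re-enters laterally, leaves through the
      bottom → 0 events (radial exit resets the attempt).

    Expected: exactly 3 events — 2 up, 1 down.
    """
    n_frames = 50
    z = np.full((n_frames, 3), 10.0)
    x = np.full((n_frames, 3), 10.0)

    z[:13, 0] = [5, 10, 16, 25, 35, 44, 50, 52, 50, 44, 30, 20, 10]
    z[:16, 1] = [8, 12, 14, 20, 30, 40, 46, 52, 58, 2, 8, 14, 16, 14, 16, 10]
    z[:8, 2] = [55, 50, 44, 35, 30, 30, 20, 10]
    x[4, 2] = 14.0  # radial exit: lateral distance 4 > radius 3

    coords = np.stack([x, np.full((n_frames, 3), 10.0), z], axis=2)
    traj = make_trajectory(coords, (20.0, 20.0, 60.0), dt=0.1)
    expected = [
        (0, 2, 6, 1),   # particle, entry frame, exit frame, direction
        (0, 9, 12, -1),
        (1, 3, 6, 1),
    ]
    return traj, expected


@pytest.fixture
def crossing_fixture():
    return build_crossing_fixture()


@pytest.fixture
def gas_trajectory():
    """Uniform ideal gas: 600 particles, 30 frames in a 20 Å cube."""
    rng = np.random.default_rng(42)
    coords = rng.random((30, 600, 3)) * 20.0
    return make_trajectory(coords, (20.0, 20.0, 20.0))


@pytest.fixture
def pore_geometry():
    """30 Å section centred in a 20×20×60 box, radius 3 Å."""
    return PoreGeometry(center=(10.0, 10.0), radius=3.0, z_lo=15.0, z_hi=45.0)
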