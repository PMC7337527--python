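"""Shared fixtures: synthetic ensembles and tiny hand-built systems."""

from __future__ import annotations

import numpy as np
import pytest

from aptadyn.model import AtomRecord, Frame, Topology, Trajectory
from aptadyn.synthetic import EnsembleSpec, generate_binding_site_ensemble


@pytest.fixture(scope="session")
def wt_small():
    """Small wild-type ensemble shared by fast tests (60 frames)."""
    spec = EnsembleSpec(n_frames=60, seed=11, n_bulk_waters=4,
                        bridge_schedule={0: 0, 1: 1, 2: 2})
    return generate_binding_site_ensemble(spec)


@pytest.fixture(scope="session")
def wt_frozen():
    """Degenerate (std = 0) wild-type ensemble: observables posed exactly."""
    from aptadyn.synthetic import VARIANT_OBSERVABLES
    obs = {k: (v[0], 0.0) for k, v in VARIANT_OBSERVABLES["wt"].items()}
    spec = EnsembleSpec(n_frames=5, seed=7, observables=obs, n_bulk_waters=2)
    return generate_binding_site_ensemble(spec)


@pytest.fixture()
def water_topology():
    """One 3-site water molecule."""
    atoms = [
        AtomRecord(1, "O", "O", "HOH", 1),
        AtomRecord(2, "H1", "H", "HOH", 1),
        AtomRecord(3, "H2", "H", "HOH", 1),
    ]
    return Topology(atoms)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    t = rng.uniform(-20, 20, 3)
    return rot, t


def transform_trajectory(traj: Trajectory, rot: np.ndarray, t: np.ndarray) -> Trajectory:
    frames = [Frame(f.coordinates @ rot.T + t, frame_index=f.frame_index)
              for f in traj.frames]
    return Trajectory(traj.topology, frames)
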