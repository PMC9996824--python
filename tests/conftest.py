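"""Shared fixtures: small synthetic ensembles and hand-built trajectories."""

import numpy as np
import pytest

from gatekin.synthetic import (
    SyntheticTrajectorySpec,
    generate_two_state_trajectory,
    variant_like_spec,
    wild_type_like_spec,
)
from gatekin.trajectory import Topology, Trajectory


def make_trajectory(coords, atom_names, residue_indices, residue_names=None):
    """Build a Trajectory from plain lists (test convenience)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    if residue_names is None:
        residue_names = ["GLY"] * n
    topo = Topology(
        atom_names=np.asarray(atom_names, dtype=object),
        residue_indices=np.asarray(residue_indices, dtype=int),
        residue_names=np.asarray(residue_names, dtype=object),
    )
    return Trajectory(coordinates=coords, topology=topo)


@pytest.fixture(scope="session")
def peptide_trajectory():
    """5-residue backbone-only peptide, 3 identical frames, CA atoms 4 A apart."""
    names, res = [], []
    frame = []
    for r in range(5):
        for i, name in enumerate(("N", "CA", "C", "O")):
            names.append(name)
            res.append(r)
            frame.append([4.0 * r + 0.5 * i, 0.0, 0.0])
    coords = np.array([frame] * 3)
    return make_trajectory(coords, names, res)


@pytest.fixture(scope="session")
def gated_pair():
    """Wild-type-like and variant-like ensembles with their state labels."""
    wt_traj, wt_labels = generate_two_state_trajectory(
        wild_type_like_spec(seed=11, n_frames=1500)
    )
    var_traj, var_labels = generate_two_state_trajectory(
        variant_like_spec(seed=12, n_frames=1500)
    )
    return (wt_traj, wt_labels), (var_traj, var_labels)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticTrajectorySpec(
        n_residues=14,
        gate_residue=13,
        probe_residue=12,
        n_frames=400,
        designed_contact_edges={(0, 3): 1.0, (1, 4): 1.0, (2, 6): 0.5},
        seed=5,
    )
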