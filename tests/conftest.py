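"""Shared fixtures: tiny pseudo-channel systems and hand-built frames."""

from __future__ import annotations

import numpy as np
import pytest

from poreblock.core import AtomRecord, Frame, Topology, Trajectory
from poreblock.synthetic import PoreSpec, build_pore_system, constricted_radius


def make_atoms(n, element="C", radius=1.7, resid_of=None, chain="A", charge=0.0):
    """n generic atoms; resid_of maps atom index -> resid for residue grouping."""
    return [
        AtomRecord(
            i, element, element, "UNK", resid_of(i) if resid_of else 1, chain, charge, radius
        )
        for i in range(n)
    ]


def two_group_topology(n_a, n_b, radius=1.7, resid_of=None):
    atoms = make_atoms(n_a + n_b, radius=radius, resid_of=resid_of)
    return Topology(
        atoms,
        named_groups={"a": set(range(n_a)), "b": set(range(n_a, n_a + n_b))},
    )


@pytest.fixture
def small_spec():
    return PoreSpec(
        n_rings=5,
        ring_radius=6.0,
        atoms_per_ring=8,
        atom_vdw=1.7,
        slab_z=(-10.0, 10.0),
        box=(40.0, 40.0, 60.0),
    )


@pytest.fixture
def demo_spec():
    """The blocked/unblocked comparison geometry: wide pore with a narrower filter."""
    return PoreSpec(
        n_rings=11,
        ring_radius=constricted_radius(8.0, 6.2, (0.0, 20.0)),
        atoms_per_ring=14,
        atom_vdw=1.7,
        slab_z=(-20.0, 20.0),
        box=(40.0, 40.0, 100.0),
    )


@pytest.fixture
def small_system(small_spec):
    return build_pore_system(small_spec, with_blocker=False, n_ions=3, seed=7)


def scripted_ion_trajectory(z_paths, box=(40.0, 40.0, 100.0), dt=1.0):
    """Trajectory of free ions following explicit z-paths (x = y = 0)."""
    z_paths = [np.asarray(p, dtype=float) for p in z_paths]
    n_frames = len(z_paths[0])
    assert all(len(p) == n_frames for p in z_paths)
    n = len(z_paths)
    atoms = [AtomRecord(i, "K", "K", "K", i + 1, "I", 1.0, 2.75) for i in range(n)]
    top = Topology(atoms, named_groups={"ions_K": set(range(n))})
    frames = []
    for k in range(n_frames):
        xyz = np.zeros((n, 3))
        for m in range(n):
            xyz[m, 2] = z_paths[m][k]
        frames.append(Frame(xyz, box, k * dt))
    return Trajectory(top, frames, dt=dt)
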