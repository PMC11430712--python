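"""Core model: file round-trips, superposition RMSD, radius of gyration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from poreblock.core import (
    Frame,
    Topology,
    Trajectory,
    default_radii_table,
    kabsch_rmsd,
    radius_of_gyration,
    read_radii_table,
    read_system,
    write_radii_table,
    write_system,
)
from poreblock.synthetic import IonScript, build_pore_system, simulate_ions

from conftest import make_atoms


def _random_frame(n, seed, box=(50.0, 50.0, 50.0)):
    rng = np.random.default_rng(seed)
    return Frame(rng.normal(scale=5.0, size=(n, 3)), box)


# ---------------------------------------------------------------------------
# I/O


def _written_system(tmp_path, spec, n_frames=5, with_blocker=True, seed=2):
    top, f0 = build_pore_system(spec, with_blocker=with_blocker, n_ions=3, seed=seed)
    traj = simulate_ions(
        top, f0, IonScript(count=3, diffusion=5.0), n_frames=n_frames, seed=seed, spec=spec
    )
    paths = tmp_path / "top.pdb", tmp_path / "traj.pdb", tmp_path / "radii.dat"
    table = default_radii_table()
    table["P"] = (2.0, 0.0)  # blocker beads
    write_system(traj, *paths, radii_table=table)
    return traj, paths


def test_write_read_round_trip_preserves_system(tmp_path, small_spec):
    """Coordinates round-trip within PDB precision; topology round-trips exactly."""
    traj, (top_p, traj_p, radii_p) = _written_system(tmp_path, small_spec)
    back = read_system(top_p, traj_p, radii_p)
    assert back.topology.n_atoms == traj.topology.n_atoms
    assert back.n_frames == traj.n_frames
    assert np.abs(back.coordinates() - traj.coordinates()).max() < 1e-3
    assert back.topology.bonds == traj.topology.bonds
    assert {k: sorted(v) for k, v in back.topology.named_groups.items()} == {
        k: sorted(v) for k, v in traj.topology.named_groups.items()
    }
    assert [a.hbond_role for a in back.topology.atoms] == [
        a.hbond_role for a in traj.topology.atoms
    ]
    assert np.allclose(back.topology.radii, traj.topology.radii)
    assert np.allclose(back.topology.charges, traj.topology.charges)


def test_atom_count_mismatch_is_fatal(tmp_path, small_spec):
    traj3, (top3, _, radii_p) = _written_system(tmp_path, small_spec)
    bigger = build_pore_system(small_spec, with_blocker=True, n_ions=5, seed=2)
    traj5 = simulate_ions(
        bigger[0], bigger[1], IonScript(count=5, diffusion=5.0), n_frames=3, seed=0, spec=small_spec
    )
    table = default_radii_table()
    table["P"] = (2.0, 0.0)
    write_system(traj5, tmp_path / "t5.pdb", tmp_path / "tr5.pdb", radii_table=table)
    with pytest.raises(ValueError, match="mismatch"):
        read_system(top3, tmp_path / "tr5.pdb", radii_p)


def test_unknown_element_without_override_is_fatal(tmp_path, small_spec):
    """Elements missing from the radii table need a per-atom override, else loading fails."""
    _, (top_p, traj_p, radii_p) = _written_system(tmp_path, small_spec)
    table = read_radii_table(radii_p)
    del table["P"]  # blocker element now unknown
    write_radii_table(tmp_path / "short.dat", table)
    # B-factor column carries the override; zero it out to force the error
    text = top_p.read_text()
    crippled = "\n".join(
        line[:60] + "  0.00" + line[66:] if line.startswith(("ATOM", "HETATM")) else line
        for line in text.splitlines()
    )
    (tmp_path / "no_override.pdb").write_text(crippled)
    with pytest.raises(ValueError, match="unknown element"):
        read_system(tmp_path / "no_override.pdb", traj_p, tmp_path / "short.dat")


def test_triclinic_box_rejected(tmp_path, small_spec):
    _, (top_p, traj_p, radii_p) = _written_system(tmp_path, small_spec)
    text = traj_p.read_text().replace(" 90.00  90.00  90.00", " 90.00  90.00  60.00")
    (tmp_path / "tric.pdb").write_text(text)
    with pytest.raises(ValueError, match="triclinic"):
        read_system(top_p, tmp_path / "tric.pdb", radii_p)


def test_dcd_trajectory_round_trip(tmp_path, small_spec):
    top, f0 = build_pore_system(small_spec, n_ions=2, seed=4)
    traj = simulate_ions(
        top, f0, IonScript(count=2, diffusion=5.0), n_frames=4, seed=4, spec=small_spec
    )
    write_system(traj, tmp_path / "t.pdb", tmp_path / "tr.dcd", tmp_path / "r.dat")
    back = read_system(tmp_path / "t.pdb", tmp_path / "tr.dcd", tmp_path / "r.dat")
    assert back.n_frames == 4
    assert np.abs(back.coordinates() - traj.coordinates()).max() < 1e-3


# ---------------------------------------------------------------------------
# Kabsch RMSD


def test_rmsd_zero_under_rigid_motion():
    fa = _random_frame(25, seed=0)
    R = Rotation.random(random_state=11).as_matrix()
    fb = Frame(fa.coordinates @ R.T + np.array([3.0, -2.0, 7.0]), fa.box)
    assert kabsch_rmsd(fa, fb, range(25)) == pytest.approx(0.0, abs=1e-8)


def test_rmsd_two_atom_closed_form_translation_only():
    """Two collinear atoms at separations 2 and 4 give RMSD 1 after centroid fit."""
    fa = Frame(np.array([[-1.0, 0, 0], [1.0, 0, 0]]), (50, 50, 50))
    fb = Frame(np.array([[-2.0, 0, 0], [2.0, 0, 0]]), (50, 50, 50))
    with pytest.warns(UserWarning, match="non-collinear"):
        assert kabsch_rmsd(fa, fb, [0, 1]) == pytest.approx(1.0, abs=1e-12)


def test_rmsd_matches_rotation_grid_minimisation():
    """SVD superposition agrees with brute-force minimisation over rotations."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(5)
    fa = _random_frame(20, seed=1)
    fb = Frame(fa.coordinates + rng.normal(scale=0.4, size=(20, 3)), fa.box)
    P = fa.coordinates - fa.coordinates.mean(axis=0)
    Q = fb.coordinates - fb.coordinates.mean(axis=0)

    def rmsd_at(euler):
        R = Rotation.from_euler("xyz", euler).as_matrix()
        return np.sqrt(((P @ R.T - Q) ** 2).sum() / len(P))

    best = np.inf
    for _ in range(200):  # coarse random grid, then local refinement
        start = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(rmsd_at, start, method="Nelder-Mead")
        best = min(best, res.fun)
    assert kabsch_rmsd(fa, fb, range(20)) == pytest.approx(best, abs=1e-3)


def test_rmsd_symmetric_and_needs_selection():
    fa, fb = _random_frame(10, 2), _random_frame(10, 3)
    assert kabsch_rmsd(fa, fb, range(10)) == pytest.approx(
        kabsch_rmsd(fb, fa, range(10)), abs=1e-10
    )
    with pytest.raises(ValueError, match="empty"):
        kabsch_rmsd(fa, fb, [])


# ---------------------------------------------------------------------------
# radius of gyration


def test_rg_closed_forms():
    single = Frame(np.array([[1.0, 2.0, 3.0]]), (50, 50, 50))
    assert radius_of_gyration(single, [0]) == 0.0
    pair = Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]]), (50, 50, 50))
    assert radius_of_gyration(pair, [0, 1]) == pytest.approx(1.5, abs=1e-12)


def test_rg_matches_direct_summation():
    fr = _random_frame(50, seed=9)
    X = fr.coordinates
    com = X.mean(axis=0)
    direct = np.sqrt(((X - com) ** 2).sum() / 50)
    assert radius_of_gyration(fr, range(50)) == pytest.approx(direct, abs=1e-10)


@settings(derandomize=True, max_examples=30)
@given(
    seed=st.integers(0, 1000),
    scale=st.floats(0.1, 10.0),
)
def test_rg_rigid_motion_invariant_and_scales_linearly(seed, scale):
    fr = _random_frame(12, seed=seed)
    rg0 = radius_of_gyration(fr, range(12))
    R = Rotation.random(random_state=seed).as_matrix()
    moved = Frame(fr.coordinates @ R.T + 4.2, fr.box)
    assert radius_of_gyration(moved, range(12)) == pytest.approx(rg0, rel=1e-9)
    scaled = Frame(fr.coordinates * scale, fr.box)
    assert radius_of_gyration(scaled, range(12)) == pytest.approx(rg0 * scale, rel=1e-9)


def test_rg_mass_weighted_differs_when_masses_do():
    top = Topology(make_atoms(2))
    fr = Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]]), (50, 50, 50))
    w = radius_of_gyration(fr, [0, 1], mass_weighted=True, masses=np.array([1.0, 3.0]))
    # com at 2.25; sqrt((1*2.25^2 + 3*0.75^2)/4)
    assert w == pytest.approx(np.sqrt((2.25**2 + 3 * 0.75**2) / 4), abs=1e-12)
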