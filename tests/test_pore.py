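"""Pore geometry, ion bookkeeping and 1-D electrostatics."""

import numpy as np
import pytest

from poreblock.core import AtomRecord, Frame, Topology, Trajectory, ZRegion
from poreblock.pore import (
    ANGSTROM,
    E_CHARGE,
    EPS0,
    applied_voltage,
    count_translocations,
    ion_density_profile,
    ion_visits,
    ion_z_traces,
    pore_radius_profile,
    potential_profile,
)

from conftest import scripted_ion_trajectory


def _ring_system(ring_radius=6.0, atom_vdw=1.7, n=24, z=0.0, extra=None):
    pts = [
        (ring_radius * np.cos(a), ring_radius * np.sin(a), z)
        for a in np.linspace(0, 2 * np.pi, n, endpoint=False)
    ]
    radii = [atom_vdw] * n
    if extra:
        for xyz, r in extra:
            pts.append(xyz)
            radii.append(r)
    atoms = [
        AtomRecord(i, "C", "C", "POR", 1, "P", 0.0, radii[i]) for i in range(len(pts))
    ]
    return Topology(atoms), Frame(np.array(pts), (40.0, 40.0, 40.0))


# ---------------------------------------------------------------------------
# pore radius


def test_ring_profile_geometric_radius():
    top, fr = _ring_system()
    prof = pore_radius_profile(fr, top, range(top.n_atoms), (0.0, 0.0), 0.5, search_radius=4.0)
    assert prof.values[0] == pytest.approx(4.3, abs=0.05)


def test_axial_blocker_bead_obstructs():
    top, fr = _ring_system(extra=[((0.0, 0.0, 0.0), 2.0)])
    prof = pore_radius_profile(fr, top, range(top.n_atoms), (0.0, 0.0), 0.5, search_radius=4.0)
    assert prof.values[0] <= 2.3 + 1e-6
    # and obstruction strictly decreases the profile
    top0, fr0 = _ring_system()
    open_prof = pore_radius_profile(fr0, top0, range(top0.n_atoms), (0.0, 0.0), 0.5, search_radius=4.0)
    assert prof.values[0] < open_prof.values[0]


def test_irregular_lining_matches_dense_grid_oracle():
    rng = np.random.default_rng(3)
    pts, radii = [], []
    for z in np.linspace(-5, 5, 5):
        for a in np.linspace(0, 2 * np.pi, 10, endpoint=False):
            R = 5.0 + 0.8 * np.sin(3 * a + z)
            pts.append((R * np.cos(a) + 0.3 * rng.normal(), R * np.sin(a) + 0.3 * rng.normal(), z))
            radii.append(rng.uniform(1.2, 2.0))
    atoms = [AtomRecord(i, "C", "C", "POR", 1, "P", 0.0, radii[i]) for i in range(len(pts))]
    top = Topology(atoms)
    fr = Frame(np.array(pts), (40.0, 40.0, 40.0))
    S = 3.0
    prof = pore_radius_profile(fr, top, range(len(pts)), (-4, 4), 1.0, search_radius=S)
    P, Rv = np.array(pts), np.array(radii)

    def oracle(zq):
        g = np.arange(-S, S + 1e-9, 0.01)
        gx, gy = np.meshgrid(g, g)
        C = np.column_stack([gx.ravel(), gy.ravel()])
        C = C[(C**2).sum(axis=1) <= S * S]
        d = np.sqrt(
            (C[:, 0, None] - P[None, :, 0]) ** 2
            + (C[:, 1, None] - P[None, :, 1]) ** 2
            + (zq - P[None, :, 2]) ** 2
        ) - Rv[None, :]
        return d.min(axis=1).max()

    for zq, v in zip(prof.z_centers, prof.values):
        assert v == pytest.approx(oracle(zq), abs=0.05)


def test_empty_slice_reports_infinity():
    top, fr = _ring_system(z=0.0)
    prof = pore_radius_profile(fr, top, range(top.n_atoms), (30.0, 30.0), 0.5)
    assert np.isinf(prof.values[0])


# ---------------------------------------------------------------------------
# densities


def test_static_ion_occupies_single_bin():
    traj = scripted_ion_trajectory([np.full(10, 10.2)])
    total, local = ion_density_profile(traj, {0}, (-20.0, 20.0, 1.0))
    hot = np.nonzero(total.values)[0]
    assert len(hot) == 1
    assert total.z_centers[hot[0]] == pytest.approx(10.5)
    assert local.values[hot[0]] == 1.0


def test_density_conserves_ion_frames_and_planted_fractions():
    """70%/30% planted occupancy between two bins is recovered exactly."""
    z = np.concatenate([np.full(70, 5.5), np.full(30, 7.5)])
    traj = scripted_ion_trajectory([z])
    total, local = ion_density_profile(traj, {0}, (0.0, 10.0, 1.0))
    assert total.values.sum() * total.bin_width == pytest.approx(1.0)  # one ion, always in range
    assert local.values[5] == pytest.approx(0.7)
    assert local.values[7] == pytest.approx(0.3)


def test_uniform_ions_give_flat_profile_within_poisson_bounds():
    rng = np.random.default_rng(11)
    n_ions, n_frames = 40, 50
    paths = [rng.uniform(-20, 20, n_frames) for _ in range(n_ions)]
    traj = scripted_ion_trajectory(paths)
    total, _ = ion_density_profile(traj, set(range(n_ions)), (-20.0, 20.0, 4.0))
    counts = total.values * total.bin_width * n_frames
    n_bins = len(counts)
    expect = n_ions * n_frames / n_bins
    sigma = np.sqrt(n_ions * n_frames * (1 / n_bins) * (1 - 1 / n_bins))
    assert np.all(np.abs(counts - expect) < 4 * sigma)


def test_empty_ion_group_warns_all_zero():
    traj = scripted_ion_trajectory([np.zeros(5)])
    with pytest.warns(UserWarning, match="empty"):
        total, local = ion_density_profile(traj, set(), (-10.0, 10.0, 1.0))
    assert np.all(total.values == 0) and np.all(local.values == 0)


# ---------------------------------------------------------------------------
# visits / translocations / traces

REGION = ZRegion(-10.0, 10.0)


def test_visit_residence_time_bookkeeping():
    z = np.full(40, 30.0)
    z[10:20] = 0.0  # inside frames 10..19
    traj = scripted_ion_trajectory([z])
    visits = ion_visits(traj, {0}, REGION)
    assert len(visits) == 1
    v = visits[0]
    assert (v.enter_frame, v.exit_frame) == (10, 19)
    assert v.residence_ns == pytest.approx(10.0)
    assert v.outcome == "returned"  # entered from above, left upward


def test_no_entry_no_visits():
    traj = scripted_ion_trajectory([np.full(20, 30.0)])
    assert ion_visits(traj, {0}, REGION) == []
    assert ion_z_traces(traj, {0}, REGION).empty


def test_translocation_vs_return_classification():
    crossing = np.linspace(30.0, -30.0, 50)
    returner = np.concatenate([np.linspace(30, -5, 25), np.linspace(-5, 30, 25)])
    traj = scripted_ion_trajectory([crossing, returner])
    counts = count_translocations(traj, {0, 1}, REGION)
    assert counts["down"] == 1 and counts["up"] == 0
    assert counts["per_ion"][0]["down"] == 1
    assert counts["per_ion"][1] == {"up": 0, "down": 0, "visits": 1}


def test_censored_visit_when_trajectory_ends_inside():
    z = np.concatenate([np.full(5, 30.0), np.full(5, 0.0)])
    traj = scripted_ion_trajectory([z])
    (v,) = ion_visits(traj, {0}, REGION)
    assert v.outcome == "censored"


def test_random_scripted_paths_match_replay_oracle():
    """Visit lists equal events computed directly from the scripts."""
    rng = np.random.default_rng(17)
    paths = [np.cumsum(rng.normal(0, 6.0, 80)) + rng.uniform(-30, 30) for _ in range(20)]
    traj = scripted_ion_trajectory(paths)
    visits = ion_visits(traj, set(range(20)), REGION)
    # independent replay: run-length scan of the inside mask per scripted path
    expected = []
    for m, z in enumerate(paths):
        inside = (z > REGION.zmin) & (z < REGION.zmax)
        k = 0
        while k < len(z):
            if not inside[k]:
                k += 1
                continue
            s = k
            while k < len(z) and inside[k]:
                k += 1
            expected.append((m, s, k - 1))
    assert [(v.ion_id, v.enter_frame, v.exit_frame) for v in visits] == sorted(expected)


def test_planted_crossings_among_decoys_counted_exactly():
    rng = np.random.default_rng(23)
    paths = []
    for _ in range(10):  # true crossings, alternating direction
        paths.append(np.linspace(30.0, -30.0, 60))
        paths.append(np.linspace(-30.0, 30.0, 60))
    for _ in range(50):  # enter-and-return decoys
        depth = rng.uniform(-8, 8)
        paths.append(np.concatenate([np.linspace(30, depth, 30), np.linspace(depth, 30, 30)]))
    traj = scripted_ion_trajectory(paths)
    counts = count_translocations(traj, set(range(len(paths))), REGION)
    assert counts["down"] == 10 and counts["up"] == 10 and counts["total"] == 20


def test_z_traces_only_for_visiting_ions():
    paths = [np.full(10, 30.0) for _ in range(9)]
    for m in (1, 4, 7):
        paths[m] = np.linspace(30.0, -30.0, 10)
    paths += [np.full(10, 25.0) for _ in range(3)]
    traj = scripted_ion_trajectory(paths)
    traces = ion_z_traces(traj, set(range(12)), REGION)
    assert sorted(traces["ion_id"].unique()) == [1, 4, 7]
    assert len(traces) == 3 * 10


def test_region_must_be_inside_box():
    traj = scripted_ion_trajectory([np.zeros(5)])
    with pytest.raises(ValueError, match="inside the box"):
        count_translocations(traj, {0}, ZRegion(-60.0, 10.0))


def test_visits_bound_translocations_and_outcomes_partition():
    rng = np.random.default_rng(31)
    paths = [np.cumsum(rng.normal(0, 5.0, 60)) for _ in range(15)]
    traj = scripted_ion_trajectory(paths)
    visits = ion_visits(traj, set(range(15)), REGION)
    counts = count_translocations(traj, set(range(15)), REGION)
    assert counts["total"] <= len(visits)
    outcomes = {"translocated_up", "translocated_down", "returned", "censored"}
    assert all(v.outcome in outcomes for v in visits)


# ---------------------------------------------------------------------------
# electrostatics


def _charged_column(z_positions, charges, box=(20.0, 20.0, 40.0)):
    atoms = [
        AtomRecord(i, "Q", "C", "CHG", 1, "A", float(q), 1.0)
        for i, q in enumerate(charges)
    ]
    xyz = np.zeros((len(charges), 3))
    xyz[:, 2] = z_positions
    return Trajectory(Topology(atoms), [Frame(xyz, box)], dt=1.0)


def test_neutral_system_zero_potential():
    traj = _charged_column([-5.0, 5.0], [1.0, -1.0])
    prof = potential_profile(traj, (-20.0, 20.0, 0.5))
    # fields cancel outside the dipole; potential returns to a constant, and a
    # system with zero charge everywhere gives identically zero
    none = _charged_column([-5.0, 5.0], [0.0, 0.0])
    assert np.all(potential_profile(none, (-20.0, 20.0, 0.5)).values == 0.0)
    assert prof.values[0] == 0.0


def test_uniform_slab_matches_closed_form():
    """One unit charge per 0.25 Å bin across [-5, 5] reproduces the parallel-slab solution."""
    width = 0.25
    centers = np.arange(-5 + width / 2, 5, width)
    traj = _charged_column(centers, np.ones(len(centers)))
    prof = potential_profile(traj, (-20.0, 20.0, width))
    A = 20 * 20 * ANGSTROM**2
    t = 10 * ANGSTROM
    rho0 = len(centers) * E_CHARGE / (A * t)
    z = prof.z_centers * ANGSTROM
    z1, z2 = -5 * ANGSTROM, 5 * ANGSTROM
    exact = np.where(
        z < z1,
        0.0,
        np.where(
            z <= z2,
            -rho0 * (z - z1) ** 2 / (2 * EPS0),
            -rho0 * ((z2 - z1) ** 2 / 2 + (z2 - z1) * (z - z2)) / EPS0,
        ),
    )
    assert np.abs(prof.values - exact).max() < 0.01 * np.abs(exact).max()


def test_potential_sign_equivariant_and_linear():
    rng = np.random.default_rng(13)
    zpos = rng.uniform(-10, 10, 30)
    q = rng.uniform(-1, 1, 30)
    plus = potential_profile(_charged_column(zpos, q), (-20.0, 20.0, 0.5))
    minus = potential_profile(_charged_column(zpos, -q), (-20.0, 20.0, 0.5))
    double = potential_profile(_charged_column(zpos, 2 * q), (-20.0, 20.0, 0.5))
    assert np.allclose(minus.values, -plus.values, atol=1e-12)
    assert np.allclose(double.values, 2 * plus.values, rtol=1e-12)


def test_applied_voltage_paper_setting():
    """E = −0.003 V/Å across a 100 Å box applies −0.3 V (−300 mV)."""
    assert applied_voltage(-0.003, 100.0) == pytest.approx(-0.3)
    assert applied_voltage(0.0, 87.0) == 0.0
    assert applied_voltage(-0.003, 200.0) == pytest.approx(2 * applied_voltage(-0.003, 100.0))
    with pytest.raises(ValueError):
        applied_voltage(-0.003, -1.0)
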