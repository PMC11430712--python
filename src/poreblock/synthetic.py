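"""Synthetic pseudo-channel systems with planted, known ground truth.

The generator emulates the geometry that the analysis stages consume — a
membrane-spanning cylindrical pore with a constriction ("selectivity
filter"), permeant monovalent cations driven along z by an applied field, an
optional pore-plugging 12-bead peptide, and donor/hydrogen/acceptor triplets
at exactly specified geometry — without any thermodynamic realism.  Every
planted event (ion crossing, pore visit, hydrogen bond, van-der-Waals pair)
is recoverable exactly, which is what makes the analysis stack testable in
the absence of deposited channel trajectories.

Ions move by overdamped Langevin dynamics: a drift μqE along z (Einstein
mobility μ = D/kBT) plus Gaussian diffusion, with hard reflecting walls at
the membrane slab, the pore lining and the blocker beads.  Channel and
blocker atoms are static apart from optional Gaussian jitter.  All
randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import (
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
    assign_hbond_roles,
    default_radii_table,
)

__all__ = ["PoreSpec", "IonScript", "build_pore_system", "simulate_ions", "plant_hbond_geometry"]

KBT_310K_EV = 0.026712  # kB * 310 K in eV; drift = q E D / kBT

# element assignments used by the generator so hbond roles survive PDB round-trips
_LINING_ELEM = "C"
_BLOCKER_ELEM = "P"
_ION_ELEM = "K"


@dataclass
class PoreSpec:
    """Geometry of a pseudo-channel: stacked atom rings forming a cylindrical pore.

    ``ring_radius`` is either a constant (Å) or a piecewise function of z so a
    constriction can be planted; the geometric open-pore radius at a ring
    plane is ``ring_radius(z) − atom_vdw``.
    """

    n_rings: int = 9
    ring_radius: float | Callable[[float], float] = 6.0
    atoms_per_ring: int = 12
    atom_vdw: float = 1.7
    slab_z: tuple[float, float] = (-20.0, 20.0)
    box: tuple[float, float, float] = (40.0, 40.0, 100.0)

    def __post_init__(self) -> None:
        zlo, zhi = self.slab_z
        if not zlo < zhi:
            raise ValueError("slab_z must satisfy zlow < zhigh")
        if not (-self.box[2] / 2 <= zlo and zhi <= self.box[2] / 2):
            raise ValueError("slab must lie inside the box")
        for z in self.ring_z():
            if self.radius_at(z) <= self.atom_vdw:
                raise ValueError("ring_radius must exceed atom_vdw everywhere")

    def radius_at(self, z: float) -> float:
        r = self.ring_radius(z) if callable(self.ring_radius) else float(self.ring_radius)
        return float(r)

    def open_radius_at(self, z: float) -> float:
        """Largest probe radius the bare lining admits at height z."""
        return self.radius_at(z) - self.atom_vdw

    def ring_z(self) -> np.ndarray:
        return np.linspace(self.slab_z[0], self.slab_z[1], self.n_rings)


def constricted_radius(
    open_radius: float = 6.0, filter_radius: float = 4.45, filter_z: tuple[float, float] = (0.0, 20.0)
) -> Callable[[float], float]:
    """Piecewise-constant ring radius with a narrower band (the filter) in ``filter_z``."""

    def radius(z: float) -> float:
        return filter_radius if filter_z[0] <= z <= filter_z[1] else open_radius

    return radius


@dataclass
class IonScript:
    """How ions move: explicit per-ion z-paths, or overdamped Langevin parameters.

    ``paths`` maps ion index (0-based within the ion group) to an array of z
    positions per frame; scripted ions keep their initial x, y.  Unscripted
    ions diffuse with coefficient ``diffusion`` (Å²/ns) and drift μqE.
    """

    count: int = 8
    diffusion: float = 15.0
    charge: float = 1.0
    paths: Mapping[int, np.ndarray] = field(default_factory=dict)
    lateral_diffusion: float | None = None  # defaults to `diffusion`

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("ion count must be >= 0")
        if self.diffusion <= 0:
            raise ValueError("diffusion coefficient must be positive")


def _ring_atoms(spec: PoreSpec) -> np.ndarray:
    coords = []
    for z in spec.ring_z():
        R = spec.radius_at(z)
        for j in range(spec.atoms_per_ring):
            phi = 2 * np.pi * j / spec.atoms_per_ring
            coords.append((R * np.cos(phi), R * np.sin(phi), z))
    return np.array(coords)


def build_pore_system(
    spec: PoreSpec,
    with_blocker: bool = False,
    n_ions: int = 0,
    blocker_radius: float = 2.0,
    blocker_n_res: int = 12,
    blocker_spacing: float = 3.2,
    seed: int = 0,
    decorate_hbond_sites: bool = True,
    ion_start_radius: float = 3.0,
) -> tuple[Topology, Frame]:
    """Build the static pseudo-channel: lining rings, optional blocker, ions.

    The blocker is a 12-bead pseudo-peptide chain placed with its first bead
    on the pore axis inside the constriction (the narrowest ring plane) and
    the rest extending toward +z (the extracellular mouth).  When
    ``decorate_hbond_sites`` is set, the first blocker bead carries an N–H
    donor pointing at an acceptor O decorated onto the nearest lining ring,
    planting one recoverable hydrogen bond.

    Named groups "pore_lining", "ligand" (blocker) and "ions_K" are
    populated; ions start above the extracellular mouth.
    """
    rng = np.random.default_rng(seed)
    records: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    bonds: set[tuple[int, int]] = set()
    groups: dict[str, set[int]] = {"pore_lining": set(), "ligand": set(), "ions_K": set()}
    table = default_radii_table()

    def add_atom(name, elem, resname, resid, chain, charge, radius, xyz) -> int:
        aid = len(records)
        records.append(
            AtomRecord(aid, name, elem, resname, resid, chain, charge, radius, "none")
        )
        coords.append(tuple(xyz))
        return aid

    # pore lining rings
    ring_xyz = _ring_atoms(spec)
    for i, xyz in enumerate(ring_xyz):
        ring_index = i // spec.atoms_per_ring
        aid = add_atom("C", _LINING_ELEM, "POR", ring_index + 1, "P", 0.0, spec.atom_vdw, xyz)
        groups["pore_lining"].add(aid)

    zs = spec.ring_z()
    z_constrict = float(zs[int(np.argmin([spec.radius_at(z) for z in zs]))])

    if with_blocker:
        mouth_open = spec.open_radius_at(z_constrict)
        if blocker_radius >= mouth_open:
            raise ValueError(
                f"blocker bead radius {blocker_radius} Å does not fit the pore mouth "
                f"(open radius {mouth_open} Å)"
            )
        prev = None
        for k in range(blocker_n_res):
            z = z_constrict + k * blocker_spacing
            # slight helical offset keeps consecutive beads from overlapping radially
            off = 0.4 * min(k, 1)
            phi = 0.9 * k
            xyz = (off * np.cos(phi), off * np.sin(phi), z)
            aid = add_atom("B", _BLOCKER_ELEM, "BLK", k + 1, "L", 0.0, blocker_radius, xyz)
            groups["ligand"].add(aid)
            if prev is not None:
                bonds.add((prev, aid))
            prev = aid
        table[_BLOCKER_ELEM] = (blocker_radius, 0.0)

        if decorate_hbond_sites:
            # planted donor (N-H on bead 1) aimed at an acceptor (O on the lining)
            d_xyz = np.array([0.0, blocker_radius + 0.4, z_constrict])
            a_xyz = np.array([0.0, d_xyz[1] + 2.9, z_constrict])
            h_xyz = d_xyz + (a_xyz - d_xyz) / np.linalg.norm(a_xyz - d_xyz) * 1.0
            d_id = add_atom("N", "N", "BLK", 1, "L", 0.0, table["N"][0], d_xyz)
            h_id = add_atom("H", "H", "BLK", 1, "L", 0.0, table["H"][0], h_xyz)
            a_id = add_atom("O", "O", "POR", 1, "P", 0.0, table["O"][0], a_xyz)
            bonds.add((d_id, h_id))
            first_bead = min(groups["ligand"])
            bonds.add((first_bead, d_id))
            groups["ligand"] |= {d_id, h_id}
            groups["pore_lining"].add(a_id)

    # ions stacked above the extracellular mouth, random lateral placement
    zhi = spec.slab_z[1]
    for k in range(n_ions):
        r = rng.uniform(0.0, min(ion_start_radius, spec.box[0] / 2 - 4.0))
        phi = rng.uniform(0.0, 2 * np.pi)
        z = rng.uniform(zhi + 4.0, spec.box[2] / 2 - 4.0)
        xyz = (r * np.cos(phi), r * np.sin(phi), z)
        aid = add_atom("K", _ION_ELEM, "K", k + 1, "I", 1.0, table["K"][0], xyz)
        groups["ions_K"].add(aid)

    roles = assign_hbond_roles(
        [a.element for a in records], bonds, [a.atom_id for a in records]
    )
    for rec, role in zip(records, roles):
        rec.hbond_role = role

    topology = Topology(atoms=records, bonds=bonds, named_groups=groups)
    frame = Frame(coordinates=np.array(coords), box=spec.box, time=0.0)
    return topology, frame


def _allowed_radial_band(
    spec: PoreSpec,
    z: float,
    ion_radius: float,
    blocker_xyz: np.ndarray | None,
    blocker_radius: float,
) -> tuple[float, float]:
    """Hard-sphere admissible radial band [r_min, r_max] for an ion centre at height z.

    Returns r_min > r_max when the slice is fully occluded.
    """
    r_max = spec.radius_at(z) - spec.atom_vdw - ion_radius
    r_min = 0.0
    if blocker_xyz is not None:
        near = np.abs(blocker_xyz[:, 2] - z) < (blocker_radius + ion_radius)
        if np.any(near):
            r_min = blocker_radius + ion_radius
    return r_min, r_max


def simulate_ions(
    topology: Topology,
    frame0: Frame,
    script: IonScript,
    n_frames: int,
    field_E: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
    spec: PoreSpec | None = None,
    jitter: float = 0.0,
) -> Trajectory:
    """Propagate ions for ``n_frames`` snapshots; everything else stays put.

    ``field_E`` is the applied electric field in V/Å along +z (negative E
    drives cations toward −z, the paper's −300 mV convention).  Scripted ions
    follow their z-paths exactly; the rest do overdamped Langevin steps with
    reflecting boundaries at the box walls, the membrane slab and — when a
    ``spec`` is supplied — the pore lining and blocker hard spheres.
    Bit-for-bit reproducible for a fixed seed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    ion_ids = sorted(topology.group("ions_K"))  # script.count sizes the generator, not this step
    for m, path in script.paths.items():
        if len(np.asarray(path)) < n_frames:
            raise ValueError(f"scripted path for ion {m} is shorter than n_frames")
    ion_idx = topology.indices(ion_ids)
    ion_radius = float(topology.radii[ion_idx[0]]) if len(ion_idx) else 0.0

    lig_ids = sorted(topology.named_groups.get("ligand", set()))
    blocker_xyz = None
    blocker_radius = 0.0
    if lig_ids and spec is not None:
        lidx = topology.indices(lig_ids)
        heavy = topology.elements[lidx] != "H"
        blocker_xyz = frame0.coordinates[lidx][heavy]
        blocker_radius = float(topology.radii[lidx][heavy].max())

    D = script.diffusion
    Dxy = script.lateral_diffusion if script.lateral_diffusion is not None else D
    drift = script.charge * field_E * D / KBT_310K_EV  # Å/ns, signed
    sigma_z = np.sqrt(2 * D * dt)
    sigma_xy = np.sqrt(2 * Dxy * dt)
    Lx, Ly, Lz = frame0.box
    zlo_slab, zhi_slab = (spec.slab_z if spec is not None else (np.inf, np.inf))

    def admissible(x: float, y: float, z: float) -> bool:
        if abs(z) > Lz / 2 - 1.0 or abs(x) > Lx / 2 - 1.0 or abs(y) > Ly / 2 - 1.0:
            return False
        if spec is None or not (zlo_slab <= z <= zhi_slab):
            return True
        r_min, r_max = _allowed_radial_band(spec, z, ion_radius, blocker_xyz, blocker_radius)
        r = np.hypot(x, y)
        return r_min <= r <= r_max

    pos = frame0.coordinates[ion_idx].copy()
    frames = [Frame(frame0.coordinates.copy(), frame0.box, 0.0)]
    static = frame0.coordinates.copy()

    for k in range(1, n_frames):
        new = pos.copy()
        steps = rng.normal(size=(len(ion_idx), 3))
        for m, aid in enumerate(ion_ids):
            if m in script.paths:
                path = np.asarray(script.paths[m], dtype=float)
                if path.ndim == 1:
                    new[m, 2] = path[k]
                else:
                    new[m] = path[k]
                continue
            trial = pos[m] + np.array(
                [sigma_xy * steps[m, 0], sigma_xy * steps[m, 1], drift * dt + sigma_z * steps[m, 2]]
            )
            # reflect rejected moves component-wise: z first (membrane / pore gate),
            # then the lateral components (walls, lining)
            x, y, z = trial
            if not admissible(pos[m, 0], pos[m, 1], z):
                z = pos[m, 2]
            if not admissible(x, y, z):
                x, y = pos[m, 0], pos[m, 1]
            new[m] = (x, y, z)
        pos = new
        xyz = static.copy()
        if jitter > 0:
            non_ion = np.ones(len(static), dtype=bool)
            non_ion[ion_idx] = False
            xyz[non_ion] += rng.normal(scale=jitter, size=(non_ion.sum(), 3))
        xyz[ion_idx] = pos
        frames.append(Frame(xyz, frame0.box, k * dt))
    return Trajectory(topology=topology, frames=frames, dt=dt)


def plant_hbond_geometry(
    topology: Topology,
    frame: Frame,
    distance: float,
    dha_angle: float,
    site: Sequence[float] | None = None,
    donor_group: str = "ligand",
    acceptor_group: str = "pore_lining",
    min_clearance: float = 0.5,
) -> tuple[Topology, Frame]:
    """Append a donor-heavy/hydrogen/acceptor triplet at an exact (d, θ) geometry.

    ``distance`` is the donor–acceptor separation (Å) and ``dha_angle`` the
    D–H–A angle (degrees, vertex at the hydrogen); the D–H bond length is
    1.0 Å.  The donor and hydrogen join ``donor_group``, the acceptor joins
    ``acceptor_group``.  Placement that comes within ``min_clearance`` Å of
    any existing atom is rejected.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if not 0 < dha_angle <= 180:
        raise ValueError("dha_angle must be in (0, 180] degrees")
    if distance <= 1.0:
        raise ValueError("donor-acceptor distance must exceed the 1.0 Å D-H bond")

    origin = np.array(site if site is not None else (frame.box[0] / 2 - 6.0, 0.0, frame.box[2] / 2 - 8.0))
    d_xyz = origin
    h_xyz = origin + np.array([1.0, 0.0, 0.0])
    theta = np.radians(dha_angle)
    alpha = np.pi - theta  # angle of H->A from +x, since H->D points along -x
    u = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    # |DA| = d with A = H + r u  =>  r^2 + 2 r cos(alpha) + 1 = d^2
    r = -np.cos(alpha) + np.sqrt(np.cos(alpha) ** 2 - 1 + distance**2)
    a_xyz = h_xyz + r * u

    for xyz in (d_xyz, h_xyz, a_xyz):
        dmin = np.linalg.norm(frame.coordinates - xyz, axis=1).min() if frame.n_atoms else np.inf
        if dmin < min_clearance:
            raise ValueError(f"planted geometry collides with an existing atom ({dmin:.2f} Å)")

    table = default_radii_table()
    next_id = max((a.atom_id for a in topology.atoms), default=-1) + 1
    d_rec = AtomRecord(next_id, "N", "N", "PLD", 900, "L", 0.0, table["N"][0], "donor-heavy")
    h_rec = AtomRecord(next_id + 1, "H", "H", "PLD", 900, "L", 0.0, table["H"][0], "hydrogen")
    a_rec = AtomRecord(next_id + 2, "O", "O", "PLA", 901, "P", 0.0, table["O"][0], "acceptor")

    atoms = topology.atoms + [d_rec, h_rec, a_rec]
    bonds = set(topology.bonds) | {(d_rec.atom_id, h_rec.atom_id)}
    groups = {k: set(v) for k, v in topology.named_groups.items()}
    groups.setdefault(donor_group, set()).update({d_rec.atom_id, h_rec.atom_id})
    groups.setdefault(acceptor_group, set()).add(a_rec.atom_id)
    new_top = Topology(atoms=atoms, bonds=bonds, named_groups=groups)
    new_coords = np.vstack([frame.coordinates, d_xyz, h_xyz, a_xyz])
    return new_top, Frame(new_coords, frame.box, frame.time)
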