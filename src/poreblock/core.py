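"""Core system model: atoms, frames, trajectories, file I/O and per-frame descriptors.

The in-memory containers are deliberately small and explicit.  A
:class:`Topology` is a static atom table (element, residue, partial charge,
van-der-Waals radius, bond list, hydrogen-bond role) plus named atom groups
("ligand", "pore_lining", "ions_K", ...).  A :class:`Trajectory` is an ordered
list of :class:`Frame` objects, each carrying coordinates in Å and an
orthorhombic box.  File I/O (PDB topology, multi-model PDB or DCD frames) is
delegated to MDAnalysis; a plain-text radii table supplies per-element
van-der-Waals radii and default partial charges.

Conventions
-----------
* Lengths are Å, times ns, charges elementary charge units.
* z is the membrane normal / pore axis.
* Boxes are orthorhombic; triclinic input is rejected at load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "ZRegion",
    "BONDI_RADII",
    "DEFAULT_CHARGES",
    "read_radii_table",
    "write_radii_table",
    "assign_hbond_roles",
    "read_system",
    "write_system",
    "minimum_image",
    "kabsch_rotation",
    "kabsch_rmsd",
    "radius_of_gyration",
]

# Bondi (1964) element radii, Å.  Used when the radii table does not override.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "K": 2.75, "NA": 2.27,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "BR": 1.85, "I": 1.98,
}

# Default formal charges for free ions; everything else defaults to 0 e.
DEFAULT_CHARGES: dict[str, float] = {"K": 1.0, "NA": 1.0, "CL": -1.0, "CA": 2.0, "MG": 2.0}

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "K": 39.098, "NA": 22.990, "CL": 35.45, "F": 18.998,
}

HBOND_ROLES = ("donor-heavy", "acceptor", "hydrogen", "none")
_POLAR_HEAVY = {"N", "O", "S"}


@dataclass
class AtomRecord:
    """One atom of the static topology table."""

    atom_id: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    charge: float
    vdw_radius: float
    hbond_role: str = "none"

    def __post_init__(self) -> None:
        if self.atom_id < 0:
            raise ValueError(f"atom_id must be >= 0, got {self.atom_id}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0 for atom {self.atom_id}")
        if self.hbond_role not in HBOND_ROLES:
            raise ValueError(f"unknown hbond_role {self.hbond_role!r}")
        if self.hbond_role == "hydrogen" and self.element.upper() != "H":
            raise ValueError(f"atom {self.atom_id}: hbond_role 'hydrogen' requires element H")


@dataclass
class Topology:
    """Ordered atom table with bonds and named atom groups."""

    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    named_groups: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom ids are not unique")
        self._index = {aid: i for i, aid in enumerate(ids)}
        self.bonds = {tuple(sorted(b)) for b in self.bonds}
        for i, j in self.bonds:
            if i not in self._index or j not in self._index:
                raise ValueError(f"bond ({i}, {j}) references unknown atom")
        for label, grp in self.named_groups.items():
            unknown = grp - set(self._index)
            if unknown:
                raise ValueError(f"group {label!r} references unknown atoms {sorted(unknown)[:5]}")
        # hydrogen role invariant: every role-hydrogen has a bonded heavy atom
        bonded: dict[int, set[int]] = {aid: set() for aid in ids}
        for i, j in self.bonds:
            bonded[i].add(j)
            bonded[j].add(i)
        self._bonded = bonded
        for a in self.atoms:
            if a.hbond_role == "hydrogen" and not bonded[a.atom_id]:
                raise ValueError(f"hydrogen atom {a.atom_id} has hbond role but no bonded heavy atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: int) -> int:
        return self._index[atom_id]

    def indices(self, atom_ids: Iterable[int]) -> np.ndarray:
        return np.array([self._index[a] for a in atom_ids], dtype=int)

    def bonded_to(self, atom_id: int) -> set[int]:
        return self._bonded[atom_id]

    def group(self, label: str) -> set[int]:
        try:
            return self.named_groups[label]
        except KeyError:
            raise KeyError(f"no named group {label!r}; have {sorted(self.named_groups)}") from None

    # convenience arrays in atom order
    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element.upper() for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([_MASSES.get(a.element.upper(), 12.0) for a in self.atoms])


@dataclass
class Frame:
    """One coordinate snapshot with its orthorhombic box (Å) and time (ns)."""

    coordinates: np.ndarray
    box: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N x 3")
        if any(L <= 0 for L in self.box):
            raise ValueError(f"box lengths must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology, with frame spacing dt (ns)."""

    topology: Topology
    frames: list[Frame]
    dt: float = 1.0

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {f.n_atoms} atoms but topology has {n} (atom-count mismatch)"
                )
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """All coordinates stacked, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass
class ZRegion:
    """A z-slab with optional cylindrical radial cutoff around an axis point."""

    zmin: float
    zmax: float
    axis_xy: tuple[float, float] = (0.0, 0.0)
    radial_cutoff: float = np.inf

    def __post_init__(self) -> None:
        if not self.zmin < self.zmax:
            raise ValueError(f"need zmin < zmax, got [{self.zmin}, {self.zmax}]")
        if self.radial_cutoff <= 0:
            raise ValueError("radial_cutoff must be > 0")

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean mask for points (…, 3) inside the region."""
        xyz = np.asarray(xyz, dtype=float)
        z_ok = (xyz[..., 2] > self.zmin) & (xyz[..., 2] < self.zmax)
        if np.isinf(self.radial_cutoff):
            return z_ok
        dx = xyz[..., 0] - self.axis_xy[0]
        dy = xyz[..., 1] - self.axis_xy[1]
        return z_ok & (dx * dx + dy * dy <= self.radial_cutoff**2)


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image(d: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    d = np.asarray(d, dtype=float)
    L = np.asarray(box, dtype=float)
    return d - L * np.round(d / L)


# ---------------------------------------------------------------------------
# radii table I/O


def read_radii_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a whitespace-separated ``element  vdw_radius_Å  charge_e`` table.

    Lines starting with ``#`` are comments.  The charge column is optional and
    defaults to 0 e.
    """
    table: dict[str, tuple[float, float]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed radii-table line: {line!r}")
        elem = parts[0].upper()
        radius = float(parts[1])
        charge = float(parts[2]) if len(parts) > 2 else 0.0
        if radius <= 0:
            raise ValueError(f"non-positive radius for element {elem}")
        table[elem] = (radius, charge)
    return table


def write_radii_table(path: str | Path, table: Mapping[str, tuple[float, float]]) -> None:
    lines = ["# element  vdw_radius_A  charge_e"]
    for elem, (r, q) in table.items():
        lines.append(f"{elem:<4s} {r:8.3f} {q:8.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_radii_table() -> dict[str, tuple[float, float]]:
    """Bondi radii with free-ion default charges."""
    return {e: (r, DEFAULT_CHARGES.get(e, 0.0)) for e, r in BONDI_RADII.items()}


# ---------------------------------------------------------------------------
# hydrogen-bond role assignment


def assign_hbond_roles(
    elements: Sequence[str], bonds: Iterable[tuple[int, int]], atom_ids: Sequence[int]
) -> list[str]:
    """Derive donor/acceptor/hydrogen roles from elements and connectivity.

    Rules (GetContacts-style, purely geometric/chemical):

    * an H bonded to N/O/S is a polar ``hydrogen``;
    * an N/O/S carrying such a hydrogen is ``donor-heavy``;
    * any other N/O/S is an ``acceptor``;
    * everything else is ``none``.
    """
    idx = {aid: i for i, aid in enumerate(atom_ids)}
    elems = [e.upper() for e in elements]
    neighbours: dict[int, list[int]] = {i: [] for i in range(len(elems))}
    for a, b in bonds:
        ia, ib = idx[a], idx[b]
        neighbours[ia].append(ib)
        neighbours[ib].append(ia)
    roles = ["none"] * len(elems)
    for i, e in enumerate(elems):
        if e == "H" and any(elems[j] in _POLAR_HEAVY for j in neighbours[i]):
            roles[i] = "hydrogen"
    for i, e in enumerate(elems):
        if e in _POLAR_HEAVY:
            if any(roles[j] == "hydrogen" for j in neighbours[i]):
                roles[i] = "donor-heavy"
            else:
                roles[i] = "acceptor"
    return roles


# ---------------------------------------------------------------------------
# system I/O (MDAnalysis-backed)


def _pdb_cryst1(path: str | Path) -> np.ndarray | None:
    """First CRYST1 record of a PDB file, or None.

    Fallback for multi-model PDBs whose single header CRYST1 precedes the
    first MODEL record and is therefore not attached to any frame by the
    reader.
    """
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    return np.array(
                        [line[6:15], line[15:24], line[24:33], line[33:40], line[40:47], line[47:54]],
                        dtype=float,
                    )
                if line.startswith(("MODEL", "ATOM", "HETATM")):
                    break
    except (OSError, UnicodeDecodeError, ValueError):
        return None
    return None


def _check_orthorhombic(dimensions: np.ndarray | None) -> tuple[float, float, float]:
    if dimensions is None or np.all(dimensions[:3] == 0):
        raise ValueError("trajectory frame carries no box; an orthorhombic box is required")
    a, b, c, alpha, beta, gamma = [float(x) for x in dimensions[:6]]
    if not (abs(alpha - 90) < 1e-3 and abs(beta - 90) < 1e-3 and abs(gamma - 90) < 1e-3):
        raise ValueError(f"triclinic box (angles {alpha}, {beta}, {gamma}) is not supported")
    return (a, b, c)


def read_system(
    topology_path: str | Path,
    trajectory_path: str | Path,
    radii_table: str | Path | Mapping[str, tuple[float, float]],
    dt: float = 1.0,
    z_offset: float = 0.0,
) -> Trajectory:
    """Load a PDB topology plus multi-model PDB or DCD frames into a Trajectory.

    ``radii_table`` maps element -> (vdw radius Å, default charge e).  Atoms
    whose element is absent from the table must carry per-atom overrides in
    the topology PDB (B-factor column = radius, occupancy column = charge);
    otherwise loading fails listing the offending atoms.  ``z_offset`` shifts
    all z coordinates so analyses can place the pore at z = 0.

    Named groups are reconstructed from chain IDs: chain L -> "ligand",
    chain P -> "pore_lining", chain I -> "ions_K", chain M -> "membrane".
    """
    import MDAnalysis as mda

    if isinstance(radii_table, (str, Path)):
        table = read_radii_table(radii_table)
    else:
        table = {k.upper(): v for k, v in radii_table.items()}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(topology_path), str(trajectory_path))
            u.trajectory[0]
        except (ValueError, IndexError, OSError) as exc:
            raise ValueError(
                f"cannot combine topology and trajectory (atom-count mismatch?): {exc}"
            ) from exc

    n = len(u.atoms)
    elements = []
    for a in u.atoms:
        e = getattr(a, "element", "") or ""
        if not e.strip():
            e = a.name.strip()[:2].strip("0123456789")
        elements.append(e.upper())

    occ = getattr(u.atoms, "occupancies", np.zeros(n))
    bfac = getattr(u.atoms, "tempfactors", np.zeros(n))

    missing: list[str] = []
    radii = np.empty(n)
    charges = np.empty(n)
    for i, e in enumerate(elements):
        if e in table:
            radii[i], charges[i] = table[e]
        elif bfac[i] > 0:
            radii[i], charges[i] = float(bfac[i]), float(occ[i])
        else:
            missing.append(f"atom {i} ({u.atoms[i].name}/{e})")
    if missing:
        raise ValueError(
            "unknown element(s) with no per-atom override in the topology file: "
            + ", ".join(missing[:10])
        )

    bonds: set[tuple[int, int]] = set()
    if hasattr(u, "bonds"):
        for b in u.bonds:
            bonds.add(tuple(sorted((int(b.atoms[0].index), int(b.atoms[1].index)))))

    roles = assign_hbond_roles(elements, bonds, list(range(n)))

    chainids = getattr(u.atoms, "chainIDs", np.array([""] * n))
    atoms = [
        AtomRecord(
            atom_id=i,
            name=u.atoms[i].name,
            element=elements[i],
            resname=u.atoms[i].resname,
            resid=int(u.atoms[i].resid),
            chain=str(chainids[i]),
            charge=float(charges[i]),
            vdw_radius=float(radii[i]),
            hbond_role=roles[i],
        )
        for i in range(n)
    ]

    group_map = {"L": "ligand", "P": "pore_lining", "I": "ions_K", "M": "membrane"}
    named_groups: dict[str, set[int]] = {}
    for i, c in enumerate(chainids):
        label = group_map.get(str(c))
        if label:
            named_groups.setdefault(label, set()).add(i)

    topology = Topology(atoms=atoms, bonds=bonds, named_groups=named_groups)

    fallback_box = None
    if str(trajectory_path).lower().endswith((".pdb", ".ent")):
        fallback_box = _pdb_cryst1(trajectory_path)

    frames = []
    for k, ts in enumerate(u.trajectory):
        dims = ts.dimensions if ts.dimensions is not None else fallback_box
        box = _check_orthorhombic(dims)
        xyz = np.array(ts.positions, dtype=float)
        xyz[:, 2] += z_offset
        frames.append(Frame(coordinates=xyz, box=box, time=k * dt))
    return Trajectory(topology=topology, frames=frames, dt=dt)


_GROUP_TO_CHAIN = {"ligand": "L", "pore_lining": "P", "ions_K": "I", "membrane": "M"}


def _build_universe(traj: Trajectory):
    """Internal: materialise an MDAnalysis Universe mirroring a Trajectory."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    top = traj.topology
    n = top.n_atoms
    resids = [a.resid for a in top.atoms]
    # consecutive (resid, resname, chain) runs become residues
    res_keys: list[tuple[int, str, str]] = []
    atom_resindex = np.empty(n, dtype=int)
    for i, a in enumerate(top.atoms):
        key = (a.resid, a.resname, a.chain)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1

    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(res_keys),
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(len(res_keys), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in top.atoms])
    u.add_TopologyAttr("elements", [a.element for a in top.atoms])
    u.add_TopologyAttr("resnames", [k[1] for k in res_keys])
    u.add_TopologyAttr("resids", [k[0] for k in res_keys])
    u.add_TopologyAttr("chainIDs", [a.chain for a in top.atoms])
    u.add_TopologyAttr("occupancies", [a.charge for a in top.atoms])
    u.add_TopologyAttr("tempfactors", [a.vdw_radius for a in top.atoms])
    u.add_TopologyAttr("record_types", ["ATOM"] * n)
    if top.bonds:
        pairs = [(top.index_of(i), top.index_of(j)) for i, j in sorted(top.bonds)]
        u.add_TopologyAttr("bonds", pairs)

    coords = traj.coordinates().astype(np.float32)
    dims = np.array(
        [[*f.box, 90.0, 90.0, 90.0] for f in traj.frames], dtype=np.float32
    )
    u.load_new(coords, format=MemoryReader, dimensions=dims)
    return u


def write_system(
    traj: Trajectory,
    topology_path: str | Path,
    trajectory_path: str | Path,
    radii_path: str | Path | None = None,
    radii_table: Mapping[str, tuple[float, float]] | None = None,
) -> None:
    """Write a Trajectory as PDB topology + multi-model PDB or DCD frames.

    The trajectory format is chosen from the ``trajectory_path`` suffix
    (``.pdb`` -> multi-model PDB, ``.dcd`` -> CHARMM/NAMD DCD).  Per-atom
    charge and vdW radius are stored in the occupancy and B-factor columns so
    elements absent from the radii table still round-trip.
    """
    import MDAnalysis as mda

    u = _build_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.trajectory[0]
        with mda.Writer(str(topology_path), n_atoms=len(u.atoms), multiframe=False, bonds="all") as w:
            w.write(u.atoms)
        with mda.Writer(str(trajectory_path), n_atoms=len(u.atoms), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    if radii_path is not None:
        write_radii_table(radii_path, radii_table if radii_table is not None else default_radii_table())


# ---------------------------------------------------------------------------
# superposition and per-frame descriptors


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R (3x3) minimising ||R P - Q|| for centred P, Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_rmsd(frame_a: Frame, frame_b: Frame, selection: Iterable[int]) -> float:
    """Minimal least-squares RMSD (Å) of ``selection`` after optimal rigid superposition.

    With fewer than 3 non-collinear atoms the rotation is undetermined; a
    warning is raised and a translation-only (centroid) fit is used.
    """
    sel = list(selection)
    if not sel:
        raise ValueError("selection is empty")
    idx = np.asarray(sel, dtype=int)
    P = frame_a.coordinates[idx] - frame_a.coordinates[idx].mean(axis=0)
    Q = frame_b.coordinates[idx] - frame_b.coordinates[idx].mean(axis=0)
    rank = np.linalg.matrix_rank(P, tol=1e-8)
    if len(sel) < 3 or rank < 2:
        warnings.warn(
            "fewer than 3 non-collinear atoms: rotation undetermined, translation-only fit",
            stacklevel=2,
        )
        diff = P - Q
    else:
        R = kabsch_rotation(P, Q)
        diff = P @ R.T - Q
    return float(np.sqrt((diff**2).sum() / len(sel)))


def radius_of_gyration(
    frame: Frame,
    selection: Iterable[int],
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
) -> float:
    """Radius of gyration (Å): sqrt(Σ wᵢ|rᵢ − r̄|² / Σ wᵢ), unweighted by default."""
    sel = list(selection)
    if not sel:
        raise ValueError("selection is empty")
    idx = np.asarray(sel, dtype=int)
    X = frame.coordinates[idx]
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted=True requires masses")
        w = np.asarray(masses, dtype=float)[idx]
    else:
        w = np.ones(len(idx))
    com = (X * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((X - com) ** 2).sum(axis=1)).sum() / w.sum()))
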