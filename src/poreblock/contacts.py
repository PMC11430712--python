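"""Hydrogen-bond and van-der-Waals contact detection and aggregation.

Criteria (GetContacts-style geometric definitions):

* van der Waals: two heavy atoms A, B from different groups are in contact
  when ``|AB| < Rvdw(A) + Rvdw(B) + 0.5 Å`` (strict inequality, minimum
  image).
* hydrogen bond: donor–acceptor distance ``< 3.5 Å`` (strict) and a D–H–A
  angle criterion.  The printed angle window "180°–70°" is ambiguous; the
  default reading is a ≤ 70° deviation from linearity (D–H–A ∈ [110°, 180°],
  the convention of the contact tool the criterion descends from), with the
  literal window [70°, 180°] selectable via ``angle_mode="literal"``.

Detection is accelerated with a cKD-tree but is guaranteed to return exactly
the brute-force all-pairs result (``method="brute"`` exposes the reference
path for testing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Frame, Topology, Trajectory, minimum_image

__all__ = [
    "ContactRecord",
    "detect_vdw_contacts",
    "detect_hbonds",
    "contact_timeseries",
    "contact_frequency",
    "flare_edges",
    "write_flare_json",
]


@dataclass(frozen=True)
class ContactRecord:
    """One typed atom-pair interaction observed in one frame."""

    kind: str  # "hbond" | "vdw"
    frame_index: int
    atom_a: int
    atom_b: int
    distance: float
    dha_angle: float | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.dha_angle is not None and not 0.0 <= self.dha_angle <= 180.0:
            raise ValueError("dha_angle must lie in [0, 180] degrees")


def _check_groups(group_a: set[int], group_b: set[int]) -> None:
    if not group_a or not group_b:
        raise ValueError("contact groups must be nonempty")
    if group_a & group_b:
        raise ValueError("contact groups must be disjoint")


def _pair_distances_mi(xa: np.ndarray, xb: np.ndarray, box) -> np.ndarray:
    d = xa[:, None, :] - xb[None, :, :]
    return np.linalg.norm(minimum_image(d, box), axis=-1)


def detect_vdw_contacts(
    frame: Frame,
    topology: Topology,
    group_a: Iterable[int],
    group_b: Iterable[int],
    fudge: float = 0.5,
    include_hydrogens: bool = False,
    frame_index: int = 0,
    method: str = "tree",
) -> list[ContactRecord]:
    """Inter-group atom pairs with ``|AB| < Rvdw(A)+Rvdw(B)+fudge`` (strict).

    Heavy atoms only by default.  ``method="tree"`` (cKD-tree candidate
    search, exact) or ``"brute"`` (all-pairs reference).
    """
    ga, gb = set(group_a), set(group_b)
    _check_groups(ga, gb)
    radii = topology.radii
    elements = topology.elements

    def keep(aid: int) -> bool:
        return include_hydrogens or elements[topology.index_of(aid)] != "H"

    ids_a = sorted(a for a in ga if keep(a))
    ids_b = sorted(b for b in gb if keep(b))
    if not ids_a or not ids_b:
        return []
    ia, ib = topology.indices(ids_a), topology.indices(ids_b)
    xa, xb = frame.coordinates[ia], frame.coordinates[ib]
    ra, rb = radii[ia], radii[ib]

    out: list[ContactRecord] = []
    if method == "brute":
        dist = _pair_distances_mi(xa, xb, frame.box)
        cut = ra[:, None] + rb[None, :] + fudge
        for i, j in zip(*np.nonzero(dist < cut)):
            out.append(ContactRecord("vdw", frame_index, ids_a[i], ids_b[j], float(dist[i, j])))
        return out

    box = np.asarray(frame.box, dtype=float)
    r_cut = float(ra.max() + rb.max() + fudge)
    # wrap into [0, L) for the periodic tree; the per-pair criterion is re-applied
    def wrap(x):
        w = np.mod(x, box)
        return np.where(w >= box, 0.0, w)  # np.mod(-eps, L) can round to exactly L

    wa, wb = wrap(xa), wrap(xb)
    tree = cKDTree(wb, boxsize=box)
    for i, neigh in enumerate(tree.query_ball_point(wa, r_cut)):
        if not neigh:
            continue
        d = np.linalg.norm(minimum_image(xa[i] - xb[neigh], box), axis=-1)
        for j, dij in zip(neigh, d):
            if dij < ra[i] + rb[j] + fudge:
                out.append(ContactRecord("vdw", frame_index, ids_a[i], ids_b[j], float(dij)))
    out.sort(key=lambda c: (c.atom_a, c.atom_b))
    return out


def _dha_angle(frame: Frame, d_idx: int, h_idx: int, a_idx: int) -> float:
    """D–H–A angle in degrees (vertex at the hydrogen), minimum image."""
    box = frame.box
    v1 = minimum_image(frame.coordinates[d_idx] - frame.coordinates[h_idx], box)
    v2 = minimum_image(frame.coordinates[a_idx] - frame.coordinates[h_idx], box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _angle_ok(angle: float, angle_mode: str) -> bool:
    if angle_mode == "deviation":  # <=70 deg deviation from linearity
        return angle >= 110.0
    if angle_mode == "literal":  # printed window 70..180 deg taken literally
        return angle >= 70.0
    raise ValueError(f"unknown angle_mode {angle_mode!r}; use 'deviation' or 'literal'")


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    group_a: Iterable[int],
    group_b: Iterable[int],
    d_max: float = 3.5,
    angle_mode: str = "deviation",
    frame_index: int = 0,
) -> list[ContactRecord]:
    """Hydrogen bonds between two groups: donor–acceptor distance < ``d_max``
    (strict) and the D–H–A angle criterion of ``angle_mode``.

    Both directions are scanned (donor in a / acceptor in b and the
    converse).  Records carry the donor as ``atom_a`` and acceptor as
    ``atom_b``.  Donors without a bonded hydrogen are skipped with a warning.
    """
    import warnings

    ga, gb = set(group_a), set(group_b)
    _check_groups(ga, gb)

    def donors_of(grp: set[int]) -> list[tuple[int, list[int]]]:
        result = []
        for aid in sorted(grp):
            rec = topology.atoms[topology.index_of(aid)]
            if rec.hbond_role != "donor-heavy":
                continue
            hyds = [
                b
                for b in topology.bonded_to(aid)
                if topology.atoms[topology.index_of(b)].hbond_role == "hydrogen"
            ]
            if not hyds:
                warnings.warn(f"donor atom {aid} has no bonded hydrogen; skipped", stacklevel=2)
                continue
            result.append((aid, hyds))
        return result

    def acceptors_of(grp: set[int]) -> list[int]:
        return [
            aid
            for aid in sorted(grp)
            if topology.atoms[topology.index_of(aid)].hbond_role == "acceptor"
        ]

    out: list[ContactRecord] = []
    for donors, acceptors in ((donors_of(ga), acceptors_of(gb)), (donors_of(gb), acceptors_of(ga))):
        for d_id, hyds in donors:
            di = topology.index_of(d_id)
            for a_id in acceptors:
                ai = topology.index_of(a_id)
                dist = float(
                    np.linalg.norm(
                        minimum_image(frame.coordinates[di] - frame.coordinates[ai], frame.box)
                    )
                )
                if not dist < d_max:
                    continue
                # best (most linear) hydrogen decides the geometry
                best = max(_dha_angle(frame, di, topology.index_of(h), ai) for h in hyds)
                if _angle_ok(best, angle_mode):
                    out.append(ContactRecord("hbond", frame_index, d_id, a_id, dist, best))
    out.sort(key=lambda c: (c.atom_a, c.atom_b))
    return out


def _residue_key(topology: Topology, atom_id: int) -> str:
    rec = topology.atoms[topology.index_of(atom_id)]
    return f"{rec.chain}:{rec.resname}:{rec.resid}"


def contact_timeseries(
    traj: Trajectory,
    group_a: Iterable[int],
    group_b: Iterable[int],
    fudge: float = 0.5,
    d_max: float = 3.5,
    angle_mode: str = "deviation",
) -> pd.DataFrame:
    """Per-frame hydrogen-bond and vdW contact counts.

    Returns a DataFrame with columns ``frame``, ``time``, ``n_hbond``
    (atom-pair granularity), ``n_hbond_res`` (distinct residue pairs) and
    ``n_vdw``; arithmetic means over frames are available as
    ``df.attrs["means"]``.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    ga, gb = set(group_a), set(group_b)
    rows = []
    for k, fr in enumerate(traj.frames):
        hb = detect_hbonds(fr, traj.topology, ga, gb, d_max=d_max, angle_mode=angle_mode, frame_index=k)
        vdw = detect_vdw_contacts(fr, traj.topology, ga, gb, fudge=fudge, frame_index=k)
        res_pairs = {
            (_residue_key(traj.topology, c.atom_a), _residue_key(traj.topology, c.atom_b))
            for c in hb
        }
        rows.append((k, fr.time, len(hb), len(res_pairs), len(vdw)))
    df = pd.DataFrame(rows, columns=["frame", "time", "n_hbond", "n_hbond_res", "n_vdw"])
    df.attrs["means"] = {
        "n_hbond": float(df["n_hbond"].mean()),
        "n_hbond_res": float(df["n_hbond_res"].mean()),
        "n_vdw": float(df["n_vdw"].mean()),
    }
    return df


def contact_frequency(
    traj: Trajectory,
    group_a: Iterable[int],
    group_b: Iterable[int],
    fudge: float = 0.5,
    d_max: float = 3.5,
    angle_mode: str = "deviation",
) -> pd.DataFrame:
    """Residue-pair contact frequencies over the trajectory.

    Fraction is (frames in which the residue pair shows >= 1 contact of that
    kind) / (total frames); mean distance and mean D–H–A angle are averaged
    over the contributing contacts.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    ga, gb = set(group_a), set(group_b)
    seen: dict[tuple[str, str, str], dict] = {}
    for k, fr in enumerate(traj.frames):
        records = detect_hbonds(fr, traj.topology, ga, gb, d_max=d_max, angle_mode=angle_mode, frame_index=k)
        records += detect_vdw_contacts(fr, traj.topology, ga, gb, fudge=fudge, frame_index=k)
        per_frame: set[tuple[str, str, str]] = set()
        for c in records:
            ra = _residue_key(traj.topology, c.atom_a)
            rb = _residue_key(traj.topology, c.atom_b)
            key = (c.kind, *sorted((ra, rb)))
            entry = seen.setdefault(
                key, {"frames": set(), "dists": [], "angles": []}
            )
            entry["dists"].append(c.distance)
            if c.dha_angle is not None:
                entry["angles"].append(c.dha_angle)
            per_frame.add(key)
        for key in per_frame:
            seen[key]["frames"].add(k)
    rows = []
    for (kind, ra, rb), entry in sorted(seen.items()):
        rows.append(
            {
                "residue_a": ra,
                "residue_b": rb,
                "kind": kind,
                "fraction": len(entry["frames"]) / traj.n_frames,
                "mean_distance": float(np.mean(entry["dists"])),
                "mean_angle": float(np.mean(entry["angles"])) if entry["angles"] else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["residue_a", "residue_b", "kind", "fraction", "mean_distance", "mean_angle"])


def flare_edges(freq: pd.DataFrame) -> list[dict]:
    """Flare-plot edge list: one edge per residue pair, weight = max fraction over kinds."""
    edges: dict[tuple[str, str], float] = {}
    for _, row in freq.iterrows():
        key = (row["residue_a"], row["residue_b"])
        edges[key] = max(edges.get(key, 0.0), float(row["fraction"]))
    return [
        {"res_a": a, "res_b": b, "weight": w} for (a, b), w in sorted(edges.items())
    ]


def write_flare_json(freq: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"edges": flare_edges(freq)}, indent=1))
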