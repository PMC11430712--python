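"""Config-driven orchestration: run any subset of analysis stages on a
blocked/unblocked system pair and emit a comparative report.

The pipeline mirrors the with-blocker / without-blocker comparison design:
both systems are either loaded from user-supplied files or generated by the
synthetic pseudo-channel module, every requested stage writes its CSV/JSON
artifacts into the output directory, and ``summary.json`` collects the
headline numbers (mean H-bond and vdW contact counts, mean contact area,
minimum pore radius and its z, visit and translocation counts per system,
RMSIP between the two ensembles, and the IC50 when dose data are present).

Every output embeds the config hash, the seed and the package version, so
two runs from the same config are comparable byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Trajectory, ZRegion, read_system, write_system, default_radii_table
from .contacts import contact_frequency, contact_timeseries, write_flare_json
from .dose import HillModel, hill_response
from .ensemble import pca_modes, rmsip
from .pore import (
    applied_voltage,
    count_translocations,
    ion_density_profile,
    ion_visits,
    ion_z_traces,
    pore_radius_profile,
    potential_profile,
)
from .surface import contact_area
from .synthetic import IonScript, PoreSpec, build_pore_system, constricted_radius, simulate_ions

log = logging.getLogger("poreblock")

STAGES = (
    "generate",
    "contacts",
    "sasa",
    "pore-radius",
    "ion-density",
    "visits",
    "translocations",
    "potential",
    "rmsip",
    "ic50",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "output_dir": "poreblock_out",
    "dt": 1.0,
    "generate": {
        "n_frames": 240,
        "n_ions": 10,
        "field_E": -0.003,  # V/Å; with Lz = 100 Å this applies -300 mV
        "diffusion": 10.0,
        "lateral_diffusion": 0.5,
        "jitter": 0.05,
        "open_radius": 8.0,
        "filter_radius": 6.2,
        "filter_z": [0.0, 20.0],
        "n_rings": 11,
        "atoms_per_ring": 14,
        "atom_vdw": 1.7,
        "slab_z": [-20.0, 20.0],
        "box": [40.0, 40.0, 100.0],
        "blocker_radius": 2.0,
    },
    "region": {"zmin": 0.0, "zmax": 20.0, "radial_cutoff": 8.0},
    "contacts": {"fudge": 0.5, "d_max": 3.5, "angle_mode": "deviation"},
    "sasa": {"probe": 1.4, "n_points": 480},
    "contact_area": {"formula": "buried_interface", "stride": 10},
    "pore_radius": {"step": 0.5, "zmin": -20.0, "zmax": 20.0},
    "density": {"zmin": -45.0, "zmax": 45.0, "width": 1.0},
    "potential": {"zmin": -45.0, "zmax": 45.0, "width": 1.0, "radial_cutoff": None},
    "rmsip": {"n_modes": 10},
    "dose": {
        "csv": None,  # user table (concentration, response); else a synthetic one is generated
        "ic50_true": 18.62,
        "hill_slope_true": 1.0,
        "concentrations": [1.0, 10.0, 20.0, 50.0],
        "noise_sd": 0.0,
    },
}


def _deep_update(base: dict, extra: Mapping) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Merge defaults <- YAML file <- overrides into a validated RunConfig dict."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _deep_update(cfg, user)
    if overrides:
        cfg = _deep_update(cfg, overrides)
    for key in ("systems",):
        if key in cfg:
            for name, spec in cfg[key].items():
                for p in ("topology", "trajectory", "radii"):
                    if p in spec and not Path(spec[p]).exists():
                        raise FileNotFoundError(f"systems.{name}.{p}: {spec[p]} does not exist")
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header_lines(cfg: Mapping) -> list[str]:
    return [
        f"# poreblock {__version__}",
        f"# config_hash: {config_hash(cfg)}",
        f"# seed: {cfg['seed']}",
    ]


def _write_csv(df: pd.DataFrame, path: Path, cfg: Mapping) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(cfg)) + "\n")
        df.to_csv(fh, index=False)


def _write_json(obj: Any, path: Path, cfg: Mapping) -> None:
    payload = {
        "poreblock_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "data": obj,
    }
    path.write_text(json.dumps(payload, indent=1, default=float))


def build_demo_pair(cfg: Mapping) -> dict[str, Trajectory]:
    """Generate the blocked/unblocked synthetic pseudo-channel pair."""
    g = cfg["generate"]
    systems: dict[str, Trajectory] = {}
    for name, with_blocker in (("without_blocker", False), ("with_blocker", True)):
        spec = PoreSpec(
            n_rings=g["n_rings"],
            ring_radius=constricted_radius(
                g["open_radius"], g["filter_radius"], tuple(g["filter_z"])
            ),
            atoms_per_ring=g["atoms_per_ring"],
            atom_vdw=g["atom_vdw"],
            slab_z=tuple(g["slab_z"]),
            box=tuple(g["box"]),
        )
        top, frame0 = build_pore_system(
            spec,
            with_blocker=with_blocker,
            n_ions=g["n_ions"],
            blocker_radius=g["blocker_radius"],
            seed=int(cfg["seed"]),
        )
        script = IonScript(
            count=g["n_ions"],
            diffusion=g["diffusion"],
            lateral_diffusion=g["lateral_diffusion"],
        )
        systems[name] = simulate_ions(
            top,
            frame0,
            script,
            n_frames=g["n_frames"],
            field_E=g["field_E"],
            seed=int(cfg["seed"]),
            dt=float(cfg["dt"]),
            spec=spec,
            jitter=g["jitter"],
        )
    return systems


def load_systems(cfg: Mapping) -> dict[str, Trajectory]:
    """User-supplied system pair from config paths, else the generated demo pair."""
    if "systems" in cfg:
        out = {}
        for name, spec in cfg["systems"].items():
            out[name] = read_system(
                spec["topology"], spec["trajectory"], spec.get("radii", default_radii_table()),
                dt=float(cfg["dt"]),
            )
        return out
    return build_demo_pair(cfg)


def _region(cfg: Mapping) -> ZRegion:
    r = cfg["region"]
    return ZRegion(zmin=r["zmin"], zmax=r["zmax"], radial_cutoff=r.get("radial_cutoff") or np.inf)


def _dose_table(cfg: Mapping) -> pd.DataFrame:
    d = cfg["dose"]
    if d.get("csv"):
        return pd.read_csv(d["csv"], comment="#")
    conc = np.asarray(d["concentrations"], dtype=float)
    resp = hill_response(conc, d["ic50_true"], d["hill_slope_true"])
    if d.get("noise_sd", 0.0) > 0:
        rng = np.random.default_rng(int(cfg["seed"]))
        resp = resp + rng.normal(scale=d["noise_sd"], size=resp.shape)
    return pd.DataFrame({"concentration": conc, "response": resp})


def run_pipeline(
    config: Mapping | str | Path | None = None,
    stages: list[str] | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Run the requested stages and return the machine-readable summary.

    ``config`` may be a YAML path, a config mapping or None (all defaults).
    Unknown stage names raise immediately, listing the valid ones; artifacts
    of completed stages are kept if a later stage fails.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}")

    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    region = _region(cfg)
    need_systems = any(s != "ic50" for s in stages)
    systems = load_systems(cfg) if need_systems else {}

    summary: dict[str, Any] = {
        "poreblock_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "systems": {name: {} for name in systems},
    }
    g = cfg.get("generate", {})
    if "field_E" in g and systems:
        Lz = next(iter(systems.values())).frames[0].box[2]
        summary["applied_voltage_V"] = applied_voltage(g["field_E"], Lz)

    if "generate" in stages:
        for name, traj in systems.items():
            write_system(
                traj,
                outdir / f"{name}.pdb",
                outdir / f"{name}_traj.pdb",
                outdir / "radii.dat",
            )
            log.info("wrote %s system (%d atoms, %d frames)", name, traj.topology.n_atoms, traj.n_frames)

    for name, traj in systems.items():
        top = traj.topology
        ssum = summary["systems"][name]
        has_ligand = bool(top.named_groups.get("ligand"))
        lining = top.group("pore_lining")
        ions = top.group("ions_K")

        if "contacts" in stages and has_ligand:
            cc = cfg["contacts"]
            ts = contact_timeseries(
                traj, top.group("ligand"), lining,
                fudge=cc["fudge"], d_max=cc["d_max"], angle_mode=cc["angle_mode"],
            )
            _write_csv(ts, outdir / f"{name}_contacts.csv", cfg)
            freq = contact_frequency(
                traj, top.group("ligand"), lining,
                fudge=cc["fudge"], d_max=cc["d_max"], angle_mode=cc["angle_mode"],
            )
            _write_csv(freq, outdir / f"{name}_contact_frequency.csv", cfg)
            write_flare_json(freq, outdir / f"{name}_flare.json")
            ssum["mean_hbonds"] = ts.attrs["means"]["n_hbond"]
            ssum["mean_hbonds_residue_pairs"] = ts.attrs["means"]["n_hbond_res"]
            ssum["mean_vdw_contacts"] = ts.attrs["means"]["n_vdw"]

        if "sasa" in stages and has_ligand:
            sc, ca = cfg["sasa"], cfg["contact_area"]
            stride = max(int(ca.get("stride", 1)), 1)
            sub = Trajectory(top, traj.frames[::stride], dt=traj.dt * stride)
            df = contact_area(
                sub, ligand_group=top.group("ligand"), receptor_group=lining,
                formula=ca["formula"], probe=sc["probe"], n_points=sc["n_points"],
            )
            _write_csv(df, outdir / f"{name}_contact_area.csv", cfg)
            ssum["mean_contact_area_A2"] = df.attrs["mean"]
            ssum["contact_area_formula"] = ca["formula"]

        if "pore-radius" in stages:
            pr = cfg["pore_radius"]
            obstructing = sorted(lining | (top.group("ligand") if has_ligand else set()))
            prof = pore_radius_profile(
                traj.frames[-1], top, obstructing, (pr["zmin"], pr["zmax"]), step=pr["step"],
            )
            _write_csv(prof.to_frame(), outdir / f"{name}_pore_radius.csv", cfg)
            zmin, rmin = prof.min()
            ssum["min_pore_radius_A"] = rmin
            ssum["min_pore_radius_z_A"] = zmin

        if "ion-density" in stages:
            dz = cfg["density"]
            total, local = ion_density_profile(
                traj, ions, (dz["zmin"], dz["zmax"], dz["width"]), region=region
            )
            df = total.to_frame()
            df["local_over_total"] = local.values
            _write_csv(df, outdir / f"{name}_ion_density.csv", cfg)

        if "visits" in stages:
            vs = ion_visits(traj, ions, region)
            df = pd.DataFrame(
                [
                    {
                        "ion_id": v.ion_id, "enter_frame": v.enter_frame, "exit_frame": v.exit_frame,
                        "residence_ns": v.residence_ns, "outcome": v.outcome,
                        "entry_side": v.entry_side, "exit_side": v.exit_side,
                    }
                    for v in vs
                ],
                columns=["ion_id", "enter_frame", "exit_frame", "residence_ns", "outcome", "entry_side", "exit_side"],
            )
            _write_csv(df, outdir / f"{name}_visits.csv", cfg)
            traces = ion_z_traces(traj, ions, region)
            _write_csv(traces, outdir / f"{name}_ion_z_traces.csv", cfg)
            ssum["n_visits"] = len(vs)
            ssum["n_visiting_ions"] = len({v.ion_id for v in vs})
            ssum["max_residence_ns"] = max((v.residence_ns for v in vs), default=0.0)

        if "translocations" in stages:
            tr = count_translocations(traj, ions, region)
            _write_json(tr, outdir / f"{name}_translocations.json", cfg)
            ssum["translocations_total"] = tr["total"]
            ssum["translocations_up"] = tr["up"]
            ssum["translocations_down"] = tr["down"]

        if "potential" in stages:
            pz = cfg["potential"]
            rc = pz.get("radial_cutoff") or np.inf
            prof = potential_profile(traj, (pz["zmin"], pz["zmax"], pz["width"]), radial_cutoff=rc)
            _write_csv(prof.to_frame(), outdir / f"{name}_potential.csv", cfg)
            ssum["potential_min_V"] = float(prof.values.min())
            ssum["potential_max_V"] = float(prof.values.max())

    if "rmsip" in stages and len(systems) == 2:
        n_modes = cfg["rmsip"]["n_modes"]
        (name_a, ta), (name_b, tb) = systems.items()
        sel_a = sorted(ta.topology.group("pore_lining"))
        sel_b = sorted(tb.topology.group("pore_lining"))
        m = min(len(sel_a), len(sel_b))
        modes_a = pca_modes(ta, sel_a[:m], n_modes=n_modes)
        modes_b = pca_modes(tb, sel_b[:m], n_modes=n_modes)
        value = rmsip(modes_a, modes_b, n=n_modes)
        modes_a.save(outdir / f"{name_a}_modes.txt")
        modes_b.save(outdir / f"{name_b}_modes.txt")
        summary["rmsip_pore_lining"] = value

    if "ic50" in stages:
        table = _dose_table(cfg)
        res = HillModel.from_dataframe(table).fit()
        _write_csv(table, outdir / "dose_response.csv", cfg)
        _write_json(res.to_dict(), outdir / "hill_fit.json", cfg)
        if res.converged:
            summary["ic50_uM"] = res.ic50
            summary["hill_slope"] = res.hill_slope
        else:
            summary["ic50_uM"] = None
            summary["ic50_message"] = res.message

    _write_json(summary, outdir / "summary.json", cfg)
    return summary
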