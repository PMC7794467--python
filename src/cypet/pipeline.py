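"""Configured pipeline stages: dock → select → describe → pathways.

Each stage is a plain function taking the validated configuration dict, so
the command-line layer stays thin and the stages can be scripted directly.
All randomness flows from the single top-level ``seed``; every output table
carries the config hash and seed in its metadata header.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import bd as bd_mod
from . import descriptors as dsc
from . import io as io_mod
from . import pathways as pw
from . import selection as sel_mod
from .config import ConfigError
from .structure import (DomainMap, Ensemble, Structure, read_ensemble,
                        read_structure, select, select_atoms, write_pdb)

__all__ = ["stage_dock", "stage_select", "stage_describe", "stage_pathways",
           "write_demo_fixtures", "membrane_from_config", "domain_map_from_config",
           "MEMBRANE_DESCRIPTORS"]


def domain_map_from_config(cfg: dict) -> DomainMap:
    return DomainMap.with_defaults(cfg.get("domain_map") or {})


def membrane_from_config(cfg: dict, structure: Structure | None = None):
    mcfg = (cfg.get("descriptors") or {}).get("membrane")
    if mcfg is None:
        return None
    if mcfg.get("infer"):
        if structure is None:
            raise ConfigError("membrane inference requested but no structure given")
        return dsc.infer_membrane_frame(structure)
    try:
        return dsc.MembraneFrame(np.asarray(mcfg["normal"], float),
                                 np.asarray(mcfg["midplane_point"], float),
                                 float(mcfg["half_thickness"]))
    except KeyError as exc:
        raise ConfigError(f"membrane config missing key {exc}") from exc


def _load_charges(path) -> np.ndarray:
    df, _ = io_mod.read_tsv(path)
    if "charge" not in df.columns:
        raise ConfigError(f"charge table {path} lacks a 'charge' column")
    return df["charge"].to_numpy(dtype=float)


def _build_body(cfg: dict, which: str) -> bd_mod.RigidBodyModel:
    inputs = cfg.get("inputs") or {}
    spath = inputs.get(f"{which}_structure")
    if not spath:
        raise ConfigError(f"inputs.{which}_structure is required for docking")
    structure = read_structure(spath)
    cpath = inputs.get(f"{which}_charges")
    charges = _load_charges(cpath) if cpath else None
    body = bd_mod.RigidBodyModel.from_structure(structure, charges=charges)
    marker_cfg = (cfg.get("bd") or {}).get(f"{which}_marker")
    if marker_cfg is None:
        marker_cfg = ({"name": "FE", "res_name": "HEM"} if which == "fixed"
                      else {"name": "N5", "res_name": "FMN"})
    try:
        body.marker_atoms["redox"] = structure.atom_index(**marker_cfg)
    except KeyError:
        pass  # body without a redox marker: distances recorded as inf
    anchor_cfg = (cfg.get("selection") or {}).get("anchor_atom")
    if which == "mobile" and anchor_cfg:
        body.marker_atoms["anchor"] = structure.atom_index(**anchor_cfg)
    return body


def _bd_params(cfg: dict) -> bd_mod.BDParameters:
    bcfg = dict(cfg.get("bd") or {})
    bcfg.pop("fixed_marker", None)
    bcfg.pop("mobile_marker", None)
    bcfg.setdefault("seed", int(cfg.get("seed", 0)))
    return bd_mod.BDParameters(**bcfg)


def stage_dock(cfg: dict, out_path=None) -> tuple[bd_mod.EncounterSet, pd.DataFrame]:
    """Run BD docking per config; write the encounter TSV if a path is given."""
    params = _bd_params(cfg)
    if params.n_trajectories < 1:
        raise ConfigError("bd.n_trajectories must be >= 1")
    fixed = _build_body(cfg, "fixed")
    mobile = _build_body(cfg, "mobile")
    encounters = bd_mod.run_docking(fixed, mobile, params)
    df = io_mod.encounters_to_frame(encounters)
    if out_path is not None:
        meta = {"config_hash": io_mod.config_hash(cfg), "seed": params.seed,
                "n_trajectories": params.n_trajectories,
                "d_fe_n5_max": params.d_fe_n5_max, "d_domain_max": params.d_domain_max}
        io_mod.write_tsv(out_path, df, meta)
    return encounters, df


def stage_select(cfg: dict, encounters: pd.DataFrame | bd_mod.EncounterSet,
                 out_path=None) -> pd.DataFrame:
    """Rank → cluster → filter encounter records into named representatives."""
    scfg = cfg.get("selection") or {}
    if isinstance(encounters, pd.DataFrame):
        encounters = io_mod.frame_to_encounters(encounters)
    mobile = _build_body(cfg, "mobile")
    records = sel_mod.rank_top(list(encounters), n=int(scfg.get("top_n", 5000)))
    if not records:
        df = pd.DataFrame(columns=["name", "record", "trajectory", "step", "energy",
                                   "cluster_rank", "reason"])
        if out_path is not None:
            io_mod.write_tsv(out_path, df, {"config_hash": io_mod.config_hash(cfg)})
        return df
    k = min(int(scfg.get("k_clusters", 10)), len(records))
    clusters = sel_mod.cluster_poses(records, mobile, k=k)
    membrane = membrane_from_config(cfg)
    report = sel_mod.select_representatives(
        clusters, mobile, membrane=membrane,
        energy_max=scfg.get("energy_max"),
        distinct_rmsd=float(scfg.get("distinct_rmsd", 1.0)),
        tether_residues=int(scfg.get("tether_residues", 15)),
        max_extension_per_residue=float(scfg.get("max_extension_per_residue", 3.5)),
        chain_id=str(scfg.get("chain_id", "A")))
    rows = []
    rank_of = {rep: rank + 1 for rank, rep in enumerate(clusters.ranked_representatives())}
    name_of = {idx: name for name, idx in report.survivors.items()}
    for rep_idx, reason in report.reasons.items():
        rec = clusters.records[rep_idx]
        rows.append({"name": name_of.get(rep_idx, ""), "record": rep_idx,
                     "trajectory": rec.trajectory, "step": rec.step,
                     "energy": rec.energy, "cluster_rank": rank_of.get(rep_idx, -1),
                     "reason": reason})
    df = pd.DataFrame(rows).sort_values("cluster_rank").reset_index(drop=True)
    if out_path is not None:
        io_mod.write_tsv(out_path, df, {"config_hash": io_mod.config_hash(cfg),
                                        "seed": cfg.get("seed", 0)})
    return df


MEMBRANE_DESCRIPTORS = {"alpha", "beta", "gamma", "heme_tilt", "D_CYP_mem",
                        "D_FG_mem", "D_FMNdomain_mem", "D_linker_mem"}


def _descriptor_row(structure: Structure, cfg: dict, membrane, dm: DomainMap) -> dict:
    dcfg = cfg.get("descriptors") or {}
    requested = dcfg.get("compute")
    mass_weighted = bool(dcfg.get("mass_weighted", True))
    if requested:
        need_mem = sorted(set(requested) & MEMBRANE_DESCRIPTORS)
        if need_mem and membrane is None:
            raise ConfigError(f"descriptors {need_mem} require a membrane frame; "
                              "set descriptors.membrane in config")
    row: dict[str, float] = {k: math.nan for k in dsc.DescriptorSet.NAMES}

    def attempt(name, fn):
        if requested and name not in requested:
            return
        try:
            row[name] = fn()
        except (KeyError, ValueError) as exc:
            if requested and name in requested:
                raise ConfigError(f"descriptor {name!r} failed: {exc}") from exc

    attempt("D_Fe_N5", lambda: dsc.pair_distance(
        structure, {"name": "FE", "res_name": "HEM"}, {"name": "N5", "res_name": "FMN"}))
    attempt("D_CYP_FMNdomain", lambda: dsc.domain_com_distance(
        structure, "cyp_globular", "fmn_domain", mass_weighted, dm))
    attempt("theta", lambda: dsc.compute_theta(structure, "c_helix", "fmn_alpha1_helix", dm))
    attempt("D_FAD_NADP", lambda: dsc.domain_com_distance(
        structure, "fad_domain", "nadp_domain", mass_weighted, dm))
    attempt("D_CYP_NADPdomain", lambda: dsc.domain_com_distance(
        structure, "cyp_globular", "nadp_domain", mass_weighted, dm))
    if membrane is not None:
        def angles():
            return dsc.membrane_orientation_angles(structure, membrane, dm, mass_weighted)
        attempt("alpha", lambda: angles()[0])
        attempt("beta", lambda: angles()[1])
        attempt("gamma", lambda: angles()[2])
        attempt("heme_tilt", lambda: dsc.heme_plane_tilt(structure, membrane))
        attempt("D_CYP_mem", lambda: dsc.axial_membrane_distance(
            structure, "cyp_globular", membrane, mass_weighted, dm))
        attempt("D_FG_mem", lambda: dsc.axial_membrane_distance(
            structure, "fg_loop", membrane, mass_weighted, dm))
        attempt("D_FMNdomain_mem", lambda: dsc.axial_membrane_distance(
            structure, "fmn_domain", membrane, mass_weighted, dm))
        attempt("D_linker_mem", lambda: dsc.axial_membrane_distance(
            structure, structure.take([structure.atom_index(name="N", res_id=66)]),
            membrane, mass_weighted, dm))
    icfg = dcfg.get("interface")
    if icfg:
        attempt("interface_area", lambda: dsc.interface_area(
            structure, icfg["sel_a"], icfg["sel_b"],
            probe=float(icfg.get("probe", 1.4)),
            convention=icfg.get("convention", "buried_total"), domain_map=dm))
    return row


def stage_describe(cfg: dict, obj: Structure | Ensemble | str | Path,
                   out_path=None) -> pd.DataFrame:
    """Per-frame descriptor table (one row per frame, units in the header)."""
    if isinstance(obj, (str, Path)):
        obj = read_ensemble(obj)
    frames = obj.frames if isinstance(obj, Ensemble) else [obj]
    dm = domain_map_from_config(cfg)
    membrane = membrane_from_config(cfg, frames[0])
    rows = []
    for i, frame in enumerate(frames):
        row = {"frame": i}
        row.update(_descriptor_row(frame, cfg, membrane, dm))
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_path is not None:
        io_mod.write_tsv(out_path, df, {
            "config_hash": io_mod.config_hash(cfg), "seed": cfg.get("seed", 0),
            "units": "distances Å, angles deg, areas Å²"})
    return df


def stage_pathways(cfg: dict, obj: Structure | Ensemble | str | Path,
                   out_prefix=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame best Beratan path plus the residue-level pathway census."""
    if isinstance(obj, (str, Path)):
        obj = read_ensemble(obj)
    pcfg = cfg.get("pathways") or {}
    donor = pcfg.get("donor", {"name": "N5", "res_name": "FMN"})
    acceptor = pcfg.get("acceptor", {"name": "FE", "res_name": "HEM"})
    params = pw.PathwayParams(prefactor=float(pcfg.get("prefactor", 1e13)))
    census = pw.pathway_census(obj, donor, acceptor, params)
    rows = []
    for i, res in enumerate(census.per_frame):
        rows.append({"frame": i, "label": res.label, "eps_total": res.eps_total,
                     "k_et_per_s": res.k_et,
                     "log10_k_et": res.log10_k_et if res.connected else math.nan})
    paths_df = pd.DataFrame(rows)
    census_df = pd.DataFrame(
        [{"label": lab, "percent": pct} for lab, pct in census.percentages.items()]
        + ([{"label": "no-path", "percent": math.nan}] if census.n_no_path else []))
    if out_prefix is not None:
        meta = {"config_hash": io_mod.config_hash(cfg), "seed": cfg.get("seed", 0)}
        io_mod.write_tsv(str(out_prefix) + "_paths.tsv", paths_df, meta)
        io_mod.write_tsv(str(out_prefix) + "_census.tsv", census_df, meta)
    return paths_df, census_df


# ---------------------------------------------------------------------------
# demo fixtures
# ---------------------------------------------------------------------------

def write_demo_fixtures(outdir, seed: int = 0, n_trajectories: int = 50) -> Path:
    """Write a self-contained toy fixture set (PDB + charges + config) into
    ``outdir`` so the whole pipeline can run without any external input."""
    from . import synthetic as syn

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair = syn.make_toy_redox_pair(seed=seed)
    write_pdb(pair.body_a.structure, outdir / "body_a.pdb")
    write_pdb(pair.body_b.structure, outdir / "body_b.pdb")
    for name, body in (("fixed", pair.body_a), ("mobile", pair.body_b)):
        io_mod.write_tsv(outdir / f"{name}_charges.tsv",
                         pd.DataFrame({"charge": body.charges}),
                         {"body": name, "seed": seed})
    system = syn.make_membrane_system(alpha=25.0, beta=90.0, tilt=40.0,
                                      axial_offset=30.0, seed=seed)
    write_pdb(system.structure, outdir / "membrane_system.pdb")
    write_pdb(syn.make_mini_redox_site(), outdir / "mini_redox_site.pdb")
    params = syn.toy_bd_params(seed=seed, n_trajectories=n_trajectories, max_steps=6000)
    cfg = {
        "inputs": {
            "fixed_structure": str(outdir / "body_a.pdb"),
            "mobile_structure": str(outdir / "body_b.pdb"),
            "fixed_charges": str(outdir / "fixed_charges.tsv"),
            "mobile_charges": str(outdir / "mobile_charges.tsv"),
            "structure": str(outdir / "membrane_system.pdb"),
        },
        "bd": {"b_radius": params.b_radius, "q_radius": params.q_radius,
               "dt_far": params.dt_far, "dt_near": params.dt_near,
               "dt_switch": params.dt_switch, "max_steps": params.max_steps,
               "n_trajectories": n_trajectories},
        "selection": {"top_n": 500, "k_clusters": 5, "distinct_rmsd": 2.0,
                      "chain_id": "A",
                      "anchor_atom": {"name": "ANC"}},
        "domain_map": {"c_helix": [[130, 145]], "cyp_globular": [[1, 350]]},
        "descriptors": {"membrane": {"normal": [0, 0, 1],
                                     "midplane_point": [0, 0, 0],
                                     "half_thickness": 19.0}},
        "pathways": {"donor": {"name": "N5", "res_name": "FMN"},
                     "acceptor": {"name": "FE", "res_name": "HEM"}},
        "seed": int(seed),
        "output_dir": str(outdir),
    }
    import yaml

    cfg_path = outdir / "demo_config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path
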