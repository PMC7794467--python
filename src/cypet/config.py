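"""Pipeline configuration: YAML/JSON key–value files with strict validation.

Unknown keys are rejected so that typos fail before any computation; the
validated configuration is serializable and echoed into every run log.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["ConfigError", "load_config", "validate_config", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


# section -> {key: (type(s), required)}
_SCHEMA: dict[str, dict] = {
    "inputs": {
        "fixed_structure": (str, False),
        "mobile_structure": (str, False),
        "structure": (str, False),          # for describe/pathways stages
        "fixed_charges": (str, False),      # TSV with a 'charge' column
        "mobile_charges": (str, False),
    },
    "domain_map": None,                      # free-form name -> ranges
    "bd": {
        "temperature": ((int, float), False),
        "ionic_strength": ((int, float), False),
        "dielectric": ((int, float), False),
        "b_radius": ((int, float), False),
        "q_radius": ((int, float), False),
        "n_trajectories": (int, False),
        "max_steps": (int, False),
        "dt_far": ((int, float), False),
        "dt_near": ((int, float), False),
        "dt_switch": ((int, float), False),
        "cutoff": ((int, float), False),
        "d_fe_n5_max": ((int, float), False),
        "d_domain_max": ((int, float), False),
        "dedup_rmsd": ((int, float), False),
        "fixed_marker": (dict, False),      # atom reference, e.g. {name: FE, res_name: HEM}
        "mobile_marker": (dict, False),
    },
    "selection": {
        "top_n": (int, False),
        "k_clusters": (int, False),
        "energy_max": ((int, float, type(None)), False),
        "distinct_rmsd": ((int, float), False),
        "tether_residues": (int, False),
        "max_extension_per_residue": ((int, float), False),
        "chain_id": (str, False),
        "anchor_atom": (dict, False),
    },
    "descriptors": {
        "membrane": (dict, False),          # {normal, midplane_point, half_thickness} or {infer: true}
        "mass_weighted": (bool, False),
        "interface": (dict, False),         # {sel_a: name, sel_b: name, convention: ...}
        "compute": (list, False),
    },
    "pathways": {
        "donor": (dict, False),
        "acceptor": (dict, False),
        "prefactor": ((int, float), False),
    },
    "output_dir": None,
    "seed": None,
    "log_level": None,
}
_TOP_SCALARS = {"output_dir": str, "seed": int, "log_level": str}


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    for key, typ in _TOP_SCALARS.items():
        if key in cfg and not isinstance(cfg[key], typ):
            raise ConfigError(f"{key} must be {typ.__name__}")
    for section, schema in _SCHEMA.items():
        if schema is None or section not in cfg:
            continue
        sub = cfg[section]
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = set(sub) - set(schema)
        if bad:
            raise ConfigError(f"unknown keys in section {section!r}: {sorted(bad)}")
        for k, (types, required) in schema.items():
            if k in sub and sub[k] is not None and not isinstance(sub[k], types):
                raise ConfigError(f"{section}.{k} has wrong type {type(sub[k]).__name__}")
            if required and k not in sub:
                raise ConfigError(f"{section}.{k} is required")
    if "domain_map" in cfg and not isinstance(cfg["domain_map"], dict):
        raise ConfigError("domain_map must be a mapping of name -> residue ranges")
    return cfg


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


DEFAULT_CONFIG: dict = {
    "bd": {},
    "selection": {},
    "descriptors": {},
    "pathways": {"donor": {"name": "N5", "res_name": "FMN"},
                 "acceptor": {"name": "FE", "res_name": "HEM"}},
    "seed": 0,
}
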