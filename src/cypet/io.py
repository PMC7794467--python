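"""TSV interchange with '#'-prefixed metadata headers.

Every pipeline stage writes and reads plain tab-separated tables whose header
comments carry the package version, a hash of the generating configuration
and the seed, so any stage can be rerun from its predecessor's files alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bd import BDParameters, EncounterRecord, EncounterSet
from .structure import RigidTransform

__all__ = ["write_tsv", "read_tsv", "encounters_to_frame", "frame_to_encounters",
           "config_hash"]


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_tsv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cypet_version: {__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
        try:
            df = pd.read_csv(fh, sep="\t")
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed table {path}: {exc}") from exc
    return df, meta


_ENC_COLUMNS = ["trajectory", "step", "energy", "d_fe_n5", "d_domain",
                "qx", "qy", "qz", "qw", "tx", "ty", "tz"]


def encounters_to_frame(encounters: EncounterSet) -> pd.DataFrame:
    rows = []
    for r in encounters.records:
        rows.append([r.trajectory, r.step, r.energy, r.d_fe_n5, r.d_domain,
                     *r.pose.quat, *r.pose.translation])
    return pd.DataFrame(rows, columns=_ENC_COLUMNS)


def frame_to_encounters(df: pd.DataFrame, params: BDParameters | None = None,
                        n_trajectories: int | None = None) -> EncounterSet:
    missing = [c for c in _ENC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"encounter table missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        q = np.array([row.qx, row.qy, row.qz, row.qw], dtype=float)
        q /= np.linalg.norm(q)
        records.append(EncounterRecord(
            pose=RigidTransform(q, np.array([row.tx, row.ty, row.tz], dtype=float)),
            energy=float(row.energy), d_fe_n5=float(row.d_fe_n5),
            d_domain=float(row.d_domain), trajectory=int(row.trajectory),
            step=int(row.step)))
    if n_trajectories is None:
        n_trajectories = (max((r.trajectory for r in records), default=-1) + 1)
    return EncounterSet(records=records, params=params or BDParameters(),
                        n_trajectories=n_trajectories)
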