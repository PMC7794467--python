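"""Macromolecular structures, ensembles, named selections and rigid-body transforms.

Structures are stored as column-oriented atom tables (numpy arrays) so that
geometric descriptors and the Brownian-dynamics engine can operate on whole
coordinate blocks at once.  Reading goes through :mod:`gemmi` (PDB and mmCIF);
writing emits fixed-column PDB, the canonical interchange format of the
pipeline, including multi-model PDB for ensembles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "Structure",
    "Ensemble",
    "DomainMap",
    "CofactorSpec",
    "RigidTransform",
    "read_structure",
    "read_ensemble",
    "write_pdb",
    "select",
    "select_atoms",
    "apply_transform",
    "DEFAULT_DOMAIN_MAP",
    "HEME_RING_ATOMS",
    "ISOALLOXAZINE_RING_ATOMS",
]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom; the row view of a :class:`Structure`."""

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    xyz: np.ndarray
    mass: float
    het: bool = False


def _element_mass(symbol: str, atom_name: str = "") -> float:
    el = gemmi.Element(symbol if symbol else _infer_element(atom_name))
    if el.weight <= 0:
        raise ValueError(f"cannot resolve a positive mass for element {symbol!r} / atom {atom_name!r}")
    return float(el.weight)


_TWO_LETTER = {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE", "NI", "CO", "MO"}


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name; cannot infer element")
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    return stripped[0]


@dataclass
class Structure:
    """One frame: parallel atom-attribute arrays plus (n, 3) coordinates in Å."""

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain: np.ndarray
    xyz: np.ndarray
    mass: np.ndarray
    het: np.ndarray = None  # type: ignore[assignment]
    frame_id: int = 0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        n = len(self.xyz)
        if self.het is None:
            self.het = np.zeros(n, dtype=bool)
        for attr in ("serial", "name", "element", "res_name", "res_id", "chain", "mass", "het"):
            arr = np.asarray(getattr(self, attr))
            if len(arr) != n:
                raise ValueError(f"attribute {attr} has length {len(arr)} != {n}")
            setattr(self, attr, arr)

    # -- basic container behaviour -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]), name=str(self.name[i]), element=str(self.element[i]),
            res_name=str(self.res_name[i]), res_id=int(self.res_id[i]), chain=str(self.chain[i]),
            xyz=self.xyz[i].copy(), mass=float(self.mass[i]), het=bool(self.het[i]),
        )

    def atoms(self) -> Iterable[AtomRecord]:
        return (self.atom(i) for i in range(self.n_atoms))

    def copy(self) -> "Structure":
        return Structure(**{f.name: np.copy(getattr(self, f.name)) if f.name != "frame_id" else self.frame_id
                            for f in dataclasses.fields(self)})

    def take(self, idx) -> "Structure":
        idx = np.asarray(idx)
        return Structure(
            serial=self.serial[idx], name=self.name[idx], element=self.element[idx],
            res_name=self.res_name[idx], res_id=self.res_id[idx], chain=self.chain[idx],
            xyz=self.xyz[idx], mass=self.mass[idx], het=self.het[idx], frame_id=self.frame_id,
        )

    def with_xyz(self, xyz: np.ndarray) -> "Structure":
        out = self.copy()
        out.xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if out.xyz.shape != self.xyz.shape:
            raise ValueError("replacement coordinates have a different shape")
        return out

    # -- lookups -------------------------------------------------------------------
    def atom_index(self, name: str, res_name: str | None = None, res_id: int | None = None,
                   chain: str | None = None) -> int:
        """Index of the unique atom matching the reference; error if absent/duplicated."""
        mask = self.name == name
        if res_name is not None:
            mask &= self.res_name == res_name
        if res_id is not None:
            mask &= self.res_id == res_id
        if chain is not None:
            mask &= self.chain == chain
        hits = np.flatnonzero(mask)
        ref = f"atom {name!r} (res_name={res_name}, res_id={res_id}, chain={chain})"
        if len(hits) == 0:
            raise KeyError(f"{ref} not found")
        if len(hits) > 1:
            raise KeyError(f"{ref} matches {len(hits)} atoms; reference is ambiguous")
        return int(hits[0])

    def com(self, mass_weighted: bool = True) -> np.ndarray:
        if self.n_atoms == 0:
            raise ValueError("center of mass of an empty structure")
        w = self.mass if mass_weighted else np.ones(self.n_atoms)
        return np.average(self.xyz, axis=0, weights=w)

    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"


@dataclass
class Ensemble:
    """Ordered frames sharing one atom topology (same count and ordering)."""

    frames: list

    def __post_init__(self):
        if not self.frames:
            raise ValueError("empty ensemble")
        n0 = self.frames[0].n_atoms
        names0 = self.frames[0].name
        for f in self.frames[1:]:
            if f.n_atoms != n0 or not np.array_equal(f.name, names0):
                raise ValueError("frames differ in atom count or ordering")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


# Residue ranges quoted in the structural literature for CYP 1A1 / CPR; the
# C-helix range is deliberately absent and must be supplied in user config
# (it has no canonical numeric definition here).
DEFAULT_DOMAIN_MAP: dict[str, list[tuple]] = {
    "cyp_tm_helix": [(None, 7, 26)],
    "fg_loop": [(None, 229, 245)],
    "bc_loop": [(None, 105, 128)],
    "f_helix": [(None, 211, 228)],
    "g_helix": [(None, 246, 272)],
    "i_helix": [(None, 304, 336)],
    "fmn_domain": [(None, 66, 230)],
    "fmn_alpha1_helix": [(None, 91, 105)],
    "fmn_alpha3_helix": [(None, 150, 158)],
}


class DomainMap(dict):
    """Named selections: name -> list of (chain-or-None, first_res, last_res)."""

    @classmethod
    def with_defaults(cls, extra: dict | None = None) -> "DomainMap":
        dm = cls({k: list(v) for k, v in DEFAULT_DOMAIN_MAP.items()})
        if extra:
            for name, ranges in extra.items():
                norm = []
                for r in ranges:
                    chain, lo, hi = (None, r[0], r[1]) if len(r) == 2 else tuple(r)
                    if hi < lo:
                        raise ValueError(f"empty residue range {r} in selection {name!r}")
                    norm.append((chain, int(lo), int(hi)))
                if not norm:
                    raise ValueError(f"selection {name!r} has no ranges")
                dm[name] = norm
        return dm


HEME_RING_ATOMS = (
    "NA", "NB", "NC", "ND",
    "C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B",
    "C1C", "C2C", "C3C", "C4C", "C1D", "C2D", "C3D", "C4D",
    "CHA", "CHB", "CHC", "CHD",
)

# Isoalloxazine ring atoms; FAD's PDB component uses an X where FMN uses an A
# (C4X/C5X/C9X vs C4A/C5A/C9A) so both spellings are accepted.
ISOALLOXAZINE_RING_ATOMS = (
    "N1", "C2", "N3", "C4", "C4A", "C4X", "N5", "C5A", "C5X",
    "C6", "C7", "C8", "C9", "C9A", "C9X", "N10", "C10",
)


@dataclass(frozen=True)
class CofactorSpec:
    """Which atoms of a cofactor carry its markers and define its plane/center."""

    res_name: str
    key_atoms: dict
    ring_atoms: tuple

    @classmethod
    def heme(cls) -> "CofactorSpec":
        return cls("HEM", {"metal": "FE"}, HEME_RING_ATOMS)

    @classmethod
    def fmn(cls) -> "CofactorSpec":
        return cls("FMN", {"n5": "N5"}, ISOALLOXAZINE_RING_ATOMS)

    @classmethod
    def fad(cls) -> "CofactorSpec":
        return cls("FAD", {"n5": "N5"}, ISOALLOXAZINE_RING_ATOMS)


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t; rotation stored as a unit quaternion
    in scipy's (x, y, z, w) convention."""

    quat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        q = np.asarray(self.quat, dtype=float).reshape(4)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm {np.linalg.norm(q):.12f} != 1")
        object.__setattr__(self, "quat", q)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_quat(), np.asarray(translation, float))

    @classmethod
    def from_rotation(cls, rot: Rotation, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(rot.as_quat(), np.asarray(translation, float))

    @classmethod
    def random(cls, rng: np.random.Generator, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(Rotation.random(rng=rng).as_quat(), np.asarray(translation, float))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return self.rotation.apply(np.asarray(xyz, float)) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        r = self.rotation * other.rotation
        t = self.rotation.apply(other.translation) + self.translation
        q = r.as_quat()
        return RigidTransform(q / np.linalg.norm(q), t)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        q = rinv.as_quat()
        return RigidTransform(q / np.linalg.norm(q), -rinv.apply(self.translation))


def apply_transform(structure: Structure, t: RigidTransform) -> Structure:
    """Rigidly move a structure; preserves all internal distances and chirality."""
    return structure.with_xyz(t.apply(structure.xyz))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _collapse_altloc(residue: gemmi.Residue) -> list:
    """Keep one atom per name: highest occupancy, ties broken by altloc letter."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif (atom.occ, -ord(atom.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
            best[atom.name] = atom
    return [best[n] for n in order]


def _model_to_structure(model: gemmi.Model, frame_id: int) -> Structure:
    serial, name, element, res_name, res_id, chain, het, xyz, mass = ([] for _ in range(9))
    for ch in model:
        for res in ch:
            is_het = res.het_flag == "H"
            for atom in _collapse_altloc(res):
                serial.append(atom.serial)
                name.append(atom.name)
                sym = atom.element.name.upper() if atom.element.name else _infer_element(atom.name)
                element.append(sym)
                res_name.append(res.name)
                res_id.append(res.seqid.num)
                chain.append(ch.name)
                het.append(is_het)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                mass.append(_element_mass(sym, atom.name))
    if not serial:
        raise ValueError("model contains no atoms")
    return Structure(
        serial=np.array(serial, dtype=int), name=np.array(name, dtype=object),
        element=np.array(element, dtype=object), res_name=np.array(res_name, dtype=object),
        res_id=np.array(res_id, dtype=int), chain=np.array(chain, dtype=object),
        xyz=np.array(xyz, dtype=float), mass=np.array(mass, dtype=float),
        het=np.array(het, dtype=bool), frame_id=frame_id,
    )


def _read_gemmi(path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path} contains no models")
    return st


def read_structure(path, format: str | None = None) -> Structure:
    """Read the first model of a PDB or mmCIF file (format auto-detected)."""
    st = _read_gemmi(path)
    return _model_to_structure(st[0], frame_id=0)


def read_ensemble(path) -> Ensemble:
    """Read a multi-model PDB (or mmCIF) file as an ensemble of frames."""
    st = _read_gemmi(path)
    return Ensemble([_model_to_structure(m, i) for i, m in enumerate(st)])


def _pdb_atom_line(i: int, s: Structure) -> str:
    name = str(s.name[i])
    # short names are left-padded per PDB convention (column 13 reserved)
    fname = f" {name:<3s}" if len(name) < 4 and len(str(s.element[i])) == 1 else f"{name:<4s}"
    record = "HETATM" if s.het[i] else "ATOM  "
    x, y, z = s.xyz[i]
    return (f"{record}{int(s.serial[i]) % 100000:5d} {fname} {str(s.res_name[i])[:3]:>3s} "
            f"{str(s.chain[i])[:1]:1s}{int(s.res_id[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {str(s.element[i]):>2s}")


def write_pdb(obj: Structure | Ensemble, path) -> None:
    """Write fixed-column PDB; an Ensemble becomes a multi-model file."""
    frames = obj.frames if isinstance(obj, Ensemble) else [obj]
    lines: list[str] = []
    multi = len(frames) > 1
    for k, fr in enumerate(frames):
        if multi:
            lines.append(f"MODEL     {k + 1:4d}")
        lines.extend(_pdb_atom_line(i, fr) for i in range(fr.n_atoms))
        lines.append("ENDMDL" if multi else "TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _ranges_mask(structure: Structure, ranges: Sequence[tuple]) -> np.ndarray:
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for chain, lo, hi in ranges:
        m = (structure.res_id >= lo) & (structure.res_id <= hi)
        if chain is not None:
            m &= structure.chain == chain
        mask |= m
    return mask


def select(structure: Structure, sel, domain_map: DomainMap | None = None) -> Structure:
    """Subset a structure by a named DomainMap entry or explicit residue ranges.

    ``sel`` may be a name in ``domain_map``, a (lo, hi) pair, or a list of
    (chain, lo, hi) / (lo, hi) tuples.  Atom order is preserved; an empty
    result is allowed.
    """
    if isinstance(sel, str):
        dm = domain_map if domain_map is not None else DomainMap.with_defaults()
        if sel not in dm:
            raise KeyError(f"unknown selection {sel!r}; available: {sorted(dm)}")
        ranges = dm[sel]
    else:
        sel = list(sel)
        if len(sel) == 2 and all(np.isscalar(x) for x in sel):
            ranges = [(None, int(sel[0]), int(sel[1]))]
        else:
            ranges = [(None, r[0], r[1]) if len(r) == 2 else (r[0], int(r[1]), int(r[2])) for r in sel]
    return structure.take(np.flatnonzero(_ranges_mask(structure, ranges)))


def select_atoms(structure: Structure, names: Sequence[str] | None = None,
                 res_names: Sequence[str] | None = None, chain: str | None = None,
                 heavy_only: bool = False) -> Structure:
    """Subset by atom name / residue name / chain, order preserved."""
    mask = np.ones(structure.n_atoms, dtype=bool)
    if names is not None:
        mask &= np.isin(structure.name, list(names))
    if res_names is not None:
        mask &= np.isin(structure.res_name, list(res_names))
    if chain is not None:
        mask &= structure.chain == chain
    if heavy_only:
        mask &= structure.heavy_mask()
    return structure.take(np.flatnonzero(mask))


def complement(structure: Structure, subset: Structure) -> Structure:
    """Atoms of ``structure`` not in ``subset`` (matched by chain/res_id/name)."""
    keys = set(zip(subset.chain, subset.res_id, subset.name))
    mask = np.array([(c, r, n) not in keys
                     for c, r, n in zip(structure.chain, structure.res_id, structure.name)])
    return structure.take(np.flatnonzero(mask))
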