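"""Rigid-body Brownian-dynamics encounter docking with electrostatic steering.

One body (the CYP) is held fixed; the other (the reductase / FMN domain)
diffuses by Ermak–McCammon translational and rotational moves in a screened-
Coulomb (Debye–Hückel) field generated by the fixed body's charges.
Trajectories start on a sphere of radius ``b`` around the fixed body, are
terminated when the center-to-center separation reaches ``q``, and record a
diffusional encounter whenever the two reaction-distance constraints hold
strictly: redox-center separation D_Fe-N5 < 20 Å and CYP–FMN-domain
center-to-center distance < 60 Å.

Units: Å, ps, kcal/mol, elementary charges, kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import Avogadro, Boltzmann, angstrom, e as elementary_charge, epsilon_0
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import RigidTransform, Structure

__all__ = [
    "RigidBodyModel", "BDParameters", "EncounterRecord", "EncounterSet",
    "assign_charges", "debye_length", "interaction_energy", "force_torque",
    "bd_step", "run_trajectory", "run_docking", "COULOMB_KCAL",
]

# 1/(4 pi eps0) * e^2 / Å, expressed in kcal/mol — the familiar 332.06
COULOMB_KCAL = (elementary_charge ** 2 / (4 * np.pi * epsilon_0 * angstrom)
                * Avogadro / 4184.0)

KB_KCAL = Boltzmann * Avogadro / 4184.0  # kcal/(mol K)

# viscosity of water at 298 K, Pa s — used only for Stokes-Einstein defaults
WATER_VISCOSITY = 0.89e-3


def debye_length(ionic_strength: float, temperature: float = 298.0,
                 dielectric: float = 78.0) -> float:
    """Debye screening length κ⁻¹ in Å for a 1:1 electrolyte of the given
    ionic strength (mol/l)."""
    if ionic_strength <= 0:
        return np.inf
    conc = ionic_strength * 1000.0 * Avogadro  # ions per m^3 per unit charge²
    kappa_sq = 2 * conc * elementary_charge ** 2 / (dielectric * epsilon_0 * Boltzmann * temperature)
    return 1.0 / (np.sqrt(kappa_sq) * angstrom)


def stokes_einstein(radius: float, temperature: float = 298.0) -> tuple[float, float]:
    """(D_t in Å²/ps, D_r in rad²/ps) for a sphere of hydrodynamic radius Å."""
    r_m = radius * angstrom
    d_t = Boltzmann * temperature / (6 * np.pi * WATER_VISCOSITY * r_m)       # m²/s
    d_r = Boltzmann * temperature / (8 * np.pi * WATER_VISCOSITY * r_m ** 3)  # rad²/s
    return d_t * 1e20 * 1e-12, d_r * 1e-12


# ---------------------------------------------------------------------------
# charge assignment
# ---------------------------------------------------------------------------

# residue -> {atom name: charge}; carboxylates split over the two oxygens
_SIDECHAIN_CHARGES = {
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
    "LYS": {"NZ": 1.0},
    "ARG": {"NH1": 0.5, "NH2": 0.5},
}
_COFACTOR_CHARGES = {
    # heme propionates: −1 per carboxylate, split over its two oxygens
    "HEM": {"O1A": -0.5, "O2A": -0.5, "O1D": -0.5, "O2D": -0.5},
    # one phosphate for FMN, two for FAD: −1 each, placed on the P atom
    "FMN": {"P": -1.0},
    "FAD": {"P": -1.0, "PA": -1.0},
}
_NEUTRAL_RESIDUES = {
    "ALA", "ASN", "CYS", "GLN", "GLY", "HIS", "ILE", "LEU", "MET", "PHE",
    "PRO", "SER", "THR", "TRP", "TYR", "VAL", "HOH",
}


def assign_charges(structure: Structure, scheme: str = "formal_ionizable",
                   cap_termini: bool = False) -> np.ndarray:
    """Formal charges per atom: Asp/Glu −1, Lys/Arg +1, His 0, free termini ±1,
    heme propionates −1 each, flavin phosphates −1 per phosphate.

    Unknown residues get 0 with a warning.  Returns an (n,) float array.
    """
    if scheme != "formal_ionizable":
        raise ValueError(f"unknown charge scheme {scheme!r}")
    q = np.zeros(structure.n_atoms)
    unknown: set[str] = set()
    for i in range(structure.n_atoms):
        res = str(structure.res_name[i])
        name = str(structure.name[i])
        if res in _SIDECHAIN_CHARGES:
            q[i] = _SIDECHAIN_CHARGES[res].get(name, 0.0)
        elif res in _COFACTOR_CHARGES:
            q[i] = _COFACTOR_CHARGES[res].get(name, 0.0)
        elif res not in _NEUTRAL_RESIDUES:
            unknown.add(res)
    if not cap_termini:
        # free termini per chain of amino-acid residues: +1 on first N, −1 on
        # the C-terminal carboxylate
        aa = set(_SIDECHAIN_CHARGES) | _NEUTRAL_RESIDUES - {"HOH"}
        for chain in dict.fromkeys(structure.chain):
            mask = (structure.chain == chain) & np.isin(structure.res_name, sorted(aa))
            idx = np.flatnonzero(mask)
            if len(idx) == 0:
                continue
            res_ids = structure.res_id[idx]
            first, last = res_ids.min(), res_ids.max()
            for i in idx[(res_ids == first)]:
                if str(structure.name[i]) == "N":
                    q[i] += 1.0
            last_idx = idx[(res_ids == last)]
            names = [str(structure.name[i]) for i in last_idx]
            if "OXT" in names:
                for i in last_idx:
                    if str(structure.name[i]) in ("O", "OXT"):
                        q[i] += -0.5
            else:
                for i in last_idx:
                    if str(structure.name[i]) == "O":
                        q[i] += -1.0
    if unknown:
        warnings.warn(f"unknown residues assigned zero charge: {sorted(unknown)}")
    return q


# ---------------------------------------------------------------------------
# body and parameter containers
# ---------------------------------------------------------------------------

@dataclass
class RigidBodyModel:
    """A rigid diffusing body: reference coordinates (centered on its center
    of mass), point charges, per-atom exclusion radii and diffusion constants."""

    structure: Structure
    charges: np.ndarray
    exclusion_radii: np.ndarray
    hydro_radius: float
    marker_atoms: dict                      # e.g. {"redox": index of FE or N5}
    d_t: float                              # Å²/ps
    d_r: float                              # rad²/ps
    com_indices: np.ndarray | None = None   # atoms defining the reaction COM (default: all)

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.exclusion_radii = np.asarray(self.exclusion_radii, dtype=float)
        if len(self.charges) != self.structure.n_atoms:
            raise ValueError("charges length mismatch")
        if np.any(self.exclusion_radii <= 0):
            raise ValueError("exclusion radii must be positive")
        if self.d_t <= 0 or self.d_r <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("non-finite charges")
        # store body-frame coordinates centered on the center of mass
        com = self.structure.com()
        self.xyz0 = self.structure.xyz - com
        self.charged = np.flatnonzero(self.charges != 0.0)

    @classmethod
    def from_structure(cls, structure: Structure, charges=None, exclusion_radius: float = 1.8,
                       marker_atoms: dict | None = None, com_indices=None,
                       temperature: float = 298.0) -> "RigidBodyModel":
        if charges is None:
            charges = assign_charges(structure)
        xyz = structure.xyz - structure.com()
        rgyr = float(np.sqrt(np.mean(np.sum(xyz ** 2, axis=1))))
        hydro = rgyr + 2.0
        d_t, d_r = stokes_einstein(hydro, temperature)
        return cls(structure=structure, charges=charges,
                   exclusion_radii=np.full(structure.n_atoms, exclusion_radius),
                   hydro_radius=hydro, marker_atoms=dict(marker_atoms or {}),
                   d_t=d_t, d_r=d_r, com_indices=None if com_indices is None
                   else np.asarray(com_indices, dtype=int))

    def reaction_com(self, xyz: np.ndarray) -> np.ndarray:
        """COM (mass weighted) of the reaction domain in the given coordinates."""
        idx = self.com_indices if self.com_indices is not None else slice(None)
        return np.average(xyz[idx], axis=0, weights=self.structure.mass[idx])


@dataclass(frozen=True)
class BDParameters:
    """Simulation conditions and the recording constraints."""

    temperature: float = 298.0
    ionic_strength: float = 0.15
    dielectric: float = 78.0
    b_radius: float = 450.0           # start sphere (Å)
    q_radius: float = 600.0           # termination separation (Å)
    n_trajectories: int = 240_000
    max_steps: int = 200_000
    seed: int = 0
    dt_far: float = 20.0              # ps, separation > dt_switch
    dt_near: float = 1.0              # ps
    dt_switch: float = 100.0          # Å
    cutoff: float = 100.0             # electrostatics pair cutoff (Å)
    d_fe_n5_max: float = 20.0         # recording constraint (strict <)
    d_domain_max: float = 60.0        # recording constraint (strict <)
    dedup_rmsd: float = 1.0           # Å, within-trajectory pose deduplication
    max_rejections: int = 1000

    def __post_init__(self):
        if self.q_radius <= self.b_radius:
            raise ValueError("termination radius q must exceed start radius b")
        if self.d_fe_n5_max <= 0 or self.d_domain_max <= 0:
            raise ValueError("recording constraints must be positive")
        if self.n_trajectories < 0:
            raise ValueError("n_trajectories must be >= 0")

    @property
    def kappa(self) -> float:
        lam = debye_length(self.ionic_strength, self.temperature, self.dielectric)
        return 0.0 if np.isinf(lam) else 1.0 / lam

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature


@dataclass(frozen=True)
class EncounterRecord:
    pose: RigidTransform
    energy: float
    d_fe_n5: float
    d_domain: float
    trajectory: int
    step: int


@dataclass
class EncounterSet:
    records: list
    params: BDParameters
    n_trajectories: int = 0

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def summary(self) -> dict:
        energies = np.array([r.energy for r in self.records])
        return {
            "n_records": len(self.records),
            "n_trajectories": self.n_trajectories,
            "records_per_trajectory": len(self.records) / max(self.n_trajectories, 1),
            "energy_min": float(energies.min()) if len(energies) else float("nan"),
            "energy_mean": float(energies.mean()) if len(energies) else float("nan"),
        }


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------

def _pair_terms(fixed: RigidBodyModel, mobile_xyz: np.ndarray, mobile: RigidBodyModel,
                params: BDParameters):
    """Charged-pair distances and prefactors within the cutoff; None if empty."""
    ia, ib = fixed.charged, mobile.charged
    if len(ia) == 0 or len(ib) == 0:
        return None
    xa = fixed.xyz0[ia]
    xb = mobile_xyz[ib]
    diff = xb[:, None, :] - xa[None, :, :]          # (nb, na, 3), vector a->b
    r = np.sqrt(np.sum(diff ** 2, axis=-1))
    if np.any(r < 1e-9):
        raise ValueError("coincident charges (r = 0) in interaction energy")
    mask = r <= params.cutoff
    if not mask.any():
        return None
    qq = np.outer(mobile.charges[ib], fixed.charges[ia])
    return diff, r, qq, mask


def interaction_energy(fixed: RigidBodyModel, mobile: RigidBodyModel,
                       pose: RigidTransform, params: BDParameters) -> float:
    """Screened-Coulomb interaction energy (kcal/mol) of the mobile body at
    ``pose`` relative to the fixed body (both in fixed-body frame):
    U = Σ 332.06 q_i q_j exp(−κ r_ij) / (ε_s r_ij) over pairs within cutoff."""
    terms = _pair_terms(fixed, pose.apply(mobile.xyz0), mobile, params)
    if terms is None:
        return 0.0
    _, r, qq, mask = terms
    kappa = params.kappa
    u = COULOMB_KCAL * qq * np.exp(-kappa * r) / (params.dielectric * r)
    return float(u[mask].sum())


def force_torque(fixed: RigidBodyModel, mobile: RigidBodyModel, pose: RigidTransform,
                 params: BDParameters) -> tuple[np.ndarray, np.ndarray]:
    """Net force (kcal/mol/Å) and torque about the mobile COM (kcal/mol) on the
    mobile body."""
    mobile_xyz = pose.apply(mobile.xyz0)
    terms = _pair_terms(fixed, mobile_xyz, mobile, params)
    if terms is None:
        return np.zeros(3), np.zeros(3)
    diff, r, qq, mask = terms
    kappa = params.kappa
    # dU/dr of A e^{-κr}/r is -A e^{-κr} (κ r + 1)/r²; force on b along +r̂(a→b)
    mag = COULOMB_KCAL * qq * np.exp(-kappa * r) * (kappa * r + 1.0) / (params.dielectric * r ** 3)
    mag = np.where(mask, mag, 0.0)
    f_atoms = mag[..., None] * diff                 # (nb, na, 3)
    f_per_atom = f_atoms.sum(axis=1)                # (nb, 3)
    force = f_per_atom.sum(axis=0)
    lever = mobile_xyz[mobile.charged] - pose.translation
    torque = np.cross(lever, f_per_atom).sum(axis=0)
    return force, torque


def _overlaps(fixed: RigidBodyModel, mobile: RigidBodyModel, mobile_xyz: np.ndarray) -> bool:
    """Any inter-body atom pair closer than the sum of exclusion radii?"""
    sep = np.linalg.norm(mobile_xyz.mean(axis=0) - fixed.xyz0.mean(axis=0))
    reach = (np.abs(fixed.xyz0).max() + np.abs(mobile.xyz0).max()
             + fixed.exclusion_radii.max() + mobile.exclusion_radii.max())
    if sep > reach:
        return False
    d = cdist(mobile_xyz, fixed.xyz0)
    thresh = mobile.exclusion_radii[:, None] + fixed.exclusion_radii[None, :]
    return bool(np.any(d < thresh))


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def bd_step(pose: RigidTransform, force: np.ndarray, torque: np.ndarray,
            mobile: RigidBodyModel, params: BDParameters, dt: float,
            rng: np.random.Generator, fixed: RigidBodyModel | None = None,
            noise: bool = True) -> RigidTransform:
    """One Ermak–McCammon move of the mobile body.

    Translation: Δr = (D_t/k_BT) F Δt + √(2 D_t Δt) G; rotation analogously
    with D_r and the torque, applied as a rotation vector about the body COM.
    If ``fixed`` is given, moves creating inter-body overlap are rejected and
    the random displacement resampled (the deterministic drift is kept).
    """
    if not (np.all(np.isfinite(force)) and np.all(np.isfinite(torque))):
        raise ValueError("non-finite force or torque")
    kt = params.kt
    drift_t = mobile.d_t / kt * np.asarray(force, float) * dt
    drift_r = mobile.d_r / kt * np.asarray(torque, float) * dt
    sigma_t = np.sqrt(2 * mobile.d_t * dt)
    sigma_r = np.sqrt(2 * mobile.d_r * dt)
    for _ in range(params.max_rejections):
        rand_t = sigma_t * rng.standard_normal(3) if noise else np.zeros(3)
        rand_r = sigma_r * rng.standard_normal(3) if noise else np.zeros(3)
        rot = Rotation.from_rotvec(drift_r + rand_r)
        q = (rot * pose.rotation).as_quat()
        new = RigidTransform(q / np.linalg.norm(q), pose.translation + drift_t + rand_t)
        if fixed is None or not _overlaps(fixed, mobile, new.apply(mobile.xyz0)):
            return new
        if not noise:
            raise RuntimeError("deterministic move creates overlap; cannot resample")
    raise RuntimeError(f"move rejected {params.max_rejections} times; geometry fault")


def _start_pose(params: BDParameters, rng: np.random.Generator) -> RigidTransform:
    """Uniform random orientation at a uniform random point on the b sphere."""
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    return RigidTransform(Rotation.random(rng=rng).as_quat(), params.b_radius * u)


# -- small quaternion helpers (x, y, z, w convention, as scipy) --------------
# hand-rolled to keep the trajectory inner loop free of object overhead;
# the update rule is identical to bd_step and tested against it.

def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = np.sqrt(v @ v)
    if angle < 1e-12:
        return np.array([0.5 * v[0], 0.5 * v[1], 0.5 * v[2], 1.0]) / np.sqrt(1 + 0.25 * (v @ v))
    s = np.sin(angle / 2) / angle
    return np.array([v[0] * s, v[1] * s, v[2] * s, np.cos(angle / 2)])


def _quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array([
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    ])


def _quat_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def run_trajectory(fixed: RigidBodyModel, mobile: RigidBodyModel, params: BDParameters,
                   rng: np.random.Generator, trajectory_id: int = 0) -> list:
    """One trajectory from the b sphere to the q sphere, recording encounter
    poses that satisfy both distance constraints strictly.  Within the
    trajectory, poses closer than ``dedup_rmsd`` (marker/charged-atom RMSD) to
    an already-recorded pose are suppressed.

    The propagation inlines the same Ermak–McCammon update as :func:`bd_step`
    (same random-draw order, so the two are step-for-step identical for a
    shared generator) but transforms only the marker atoms per step.
    """
    start = _start_pose(params, rng)
    quat = start.quat.copy()
    trans = start.translation.copy()
    records: list[EncounterRecord] = []
    recorded_xyz: list[np.ndarray] = []
    # atoms used for the dedup RMSD: charged atoms plus markers (cheap subset)
    dd_idx = np.unique(np.concatenate([
        mobile.charged, np.array([v for v in mobile.marker_atoms.values()], dtype=int)
    ])) if (len(mobile.charged) or mobile.marker_atoms) else np.arange(min(mobile.structure.n_atoms, 10))

    fi = fixed.marker_atoms.get("redox")
    mi = mobile.marker_atoms.get("redox")
    fixed_marker = fixed.xyz0[fi] if fi is not None else None
    mobile_marker0 = mobile.xyz0[mi] if mi is not None else None
    fixed_com = fixed.reaction_com(fixed.xyz0)
    mobile_com0 = mobile.reaction_com(mobile.xyz0)
    kt = params.kt
    xa = fixed.xyz0[fixed.charged]
    qa = fixed.charges[fixed.charged]
    xb0 = mobile.xyz0[mobile.charged]
    qb = mobile.charges[mobile.charged]
    kappa = params.kappa
    have_charges = len(xa) > 0 and len(xb0) > 0
    force_reach = params.cutoff + (np.abs(xa).max() if len(xa) else 0) \
        + (np.abs(xb0).max() if len(xb0) else 0)
    contact_reach = ((np.linalg.norm(fixed.xyz0, axis=1).max() if fixed.structure.n_atoms else 0)
                     + (np.linalg.norm(mobile.xyz0, axis=1).max() if mobile.structure.n_atoms else 0)
                     + fixed.exclusion_radii.max() + mobile.exclusion_radii.max())
    excl_sum = mobile.exclusion_radii[:, None] + fixed.exclusion_radii[None, :]

    for step in range(params.max_steps):
        sep = np.sqrt(trans @ trans)
        if sep >= params.q_radius:
            break
        dt = params.dt_far if sep > params.dt_switch else params.dt_near
        if have_charges and sep < force_reach:
            mat = _quat_matrix(quat)
            xb = xb0 @ mat.T + trans
            diff = xb[:, None, :] - xa[None, :, :]
            r = np.sqrt(np.sum(diff ** 2, axis=-1))
            mag = COULOMB_KCAL * np.outer(qb, qa) * np.exp(-kappa * r) \
                * (kappa * r + 1.0) / (params.dielectric * r ** 3)
            mag[r > params.cutoff] = 0.0
            f_atoms = (mag[..., None] * diff).sum(axis=1)
            force = f_atoms.sum(axis=0)
            torque = np.cross(xb - trans, f_atoms).sum(axis=0)
        else:
            force = torque = np.zeros(3)
        drift_t = mobile.d_t / kt * force * dt
        drift_r = mobile.d_r / kt * torque * dt
        sigma_t = np.sqrt(2 * mobile.d_t * dt)
        sigma_r = np.sqrt(2 * mobile.d_r * dt)
        for attempt in range(params.max_rejections + 1):
            if attempt == params.max_rejections:
                raise RuntimeError(f"move rejected {params.max_rejections} times; geometry fault")
            new_trans = trans + drift_t + sigma_t * rng.standard_normal(3)
            dq = _quat_from_rotvec(drift_r + sigma_r * rng.standard_normal(3))
            new_quat = _quat_mul(dq, quat)
            new_quat /= np.sqrt(new_quat @ new_quat)
            if np.sqrt(new_trans @ new_trans) >= contact_reach:
                break
            mat = _quat_matrix(new_quat)
            d = cdist(mobile.xyz0 @ mat.T + new_trans, fixed.xyz0)
            if not np.any(d < excl_sum):
                break
        quat, trans = new_quat, new_trans

        if fixed_marker is None or mobile_marker0 is None:
            continue
        # cheap gate: markers cannot be within range unless the bodies are close
        if np.sqrt(trans @ trans) > params.d_fe_n5_max + np.linalg.norm(fixed_marker) \
                + np.linalg.norm(mobile_marker0):
            continue
        mat = _quat_matrix(quat)
        d_fe_n5 = float(np.linalg.norm(mat @ mobile_marker0 + trans - fixed_marker))
        if d_fe_n5 < params.d_fe_n5_max:
            d_dom = float(np.linalg.norm(mat @ mobile_com0 + trans - fixed_com))
            if d_dom < params.d_domain_max:
                probe = mobile.xyz0[dd_idx] @ mat.T + trans
                if all(np.sqrt(np.mean(np.sum((probe - prev) ** 2, axis=1))) >= params.dedup_rmsd
                       for prev in recorded_xyz):
                    pose = RigidTransform(quat, trans.copy())
                    energy = interaction_energy(fixed, mobile, pose, params)
                    records.append(EncounterRecord(pose=pose, energy=energy, d_fe_n5=d_fe_n5,
                                                   d_domain=d_dom, trajectory=trajectory_id,
                                                   step=step))
                    recorded_xyz.append(probe)
    return records


def run_docking(fixed: RigidBodyModel, mobile: RigidBodyModel,
                params: BDParameters) -> EncounterSet:
    """Independent seeded trajectories; deterministic for a given (seed, params)."""
    if params.n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_trajectories)
    records: list[EncounterRecord] = []
    for tid, ss in enumerate(seeds):
        records.extend(run_trajectory(fixed, mobile, params, np.random.default_rng(ss), tid))
    out = EncounterSet(records=records, params=params, n_trajectories=params.n_trajectories)
    if not records:
        warnings.warn("docking produced zero encounter records")
    return out
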