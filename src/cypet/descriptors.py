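"""Geometric descriptors of CYP–CPR complexes: redox-center distances, helix
angles, membrane-relative orientation, interface area, contacts, hydrogen-bond
occupancy and the open/semi-open/closed classification of the reductase.

All angles are returned in degrees, all distances in Å.  Membrane-relative
quantities are defined in a :class:`MembraneFrame` whose normal is the z axis;
every descriptor is invariant under a joint rigid transform of structure and
membrane frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import (
    CofactorSpec,
    DomainMap,
    Ensemble,
    ISOALLOXAZINE_RING_ATOMS,
    Structure,
    select,
    select_atoms,
)

__all__ = [
    "MembraneFrame", "HelixAxis", "DescriptorSet", "ContactTable",
    "pair_distance", "domain_com_distance", "fit_helix_axis", "angle_between",
    "compute_theta", "heme_plane_tilt", "membrane_orientation_angles",
    "axial_membrane_distance", "infer_membrane_frame", "interface_area",
    "contact_map", "hydrogen_bond_occupancy", "classify_cpr_conformation",
]


@dataclass(frozen=True)
class MembraneFrame:
    """Bilayer coordinate frame: unit normal (the z axis), a point on the
    midplane, and the half-thickness of the slab in Å."""

    normal: np.ndarray
    midplane_point: np.ndarray
    half_thickness: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("zero membrane normal")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "midplane_point", np.asarray(self.midplane_point, float).reshape(3))
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")

    def axial(self, xyz: np.ndarray) -> np.ndarray:
        """Signed axial coordinate(s) of point(s) relative to the midplane."""
        return (np.atleast_2d(xyz) - self.midplane_point) @ self.normal

    def transformed(self, t) -> "MembraneFrame":
        return MembraneFrame(t.rotation.apply(self.normal), t.apply(self.midplane_point),
                             self.half_thickness)


@dataclass(frozen=True)
class HelixAxis:
    direction: np.ndarray       # unit vector, N-terminus -> C-terminus
    centroid: np.ndarray
    residual: float             # RMS distance of Cα from the fitted axis (Å)


def pair_distance(structure: Structure, atom_ref_a: dict, atom_ref_b: dict) -> float:
    """Euclidean distance between two uniquely resolved atoms.

    Atom references are keyword dicts for :meth:`Structure.atom_index`,
    e.g. ``{"name": "FE", "res_name": "HEM"}``.
    """
    ia = structure.atom_index(**atom_ref_a)
    ib = structure.atom_index(**atom_ref_b)
    return float(np.linalg.norm(structure.xyz[ia] - structure.xyz[ib]))


def domain_com_distance(structure: Structure, sel_a, sel_b,
                        mass_weighted: bool = True,
                        domain_map: DomainMap | None = None) -> float:
    """Distance between the (mass-weighted) centroids of two selections."""
    a = sel_a if isinstance(sel_a, Structure) else select(structure, sel_a, domain_map)
    b = sel_b if isinstance(sel_b, Structure) else select(structure, sel_b, domain_map)
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("empty selection in center-of-mass distance")
    return float(np.linalg.norm(a.com(mass_weighted) - b.com(mass_weighted)))


def fit_helix_axis(structure: Structure, residue_range=None,
                   domain_map: DomainMap | None = None) -> HelixAxis:
    """Principal axis of the Cα trace of a helix.

    The direction sign is chosen so that it points from the first toward the
    last Cα (N→C).  At least 4 Cα atoms are required.
    """
    sub = structure if residue_range is None else select(structure, residue_range, domain_map)
    ca = select_atoms(sub, names=["CA"])
    if ca.n_atoms < 4:
        raise ValueError(f"helix fit needs >= 4 CA atoms, got {ca.n_atoms}")
    # order along the chain
    order = np.argsort(ca.res_id, kind="stable")
    xyz = ca.xyz[order]
    centroid = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - centroid)
    direction = vt[0]
    if direction @ (xyz[-1] - xyz[0]) < 0:
        direction = -direction
    perp = (xyz - centroid) - np.outer((xyz - centroid) @ direction, direction)
    residual = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    return HelixAxis(direction=direction, centroid=centroid, residual=residual)


def angle_between(u: np.ndarray, v: np.ndarray, fold: str = "none") -> float:
    """Angle in degrees between two vectors; ``fold='to_90'`` maps x to min(x, 180−x)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector in angle computation")
    ang = float(np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0))))
    if fold == "to_90":
        return min(ang, 180.0 - ang)
    if fold != "none":
        raise ValueError(f"unknown fold mode {fold!r}")
    return ang


def compute_theta(structure: Structure, c_helix_range, alpha1_range=(91, 105),
                  domain_map: DomainMap | None = None) -> float:
    """θ: angle between the CYP C-helix axis and the FMN-domain α1-helix axis
    (N→C directions, unfolded, so values above 90° are meaningful)."""
    ax1 = fit_helix_axis(structure, c_helix_range, domain_map)
    ax2 = fit_helix_axis(structure, alpha1_range, domain_map)
    return angle_between(ax1.direction, ax2.direction, fold="none")


def _plane_normal(xyz: np.ndarray) -> np.ndarray:
    centered = xyz - xyz.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if len(s) < 3 or s[1] < 1e-9:
        raise ValueError("degenerate (collinear) points; no plane defined")
    return vt[2]


def heme_plane_tilt(structure: Structure, membrane: MembraneFrame,
                    cofactor: CofactorSpec | None = None) -> float:
    """Angle in [0°, 90°] between the least-squares heme plane and the membrane
    normal (z axis): 90° when the macrocycle lies flat in the membrane plane,
    0° when the plane contains the z axis."""
    spec = cofactor or CofactorSpec.heme()
    ring = select_atoms(structure, names=list(spec.ring_atoms), res_names=[spec.res_name])
    if ring.n_atoms < 3:
        raise ValueError(f"need >= 3 ring atoms of {spec.res_name}, got {ring.n_atoms}")
    normal = _plane_normal(ring.xyz)
    return 90.0 - angle_between(normal, membrane.normal, fold="to_90")


def membrane_orientation_angles(structure: Structure, membrane: MembraneFrame,
                                domain_map: DomainMap | None = None,
                                mass_weighted: bool = True) -> tuple[float, float, float]:
    """(α, β, γ): angles between the membrane normal and
    v1 (I-helix axis), v2 (C→F inter-helix centroid vector orthogonalized to
    v1) and v3 (TM-helix axis)."""
    dm = domain_map if domain_map is not None else DomainMap.with_defaults()
    v1 = fit_helix_axis(structure, "i_helix", dm).direction
    if "c_helix" not in dm:
        raise KeyError("domain map must define 'c_helix' (no canonical residue range; supply in config)")
    c_com = select(structure, "c_helix", dm).com(mass_weighted)
    f_com = select(structure, "f_helix", dm).com(mass_weighted)
    v2 = f_com - c_com
    v2 = v2 - (v2 @ v1) * v1
    if np.linalg.norm(v2) < 1e-9:
        raise ValueError("degenerate v2: C- and F-helix centroids coincide along v1")
    v2 /= np.linalg.norm(v2)
    v3 = fit_helix_axis(structure, "cyp_tm_helix", dm).direction
    z = membrane.normal
    return (angle_between(v1, z), angle_between(v2, z), angle_between(v3, z))


def axial_membrane_distance(structure: Structure, sel, membrane: MembraneFrame,
                            mass_weighted: bool = True,
                            domain_map: DomainMap | None = None) -> float:
    """|axial coordinate| of the selection's center of mass relative to the
    membrane midplane."""
    sub = sel if isinstance(sel, Structure) else select(structure, sel, domain_map)
    if sub.n_atoms == 0:
        raise ValueError("empty selection for axial membrane distance")
    return float(abs(membrane.axial(sub.com(mass_weighted))[0]))


def infer_membrane_frame(structure: Structure, min_phosphorus: int = 10) -> MembraneFrame:
    """Derive the bilayer frame from lipid phosphorus atoms.

    The leaflet-separation axis is found by splitting the P atoms into two
    leaflets along each principal axis of their spread and keeping the axis
    with the cleanest bimodal split; the normal is the difference of leaflet
    centroids, the midplane their mean, and the half-thickness half their
    separation.
    """
    p = select_atoms(structure, heavy_only=True)
    p = p.take(np.flatnonzero(p.element == "P"))
    if p.n_atoms < min_phosphorus:
        raise ValueError(
            f"only {p.n_atoms} phosphorus atoms found (< {min_phosphorus}); "
            "no lipid bilayer present — supply the membrane frame in config")
    xyz = p.xyz
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    best = None
    for axis in vt:
        proj = centered @ axis
        upper = proj >= np.median(proj)
        sep = proj[upper].mean() - proj[~upper].mean()
        spread = proj[upper].std() + proj[~upper].std() + 1e-12
        score = sep / spread
        if best is None or score > best[0]:
            best = (score, axis, upper)
    _, axis, upper = best
    com_u = xyz[upper].mean(axis=0)
    com_l = xyz[~upper].mean(axis=0)
    delta = com_u - com_l
    half = float(np.linalg.norm(delta) / 2.0)
    if half <= 0:
        raise ValueError("degenerate leaflet separation")
    normal = delta / (2 * half)
    if normal[np.argmax(np.abs(normal))] < 0:  # deterministic sign convention
        normal = -normal
    return MembraneFrame(normal=normal, midplane_point=(com_u + com_l) / 2.0,
                         half_thickness=half)


# ---------------------------------------------------------------------------
# interface area (Shrake-Rupley SASA through biotite)
# ---------------------------------------------------------------------------

def _sasa(structure: Structure, probe: float, point_number: int) -> float:
    import biotite.structure as struc

    arr = struc.AtomArray(structure.n_atoms)
    arr.coord = np.asarray(structure.xyz, dtype=np.float32)
    arr.element = np.array([str(e) for e in structure.element], dtype="U2")
    arr.chain_id = np.array([str(c)[:1] or "A" for c in structure.chain], dtype="U4")
    arr.res_id = np.asarray(structure.res_id, dtype=int)
    arr.res_name = np.array([str(r) for r in structure.res_name], dtype="U5")
    arr.atom_name = np.array([str(n) for n in structure.name], dtype="U6")
    arr.hetero = np.asarray(structure.het, dtype=bool)
    vals = struc.sasa(arr, probe_radius=probe, vdw_radii="Single", point_number=point_number)
    return float(np.nansum(vals))


def _concat(a: Structure, b: Structure) -> Structure:
    return Structure(
        serial=np.concatenate([a.serial, b.serial]),
        name=np.concatenate([a.name, b.name]),
        element=np.concatenate([a.element, b.element]),
        res_name=np.concatenate([a.res_name, b.res_name]),
        res_id=np.concatenate([a.res_id, b.res_id]),
        chain=np.concatenate([a.chain, b.chain]),
        xyz=np.vstack([a.xyz, b.xyz]),
        mass=np.concatenate([a.mass, b.mass]),
        het=np.concatenate([a.het, b.het]),
    )


def interface_area(structure: Structure, sel_a, sel_b, probe: float = 1.4,
                   convention: str = "buried_total", point_number: int = 500,
                   domain_map: DomainMap | None = None) -> float:
    """Buried solvent-accessible surface area between two disjoint selections:
    SASA(A) + SASA(B) − SASA(A∪B), halved for ``convention='buried_half'``."""
    a = sel_a if isinstance(sel_a, Structure) else select(structure, sel_a, domain_map)
    b = sel_b if isinstance(sel_b, Structure) else select(structure, sel_b, domain_map)
    keys_a = set(zip(a.chain, a.res_id, a.name))
    if any((c, r, n) in keys_a for c, r, n in zip(b.chain, b.res_id, b.name)):
        raise ValueError("selections overlap; interface area undefined")
    if convention not in ("buried_total", "buried_half"):
        raise ValueError(f"unknown convention {convention!r}")
    buried = (_sasa(a, probe, point_number) + _sasa(b, probe, point_number)
              - _sasa(_concat(a, b), probe, point_number))
    buried = max(buried, 0.0)
    return buried / 2.0 if convention == "buried_half" else buried


# ---------------------------------------------------------------------------
# contacts and hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class ContactTable:
    """Residue–residue contacts over an ensemble.

    ``pairs`` maps (chain_a, res_id_a, chain_b, res_id_b) to a per-frame
    boolean list; ``min_distance`` holds the smallest heavy-atom distance seen.
    """

    pairs: dict = field(default_factory=dict)
    min_distance: dict = field(default_factory=dict)
    n_frames: int = 0

    def occupancy(self, pair=None):
        occ = {p: sum(flags) / self.n_frames for p, flags in self.pairs.items()}
        return occ if pair is None else occ.get(tuple(pair), 0.0)


def _residue_keys(s: Structure):
    keys = list(dict.fromkeys(zip(s.chain, s.res_id)))
    idx = {k: [] for k in keys}
    for i, k in enumerate(zip(s.chain, s.res_id)):
        idx[k].append(i)
    return keys, idx


def contact_map(ensemble: Ensemble | Structure, sel_a, sel_b, cutoff: float = 5.0,
                domain_map: DomainMap | None = None) -> ContactTable:
    """Residue pairs whose minimum heavy-atom distance is < cutoff per frame,
    with occupancies over the ensemble."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = ensemble.frames if isinstance(ensemble, Ensemble) else [ensemble]

    def frame_indices(sel):
        """Atom indices of the selection in frame 0 (topology shared by all frames)."""
        f0 = frames[0]
        if isinstance(sel, Structure):
            keys = set(zip(sel.chain, sel.res_id, sel.name))
            idx = [i for i, k in enumerate(zip(f0.chain, f0.res_id, f0.name)) if k in keys]
        else:
            sub = select(f0, sel, domain_map)
            keys = set(zip(sub.chain, sub.res_id, sub.name))
            idx = [i for i, k in enumerate(zip(f0.chain, f0.res_id, f0.name)) if k in keys]
        return np.array([i for i in idx if f0.element[i] != "H"], dtype=int)

    ia_all, ib_all = frame_indices(sel_a), frame_indices(sel_b)
    table = ContactTable(n_frames=len(frames))
    for fi, frame in enumerate(frames):
        a, b = frame.take(ia_all), frame.take(ib_all)
        if a.n_atoms == 0 or b.n_atoms == 0:
            continue
        keys_a, idx_a = _residue_keys(a)
        keys_b, idx_b = _residue_keys(b)
        d = cdist(a.xyz, b.xyz)
        for ka in keys_a:
            for kb in keys_b:
                dmin = float(d[np.ix_(idx_a[ka], idx_b[kb])].min())
                pair = (*ka, *kb)
                flags = table.pairs.setdefault(pair, [False] * len(frames))
                flags[fi] = dmin < cutoff
                table.min_distance[pair] = min(table.min_distance.get(pair, np.inf), dmin)
    # drop never-in-contact pairs to keep tables small
    table.pairs = {p: f for p, f in table.pairs.items() if any(f)}
    return table


_DONOR_ELEMENTS = {"N", "O", "S"}


def hydrogen_bond_occupancy(ensemble: Ensemble | Structure, donor_ref: dict, acceptor_ref: dict,
                            d_cut: float = 3.5, angle_cut: float = 120.0) -> float:
    """Fraction of frames with a donor–acceptor hydrogen bond.

    A bond is present when the donor–acceptor heavy-atom distance is below
    ``d_cut`` and, if a hydrogen bound to the donor exists in the frame, the
    D–H…A angle exceeds ``angle_cut``.
    """
    frames = ensemble.frames if isinstance(ensemble, Ensemble) else [ensemble]
    bonded = 0
    for frame in frames:
        di = frame.atom_index(**donor_ref)
        ai = frame.atom_index(**acceptor_ref)
        if str(frame.element[di]) not in _DONOR_ELEMENTS or str(frame.element[ai]) not in _DONOR_ELEMENTS:
            raise ValueError("donor/acceptor must be N, O or S heavy atoms")
        d_xyz, a_xyz = frame.xyz[di], frame.xyz[ai]
        if np.linalg.norm(d_xyz - a_xyz) >= d_cut:
            continue
        # any hydrogen within covalent range of the donor, same residue
        h_mask = ((frame.element == "H") & (frame.res_id == frame.res_id[di])
                  & (frame.chain == frame.chain[di]))
        h_idx = np.flatnonzero(h_mask)
        h_idx = [h for h in h_idx if np.linalg.norm(frame.xyz[h] - d_xyz) < 1.3]
        if h_idx:
            ok = any(angle_between(d_xyz - frame.xyz[h], a_xyz - frame.xyz[h]) > angle_cut
                     for h in h_idx)
            if not ok:
                continue
        bonded += 1
    return bonded / len(frames)


# ---------------------------------------------------------------------------
# CPR conformational state
# ---------------------------------------------------------------------------

def cofactor_ring_centroid(structure: Structure, res_name: str, chain: str | None = None) -> np.ndarray:
    ring = select_atoms(structure, names=list(ISOALLOXAZINE_RING_ATOMS),
                        res_names=[res_name], chain=chain)
    if ring.n_atoms < 3:
        raise ValueError(f"cofactor {res_name} isoalloxazine ring not found "
                         f"({ring.n_atoms} ring atoms)")
    return ring.xyz.mean(axis=0)


def classify_cpr_conformation(structure: Structure, chain: str | None = None,
                              closed_max: float = 25.0, open_min: float = 55.0
                              ) -> tuple[str, float]:
    """Classify the reductase as closed / semi-open / open from the distance
    between the FMN and FAD isoalloxazine-ring centroids.

    Thresholds (25 / 55 Å) separate the crystallographic anchors: 14.2 Å for
    the closed form, ~44.7 Å semi-open, 61.3 Å fully open.
    """
    d = float(np.linalg.norm(cofactor_ring_centroid(structure, "FMN", chain)
                             - cofactor_ring_centroid(structure, "FAD", chain)))
    if d < closed_max:
        state = "closed"
    elif d > open_min:
        state = "open"
    else:
        state = "semi-open"
    return state, d


# ---------------------------------------------------------------------------
# per-frame descriptor sets
# ---------------------------------------------------------------------------

@dataclass
class DescriptorSet:
    """Named per-frame scalars; missing descriptors are NaN."""

    values: dict

    NAMES = ("D_Fe_N5", "D_CYP_FMNdomain", "theta", "alpha", "beta", "gamma",
             "heme_tilt", "D_CYP_mem", "D_FG_mem", "D_FMNdomain_mem",
             "D_linker_mem", "D_FAD_NADP", "D_CYP_NADPdomain", "interface_area")

    def __getitem__(self, key):
        return self.values[key]

    def as_row(self) -> dict:
        return {k: self.values.get(k, float("nan")) for k in self.NAMES}
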