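"""Synthetic fixtures: charged rigid bead bodies, ideal helices, membrane
slabs, posed pseudo-proteins and small pathway graphs with enumerated
couplings.

Every generator is a pure function of its parameters and seed and attaches
the construction parameters to its output, so tests can recover them with the
descriptor machinery and compare against the prescription.  The bead bodies
emulate the electrostatic-steering premise of CYP–reductase association — a
positive patch on the CYP proximal face against a negative patch around the
FMN cofactor — without all-atom detail, which the propagation, recording,
clustering and filtering contracts do not need.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .bd import BDParameters, RigidBodyModel
from .descriptors import MembraneFrame
from .pathways import MolecularGraph, PathwayParams
from .structure import DomainMap, HEME_RING_ATOMS, Structure

__all__ = [
    "ToyRedoxPair", "ToyMembraneSystem", "ToyGraphSpec",
    "make_helix", "make_toy_redox_pair", "toy_bd_params", "make_bilayer",
    "make_membrane_system", "make_toy_graph", "make_covalent_chain",
    "make_mini_redox_site", "exhaustive_best_coupling", "build_structure",
]


def build_structure(rows, frame_id: int = 0) -> Structure:
    """Structure from rows of (name, element, res_name, res_id, chain, xyz[, het])."""
    import gemmi

    cols = list(zip(*[(r + (False,))[:7] for r in rows]))
    name, element, res_name, res_id, chain, xyz, het = cols
    mass = [float(gemmi.Element(e).weight) for e in element]
    return Structure(
        serial=np.arange(1, len(rows) + 1), name=np.array(name, dtype=object),
        element=np.array(element, dtype=object), res_name=np.array(res_name, dtype=object),
        res_id=np.array(res_id, dtype=int), chain=np.array(chain, dtype=object),
        xyz=np.array(xyz, dtype=float), mass=np.array(mass, dtype=float),
        het=np.array(het, dtype=bool), frame_id=frame_id,
    )


# ---------------------------------------------------------------------------
# helices
# ---------------------------------------------------------------------------

def _rotation_to(direction) -> Rotation:
    """Minimal rotation taking +z to the given direction."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("zero direction vector")
    d = d / n
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(z, d)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return Rotation.identity() if d @ z > 0 else Rotation.from_rotvec([np.pi, 0, 0])
    angle = math.atan2(s, float(z @ d))
    return Rotation.from_rotvec(axis / s * angle)


def make_helix(n_res: int, direction=(0, 0, 1), rise: float = 1.5,
               twist: float = 100.0, radius: float = 2.3, origin=(0, 0, 0),
               chain: str = "A", first_res: int = 1, res_name: str = "ALA") -> Structure:
    """Ideal α-helical Cα trace whose principal axis lies along ``direction``
    (within 1° for n_res ≥ ~10), N-terminus first."""
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    i = np.arange(n_res)
    phi = np.radians(twist) * i
    base = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), rise * i])
    base -= base.mean(axis=0)
    # pre-align the fitted principal axis (slightly off z for partial turns)
    # onto z so the generated helix axis equals the requested direction exactly
    _, _, vt = np.linalg.svd(base)
    u = vt[0] if vt[0] @ (base[-1] - base[0]) > 0 else -vt[0]
    base = Rotation.align_vectors([[0.0, 0.0, 1.0]], [u])[0].apply(base)
    xyz = _rotation_to(direction).apply(base) + np.asarray(origin, float)
    rows = [("CA", "C", res_name, first_res + k, chain, xyz[k]) for k in range(n_res)]
    return build_structure(rows)


# ---------------------------------------------------------------------------
# toy redox pair for BD docking
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistant unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z ** 2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class ToyRedoxPair:
    """Pseudo-CYP (body A, + patch, buried FE marker) and pseudo-FMN-domain
    (body B, − patch, surface N5 marker), patches on each body's +z axis."""

    body_a: RigidBodyModel
    body_b: RigidBodyModel
    metadata: dict = field(default_factory=dict)


def _bead_body(n: int, radius: float, patch_charge: float, patch_half_angle: float,
               marker: tuple, chain: str, res_prefix: str,
               rng: np.random.Generator, jitter: float = 0.1,
               extra_atoms=()) -> tuple[Structure, np.ndarray, dict]:
    unit = _fibonacci_sphere(n)
    xyz = radius * unit + jitter * rng.standard_normal((n, 3))
    charges = np.zeros(n + 1 + len(extra_atoms))
    patch = unit[:, 2] > math.cos(math.radians(patch_half_angle))
    charges[:n][patch] = patch_charge / max(int(patch.sum()), 1)
    rows = [(f"C", "C", res_prefix, k + 1, chain, xyz[k]) for k in range(n)]
    marker_name, marker_res, marker_xyz = marker
    rows.append((marker_name, "FE" if marker_name == "FE" else "N", marker_res, 9000, chain,
                 np.asarray(marker_xyz, float), True))
    markers = {"redox": n}
    for j, (aname, elem, axyz) in enumerate(extra_atoms):
        rows.append((aname, elem, "ANC", 9100 + j, chain, np.asarray(axyz, float), True))
        markers[aname.lower()] = n + 1 + j
    return build_structure(rows), charges, markers


def make_toy_redox_pair(seed: int = 0, patch_charge: float = 5.0,
                        n_a: int = 200, n_b: int = 100,
                        radius_a: float = 16.0, radius_b: float = 10.0,
                        patch_half_angle: float = 25.0,
                        fe_depth: float = 11.0) -> ToyRedoxPair:
    """Two charged bead spheres with redox markers.

    Body A carries +``patch_charge`` on the beads within ``patch_half_angle``
    of its +z axis and an FE marker buried ``fe_depth`` Å from its center
    under the patch; body B carries the opposite charge and an N5 marker on
    its patch surface, plus an 'anc' tether-anchor atom at 90° from the patch.
    Reproducible for a given seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA]))
    struct_a, q_a, markers_a = _bead_body(
        n_a, radius_a, patch_charge, patch_half_angle,
        marker=("FE", "HEM", (0.0, 0.0, fe_depth)), chain="A", res_prefix="BDA", rng=rng)
    struct_b, q_b, markers_b = _bead_body(
        n_b, radius_b, -patch_charge, patch_half_angle,
        marker=("N5", "FMN", (0.0, 0.0, radius_b)), chain="B", res_prefix="BDB", rng=rng,
        extra_atoms=[("ANC", "N", (radius_b, 0.0, 0.0))])
    markers_b["anchor"] = markers_b.pop("anc")  # tether anchor for the membrane filter
    # bead radius 1.4 Å keeps the bead diameter below the minimum Fibonacci
    # spacing of either body, so generated bodies never self-overlap
    body_a = RigidBodyModel.from_structure(struct_a, charges=q_a, marker_atoms=markers_a,
                                           exclusion_radius=1.4)
    body_b = RigidBodyModel.from_structure(struct_b, charges=q_b, marker_atoms=markers_b,
                                           exclusion_radius=1.4)
    return ToyRedoxPair(body_a=body_a, body_b=body_b, metadata={
        "seed": int(seed), "patch_charge": patch_charge, "n_a": n_a, "n_b": n_b,
        "radius_a": radius_a, "radius_b": radius_b,
        "patch_half_angle": patch_half_angle, "fe_depth": fe_depth,
    })


def toy_bd_params(seed: int = 0, n_trajectories: int = 200, **overrides) -> BDParameters:
    """BD conditions scaled to the toy pair's geometry: start sphere 50 Å,
    termination 80 Å, step schedule 10 ps beyond 45 Å separation and 1 ps
    inside it.  Temperature, ionic strength and dielectric keep the
    physiological defaults."""
    kw = dict(b_radius=50.0, q_radius=80.0, dt_far=10.0, dt_near=1.0,
              dt_switch=45.0, max_steps=20_000, n_trajectories=n_trajectories,
              seed=seed)
    kw.update(overrides)
    return BDParameters(**kw)


# ---------------------------------------------------------------------------
# membrane systems
# ---------------------------------------------------------------------------

def make_bilayer(normal=(0, 0, 1), half_thickness: float = 19.0, n_side: int = 9,
                 spacing: float = 8.0, center=(0, 0, 0), chain: str = "M") -> Structure:
    """Two parallel planes of lipid-phosphorus pseudo-atoms at ±half_thickness
    along ``normal``."""
    g = (np.arange(n_side) - (n_side - 1) / 2) * spacing
    xx, yy = np.meshgrid(g, g)
    plane = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    rot = _rotation_to(normal)
    rows = []
    res = 5001  # lipid numbering kept clear of protein residue ranges
    for sign in (+1, -1):
        pts = rot.apply(plane + [0, 0, sign * half_thickness]) + np.asarray(center, float)
        for p in pts:
            rows.append(("P", "P", "POP", res, chain, p, True))
            res += 1
    return build_structure(rows)


@dataclass
class ToyMembraneSystem:
    """Posed pseudo-CYP in a bilayer with prescribed orientation parameters."""

    structure: Structure          # protein + lipids, one frame
    protein: Structure            # protein only
    membrane: MembraneFrame
    domain_map: DomainMap
    prescribed: dict


def make_membrane_system(alpha: float = 25.0, beta: float = 90.0, tilt: float = 40.0,
                         axial_offset: float = 30.0, seed: int = 0) -> ToyMembraneSystem:
    """Pseudo-protein (I-, C-, F-, TM-helices and a heme ring) posed over a
    flat bilayer at prescribed (α, β, heme-tilt, axial COM offset).

    α rotates the I-helix away from the membrane normal; β is realized by the
    azimuth of the C→F inter-helix vector and must satisfy
    |cos β| ≤ sin α (for α = 0 only β = 90° is constructible).  The TM-helix is
    built parallel to the I-helix, so the expected γ equals α.
    """
    for name, val, lo, hi in (("alpha", alpha, 0, 180), ("beta", beta, 0, 180),
                              ("tilt", tilt, 0, 90)):
        if not lo <= val <= hi:
            raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
    sin_a = math.sin(math.radians(alpha))
    target = -math.cos(math.radians(beta))
    if abs(target) > sin_a + 1e-12:
        raise ValueError(f"beta={beta} not constructible with alpha={alpha}: "
                         "need |cos beta| <= sin alpha")
    phi = math.acos(np.clip(target / sin_a, -1, 1)) if sin_a > 1e-12 else 0.0

    helices = [
        make_helix(33, (0, 0, 1), origin=(0, 0, 0), first_res=304),            # I-helix
        make_helix(16, (0, 0, 1), origin=(-6, 0, 0), first_res=130),           # C-helix
        make_helix(18, (0, 0, 1), origin=(6, 0, 0), first_res=211),            # F-helix
        make_helix(20, (0, 0, 1), origin=(0, 12, -8), first_res=7),            # TM-helix
        make_helix(17, (0, 1, 0), origin=(8, -8, -14), first_res=229),         # FG-loop trace
    ]
    rows = []
    for h in helices:
        for a in h.atoms():
            rows.append((a.name, a.element, a.res_name, a.res_id, a.chain, a.xyz))
    rot = Rotation.from_euler("y", alpha, degrees=True) * Rotation.from_euler("z", math.degrees(phi), degrees=True)
    xyz = np.array([r[5] for r in rows], dtype=float)
    xyz = rot.apply(xyz)

    # heme ring placed directly in final coordinates: plane normal at
    # (90 − tilt)° from z, ring centered on the rotated I-helix centroid
    t_rad = math.radians(tilt)
    ring_normal = np.array([math.cos(t_rad), 0.0, math.sin(t_rad)])
    ring_rot = _rotation_to(ring_normal)
    n_ring = len(HEME_RING_ATOMS)
    ang = 2 * np.pi * np.arange(n_ring) / n_ring
    ring = ring_rot.apply(np.column_stack([3.4 * np.cos(ang), 3.4 * np.sin(ang),
                                           np.zeros(n_ring)]))
    center = xyz[:33].mean(axis=0)
    heme_rows = [(nm, "N" if nm.startswith("N") else "C", "HEM", 900, "A",
                  center + ring[k], True) for k, nm in enumerate(HEME_RING_ATOMS)]
    heme_rows.append(("FE", "FE", "HEM", 900, "A", center, True))

    rows = [(r[0], r[1], r[2], r[3], r[4], xyz[k]) for k, r in enumerate(rows)] + heme_rows
    protein = build_structure(rows)
    # shift so the whole-protein COM sits at the prescribed axial offset
    shift = axial_offset - protein.com()[2]
    protein = protein.with_xyz(protein.xyz + np.array([0.0, 0.0, shift]))

    bilayer = make_bilayer((0, 0, 1), half_thickness=19.0)
    combined_rows = []
    for s in (protein, bilayer):
        for a in s.atoms():
            combined_rows.append((a.name, a.element, a.res_name, a.res_id, a.chain, a.xyz, a.het))
    system = build_structure(combined_rows)
    membrane = MembraneFrame((0, 0, 1), (0, 0, 0), 19.0)
    dm = DomainMap.with_defaults({"c_helix": [(130, 145)]})
    expected_beta = beta if sin_a > 1e-12 else 90.0
    return ToyMembraneSystem(structure=system, protein=protein, membrane=membrane,
                             domain_map=dm,
                             prescribed={"alpha": alpha, "beta": expected_beta,
                                         "gamma": alpha, "tilt": tilt,
                                         "axial_offset": axial_offset, "seed": seed})


# ---------------------------------------------------------------------------
# pathway graphs
# ---------------------------------------------------------------------------

def exhaustive_best_coupling(graph: nx.Graph, source: int, target: int) -> tuple[float, tuple]:
    """Brute-force maximum-coupling simple path by DFS enumeration; ties go to
    the lexicographically smallest atom-id sequence.  Independent of the
    shortest-path route used by the analysis code."""
    adj = {u: {v: graph[u][v]["eps"] for v in graph[u]} for u in graph}
    if source not in adj or target not in adj:
        return 0.0, ()
    best = (0.0, ())
    stack = [(source, (source,), 1.0, {source})]
    while stack:
        node, path, eps, seen = stack.pop()
        if node == target:
            if eps > best[0] or (eps == best[0] and (not best[1] or path < best[1])):
                best = (eps, path)
            continue
        for v, e in adj[node].items():
            if v not in seen:
                stack.append((v, path + (v,), eps * e, seen | {v}))
    return best


@dataclass
class ToyGraphSpec:
    """A random small pathway graph with its enumerated best coupling frozen
    at generation time."""

    mol_graph: MolecularGraph
    best_eps: float
    best_path: tuple
    metadata: dict = field(default_factory=dict)


def make_toy_graph(seed: int = 0, n: int | None = None,
                   edge_prob: float = 0.35) -> ToyGraphSpec:
    """Random ≤12-node typed-edge graph; donor is node 0, acceptor node n−1.

    Edge lengths are drawn per type (covalent ~1.5 Å, hbond 2.8–3.4 Å, space
    1.5–6 Å) and the decay factors follow the pathways model.  The stored best
    path comes from exhaustive simple-path enumeration; a disconnected
    donor/acceptor yields a stored no-path (ε = 0).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6]))
    if n is None:
        n = int(rng.integers(4, 13))
    if not 2 <= n <= 12:
        raise ValueError("n must be in [2, 12]")
    params = PathwayParams()
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() >= edge_prob:
            continue
        kind = ["covalent", "hbond", "space"][int(rng.integers(3))]
        if kind == "covalent":
            r, eps = float(rng.uniform(1.3, 1.8)), params.eps_covalent
        elif kind == "hbond":
            r = float(rng.uniform(2.8, 3.4))
            eps = params.eps_hbond(r)
        else:
            r = float(rng.uniform(1.5, 6.0))
            eps = min(params.eps_space(r), 1.0)
        g.add_edge(i, j, kind=kind, length=r, eps=eps, weight=-math.log(eps))
    rows = [("C", "C", "CHN", i + 1, "A", (float(i), 0.0, 0.0)) for i in range(n)]
    structure = build_structure(rows)
    mg = MolecularGraph(graph=g, structure=structure, donor=0, acceptor=n - 1,
                        params=params)
    eps, path = exhaustive_best_coupling(g, 0, n - 1)
    return ToyGraphSpec(mol_graph=mg, best_eps=eps, best_path=path,
                        metadata={"seed": int(seed), "n": n, "edge_prob": edge_prob})


def make_covalent_chain(n_bonds: int, spacing: float = 1.5) -> Structure:
    """Linear chain of carbons spaced within covalent range: n_bonds edges."""
    if n_bonds < 1:
        raise ValueError("need at least one bond")
    rows = [("C", "C", "CHN", i + 1, "A", (spacing * i, 0.0, 0.0))
            for i in range(n_bonds + 1)]
    return build_structure(rows)


def make_mini_redox_site() -> Structure:
    """Synthetic stand-in for the FMN → heme electron-transfer site.

    A hand-built arrangement of an FMN N5, the K456/C457 backbone and a heme
    iron in which the strongest Beratan path is the hydrogen bond from FMN:N5
    to the K456 backbone nitrogen followed by covalent steps through C457's
    thiolate to the iron — the residue-level route FMN-K456-C457-HEME.  This
    is a constructed test geometry, not coordinates from any deposited model.
    """
    rows = [
        ("N5", "N", "FMN", 901, "B", (0.0, 0.0, 0.0), True),
        ("C4A", "C", "FMN", 901, "B", (-1.4, 0.0, 0.0), True),
        # K456 backbone: N accepts the H-bond from N5 at 3.0 Å
        ("N", "N", "LYS", 456, "A", (0.0, 3.0, 0.0)),
        ("CA", "C", "LYS", 456, "A", (1.45, 3.0, 0.0)),
        ("C", "C", "LYS", 456, "A", (2.17, 4.28, 0.0)),
        ("O", "O", "LYS", 456, "A", (1.62, 5.38, 0.0)),
        # C457: backbone then side chain to SG
        ("N", "N", "CYS", 457, "A", (3.50, 4.28, 0.0)),
        ("CA", "C", "CYS", 457, "A", (4.25, 5.58, 0.0)),
        ("CB", "C", "CYS", 457, "A", (5.75, 5.58, 0.0)),
        ("SG", "S", "CYS", 457, "A", (6.70, 7.00, 0.0)),
        ("FE", "FE", "HEM", 900, "A", (8.10, 8.40, 0.0), True),
        ("NA", "N", "HEM", 900, "A", (9.50, 9.80, 0.0), True),
    ]
    return build_structure(rows)
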