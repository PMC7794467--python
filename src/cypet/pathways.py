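"""Electron-tunneling pathway analysis (Beratan–Onuchic pathways model).

The donor–acceptor coupling is the product of per-step decay factors along a
path through a molecular graph whose edges are covalent bonds, hydrogen bonds
and through-space jumps:

    covalent        ε_C = 0.6
    hydrogen bond   ε_H = ε_C² · exp(−1.7 (R − 2.8))
    through-space   ε_S = 0.5 ε_C · exp(−1.7 (R − 1.4))

with R the heavy-atom separation in Å.  The best path maximizes the total
coupling ε_total = Π ε, found exactly as the shortest path under edge weight
−ln ε (all weights positive).  Rates use an activationless golden-rule
prefactor: k_ET = 10¹³ · ε_total² s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .structure import Ensemble, Structure

__all__ = [
    "PathwayParams", "MolecularGraph", "PathResult", "PathwayCensus",
    "build_graph", "best_path", "rate_from_coupling", "pathway_census",
    "histogram2d", "residue_label",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class PathwayParams:
    """Decay constants and geometric cutoffs of the pathways model."""

    eps_covalent: float = 0.6
    covalent_cutoff: float = 1.9      # heavy–heavy bond detection (Å)
    metal_cutoff: float = 2.8         # coordination bonds to Fe & other metals (Å)
    hbond_cutoff: float = 3.5         # donor–acceptor heteroatom distance (Å)
    hbond_decay: float = 1.7
    hbond_r0: float = 2.8
    space_cutoff: float = 6.0
    space_decay: float = 1.7
    space_r0: float = 1.4
    prefactor: float = 1e13           # s⁻¹

    def eps_hbond(self, r: float) -> float:
        return self.eps_covalent ** 2 * math.exp(-self.hbond_decay * (r - self.hbond_r0))

    def eps_space(self, r: float) -> float:
        return 0.5 * self.eps_covalent * math.exp(-self.space_decay * (r - self.space_r0))


_METALS = {"FE", "ZN", "CU", "MN", "CO", "NI", "MO", "MG"}
_HETERO = {"N", "O", "S"}


@dataclass
class MolecularGraph:
    """Typed-edge atom graph with per-edge decay factors.

    ``graph`` is an undirected networkx graph on atom indices; every edge
    carries ``kind`` ({covalent, hbond, space}), ``length`` (Å), ``eps`` and
    ``weight`` = −ln eps.
    """

    graph: nx.Graph
    structure: Structure
    donor: int
    acceptor: int
    params: PathwayParams = field(default_factory=PathwayParams)


def build_graph(structure: Structure, donor_ref: dict, acceptor_ref: dict,
                params: PathwayParams | None = None) -> MolecularGraph:
    """Construct the pathway graph over heavy atoms.

    Covalent edges come from element-aware distance detection (1.9 Å between
    light heavy atoms, 2.8 Å for metal coordination); hydrogen-bond edges link
    N/O/S heteroatoms below 3.5 Å that are not covalently bonded; through-
    space edges link any remaining heavy-atom pairs below 6 Å.  Hydrogens are
    collapsed onto their heavy-atom hosts (they never appear as path nodes).
    """
    params = params or PathwayParams()
    donor = structure.atom_index(**donor_ref)
    acceptor = structure.atom_index(**acceptor_ref)
    heavy = np.flatnonzero(structure.heavy_mask())
    if donor not in heavy or acceptor not in heavy:
        raise ValueError("donor/acceptor must be heavy atoms")
    xyz = structure.xyz[heavy]
    elements = np.array([str(e) for e in structure.element[heavy]])
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in heavy)
    d = cdist(xyz, xyz)
    n = len(heavy)
    metal = np.isin(elements, sorted(_METALS))
    cov_cut = np.where(metal[:, None] | metal[None, :], params.metal_cutoff,
                       params.covalent_cutoff)
    hetero = np.isin(elements, sorted(_HETERO))
    iu, ju = np.triu_indices(n, k=1)
    dist = d[iu, ju]
    in_space = dist < params.space_cutoff
    for i, j, r in zip(iu[in_space], ju[in_space], dist[in_space]):
        a, b = int(heavy[i]), int(heavy[j])
        r = float(r)
        if r < cov_cut[i, j]:
            kind, eps = "covalent", params.eps_covalent
        elif hetero[i] and hetero[j] and r < params.hbond_cutoff:
            kind, eps = "hbond", params.eps_hbond(r)
        else:
            kind, eps = "space", params.eps_space(r)
        eps = min(eps, 1.0)
        if eps <= 0:
            continue
        g.add_edge(a, b, kind=kind, length=r, eps=eps, weight=-math.log(eps))
    return MolecularGraph(graph=g, structure=structure, donor=donor,
                          acceptor=acceptor, params=params)


@dataclass(frozen=True)
class PathResult:
    atoms: tuple                    # atom indices, donor..acceptor; empty if no path
    label: str                      # residue-collapsed, e.g. FMN-K456-C457-HEME
    eps_total: float
    k_et: float

    @property
    def log10_k_et(self) -> float:
        return math.log10(self.k_et) if self.k_et > 0 else -math.inf

    @property
    def connected(self) -> bool:
        return len(self.atoms) > 0


def residue_label(structure: Structure, atom_indices) -> str:
    """Collapse an atom path to residue level: cofactors by residue name,
    amino acids as one-letter code + residue id, consecutive repeats merged."""
    parts: list[str] = []
    for i in atom_indices:
        res = str(structure.res_name[i])
        if res in THREE_TO_ONE:
            tag = f"{THREE_TO_ONE[res]}{int(structure.res_id[i])}"
        elif res == "HEM":
            tag = "HEME"
        else:
            tag = res
        if not parts or parts[-1] != tag:
            parts.append(tag)
    return "-".join(parts)


def _lexicographic_best_path(g: nx.Graph, source: int, target: int,
                             rtol: float = 1e-9) -> list | None:
    """Maximum-coupling path; among ties the lexicographically smallest atom-id
    sequence, reconstructed greedily from the two one-to-all distance maps."""
    try:
        dist_s = nx.single_source_dijkstra_path_length(g, source, weight="weight")
        dist_t = nx.single_source_dijkstra_path_length(g, target, weight="weight")
    except nx.NodeNotFound:
        return None
    if target not in dist_s:
        return None
    total = dist_s[target]
    tol = max(total, 1.0) * rtol
    path = [source]
    node = source
    visited = {source}
    while node != target:
        candidates = [v for v in g.neighbors(node)
                      if v not in visited and v in dist_t
                      and abs(dist_s[node] + g[node][v]["weight"] + dist_t[v] - total) <= tol]
        if not candidates:  # numeric corner: fall back to plain dijkstra
            return nx.dijkstra_path(g, source, target, weight="weight")
        node = min(candidates)
        visited.add(node)
        path.append(node)
    return path


def best_path(mol_graph: MolecularGraph) -> PathResult:
    """Strongest-coupling donor→acceptor path; an explicit no-path result with
    ε_total = 0 if donor and acceptor are disconnected."""
    g, s, t = mol_graph.graph, mol_graph.donor, mol_graph.acceptor
    path = _lexicographic_best_path(g, s, t)
    if path is None:
        return PathResult(atoms=(), label="no-path", eps_total=0.0, k_et=0.0)
    eps_total = 1.0
    for a, b in zip(path, path[1:]):
        eps_total *= g[a][b]["eps"]
    return PathResult(atoms=tuple(path),
                      label=residue_label(mol_graph.structure, path),
                      eps_total=eps_total,
                      k_et=rate_from_coupling(eps_total, mol_graph.params.prefactor))


def rate_from_coupling(eps_total: float, prefactor: float = 1e13) -> float:
    """k_ET = prefactor · ε_total² (s⁻¹); monotone in the coupling."""
    if not 0.0 <= eps_total <= 1.0:
        raise ValueError(f"eps_total {eps_total} outside [0, 1]")
    return prefactor * eps_total ** 2


@dataclass
class PathwayCensus:
    """Best path per frame and the relative occurrence of each residue-level
    route over an ensemble; percentages sum to 100 over observed routes."""

    per_frame: list
    percentages: dict
    n_no_path: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.per_frame)


def pathway_census(ensemble: Ensemble | Structure, donor_ref: dict, acceptor_ref: dict,
                   params: PathwayParams | None = None) -> PathwayCensus:
    """Best Beratan path for every frame; frames without a connected path are
    counted in a separate no-path bin and excluded from the percentages."""
    frames = ensemble.frames if isinstance(ensemble, Ensemble) else [ensemble]
    per_frame: list[PathResult] = []
    for frame in frames:
        per_frame.append(best_path(build_graph(frame, donor_ref, acceptor_ref, params)))
    connected = [p for p in per_frame if p.connected]
    counts: dict[str, int] = {}
    for p in connected:
        counts[p.label] = counts.get(p.label, 0) + 1
    total = len(connected)
    percentages = {lab: 100.0 * c / total for lab, c in
                   sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))} if total else {}
    return PathwayCensus(per_frame=per_frame, percentages=percentages,
                         n_no_path=len(per_frame) - total)


def histogram2d(descriptor: np.ndarray, log10_k_et: np.ndarray, bins=20,
                range=None) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """2D histogram of a descriptor series against log10(k_ET).

    NaN/−inf pairs are excluded and counted; returns (counts, x_edges,
    y_edges, n_excluded).
    """
    x = np.asarray(descriptor, dtype=float)
    y = np.asarray(log10_k_et, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    ok = np.isfinite(x) & np.isfinite(y)
    counts, xe, ye = np.histogram2d(x[ok], y[ok], bins=bins, range=range)
    return counts, xe, ye, int((~ok).sum())
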