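"""Selection funnel for encounter complexes: energy ranking, hierarchical
clustering of poses, membrane-compatibility filtering and representative
selection.

Reproduces the docking post-processing funnel: keep the n lowest-energy
records, cluster them into k clusters (average-linkage agglomerative
clustering on the pairwise RMSD of the mobile body's interface atoms with the
fixed body superposed), take each cluster's medoid, then discard medoids that
fail the interaction-energy screen, clash with or over-extend from the
membrane, or duplicate an already-kept pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .bd import EncounterRecord, RigidBodyModel
from .descriptors import MembraneFrame

__all__ = [
    "ClusterResult", "SelectionReport", "rank_top", "pose_rmsd_matrix",
    "cluster_poses", "membrane_compatibility_filter", "select_representatives",
]


def rank_top(records: list, n: int = 5000) -> list:
    """The n lowest-energy records (all if fewer); ties broken by
    (trajectory id, step index) so the ranking is deterministic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(records, key=lambda r: (r.energy, r.trajectory, r.step))[:n]


@dataclass
class ClusterResult:
    labels: np.ndarray            # cluster label per record, 0-based arbitrary
    order: list                   # cluster labels ranked by size (rank 1 first)
    representatives: dict         # label -> index of medoid record
    records: list
    linkage_method: str = "average"

    def ranked_representatives(self) -> list:
        """Medoid record indices in cluster-size rank order."""
        return [self.representatives[lab] for lab in self.order]

    def sizes(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def pose_rmsd_matrix(records: list, mobile: RigidBodyModel,
                     interface_indices=None) -> np.ndarray:
    """Pairwise RMSD between recorded poses over the mobile body's interface
    atoms, with the fixed body (and hence its frame) superposed by
    construction."""
    idx = (np.asarray(interface_indices, dtype=int) if interface_indices is not None
           else np.arange(mobile.structure.n_atoms))
    coords = np.stack([r.pose.apply(mobile.xyz0)[idx] for r in records])  # (n, m, 3)
    n = len(records)
    rmsd = np.zeros((n, n))
    for i in range(n):
        d = coords[i + 1:] - coords[i]
        rmsd[i, i + 1:] = rmsd[i + 1:, i] = np.sqrt(np.mean(np.sum(d ** 2, axis=2), axis=1))
    return rmsd


def cluster_poses(records: list, mobile: RigidBodyModel, k: int = 10,
                  interface_indices=None, linkage_method: str = "average") -> ClusterResult:
    """Agglomerative clustering of poses cut at k clusters, ranked by size.

    The metric is the interface-atom RMSD of the mobile body between poses.
    Deterministic given the input order; the medoid (smallest mean
    intra-cluster distance, ties by record order) represents each cluster.
    """
    n = len(records)
    if k > n:
        raise ValueError(f"k={k} exceeds number of records ({n})")
    rmsd = pose_rmsd_matrix(records, mobile, interface_indices)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        z = linkage(squareform(rmsd, checks=False), method=linkage_method)
        labels = fcluster(z, t=k, criterion="maxclust") - 1
    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    # rank clusters by size, ties by smallest first record index (stable)
    first_idx = {lab: int(np.flatnonzero(labels == lab)[0]) for lab in sizes}
    order = sorted(sizes, key=lambda lab: (-sizes[lab], first_idx[lab]))
    reps = {}
    for lab in sizes:
        members = np.flatnonzero(labels == lab)
        mean_d = rmsd[np.ix_(members, members)].mean(axis=1)
        reps[lab] = int(members[int(np.argmin(mean_d))])
    return ClusterResult(labels=labels, order=order, representatives=reps,
                         records=list(records), linkage_method=linkage_method)


def membrane_compatibility_filter(record: EncounterRecord, mobile: RigidBodyModel,
                                  membrane: MembraneFrame, anchor_index: int | None = None,
                                  tether_residues: int = 15,
                                  max_extension_per_residue: float = 3.5
                                  ) -> tuple[bool, str]:
    """Membrane consistency of a pose, assuming the fixed CYP sits in the
    membrane as in its simulated pose.

    FAIL if any mobile heavy atom penetrates the bilayer slab, or if the
    FMN-domain N-terminal anchor atom lies farther above the membrane surface
    than the flexible tether can reach (residues × 3.5 Å extended-chain rise).
    """
    if membrane is None:
        raise ValueError("membrane frame undefined")
    xyz = record.pose.apply(mobile.xyz0)
    heavy = mobile.structure.heavy_mask()
    axial = membrane.axial(xyz[heavy])
    if np.any(np.abs(axial) < membrane.half_thickness):
        return False, "membrane_penetration"
    reach = tether_residues * max_extension_per_residue
    if anchor_index is None:
        anchor_index = mobile.marker_atoms.get("anchor")
    if anchor_index is not None:
        height = float(membrane.axial(xyz[int(anchor_index)])[0]) - membrane.half_thickness
        if height > reach:
            return False, "tether_overextension"
    return True, "pass"


@dataclass
class SelectionReport:
    """Named survivors of the funnel plus per-candidate pass/fail bookkeeping."""

    survivors: dict = field(default_factory=dict)   # name -> record index
    reasons: dict = field(default_factory=dict)     # record index -> primary reason
    chain_id: str = "A"

    def names(self) -> list:
        return list(self.survivors)


def select_representatives(cluster_result: ClusterResult, mobile: RigidBodyModel,
                           membrane: MembraneFrame | None = None,
                           energy_max: float | None = None,
                           distinct_rmsd: float = 1.0,
                           interface_indices=None,
                           anchor_index: int | None = None,
                           tether_residues: int = 15,
                           max_extension_per_residue: float = 3.5,
                           chain_id: str = "A") -> SelectionReport:
    """Apply the post-clustering screens to the cluster medoids in size-rank
    order and name the survivors '<chain><cluster rank>' (e.g. 'A3').

    Each discarded candidate carries exactly one primary reason: the first
    failing screen in the order energy → membrane → distinctness.
    """
    report = SelectionReport(chain_id=chain_id)
    kept_records = []
    for rank, rep_idx in enumerate(cluster_result.ranked_representatives(), start=1):
        rec = cluster_result.records[rep_idx]
        if energy_max is not None and rec.energy > energy_max:
            report.reasons[rep_idx] = "energy_above_threshold"
            continue
        if membrane is not None:
            ok, reason = membrane_compatibility_filter(
                rec, mobile, membrane, anchor_index=anchor_index,
                tether_residues=tether_residues,
                max_extension_per_residue=max_extension_per_residue)
            if not ok:
                report.reasons[rep_idx] = reason
                continue
        if kept_records:
            rmsd = pose_rmsd_matrix(kept_records + [rec], mobile, interface_indices)
            if np.any(rmsd[-1, :-1] < distinct_rmsd):
                report.reasons[rep_idx] = "not_distinct"
                continue
        report.survivors[f"{chain_id}{rank}"] = rep_idx
        report.reasons[rep_idx] = "pass"
        kept_records.append(rec)
    return report
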