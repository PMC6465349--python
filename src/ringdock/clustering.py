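"""Pose clustering by fraction of common contacts (FCC).

Two docking poses of the same complex are similar when they bury the same
residue-residue interface, regardless of small rigid shifts; FCC measures
this as the overlap of their inter-molecular residue-contact sets.  The
normalization here is min(|A|, |B|), which makes the similarity symmetric
(the classical formulation normalizes by one side and is asymmetric);
``fcc_reference`` exposes the asymmetric variant.

Clusters are grown leader-style: the unclustered pose with the most
neighbors above the similarity cutoff becomes a leader, its neighbors the
members; clusters below the minimum size dissolve back to unclustered.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .docking import ScoredPose
from .pose import Pose
from .structure_io import StructureModel

__all__ = ["ContactSet", "ClusterResult", "contact_set", "fcc", "cluster_poses"]

CONTACT_CUTOFF = 5.0  # A, any heavy-atom pair
FCC_CUTOFF = 0.75
MIN_CLUSTER_SIZE = 4


@dataclasses.dataclass
class ContactSet:
    """Inter-molecule residue-pair contacts of one pose (receptor residue first)."""

    pose_rank: int | None
    pairs: frozenset  # of ((rec_chain, rec_resnum), (lig_chain, lig_resnum))


def contact_set(
    pose: Pose,
    receptor: StructureModel,
    ligand: StructureModel,
    cutoff: float = CONTACT_CUTOFF,
    rank: int | None = None,
) -> ContactSet:
    """Residue pairs with any heavy-atom distance <= cutoff across the interface."""
    heavy_r = receptor.heavy_mask()
    heavy_l = ligand.heavy_mask()
    rec_pos = receptor.positions[heavy_r]
    lig_pos = pose.apply(ligand.positions)[heavy_l]
    rec_res = list(zip(receptor.chain_ids[heavy_r], receptor.residue_numbers[heavy_r]))
    lig_res = list(zip(ligand.chain_ids[heavy_l], ligand.residue_numbers[heavy_l]))
    tree = cKDTree(rec_pos)
    pairs = set()
    for i, neigh in enumerate(tree.query_ball_point(lig_pos, r=cutoff)):
        for j in neigh:
            pairs.add(
                ((rec_res[j][0], int(rec_res[j][1])), (lig_res[i][0], int(lig_res[i][1])))
            )
    return ContactSet(pose_rank=rank, pairs=frozenset(pairs))


def fcc(a: ContactSet, b: ContactSet) -> float:
    """Fraction of common contacts: |A ∩ B| / min(|A|, |B|), in [0, 1]."""
    if not a.pairs or not b.pairs:
        warnings.warn("empty contact set in FCC; returning 0")
        return 0.0
    inter = len(a.pairs & b.pairs)
    return inter / min(len(a.pairs), len(b.pairs))


def fcc_reference(a: ContactSet, b: ContactSet) -> float:
    """Asymmetric variant normalized by |A| (the classical definition)."""
    if not a.pairs:
        warnings.warn("empty reference contact set in FCC; returning 0")
        return 0.0
    return len(a.pairs & b.pairs) / len(a.pairs)


@dataclasses.dataclass
class ClusterResult:
    clusters: list[list[int]]  # pose ranks, leader first
    representatives: list[int]  # best-scoring member rank per cluster
    fraction_clustered: float
    unclustered: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def top_cluster_index(self, by: str = "best_rank") -> int | None:
        """Index of the dominant cluster.

        ``best_rank`` (default) picks the cluster containing the
        best-scoring clustered pose — the convention for calling a docking
        run's dominant cluster; ``size`` picks the most populated one.
        """
        if not self.clusters:
            return None
        if by == "best_rank":
            return int(np.argmin([min(c) for c in self.clusters]))
        if by == "size":
            return int(np.argmax([len(c) for c in self.clusters]))
        raise ValueError("by must be 'best_rank' or 'size'")


def cluster_poses(
    poses: Sequence[ScoredPose],
    receptor: StructureModel,
    ligand: StructureModel,
    similarity_cutoff: float = FCC_CUTOFF,
    min_size: int = MIN_CLUSTER_SIZE,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> ClusterResult:
    """Leader-style FCC clustering of a ranked ensemble.

    Deterministic given the input order: leader ties break toward the
    better-ranked pose.  The representative of each cluster is its member
    with the best total score.
    """
    if not poses:
        raise ValueError("need at least one pose")
    ranks = [sp.rank if sp.rank is not None else i + 1 for i, sp in enumerate(poses)]
    sets = [
        contact_set(sp.pose, receptor, ligand, cutoff=contact_cutoff, rank=r)
        for sp, r in zip(poses, ranks)
    ]
    n = len(poses)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                sim[i, j] = sim[j, i] = fcc(sets[i], sets[j])
    neighbors = [set(np.flatnonzero(sim[i] >= similarity_cutoff)) for i in range(n)]
    unassigned = set(range(n))
    clusters_idx: list[list[int]] = []
    while unassigned:
        # most-populated leader; ties go to the better (lower) rank
        leader = min(unassigned, key=lambda i: (-len(neighbors[i] & unassigned), ranks[i]))
        members = sorted(neighbors[leader] & unassigned)
        if len(members) < min_size:
            break  # no remaining leader can form a valid cluster
        clusters_idx.append([leader] + [m for m in members if m != leader])
        unassigned -= set(members)
    by_idx = {i: poses[i] for i in range(n)}
    clusters = [[ranks[i] for i in cl] for cl in clusters_idx]
    reps = [
        ranks[min(cl, key=lambda i: by_idx[i].sort_key())]
        for cl in clusters_idx
    ]
    n_clustered = sum(len(c) for c in clusters)
    return ClusterResult(
        clusters=clusters,
        representatives=reps,
        fraction_clustered=n_clustered / n,
        unclustered=sorted(ranks[i] for i in unassigned),
    )
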