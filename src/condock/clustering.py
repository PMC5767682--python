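"""Hierarchical RMSD clustering of top-ranked poses across a chemical series.

Pooled top-ranked engine-A poses from chemically similar compounds are
clustered agglomeratively on the Hungarian-RMSD matrix (relaxed, rectangular
assignment when the compounds differ in atom count) and the tree is cut at a
distance cutoff. The most populated clusters are read as the consensus
binding modes — locations predicted consistently across the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .mol_io import Pose
from .pose_rmsd import pairwise_rmsd_matrix


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterSet:
    poses: list[Pose]
    labels: np.ndarray                  # cluster id per pose (1-based)
    populations: dict[int, int]
    representatives: dict[int, int]     # cluster id -> pose index
    linkage_record: np.ndarray | None = None
    borda_ranks: list[float] | None = None
    distance_matrix: np.ndarray | None = None

    def members(self, cluster_id: int) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == cluster_id]


@dataclass
class ConsensusMode:
    cluster_id: int
    population: int
    member_indices: list[int]
    member_ligands: list[str]
    representative: Pose
    mean_borda_rank: float = float("nan")


def _pick_representative(members: list[int], borda_ranks, dist: np.ndarray) -> int:
    """Best (lowest) final Borda rank; ties by lowest mean RMSD to the cluster."""
    if borda_ranks is not None:
        best = min(borda_ranks[i] for i in members)
        tied = [i for i in members if borda_ranks[i] == best]
    else:
        tied = list(members)
    if len(tied) == 1:
        return tied[0]
    mean_d = {i: float(np.mean([dist[i, j] for j in members if j != i]) if len(members) > 1 else 0.0)
              for i in tied}
    return min(tied, key=lambda i: (mean_d[i], i))


def cluster_poses(poses: list[Pose], linkage_method: str = "complete",
                  cutoff: float = 2.0, mode: str | None = None,
                  borda_ranks: list[float] | None = None) -> ClusterSet:
    """Agglomerative clustering of poses cut at an RMSD cutoff.

    ``mode`` defaults to 'same_element' when all poses share one element
    multiset, else 'relaxed' (cross-ligand rectangular assignment). The
    result is deterministic under fixed input order.
    """
    if linkage_method not in {"complete", "average", "single"}:
        raise ClusteringError(f"unsupported linkage: {linkage_method}")
    if len(poses) < 2:
        warnings.warn("fewer than 2 poses: single trivial cluster", stacklevel=2)
        labels = np.ones(len(poses), dtype=int)
        return ClusterSet(poses=list(poses), labels=labels,
                          populations={1: len(poses)},
                          representatives={1: 0} if poses else {},
                          borda_ranks=borda_ranks)
    if mode is None:
        multisets = {frozenset(p.element_multiset().items()) for p in poses}
        mode = "same_element" if len(multisets) == 1 else "relaxed"
    dist = pairwise_rmsd_matrix(poses, mode=mode)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = fcluster(z, t=cutoff, criterion="distance")
    populations = {int(c): int(np.sum(labels == c)) for c in np.unique(labels)}
    representatives = {
        c: _pick_representative([i for i in range(len(poses)) if labels[i] == c],
                                borda_ranks, dist)
        for c in populations
    }
    return ClusterSet(poses=list(poses), labels=labels, populations=populations,
                      representatives=representatives, linkage_record=z,
                      borda_ranks=borda_ranks, distance_matrix=dist)


def consensus_modes(clusterset: ClusterSet, min_population: int = 2) -> list[ConsensusMode]:
    """Clusters with population ≥ ``min_population``, most populated first;
    ties order by mean Borda rank ascending, then cluster id."""
    modes = []
    for cid, pop in clusterset.populations.items():
        if pop < min_population:
            continue
        members = clusterset.members(cid)
        if clusterset.borda_ranks is not None:
            mean_rank = float(np.mean([clusterset.borda_ranks[i] for i in members]))
        else:
            mean_rank = float("nan")
        modes.append(ConsensusMode(
            cluster_id=cid, population=pop, member_indices=members,
            member_ligands=sorted({clusterset.poses[i].ligand_id for i in members}),
            representative=clusterset.poses[clusterset.representatives[cid]],
            mean_borda_rank=mean_rank,
        ))
    def sort_key(m: ConsensusMode):
        rank = m.mean_borda_rank if np.isfinite(m.mean_borda_rank) else np.inf
        return (-m.population, rank, m.cluster_id)
    modes.sort(key=sort_key)
    return modes
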