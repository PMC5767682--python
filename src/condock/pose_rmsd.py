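"""Symmetry-corrected ligand RMSD via optimal atom assignment.

Docking engines output atoms in arbitrary (and topology-symmetric) orders, so
an index-by-index RMSD overstates the difference between two placements of the
same molecule. The metric here minimises the total squared distance over
atom correspondences with the Hungarian (linear-sum-assignment) algorithm,
constrained so only atoms of the same element may pair. No superposition is
applied anywhere: the comparison is between binding positions in the shared
receptor frame, not between conformers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .mol_io import Pose


class RmsdError(ValueError):
    pass


@dataclass
class AtomAssignment:
    """An element-respecting atom correspondence with its squared-distance cost."""

    pairs: list[tuple[int, int]]
    cost: float  # Å², total over pairs

    def __post_init__(self) -> None:
        a_idx = [i for i, _ in self.pairs]
        b_idx = [j for _, j in self.pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise RmsdError("assignment reuses an atom index")


def naive_rmsd(a: Pose, b: Pose, heavy_only: bool = True) -> float:
    """Index-identical RMSD, defined only for equal ordered element lists."""
    ea, eb = a.elements(heavy_only), b.elements(heavy_only)
    if ea != eb:
        raise RmsdError(
            f"naive RMSD undefined: ordered element lists differ "
            f"({len(ea)} vs {len(eb)} atoms)"
        )
    xa, xb = a.coords(heavy_only), b.coords(heavy_only)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def assign_atoms(a: Pose, b: Pose, same_element: bool = True,
                 heavy_only: bool = True) -> AtomAssignment:
    """Minimum-cost atom assignment between two poses.

    With ``same_element`` the cost matrix is solved block-diagonally per
    element class (equivalent to infinite cross-element costs, but cheaper).
    Without it, every atom of the smaller pose is matched to a distinct atom
    of the larger via a rectangular assignment — the cross-ligand mode used
    when clustering chemically similar but non-identical compounds.
    """
    xa, xb = a.coords(heavy_only), b.coords(heavy_only)
    if xa.shape[0] == 0 or xb.shape[0] == 0:
        raise RmsdError("empty pose")
    if same_element:
        ea = np.array(a.elements(heavy_only))
        eb = np.array(b.elements(heavy_only))
        if a.element_multiset(heavy_only) != b.element_multiset(heavy_only):
            raise RmsdError(
                "same-element assignment needs identical heavy-atom element "
                "multisets; use same_element=False for cross-ligand mode"
            )
        pairs: list[tuple[int, int]] = []
        total = 0.0
        for elem in sorted(set(ea)):
            ia = np.flatnonzero(ea == elem)
            ib = np.flatnonzero(eb == elem)
            cost = cdist(xa[ia], xb[ib], metric="sqeuclidean")
            ri, ci = linear_sum_assignment(cost)
            total += float(cost[ri, ci].sum())
            pairs.extend((int(ia[r]), int(ib[c])) for r, c in zip(ri, ci))
        pairs.sort()
        return AtomAssignment(pairs=pairs, cost=total)
    # relaxed rectangular mode: elements ignored
    cost = cdist(xa, xb, metric="sqeuclidean")
    ri, ci = linear_sum_assignment(cost)
    return AtomAssignment(
        pairs=sorted((int(r), int(c)) for r, c in zip(ri, ci)),
        cost=float(cost[ri, ci].sum()),
    )


def hungarian_rmsd(a: Pose, b: Pose, same_element: bool = True,
                   heavy_only: bool = True) -> float:
    """RMSD under the minimum-cost atom assignment (no superposition).

    Always ≤ the naive RMSD when the latter is defined, and 0 exactly when an
    element-respecting exact correspondence exists.
    """
    assignment = assign_atoms(a, b, same_element=same_element, heavy_only=heavy_only)
    return float(np.sqrt(assignment.cost / len(assignment.pairs)))


def pairwise_rmsd_matrix(poses: list[Pose], mode: str = "same_element",
                         heavy_only: bool = True) -> np.ndarray:
    """Symmetric Hungarian-RMSD matrix over a pose list.

    ``mode`` is 'same_element' or 'relaxed'; relaxed permits poses with
    different atom counts (RMSD over the matched-atom count).
    """
    if mode not in {"same_element", "relaxed"}:
        raise RmsdError(f"unknown mode: {mode}")
    if len(poses) < 2:
        raise RmsdError("need at least 2 poses")
    same = mode == "same_element"
    n = len(poses)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = hungarian_rmsd(
                poses[i], poses[j], same_element=same, heavy_only=heavy_only
            )
    return mat
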