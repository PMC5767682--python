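"""Two-engine consensus stages of the docking protocol.

Stage 1 docks rigidly with both engines inside a generous seed region (an
18 Å sphere / 32 Å cube around the anchor residue's γ-carbon). Poses that
agree between engines — Hungarian RMSD ≤ 2.0 Å — define a consensus subset;
their atom centroid and extent give the refined search region for stage 2,
in which ten side chains are made flexible (mutated residues first, then
polar, then an even spatial spread). Stage-2 pose pairs are again RMSD
filtered, de-duplicated best-rank-first at the same 2.0 Å scale, and capped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mol_io import Pose, PoseSet, Structure
from .pose_rmsd import hungarian_rmsd

logger = logging.getLogger("condock")

MATCH_THRESHOLD = 2.0        # Å, cross-engine pose agreement
REDUNDANCY_RMSD = 2.0        # Å, de-duplication radius
MAX_CONSENSUS_PAIRS = 20
SEED_SPHERE_RADIUS = 18.0    # Å
SEED_BOX_EDGE = 32.0         # Å
N_FLEXIBLE = 10

POLAR_RESIDUES = frozenset(
    {"SER", "THR", "TYR", "CYS", "ASN", "GLN", "HIS", "LYS", "ARG", "ASP", "GLU"}
)
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


class ConsensusError(ValueError):
    pass


@dataclass
class MatchedPair:
    """A cross-engine pose pair whose Hungarian RMSD met the agreement cutoff."""

    pose_a: Pose
    pose_b: Pose
    rmsd: float
    index_a: int = -1
    index_b: int = -1


@dataclass
class SearchRegion:
    """Sphere (engine A) and box (engine B) dialects sharing one centre."""

    center: np.ndarray
    sphere_radius: float
    box_edges: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.box_edges = np.asarray(self.box_edges, dtype=float)
        if self.sphere_radius <= 0 or np.any(self.box_edges <= 0):
            raise ConsensusError("region radius and box edges must be positive")

    def contains_sphere(self, point, tol: float = 1e-9) -> bool:
        return bool(np.linalg.norm(np.asarray(point) - self.center) <= self.sphere_radius + tol)

    def contains_box(self, point, tol: float = 1e-9) -> bool:
        d = np.abs(np.asarray(point) - self.center)
        return bool(np.all(d <= self.box_edges / 2 + tol))


@dataclass
class FlexibleSelection:
    """Side chains granted full flexibility, with per-residue rationale tags."""

    residues: list[tuple[str, int, str]]
    rationale_tags: list[str] = field(default_factory=list)


def _find_anchor_atom(receptor: Structure, chain_id: str, residue_number: int,
                      anchor_atom: str | None = None):
    atoms = receptor.residue_atoms(chain_id, residue_number)
    if not atoms:
        raise ConsensusError(f"anchor residue {chain_id}:{residue_number} not found")
    candidates = [anchor_atom] if anchor_atom else ["CG2", "CG", "CG1"]
    for name in candidates:
        for a in atoms:
            if a.name == name:
                return a
    raise ConsensusError(
        f"anchor residue {chain_id}:{residue_number} ({atoms[0].residue_name}) "
        f"has no atom named {' / '.join(candidates)}"
    )


def seed_region(receptor: Structure, chain_id: str, residue_number: int,
                sphere_radius: float = SEED_SPHERE_RADIUS,
                box_edge: float = SEED_BOX_EDGE,
                anchor_atom: str | None = None) -> SearchRegion:
    """Initial search region centred on the anchor residue's γ-carbon.

    Defaults reproduce the protocol seeds: an 18 Å-radius sphere and a 32 Å
    cube, both centred on the same anchor atom (CG2 for threonine).
    """
    atom = _find_anchor_atom(receptor, chain_id, residue_number, anchor_atom)
    return SearchRegion(center=atom.coords.copy(), sphere_radius=sphere_radius,
                        box_edges=np.full(3, float(box_edge)))


def match_poses(set_a: PoseSet, set_b: PoseSet,
                threshold: float = MATCH_THRESHOLD) -> list[MatchedPair]:
    """All cross-engine pose pairs with Hungarian RMSD ≤ threshold, best first."""
    if set_a.ligand_id != set_b.ligand_id:
        raise ConsensusError(
            f"ligand mismatch: {set_a.ligand_id} vs {set_b.ligand_id}"
        )
    pairs = []
    for i, pa in enumerate(set_a.poses):
        for j, pb in enumerate(set_b.poses):
            r = hungarian_rmsd(pa, pb)
            if r <= threshold:
                pairs.append(MatchedPair(pose_a=pa, pose_b=pb, rmsd=r,
                                         index_a=i, index_b=j))
    pairs.sort(key=lambda p: (p.rmsd, p.index_a, p.index_b))
    logger.info("match_poses: %d/%d cross pairs within %.2f Å",
                len(pairs), len(set_a) * len(set_b), threshold)
    return pairs


def _consensus_coords(pairs: list[MatchedPair]) -> np.ndarray:
    """Heavy-atom coordinates of every pose appearing in the pair list."""
    if not pairs:
        raise ConsensusError("no matched pairs")
    blocks = []
    for p in pairs:
        blocks.append(p.pose_a.coords(heavy_only=True))
        blocks.append(p.pose_b.coords(heavy_only=True))
    return np.vstack(blocks)


def consensus_centroid(pairs: list[MatchedPair]) -> np.ndarray:
    """Unweighted mean of all heavy-atom positions over every consensus pose."""
    return _consensus_coords(pairs).mean(axis=0)


def derive_region(pairs: list[MatchedPair], pad: float = 0.0) -> SearchRegion:
    """Refined region enclosing every consensus atom.

    Sphere radius = max atom distance from the centroid + pad; box edges =
    doubled per-axis extent about the centroid + 2·pad. Zero-extent axes are
    floored at 1 Å (engines reject zero volumes) with a warning.
    """
    coords = _consensus_coords(pairs)
    center = coords.mean(axis=0)
    d = coords - center
    radius = float(np.max(np.linalg.norm(d, axis=1))) + pad
    edges = 2.0 * np.max(np.abs(d), axis=0) + 2.0 * pad
    if radius < 1.0 or np.any(edges < 1.0):
        warnings.warn("degenerate search region floored at 1 Å", stacklevel=2)
        radius = max(radius, 1.0)
        edges = np.maximum(edges, 1.0)
    return SearchRegion(center=center, sphere_radius=radius, box_edges=edges)


def _side_chain_atoms(atoms):
    side = [a for a in atoms if a.name not in BACKBONE_ATOMS and not a.is_hydrogen]
    return side or [a for a in atoms if a.name == "CA"]  # GLY: fall back to CA


def _greedy_farthest_point(candidates: list[tuple[tuple[str, int, str], np.ndarray]],
                           selected_points: list[np.ndarray], k: int):
    """Greedy max-min spread: repeatedly take the candidate whose centroid is
    farthest from everything already selected; deterministic tie-break by
    (chain_id, residue_number). With an empty selection the first pick is the
    lowest-keyed candidate."""
    chosen: list[tuple[str, int, str]] = []
    pool = sorted(candidates, key=lambda c: (c[0][0], c[0][1]))
    pts = [p.copy() for p in selected_points]
    while pool and len(chosen) < k:
        if not pts:
            best = pool[0]
        else:
            best, best_d = None, -1.0
            for cand in pool:
                d = min(float(np.linalg.norm(cand[1] - q)) for q in pts)
                if d > best_d + 1e-12:
                    best, best_d = cand, d
            assert best is not None
        chosen.append(best[0])
        pts.append(best[1])
        pool.remove(best)
    return chosen


def select_flexible_residues(receptor: Structure, region: SearchRegion,
                             n: int = N_FLEXIBLE,
                             mutated: list[tuple[str, int]] | None = None,
                             polar_set: frozenset = POLAR_RESIDUES) -> FlexibleSelection:
    """Choose ``n`` side chains for stage-2 flexibility, in priority tiers.

    Tier 1: residues mutated in the accompanying functional study; tier 2:
    polar residues; tier 3: remaining residues. Within tiers 2–3, greedy
    farthest-point selection on side-chain centroids spreads the picks evenly
    over the region. A residue is "in region" when any side-chain heavy atom
    lies inside the sphere dialect.
    """
    if n < 1:
        raise ConsensusError("n must be >= 1")
    mutated = mutated or []
    mutated_set = {(c, r) for c, r in mutated}
    candidates: list[tuple[tuple[str, int, str], np.ndarray]] = []
    for chain_id, resnum, resname in receptor.residues():
        atoms = receptor.residue_atoms(chain_id, resnum)
        side = _side_chain_atoms(atoms)
        if any(region.contains_sphere(a.coords) for a in side):
            centroid = np.mean([a.coords for a in side], axis=0)
            candidates.append(((chain_id, resnum, resname), centroid))
    if len(candidates) < n:
        warnings.warn(
            f"only {len(candidates)} candidate residues in region (requested {n})",
            stacklevel=2,
        )
    by_key = {c[0][:2]: c for c in candidates}
    tier1 = [by_key[m] for m in sorted(mutated_set) if m in by_key]
    taken = {c[0][:2] for c in tier1}
    tier2_pool = [c for c in candidates
                  if c[0][:2] not in taken and c[0][2] in polar_set]
    tier3_pool = [c for c in candidates
                  if c[0][:2] not in taken and c[0][2] not in polar_set]

    residues = [c[0] for c in tier1][:n]
    tags = ["mutated"] * len(residues)
    pts = [c[1] for c in tier1]
    if len(residues) < n:
        picks = _greedy_farthest_point(tier2_pool, pts, n - len(residues))
        keymap = {c[0]: c[1] for c in tier2_pool}
        for r in picks:
            residues.append(r)
            tags.append("polar")
            pts.append(keymap[r])
    if len(residues) < n:
        picks = _greedy_farthest_point(tier3_pool, pts, n - len(residues))
        keymap = {c[0]: c[1] for c in tier3_pool}
        for r in picks:
            residues.append(r)
            tags.append("spread")
            pts.append(keymap[r])
    return FlexibleSelection(residues=residues, rationale_tags=tags)


def deduplicate_pairs(pairs: list[MatchedPair],
                      order: list[int] | None = None,
                      max_pairs: int = MAX_CONSENSUS_PAIRS,
                      redundancy_rmsd: float = REDUNDANCY_RMSD) -> list[MatchedPair]:
    """Greedy redundancy removal in rank order, capped at ``max_pairs``.

    ``order`` gives pair indices best-first (e.g. the Borda final order);
    input order is used when omitted. A pair is kept only if its engine-A
    pose sits more than ``redundancy_rmsd`` from every already-kept engine-A
    pose.
    """
    idx = list(order) if order is not None else list(range(len(pairs)))
    kept: list[MatchedPair] = []
    for i in idx:
        p = pairs[i]
        if all(hungarian_rmsd(p.pose_a, q.pose_a) > redundancy_rmsd for q in kept):
            kept.append(p)
            if len(kept) >= max_pairs:
                break
    logger.info("deduplicate_pairs: kept %d of %d", len(kept), len(pairs))
    return kept
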