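"""Ligand–receptor geometry on docked complexes.

Reports the quantities used to rationalise structure–activity data: minimal
heavy-atom distances between a ligand moiety and named side chains, geometric
hydrogen bonds, and the residues lining the pocket. Distances follow the
closest-heavy-atom convention by default, with a centroid mode available,
since published "∼X Å from residue" figures rarely state their convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .consensus import BACKBONE_ATOMS
from .mol_io import Atom, Structure


class InteractionError(ValueError):
    pass


HBOND_DMAX = 3.5      # Å, donor–acceptor heavy-atom distance
HBOND_ANGLE_MIN = 120.0  # °, D–H···A
POCKET_CUTOFF = 4.5   # Å
_POLAR = {"N", "O"}
_COVALENT_H = 1.3     # Å, H bonded to donor if within this distance


@dataclass
class HBond:
    donor: Atom
    hydrogen: Atom | None
    acceptor: Atom
    distance: float
    angle: float | None  # None in distance-only mode


@dataclass
class ContactReport:
    distances: dict[str, float] = field(default_factory=dict)
    centroid_distances: dict[str, float] = field(default_factory=dict)
    hbonds: list[HBond] = field(default_factory=list)
    pocket: list[tuple[str, int, str, str]] = field(default_factory=list)  # +, chain, num, name
    distance_only_hbonds: bool = False


def _atoms_of_selection(complex: Structure, ligand_sel) -> list[Atom]:
    """Resolve a ligand selection: a list of Atoms, a residue name, or a
    callable predicate over atoms."""
    if callable(ligand_sel):
        return [a for a in complex.atoms if ligand_sel(a)]
    if isinstance(ligand_sel, str):
        return [a for a in complex.atoms if a.residue_name == ligand_sel]
    return list(ligand_sel)


def _residue_atoms(complex: Structure, residue, side_chain_only: bool) -> list[Atom]:
    chain_id, resnum = residue
    atoms = complex.residue_atoms(chain_id, resnum)
    if side_chain_only:
        atoms = [a for a in atoms if a.name not in BACKBONE_ATOMS]
    return [a for a in atoms if not a.is_hydrogen]


def min_distance(complex: Structure, ligand_sel, residue: tuple[str, int],
                 side_chain_only: bool = True, mode: str = "closest") -> float:
    """Distance from a ligand selection to one residue.

    ``mode='closest'``: minimum over all heavy-atom pairs (default).
    ``mode='centroid'``: distance between heavy-atom centroids.
    """
    lig = [a for a in _atoms_of_selection(complex, ligand_sel) if not a.is_hydrogen]
    res = _residue_atoms(complex, residue, side_chain_only)
    if not lig:
        raise InteractionError("empty ligand selection")
    if not res:
        raise InteractionError(f"empty residue selection {residue[0]}:{residue[1]}")
    xl = np.array([a.coords for a in lig])
    xr = np.array([a.coords for a in res])
    if mode == "centroid":
        return float(np.linalg.norm(xl.mean(axis=0) - xr.mean(axis=0)))
    return float(cdist(xl, xr).min())


def _attached_hydrogens(donor: Atom, pool: list[Atom]) -> list[Atom]:
    return [h for h in pool
            if h.is_hydrogen and np.linalg.norm(h.coords - donor.coords) <= _COVALENT_H]


def _dha_angle(donor: Atom, h: Atom, acceptor: Atom) -> float:
    v1 = donor.coords - h.coords
    v2 = acceptor.coords - h.coords
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(complex: Structure, ligand_sel, d_max: float = HBOND_DMAX,
                  angle_min: float = HBOND_ANGLE_MIN) -> list[HBond]:
    """Geometric hydrogen bonds between the ligand and the receptor.

    A bond requires polar (N/O) donor and acceptor within ``d_max`` and,
    when the donor carries an explicit hydrogen, a D–H···A angle of at least
    ``angle_min``. Polar atoms with no modelled hydrogens are treated in
    distance-only mode (angle=None), flagged on the report.
    """
    lig = _atoms_of_selection(complex, ligand_sel)
    lig_ids = {id(a) for a in lig}
    rec = [a for a in complex.atoms if id(a) not in lig_ids]
    lig_polar = [a for a in lig if a.element in _POLAR]
    rec_polar = [a for a in rec if a.element in _POLAR]
    # Mode is decided per structure: with explicit hydrogens anywhere, only
    # H-bearing polar atoms can donate and the angle criterion applies; a
    # hydrogen-free structure falls back to distance-only screening.
    has_h = any(a.is_hydrogen for a in complex.atoms)
    bonds: list[HBond] = []
    seen: set[frozenset] = set()
    for pool_d, pool_a, d_pool_all in ((lig_polar, rec_polar, lig),
                                       (rec_polar, lig_polar, rec)):
        for donor in pool_d:
            hs = _attached_hydrogens(donor, d_pool_all)
            if has_h and not hs:
                continue
            for acceptor in pool_a:
                d = float(np.linalg.norm(donor.coords - acceptor.coords))
                if d > d_max or d < 1e-6:
                    continue
                key = frozenset((id(donor), id(acceptor)))
                if key in seen:
                    continue
                if hs:
                    angles = [_dha_angle(donor, h, acceptor) for h in hs]
                    best = max(angles)
                    if best >= angle_min:
                        hbest = hs[int(np.argmax(angles))]
                        bonds.append(HBond(donor, hbest, acceptor, d, best))
                        seen.add(key)
                else:
                    bonds.append(HBond(donor, None, acceptor, d, None))
                    seen.add(key)
    return bonds


def pocket_residues(complex: Structure, ligand_sel,
                    pocket_cutoff: float = POCKET_CUTOFF) -> list[tuple[str, str, int, str]]:
    """Residues with any side-chain heavy atom within ``pocket_cutoff`` of the
    ligand, annotated with the interface role of their chain.

    The chain contributing the most contact atoms is labelled '+' (principal
    subunit); every other chain '−'.
    """
    lig = [a for a in _atoms_of_selection(complex, ligand_sel) if not a.is_hydrogen]
    if not lig:
        raise InteractionError("empty ligand selection")
    xl = np.array([a.coords for a in lig])
    hits: list[tuple[str, int, str]] = []
    chain_contacts: dict[str, int] = {}
    for chain_id, resnum, resname in complex.residues():
        atoms = _residue_atoms(complex, (chain_id, resnum), side_chain_only=True)
        atoms = [a for a in atoms if not a.is_hetero]
        if not atoms:
            continue
        xr = np.array([a.coords for a in atoms])
        d = cdist(xr, xl)
        n_contact = int(np.sum(d.min(axis=1) <= pocket_cutoff))
        if n_contact:
            hits.append((chain_id, resnum, resname))
            chain_contacts[chain_id] = chain_contacts.get(chain_id, 0) + n_contact
    principal = max(chain_contacts, key=lambda c: (chain_contacts[c], c), default=None)
    return [(("+" if c == principal else "-"), c, num, name) for c, num, name in hits]


def contact_report(complex: Structure, ligand_sel,
                   residues: list[tuple[str, int]] | None = None,
                   d_max: float = HBOND_DMAX, angle_min: float = HBOND_ANGLE_MIN,
                   pocket_cutoff: float = POCKET_CUTOFF) -> ContactReport:
    """Full report: named-residue distances (both conventions), hydrogen
    bonds, and the pocket list."""
    report = ContactReport()
    for res in residues or []:
        key = f"{res[0]}:{res[1]}"
        report.distances[key] = min_distance(complex, ligand_sel, res)
        report.centroid_distances[key] = min_distance(complex, ligand_sel, res,
                                                      mode="centroid")
    report.hbonds = detect_hbonds(complex, ligand_sel, d_max, angle_min)
    report.distance_only_hbonds = any(h.angle is None for h in report.hbonds)
    report.pocket = pocket_residues(complex, ligand_sel, pocket_cutoff)
    return report
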