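"""Deterministic synthetic fixtures for every pipeline stage.

Generates symmetric toy ligands, two-engine pose ensembles with planted
consensus binding modes and scattered decoys, rank-structured score tables,
toy receptor pockets with tagged mutated residues, and planted density grids.
Each generator is bit-deterministic given its seed, and ground-truth labels
accompany every ensemble so matching/ranking/clustering recovery can be
scored without any external file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mol_io import Atom, Pose, PoseSet, Structure

# Default pose counts mirror the protocol's two engines: 50 diverse solutions
# from the first engine, a maximum of 20 from the second.
DEFAULT_POSES = (50, 20)
MODE_CLEARANCE = 8.0  # Å; minimum decoy distance from any planted mode centre

POLAR_RESNAMES = ("SER", "THR", "TYR", "ASN", "GLN", "HIS", "LYS", "ARG", "ASP", "GLU")


@dataclass
class FixtureSpec:
    """Conditions for a planted two-engine pose ensemble."""

    seed: int = 0
    poses_per_engine: tuple[int, int] = DEFAULT_POSES
    n_modes: int = 2
    noise_sd: float = 0.3          # Å, per-coordinate Gaussian placement noise
    permute_atoms: bool = True     # shuffle atoms within element classes
    decoy_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.poses_per_engine):
            raise ValueError("pose counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must lie in [0, 1]")


def make_symmetric_ligand(fold: int, radius: float = 1.4, marker: bool = False,
                          ligand_id: str = "LIG", engine: str = "fixture") -> Pose:
    """Planar regular n-gon of carbons, optionally with an axial nitrogen marker.

    The marker breaks the n-fold rotational symmetry (different element), so
    the same scaffold serves both symmetry-degenerate and symmetry-broken
    RMSD tests.
    """
    if fold < 2:
        raise ValueError("fold must be >= 2")
    angles = 2 * np.pi * np.arange(fold) / fold
    atoms = [
        Atom(serial=i + 1, name=f"C{i + 1}", element="C",
             coords=np.array([radius * np.cos(t), radius * np.sin(t), 0.0]),
             residue_name="LIG", residue_number=1, chain_id="X", is_hetero=True)
        for i, t in enumerate(angles)
    ]
    if marker:
        atoms.append(Atom(serial=fold + 1, name="N1", element="N",
                          coords=np.array([0.0, 0.0, 1.5]),
                          residue_name="LIG", residue_number=1, chain_id="X",
                          is_hetero=True))
    return Pose(ligand_id=ligand_id, engine=engine, atoms=atoms)


def rotate_pose(pose: Pose, angle_deg: float, axis: str = "z") -> Pose:
    """Rigid rotation of a pose about a coordinate axis through the origin."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    rot = {
        "z": np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]),
        "x": np.array([[1, 0, 0], [0, c, -s], [0, s, c]]),
        "y": np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]]),
    }[axis]
    atoms = [
        Atom(a.serial, a.name, a.element, rot @ a.coords, a.residue_name,
             a.residue_number, a.chain_id, a.is_hetero)
        for a in pose.atoms
    ]
    return Pose(pose.ligand_id, pose.engine, atoms, dict(pose.scores))


def translate_pose(pose: Pose, vector) -> Pose:
    v = np.asarray(vector, dtype=float)
    atoms = [
        Atom(a.serial, a.name, a.element, a.coords + v, a.residue_name,
             a.residue_number, a.chain_id, a.is_hetero)
        for a in pose.atoms
    ]
    return Pose(pose.ligand_id, pose.engine, atoms, dict(pose.scores))


def random_pose(n_atoms: int, rng: np.random.Generator, elements=("C", "N", "O"),
                box: float = 6.0, ligand_id: str = "RND", engine: str = "fixture") -> Pose:
    """Random heavy-atom cloud for oracle tests (elements cycled)."""
    atoms = [
        Atom(serial=i + 1, name=f"A{i + 1}", element=elements[i % len(elements)],
             coords=rng.uniform(-box / 2, box / 2, size=3),
             residue_name="LIG", residue_number=1, chain_id="X", is_hetero=True)
        for i in range(n_atoms)
    ]
    return Pose(ligand_id=ligand_id, engine=engine, atoms=atoms)


def _permute_within_elements(pose: Pose, rng: np.random.Generator) -> Pose:
    elems = np.array([a.element for a in pose.atoms])
    order = np.arange(len(pose.atoms))
    for e in np.unique(elems):
        idx = np.flatnonzero(elems == e)
        order[idx] = rng.permutation(idx)
    atoms = [pose.atoms[i] for i in order]
    atoms = [
        Atom(j + 1, a.name, a.element, a.coords.copy(), a.residue_name,
             a.residue_number, a.chain_id, a.is_hetero)
        for j, a in enumerate(atoms)
    ]
    return Pose(pose.ligand_id, pose.engine, atoms, dict(pose.scores))


def _mode_centers(n_modes: int, rng: np.random.Generator,
                  spacing: float = 12.0) -> np.ndarray:
    """Well-separated planted mode centres (pairwise >= spacing)."""
    base = np.array([
        [0.0, 0.0, 0.0], [spacing, 0.0, 0.0], [0.0, spacing, 0.0],
        [0.0, 0.0, spacing], [spacing, spacing, 0.0],
    ])
    if n_modes > len(base):
        raise ValueError(f"at most {len(base)} planted modes supported")
    jitter = rng.uniform(-0.5, 0.5, size=(n_modes, 3))
    return base[:n_modes] + jitter


def _sample_decoy(centers: np.ndarray, rng: np.random.Generator,
                  box: float = 40.0) -> np.ndarray:
    """Rejection-sample a decoy site >= MODE_CLEARANCE from every mode centre."""
    for _ in range(10000):
        p = rng.uniform(-box / 2, box / 2, size=3)
        if np.min(np.linalg.norm(centers - p, axis=1)) >= MODE_CLEARANCE:
            return p
    raise RuntimeError("decoy rejection sampling failed")


@dataclass
class EnsembleTruth:
    """Ground truth: planted mode id per (engine, pose_index); -1 for decoys."""

    mode_centers: np.ndarray
    labels: dict[tuple[str, int], int] = field(default_factory=dict)

    def mode_of(self, engine: str, pose_index: int) -> int:
        return self.labels[(engine, pose_index)]


def make_pose_ensemble(spec: FixtureSpec, template: Pose,
                       engines: tuple[str, str] = ("engine_A", "engine_B"),
                       ligand_id: str = "LIG") -> tuple[PoseSet, PoseSet, EnsembleTruth]:
    """Two-engine pose ensemble with planted consensus modes and decoys.

    Non-decoy poses are the template placed at a mode centre with per-atom
    Gaussian coordinate noise (sd ``noise_sd``); modes are assigned
    round-robin so every mode is populated by both engines. Decoys are
    scattered at least 8 Å from every mode centre.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _mode_centers(spec.n_modes, rng)
    truth = EnsembleTruth(mode_centers=centers)
    sets = []
    for engine, n_poses in zip(engines, spec.poses_per_engine):
        n_decoys = int(round(spec.decoy_fraction * n_poses))
        poses = []
        for i in range(n_poses):
            if i < n_poses - n_decoys:
                mode = i % spec.n_modes
                origin = centers[mode]
            else:
                mode = -1
                origin = _sample_decoy(centers, rng)
            noise = rng.normal(0.0, spec.noise_sd, size=(len(template.atoms), 3))
            atoms = [
                Atom(a.serial, a.name, a.element, a.coords + origin + noise[k],
                     a.residue_name, a.residue_number, a.chain_id, a.is_hetero)
                for k, a in enumerate(template.atoms)
            ]
            pose = Pose(ligand_id=ligand_id, engine=engine, atoms=atoms)
            if spec.permute_atoms:
                pose = _permute_within_elements(pose, rng)
            poses.append(pose)
            truth.labels[(engine, i)] = mode
        sets.append(PoseSet(ligand_id=ligand_id, engine=engine, poses=poses))
    return sets[0], sets[1], truth


def make_score_table(set_a: PoseSet, set_b: PoseSet,
                     planted_order: list[tuple[str, int]] | None = None,
                     noise: float = 0.0, seed: int = 0,
                     truth: EnsembleTruth | None = None):
    """Three-metric score table whose noiseless Borda aggregate reproduces a
    planted quality order.

    ``planted_order`` lists (engine, pose_index) best-first over all poses of
    both sets; by default mode poses precede decoys (using ``truth``) and
    ties break by (engine, index). Metrics: ``vina`` (lower better),
    ``goldscore`` and ``chemplp`` (higher better).
    """
    rng = np.random.default_rng(seed)
    keys = [(set_a.engine, i) for i in range(len(set_a))] + \
           [(set_b.engine, i) for i in range(len(set_b))]
    if planted_order is None:
        if truth is not None:
            keys_sorted = sorted(keys, key=lambda k: (truth.labels[k] < 0, k))
        else:
            keys_sorted = list(keys)
        planted_order = keys_sorted
    if set(planted_order) != set(keys):
        raise ValueError("planted_order must cover every pose of both sets")
    table = {}
    for pos, key in enumerate(planted_order):
        table[(set_a.ligand_id, key[0], key[1])] = {
            "vina": -12.0 + 0.25 * pos + noise * rng.normal(),
            "goldscore": 90.0 - 1.0 * pos + noise * rng.normal(),
            "chemplp": 80.0 - 0.5 * pos + noise * rng.normal(),
        }
    for ps in (set_a, set_b):
        for i, pose in enumerate(ps.poses):
            pose.scores.update(table[(ps.ligand_id, ps.engine, i)])
    return table


def make_toy_receptor(n_residues: int = 30, pocket_center=(0.0, 0.0, 0.0),
                      seed: int = 0, n_mutated: int = 3) -> Structure:
    """Toy pocket: residues ringed around a centre, CB/CG side-chain stubs.

    Residue names cycle ALA plus polar types; the first ``n_mutated``
    pocket-facing residues are tagged in ``annotations['mutated']`` (their
    positions mirror a transmembrane mutation panel in toy numbering). One
    THR near the centre carries a CG2 atom so anchor-based search-region
    seeding is testable.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(pocket_center, dtype=float)
    atoms: list[Atom] = []
    serial = 1
    mutated: list[tuple[str, int]] = []
    # anchor THR at the pocket centre, residue number 277 in toy numbering
    for name, offset in (("N", (-1.0, 0.4, 0)), ("CA", (0, 0, 0)),
                         ("C", (1.2, 0.3, 0)), ("O", (1.8, 1.3, 0)),
                         ("CB", (0.2, -1.4, 0.3)), ("CG2", (0.1, -2.2, 1.4)),
                         ("OG1", (-0.6, -2.0, -0.7))):
        atoms.append(Atom(serial, name, element_of(name), center + np.array(offset),
                          "THR", 277, "A", False))
        serial += 1
    ring_r = 8.0
    for i in range(n_residues):
        t = 2 * np.pi * i / n_residues
        z = rng.uniform(-4, 4)
        pos = center + np.array([ring_r * np.cos(t), ring_r * np.sin(t), z])
        if i < n_mutated:
            resname = ("TRP", "SER", "LEU", "MET", "MET")[i % 5]
        else:
            resname = "ALA" if i % 2 else POLAR_RESNAMES[i % len(POLAR_RESNAMES)]
        resnum = 100 + i
        inward = (center - pos) / np.linalg.norm(center - pos)
        backbone = [("N", pos + [-0.8, 0.5, 0]), ("CA", pos), ("C", pos + [1.0, 0.5, 0]),
                    ("O", pos + [1.6, 1.4, 0])]
        side = [("CB", pos + 1.5 * inward)]
        if resname != "ALA":
            side.append(("CG", pos + 3.0 * inward))
        for name, xyz in backbone + side:
            atoms.append(Atom(serial, name, element_of(name), np.asarray(xyz, float),
                              resname, resnum, "A", False))
            serial += 1
        if i < n_mutated:
            mutated.append(("A", resnum))
    return Structure(atoms=atoms, annotations={"mutated": mutated,
                                               "anchor": ("A", 277)})


def element_of(atom_name: str) -> str:
    """Element of a standard protein atom name (N/CA/CB/OG1/...)."""
    return atom_name.strip()[0]


def make_planted_density(model: Structure, resolution: float = 6.2,
                         voxel: float = 2.0, displaced_segment=None,
                         displacement=(10.0, 0.0, 0.0)):
    """Simulated map of a model, optionally with one segment's density displaced.

    ``displaced_segment`` is (chain_id, first_resnum, last_resnum); its atoms
    contribute density at a translated location, creating a planted wrong-
    register region for loop-ranking tests.
    """
    from .model_assessment import simulate_map
    from .mol_io import Atom as _Atom, Structure as _Structure

    if displaced_segment is None:
        return simulate_map(model, resolution=resolution, voxel=voxel)
    chain, lo, hi = displaced_segment
    shift = np.asarray(displacement, dtype=float)
    atoms = []
    for a in model.atoms:
        if a.chain_id == chain and lo <= a.residue_number <= hi:
            atoms.append(_Atom(a.serial, a.name, a.element, a.coords + shift,
                               a.residue_name, a.residue_number, a.chain_id,
                               a.is_hetero))
        else:
            atoms.append(a)
    ghost = _Structure(atoms=atoms, annotations=dict(model.annotations))
    # pad the grid with the union of both models so the shifted density fits
    return simulate_map(ghost, resolution=resolution, voxel=voxel,
                        grid_like=None, extra_points=model.coords())
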