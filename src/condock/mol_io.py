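"""Structural and tabular I/O for the consensus-docking pipeline.

Receptors are read from PDB (via gemmi); ligand pose sets from multi-MODEL
PDB, SDF or MOL2 (via gemmi/RDKit); per-pose docking scores from delimited
sidecar tables (via pandas). All coordinates live in one shared rigid frame:
docking engines place ligands in the receptor frame, and nothing downstream
ever superposes.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("condock")

# Subset of elements that can appear in small molecules / proteins; used to
# validate parsed symbols and to infer elements from PDB atom names.
_KNOWN_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "MN", "FE", "CO", "NI", "CU",
    "ZN", "SE", "BR", "I",
}

# Two-letter element symbols whose names can collide with C/N/O/H prefixes.
_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "SE", "CU", "NI", "CO"}


class MolIOError(ValueError):
    """Raised for malformed or inconsistent structural/tabular inputs."""


def normalize_element(symbol: str) -> str:
    """Canonicalise an element symbol ('CL' -> 'Cl', 'c' -> 'C')."""
    s = symbol.strip()
    if not s:
        raise MolIOError("empty element symbol")
    if s.upper() not in _KNOWN_ELEMENTS:
        raise MolIOError(f"unknown element symbol: {symbol!r}")
    return s[0].upper() + s[1:].lower()


def element_from_atom_name(name: str, residue_name: str = "") -> str:
    """Infer the element from a PDB atom name when the element column is blank.

    PDB v3 convention: columns 13-14 hold the element right-justified, so a
    name like ' CA ' is carbon while 'CA  ' in an ion residue is calcium.
    Here we get the stripped name, so we use the two-letter table plus the
    leading-letter rule.
    """
    n = name.strip().upper()
    if not n:
        raise MolIOError("cannot infer element from empty atom name")
    if n[:2] in _TWO_LETTER and (residue_name.strip().upper() == n[:2] or n[:2] in {"CL", "BR", "SE"}):
        return normalize_element(n[:2])
    head = n.lstrip("0123456789")
    if head[:1] in {"C", "N", "O", "S", "P", "H", "F", "I", "K", "B"}:
        return normalize_element(head[0])
    return normalize_element(head[:2])


@dataclass
class Atom:
    """One atom record in the shared receptor frame."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    residue_name: str = ""
    residue_number: int = 0
    chain_id: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise MolIOError(f"atom {self.name}: coordinates must be a finite 3-vector")
        self.element = normalize_element(self.element)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Structure:
    """An ordered atom list with a per-chain index and free-form annotations."""

    atoms: list[Atom]
    annotations: dict = field(default_factory=dict)

    @property
    def chains(self) -> dict[str, list[Atom]]:
        out: dict[str, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        sel = [a for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        return np.array([a.coords for a in sel], dtype=float).reshape(-1, 3)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_number, residue_name) triples."""
        seen: list[tuple[str, int, str]] = []
        prev = None
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.residue_name)
            if key != prev:
                if key not in seen:
                    seen.append(key)
                prev = key
        return seen

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[Atom]:
        return [
            a for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def het_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_hetero]


@dataclass
class Pose:
    """One docked ligand conformation with its engine tag and metric scores."""

    ligand_id: str
    engine: str
    atoms: list[Atom]
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(not a.is_hydrogen for a in self.atoms):
            raise MolIOError(f"pose of {self.ligand_id}: needs at least one heavy atom")

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        sel = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.coords for a in sel], dtype=float).reshape(-1, 3)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def elements(self, heavy_only: bool = True) -> list[str]:
        sel = self.heavy_atoms() if heavy_only else self.atoms
        return [a.element for a in sel]

    def element_multiset(self, heavy_only: bool = True) -> Counter:
        return Counter(self.elements(heavy_only=heavy_only))


@dataclass
class PoseSet:
    """All poses of one ligand from one engine, in file order."""

    ligand_id: str
    engine: str
    poses: list[Pose]

    def __post_init__(self) -> None:
        for p in self.poses:
            if p.ligand_id != self.ligand_id or p.engine != self.engine:
                raise MolIOError(
                    f"pose set {self.ligand_id}/{self.engine}: member pose "
                    f"tagged {p.ligand_id}/{p.engine}"
                )

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


# ---------------------------------------------------------------------------
# Receptor reading
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: list[tuple[Atom, str, float]]) -> list[Atom]:
    """Keep one conformer per (chain, resnum, name): highest occupancy, tie 'A'."""
    best: dict[tuple, tuple[Atom, str, float]] = {}
    order: list[tuple] = []
    for atom, altloc, occ in atoms:
        key = (atom.chain_id, atom.residue_number, atom.name)
        if key not in best:
            best[key] = (atom, altloc, occ)
            order.append(key)
        else:
            _, prev_alt, prev_occ = best[key]
            if occ > prev_occ or (occ == prev_occ and (altloc or "A") < (prev_alt or "A")):
                best[key] = (atom, altloc, occ)
    return [best[k][0] for k in order]


def read_receptor(path: str | Path, format: str = "pdb") -> Structure:
    """Read a receptor PDB into a :class:`Structure`.

    One atom per resolved record; alternate locations collapse to the
    highest-occupancy conformer (ties go to altloc 'A'). HETATM ligands are
    kept and distinguishable via ``Atom.is_hetero``.
    """
    path = Path(path)
    if format != "pdb":
        raise MolIOError(f"unsupported receptor format: {format}")
    if not path.exists():
        raise MolIOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise MolIOError(f"empty file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise MolIOError(f"failed to parse {path}: {exc}") from exc
    st.setup_entities()
    raw: list[tuple[Atom, str, float]] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                elem = at.element.name if at.element and at.element.name != "X" else ""
                if not elem:
                    elem = element_from_atom_name(at.name, res.name)
                atom = Atom(
                    serial=at.serial,
                    name=at.name,
                    element=elem,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    is_hetero=res.het_flag == "H",
                )
                raw.append((atom, at.altloc or "", at.occ))
    if not raw:
        raise MolIOError(f"{path}: no atom records found")
    return Structure(atoms=_resolve_altlocs(raw), annotations={"source": str(path)})


def apply_numbering_offset(structure: Structure, offsets: dict[str, int]) -> Structure:
    """Shift residue numbers per chain (e.g. to match signal-cleavage numbering)."""
    atoms = []
    for a in structure.atoms:
        off = offsets.get(a.chain_id, 0)
        atoms.append(Atom(a.serial, a.name, a.element, a.coords.copy(),
                          a.residue_name, a.residue_number + off, a.chain_id, a.is_hetero))
    return Structure(atoms=atoms, annotations=dict(structure.annotations))


# ---------------------------------------------------------------------------
# Pose reading / writing
# ---------------------------------------------------------------------------

def _check_multiset_consistency(poses: list[Pose], ligand_id: str) -> None:
    if not poses:
        return
    ref = poses[0].element_multiset(heavy_only=True)
    for i, p in enumerate(poses[1:], start=2):
        if p.element_multiset(heavy_only=True) != ref:
            raise MolIOError(
                f"ligand {ligand_id}: record {i} has a different heavy-atom "
                f"element multiset than record 1"
            )


def _poses_from_pdb(path: Path, ligand_id: str, engine: str) -> list[Pose]:
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    poses = []
    for model in st:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                for at in res:
                    elem = at.element.name if at.element and at.element.name != "X" else ""
                    if not elem:
                        elem = element_from_atom_name(at.name, res.name)
                    atoms.append(Atom(
                        serial=at.serial, name=at.name, element=elem,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        residue_name=res.name, residue_number=res.seqid.num,
                        chain_id=chain.name, is_hetero=True,
                    ))
        if atoms:
            poses.append(Pose(ligand_id=ligand_id, engine=engine, atoms=atoms))
    return poses


def _poses_from_sdf(path: Path, ligand_id: str, engine: str) -> list[Pose]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    poses = []
    for ri, mol in enumerate(supplier):
        if mol is None:
            raise MolIOError(f"{path}: unparseable SDF record")
        # the first record's title overrides the filename-derived ligand id
        if ri == 0 and mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            ligand_id = mol.GetProp("_Name").strip()
        conf = mol.GetConformer()
        atoms = []
        for i, a in enumerate(mol.GetAtoms()):
            p = conf.GetAtomPosition(i)
            atoms.append(Atom(
                serial=i + 1, name=f"{a.GetSymbol()}{i + 1}", element=a.GetSymbol(),
                coords=np.array([p.x, p.y, p.z]),
                residue_name="LIG", residue_number=1, chain_id="X", is_hetero=True,
            ))
        poses.append(Pose(ligand_id=ligand_id, engine=engine, atoms=atoms))
    return poses


def _poses_from_mol2(path: Path, ligand_id: str, engine: str) -> list[Pose]:
    from rdkit import Chem

    text = path.read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
    poses = []
    for bi, block in enumerate(blocks):
        mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
        if mol is None:
            raise MolIOError(f"{path}: unparseable MOL2 record {bi + 1}")
        conf = mol.GetConformer()
        atoms = []
        for i, a in enumerate(mol.GetAtoms()):
            p = conf.GetAtomPosition(i)
            # RDKit normalizes SYBYL types (C.ar, N.am, ...) to bare elements.
            atoms.append(Atom(
                serial=i + 1, name=f"{a.GetSymbol()}{i + 1}", element=a.GetSymbol(),
                coords=np.array([p.x, p.y, p.z]),
                residue_name="LIG", residue_number=1, chain_id="X", is_hetero=True,
            ))
        poses.append(Pose(ligand_id=ligand_id, engine=engine, atoms=atoms))
    return poses


def read_poses(path: str | Path, format: str | None = None,
               engine: str = "engine_A", ligand_id: str | None = None) -> PoseSet:
    """Read a multi-record pose file into a :class:`PoseSet`.

    One pose per MODEL (PDB), record (SDF) or molecule (MOL2), in file order,
    so pose_index equals position in the file. Hydrogens are retained; all
    geometry downstream defaults to heavy atoms.
    """
    path = Path(path)
    if not path.exists():
        raise MolIOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    lig = ligand_id or path.stem
    if fmt == "pdb":
        poses = _poses_from_pdb(path, lig, engine)
    elif fmt == "sdf":
        poses = _poses_from_sdf(path, lig, engine)
        if ligand_id is not None:  # explicit id beats the record title
            for p in poses:
                p.ligand_id = ligand_id
    elif fmt == "mol2":
        poses = _poses_from_mol2(path, lig, engine)
    else:
        raise MolIOError(f"unsupported pose format: {fmt}")
    if not poses:
        raise MolIOError(f"{path}: no poses found")
    lig = poses[0].ligand_id
    _check_multiset_consistency(poses, lig)
    return PoseSet(ligand_id=lig, engine=engine, poses=poses)


def write_poses_pdb(poses: list[Pose], path: str | Path) -> None:
    """Write poses as a multi-MODEL PDB (HETATM records, 3-decimal coords)."""
    path = Path(path)
    lines: list[str] = []
    for mi, pose in enumerate(poses, start=1):
        lines.append(f"MODEL     {mi:4d}")
        for a in pose.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"HETATM{a.serial:5d} {name[:4]:<4s}{a.residue_name[:3]:>4s} "
                f"{(a.chain_id or 'X')[:1]}{a.residue_number:4d}    "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_poses_sdf(poses: list[Pose], path: str | Path) -> None:
    """Write poses as an SDF file (V2000, atoms only, no bond block)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            rw = Chem.RWMol()
            conf = Chem.Conformer(len(pose.atoms))
            for i, a in enumerate(pose.atoms):
                rw.AddAtom(Chem.Atom(a.element))
                conf.SetAtomPosition(i, Point3D(*a.coords))
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", pose.ligand_id)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

KEY_COLUMNS = ("ligand_id", "engine", "pose_index")


def read_score_table(path: str | Path) -> dict[tuple[str, str, int], dict[str, float]]:
    """Read a delimited score sidecar into (ligand_id, engine, pose_index) -> scores.

    The header must name the key columns plus one column per metric. Missing
    cells leave that metric absent from the pose's score map; the pose is
    flagged by omission and later excluded from ranking with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise MolIOError(f"{path}: missing key columns {missing}")
    metrics = [c for c in df.columns if c not in KEY_COLUMNS]
    if df.duplicated(subset=list(KEY_COLUMNS)).any():
        dup = df[df.duplicated(subset=list(KEY_COLUMNS))].iloc[0]
        raise MolIOError(
            f"{path}: duplicate key row "
            f"({dup['ligand_id']}, {dup['engine']}, {dup['pose_index']})"
        )
    table: dict[tuple[str, str, int], dict[str, float]] = {}
    n_incomplete = 0
    for _, row in df.iterrows():
        key = (str(row["ligand_id"]), str(row["engine"]), int(row["pose_index"]))
        scores = {m: float(row[m]) for m in metrics if pd.notna(row[m])}
        if len(scores) < len(metrics):
            n_incomplete += 1
        table[key] = scores
    if not table:
        warnings.warn(f"{path}: header-only score table, no rows", stacklevel=2)
    if n_incomplete:
        logger.warning("%s: %d pose(s) metric-incomplete", path, n_incomplete)
    return table


def attach_scores(pose_set: PoseSet,
                  table: dict[tuple[str, str, int], dict[str, float]]) -> PoseSet:
    """Copy table entries onto poses by (ligand_id, engine, position-in-file)."""
    for i, pose in enumerate(pose_set.poses):
        key = (pose_set.ligand_id, pose_set.engine, i)
        if key in table:
            pose.scores.update(table[key])
    return pose_set
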