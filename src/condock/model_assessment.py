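"""Model-vs-density assessment and alignment bookkeeping for refinement.

Covers the computations used to judge a hierarchically refined model:
Gaussian-simulated density from coordinates, global and segment-masked
cross-correlation (SCCC), the segment-based Manders overlap coefficient,
ranking of candidate loop models by SCCC, the register-shift correction
(gap insertion in a sequence–structure alignment), and region-restricted
percent identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mol_io import Structure

# Approximate atomic numbers for density amplitudes.
_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "F": 9, "Cl": 17,
      "Br": 35, "I": 53, "Se": 34}


class AssessmentError(ValueError):
    pass


@dataclass
class DensityGrid:
    """A 3D scalar field on a regular grid (values indexed [ix, iy, iz])."""

    values: np.ndarray
    voxel_size: np.ndarray  # Å per axis, shape (3,)
    origin: np.ndarray      # Å, position of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_size = np.broadcast_to(np.asarray(self.voxel_size, dtype=float),
                                          (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise AssessmentError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.values)):
            raise AssessmentError("grid contains non-finite values")

    def congruent_with(self, other: "DensityGrid", tol: float = 1e-6) -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)


def sigma_from_resolution(resolution: float, convention: str = "fwhm") -> float:
    """Gaussian width from nominal resolution.

    'fwhm': the resolution is the peak's full width at half maximum, so
    σ = resolution / (2·sqrt(2·ln 2)). 'pi': σ = resolution / π, the
    convention of some fitting tools.
    """
    if convention == "fwhm":
        return resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if convention == "pi":
        return resolution / np.pi
    raise AssessmentError(f"unknown sigma convention: {convention}")


def simulate_map(model: Structure, resolution: float, voxel: float = 1.0,
                 sigma_convention: str = "fwhm",
                 grid_like: DensityGrid | None = None,
                 extra_points: np.ndarray | None = None) -> DensityGrid:
    """Sum of spherical Gaussians at atom centres, amplitude ∝ atomic number.

    The grid spans the model's bounding box padded by 4σ unless ``grid_like``
    supplies the geometry (used to score a model against an experimental
    map on that map's own grid). ``extra_points`` widens the bounding box.
    """
    coords = model.coords()
    if coords.size == 0:
        raise AssessmentError("empty model")
    if resolution <= 2 * voxel and grid_like is None:
        raise AssessmentError("resolution must exceed 2 × voxel size")
    sigma = sigma_from_resolution(resolution, sigma_convention)
    if grid_like is None:
        pts = coords if extra_points is None else np.vstack([coords, extra_points])
        pad = 4.0 * sigma
        lo = pts.min(axis=0) - pad
        hi = pts.max(axis=0) + pad
        shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
        grid = DensityGrid(values=np.zeros(shape), voxel_size=np.full(3, voxel),
                           origin=lo)
    else:
        grid = DensityGrid(values=np.zeros_like(grid_like.values),
                           voxel_size=grid_like.voxel_size.copy(),
                           origin=grid_like.origin.copy())
    axes = [grid.voxel_centers_axis(k) for k in range(3)]
    cut = 4.0 * sigma
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    elements = [a.element for a in model.atoms]
    for xyz, elem in zip(model.coords(), elements):
        amp = float(_Z.get(elem, 6))
        sl, gax = [], []
        for k in range(3):
            ax = axes[k]
            i0 = int(np.searchsorted(ax, xyz[k] - cut))
            i1 = int(np.searchsorted(ax, xyz[k] + cut))
            if i0 >= i1:
                break
            sl.append(slice(i0, i1))
            gax.append(np.exp(-((ax[i0:i1] - xyz[k]) ** 2) * inv2s2))
        else:
            grid.values[tuple(sl)] += amp * (
                gax[0][:, None, None] * gax[1][None, :, None] * gax[2][None, None, :]
            )
    return grid


def regrid(grid: DensityGrid, like: DensityGrid) -> DensityGrid:
    """Trilinear resampling of ``grid`` onto the geometry of ``like``."""
    from scipy.ndimage import map_coordinates

    axes = [like.voxel_centers_axis(k) for k in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = [
        (mesh[k] - grid.origin[k]) / grid.voxel_size[k] for k in range(3)
    ]
    vals = map_coordinates(grid.values, np.stack(coords), order=1, mode="constant",
                           cval=0.0)
    return DensityGrid(values=vals, voxel_size=like.voxel_size.copy(),
                       origin=like.origin.copy())


def _check_congruent(a: DensityGrid, b: DensityGrid) -> None:
    if not a.congruent_with(b):
        raise AssessmentError(
            "grids are not congruent (shape/voxel/origin); use regrid() first"
        )


def ccc(a: DensityGrid, b: DensityGrid, mask: np.ndarray | None = None) -> float:
    """Pearson cross-correlation of voxel values over an optional boolean mask."""
    _check_congruent(a, b)
    va, vb = a.values, b.values
    if mask is not None:
        if mask.shape != va.shape:
            raise AssessmentError("mask shape mismatch")
        va, vb = va[mask], vb[mask]
    else:
        va, vb = va.ravel(), vb.ravel()
    if va.size == 0:
        raise AssessmentError("empty mask")
    da, db = va - va.mean(), vb - vb.mean()
    na, nb = float(np.sqrt(np.sum(da ** 2))), float(np.sqrt(np.sum(db ** 2)))
    if na == 0 or nb == 0:
        raise AssessmentError("zero-variance input")
    return float(np.dot(da, db) / (na * nb))


@dataclass
class Segment:
    """Residue range(s) on named chain(s): list of (chain_id, first, last)."""

    ranges: list[tuple[str, int, int]]

    def atoms(self, model: Structure):
        out = [a for a in model.atoms
               if any(c == a.chain_id and lo <= a.residue_number <= hi
                      for c, lo, hi in self.ranges)]
        if not out:
            raise AssessmentError(f"segment resolves to no atoms: {self.ranges}")
        return out


def segment_mask(model: Structure, segment: Segment, grid: DensityGrid,
                 mask_radius: float = 3.0) -> np.ndarray:
    """Boolean mask of voxels within ``mask_radius`` of any segment atom."""
    coords = np.array([a.coords for a in segment.atoms(model)])
    axes = [grid.voxel_centers_axis(k) for k in range(3)]
    mask = np.zeros(grid.values.shape, dtype=bool)
    r2 = mask_radius ** 2
    for xyz in coords:
        sl, dax = [], []
        for k in range(3):
            ax = axes[k]
            i0 = int(np.searchsorted(ax, xyz[k] - mask_radius))
            i1 = int(np.searchsorted(ax, xyz[k] + mask_radius))
            if i0 >= i1:
                break
            sl.append(slice(i0, i1))
            dax.append((ax[i0:i1] - xyz[k]) ** 2)
        else:
            d2 = (dax[0][:, None, None] + dax[1][None, :, None]
                  + dax[2][None, None, :])
            mask[tuple(sl)] |= d2 <= r2
    if not mask.any():
        raise AssessmentError("segment mask is empty on this grid")
    return mask


def segment_ccc(model: Structure, segment: Segment, exp_map: DensityGrid,
                resolution: float, mask_radius: float = 3.0,
                sigma_convention: str = "fwhm") -> float:
    """Segment-based cross-correlation: Pearson CC between the experimental
    map and the model's simulated map, restricted to voxels near the segment."""
    sim = simulate_map(model, resolution=resolution,
                       sigma_convention=sigma_convention, grid_like=exp_map)
    mask = segment_mask(model, segment, exp_map, mask_radius)
    return ccc(exp_map, sim, mask=mask)


def manders_overlap(a: DensityGrid, b: DensityGrid,
                    mask: np.ndarray | None = None) -> float:
    """Manders overlap coefficient Σab / sqrt(Σa²·Σb²) over the mask.

    Values are thresholded at 0 first, so the coefficient lies in [0, 1]
    and measures colocalisation of positive density.
    """
    _check_congruent(a, b)
    va, vb = np.clip(a.values, 0, None), np.clip(b.values, 0, None)
    if mask is not None:
        va, vb = va[mask], vb[mask]
    na2, nb2 = float(np.sum(va ** 2)), float(np.sum(vb ** 2))
    if na2 == 0 or nb2 == 0:
        raise AssessmentError("zero-norm grid under the mask")
    return float(np.sum(va * vb) / np.sqrt(na2 * nb2))


def rank_loops(candidates: list[Structure], segment: Segment,
               exp_map: DensityGrid, resolution: float = 6.2,
               mask_radius: float = 3.0) -> list[tuple[int, float]]:
    """Order candidate loop models by segment CCC, best first.

    Returns (candidate index, score), stable under ties; the first entry is
    the top-ranked loop.
    """
    if not candidates:
        raise AssessmentError("no candidates")
    scored = [(i, segment_ccc(m, segment, exp_map, resolution, mask_radius))
              for i, m in enumerate(candidates)]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


# ---------------------------------------------------------------------------
# Sequence–structure alignment bookkeeping
# ---------------------------------------------------------------------------

GAP = "-"


@dataclass
class RegionAlignment:
    """Two gapped sequences of equal length plus named column ranges.

    Regions map name -> (start, end) half-open column indices (0-based).
    """

    seq1: str
    seq2: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise AssessmentError("gapped sequences must have equal length")
        for name, (s, e) in self.regions.items():
            if not (0 <= s <= e <= len(self.seq1)):
                raise AssessmentError(f"region {name} out of bounds")


def read_region_alignment(path: str | Path,
                          regions: dict[str, tuple[int, int]] | None = None) -> RegionAlignment:
    """Read the first two records of an aligned FASTA into a RegionAlignment."""
    from Bio import SeqIO  # biopython is optional at runtime; only this reader needs it

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AssessmentError(f"{path}: need two aligned sequences")
    return RegionAlignment(seq1=str(records[0].seq), seq2=str(records[1].seq),
                           regions=regions or {})


def _column_of_label(seq: str, label: str) -> int:
    """Column index of residue ``label`` (one-letter code + ungapped 1-based
    position, e.g. 'P236') in a gapped sequence."""
    letter, num = label[0].upper(), int(label[1:])
    count = 0
    for col, ch in enumerate(seq):
        if ch != GAP:
            count += 1
            if count == num:
                if ch.upper() != letter:
                    raise AssessmentError(
                        f"label {label}: position {num} holds {ch!r}, not {letter!r}"
                    )
                return col
    raise AssessmentError(f"label {label}: sequence has only {count} residues")


def apply_register_shift(alignment: RegionAlignment, after_position: str,
                         gap_length: int = 4) -> RegionAlignment:
    """Insert a gap run in sequence 1 immediately after a labelled residue.

    This re-registers everything downstream of that residue by ``gap_length``
    columns relative to sequence 2 — the correction for a systematic off-by-n
    helix register. Sequence 2 keeps its columns and gains trailing gaps so
    the alignment stays rectangular; named regions are remapped.
    """
    if gap_length == 0:
        return RegionAlignment(alignment.seq1, alignment.seq2,
                               dict(alignment.regions))
    if gap_length < 0:
        raise AssessmentError("gap_length must be >= 0")
    col = _column_of_label(alignment.seq1, after_position)
    ins = col + 1
    seq1 = alignment.seq1[:ins] + GAP * gap_length + alignment.seq1[ins:]
    seq2 = alignment.seq2 + GAP * gap_length
    regions = {}
    for name, (s, e) in alignment.regions.items():
        regions[name] = (s + gap_length if s >= ins else s,
                         e + gap_length if e > ins else e)
    return RegionAlignment(seq1=seq1, seq2=seq2, regions=regions)


def percent_identity(alignment: RegionAlignment, region: str | None = None) -> float:
    """Percent identity over a named region (or all columns).

    Identical columns / aligned columns × 100, where an aligned column has a
    residue in at least one sequence; double-gap columns are excluded from
    the denominator, gap-vs-residue columns count against identity. Returns
    the raw value; round for reporting.
    """
    if region is not None:
        if region not in alignment.regions:
            raise AssessmentError(f"unknown region: {region}")
        s, e = alignment.regions[region]
    else:
        s, e = 0, len(alignment.seq1)
    aligned = identical = 0
    for c1, c2 in zip(alignment.seq1[s:e], alignment.seq2[s:e]):
        if c1 == GAP and c2 == GAP:
            continue
        aligned += 1
        if c1 != GAP and c1.upper() == c2.upper():
            identical += 1
    if aligned == 0:
        raise AssessmentError("region has zero aligned columns")
    return 100.0 * identical / aligned


# ---------------------------------------------------------------------------
# MRC/CCP4 map I/O
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> DensityGrid:
    """Read an MRC/CCP4 map into a DensityGrid (axes reordered to X,Y,Z)."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path), setup=True)
    arr = np.array(m.grid, copy=True)
    voxel = np.array([m.grid.unit_cell.a / m.grid.nu,
                      m.grid.unit_cell.b / m.grid.nv,
                      m.grid.unit_cell.c / m.grid.nw])
    pos0 = m.grid.get_position(0, 0, 0)
    return DensityGrid(values=arr, voxel_size=voxel,
                       origin=np.array([pos0.x, pos0.y, pos0.z]))


def write_map(grid: DensityGrid, path: str | Path) -> None:
    import gemmi

    m = gemmi.Ccp4Map()
    g = gemmi.FloatGrid(*grid.values.shape)
    g.set_unit_cell(gemmi.UnitCell(
        grid.voxel_size[0] * grid.values.shape[0],
        grid.voxel_size[1] * grid.values.shape[1],
        grid.voxel_size[2] * grid.values.shape[2], 90, 90, 90))
    arr = np.array(g, copy=False)
    arr[...] = grid.values
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
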