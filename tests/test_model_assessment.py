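"""Density simulation, cross-correlation and Manders overlap, loop ranking,
register-shift bookkeeping, and region-restricted percent identity."""

import numpy as np
import pytest

from condock import fixtures as fx
from condock.model_assessment import (
    AssessmentError,
    DensityGrid,
    RegionAlignment,
    Segment,
    apply_register_shift,
    ccc,
    manders_overlap,
    percent_identity,
    rank_loops,
    regrid,
    segment_ccc,
    segment_mask,
    sigma_from_resolution,
    simulate_map,
)
from condock.mol_io import Atom, Structure


def atom(serial, xyz, element="C", resnum=1, chain="A", name=None):
    return Atom(serial, name or f"C{serial}", element, np.asarray(xyz, float),
                "ALA", resnum, chain, False)


def grid_pair(rng, shape=(8, 8, 8)):
    a = DensityGrid(rng.random(shape), 1.0, np.zeros(3))
    b = DensityGrid(rng.random(shape), 1.0, np.zeros(3))
    return a, b


# --- simulate_map --------------------------------------------------------

def test_single_atom_peak_at_nearest_voxel():
    st = Structure(atoms=[atom(1, (3.2, 4.1, 5.0))])
    g = simulate_map(st, resolution=5.0, voxel=1.0)
    idx = np.unravel_index(np.argmax(g.values), g.values.shape)
    center = g.origin + np.array(idx) * g.voxel_size
    assert np.all(np.abs(center - [3.2, 4.1, 5.0]) <= g.voxel_size / 2 + 1e-9)


def test_two_distant_atoms_two_local_maxima():
    st = Structure(atoms=[atom(1, (0, 0, 0)), atom(2, (14, 0, 0))])
    g = simulate_map(st, resolution=5.0, voxel=1.0)
    v = g.values
    interior = v[1:-1, 1:-1, 1:-1]
    neighborhood_max = np.stack([
        v[s0, s1, s2]
        for s0 in (slice(0, -2), slice(1, -1), slice(2, None))
        for s1 in (slice(0, -2), slice(1, -1), slice(2, None))
        for s2 in (slice(0, -2), slice(1, -1), slice(2, None))
    ]).max(axis=0)
    n_maxima = int(np.sum((interior == neighborhood_max) & (interior > 0.5 * v.max())))
    assert n_maxima == 2


def test_one_atom_integral_matches_analytic_gaussian():
    st = Structure(atoms=[atom(1, (0, 0, 0))])
    res, vox = 6.0, 0.5
    g = simulate_map(st, resolution=res, voxel=vox)
    sigma = sigma_from_resolution(res)
    numeric = g.values.sum() * vox ** 3
    analytic = 6.0 * (2 * np.pi * sigma ** 2) ** 1.5  # amplitude Z=6 Gaussian
    assert numeric == pytest.approx(analytic, rel=0.01)


def test_empty_model_errors():
    with pytest.raises(AssessmentError):
        simulate_map(Structure(atoms=[]), resolution=6.0)


# --- ccc -----------------------------------------------------------------

def test_ccc_self_is_one(rng):
    a, _ = grid_pair(rng)
    assert ccc(a, a) == pytest.approx(1.0)


def test_ccc_negation_is_minus_one(rng):
    a, _ = grid_pair(rng)
    neg = DensityGrid(-a.values, a.voxel_size, a.origin)
    assert ccc(a, neg) == pytest.approx(-1.0)


def test_ccc_matches_two_pass_pearson(rng):
    a, b = grid_pair(rng)
    x, y = a.values.ravel(), b.values.ravel()
    mx, my = x.mean(), y.mean()
    expected = np.sum((x - mx) * (y - my)) / np.sqrt(
        np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    assert ccc(a, b) == pytest.approx(float(expected), abs=1e-12)


def test_ccc_zero_variance_errors():
    flat = DensityGrid(np.ones((4, 4, 4)), 1.0, np.zeros(3))
    with pytest.raises(AssessmentError):
        ccc(flat, flat)


def test_ccc_requires_congruent_grids(rng):
    a = DensityGrid(rng.random((4, 4, 4)), 1.0, np.zeros(3))
    b = DensityGrid(rng.random((5, 4, 4)), 1.0, np.zeros(3))
    with pytest.raises(AssessmentError):
        ccc(a, b)


def test_ccc_scale_invariance(rng):
    a, b = grid_pair(rng)
    scaled = DensityGrid(3.7 * b.values, b.voxel_size, b.origin)
    assert ccc(a, scaled) == pytest.approx(ccc(a, b), abs=1e-12)


# --- segment_ccc ---------------------------------------------------------

def helix_model(n_res=12, chain="A"):
    """Extended Cα trace (3.8 Å rise, slight zigzag) standing in for a loop."""
    atoms = []
    for i in range(n_res):
        xyz = (3.8 * i, 1.0 * (i % 2), 0.0)
        atoms.append(atom(i + 1, xyz, element="C", resnum=i + 1, chain=chain,
                          name="CA"))
    return Structure(atoms=atoms)


def test_segment_ccc_self_consistency():
    model = helix_model()
    exp = simulate_map(model, resolution=6.2, voxel=1.5)
    seg = Segment([("A", 4, 8)])
    assert segment_ccc(model, seg, exp, resolution=6.2) >= 0.99


def test_segment_ccc_displaced_segment_scores_low():
    # sharper simulated resolution keeps flanking density out of the mask,
    # so the planted 14 Å displacement reads as a clean register error
    model = helix_model()
    exp = fx.make_planted_density(model, resolution=4.0, voxel=1.0,
                                  displaced_segment=("A", 4, 8),
                                  displacement=(0.0, 14.0, 0.0))
    seg = Segment([("A", 4, 8)])
    assert segment_ccc(model, seg, exp, resolution=4.0, mask_radius=2.0) < 0.2


def test_segment_mask_restricted_to_neighborhood():
    model = helix_model()
    exp = simulate_map(model, resolution=6.2, voxel=1.5)
    mask = segment_mask(model, Segment([("A", 4, 8)]), exp, mask_radius=3.0)
    assert 0 < mask.sum() < mask.size


# --- manders -------------------------------------------------------------

def test_manders_identical_is_one(rng):
    a = DensityGrid(rng.random((6, 6, 6)), 1.0, np.zeros(3))
    assert manders_overlap(a, a) == pytest.approx(1.0)


def test_manders_disjoint_is_zero():
    v1 = np.zeros((6, 6, 6))
    v2 = np.zeros((6, 6, 6))
    v1[:3] = 1.0
    v2[3:] = 1.0
    a = DensityGrid(v1, 1.0, np.zeros(3))
    b = DensityGrid(v2, 1.0, np.zeros(3))
    assert manders_overlap(a, b) == pytest.approx(0.0)


def test_manders_matches_direct_formula(rng):
    a, b = grid_pair(rng)
    expected = np.sum(a.values * b.values) / np.sqrt(
        np.sum(a.values ** 2) * np.sum(b.values ** 2))
    assert manders_overlap(a, b) == pytest.approx(float(expected), abs=1e-12)


def test_manders_symmetric_and_scale_invariant(rng):
    a, b = grid_pair(rng)
    assert manders_overlap(a, b) == pytest.approx(manders_overlap(b, a))
    scaled = DensityGrid(2.5 * b.values, b.voxel_size, b.origin)
    assert manders_overlap(a, scaled) == pytest.approx(manders_overlap(a, b))


# --- rank_loops ----------------------------------------------------------

def test_true_loop_ranks_first(rng):
    true_model = helix_model()
    exp = simulate_map(true_model, resolution=6.2, voxel=1.5)
    seg = Segment([("A", 4, 8)])
    candidates = [true_model]
    for k in range(4):
        shifted = Structure(atoms=[
            Atom(a.serial, a.name, a.element,
                 a.coords + (np.array([3.0 + 2 * k, 0, 0])
                             if 4 <= a.residue_number <= 8 else 0),
                 a.residue_name, a.residue_number, a.chain_id, a.is_hetero)
            for a in true_model.atoms
        ])
        candidates.append(shifted)
    ranked = rank_loops(candidates, seg, exp, resolution=6.2)
    assert ranked[0][0] == 0
    assert ranked[0][1] >= 0.99


def test_identical_candidates_stable_tie_break():
    model = helix_model()
    exp = simulate_map(model, resolution=6.2, voxel=1.5)
    ranked = rank_loops([model, model, model], Segment([("A", 4, 8)]), exp)
    assert [i for i, _ in ranked] == [0, 1, 2]


def test_single_candidate_returned():
    model = helix_model()
    exp = simulate_map(model, resolution=6.2, voxel=1.5)
    ranked = rank_loops([model], Segment([("A", 4, 8)]), exp)
    assert len(ranked) == 1 and ranked[0][0] == 0


# --- regrid and map I/O --------------------------------------------------

def test_regrid_identity_geometry_is_noop(rng):
    a = DensityGrid(rng.random((6, 6, 6)), 1.0, np.zeros(3))
    out = regrid(a, a)
    np.testing.assert_allclose(out.values, a.values, atol=1e-12)


def test_mrc_map_round_trip(tmp_path, rng):
    from condock.model_assessment import read_map, write_map

    g = DensityGrid(rng.random((5, 6, 7)), np.array([1.5, 1.5, 1.5]), np.zeros(3))
    write_map(g, tmp_path / "m.mrc")
    back = read_map(tmp_path / "m.mrc")
    assert back.values.shape == g.values.shape
    np.testing.assert_allclose(back.values, g.values, atol=1e-6)
    np.testing.assert_allclose(back.voxel_size, g.voxel_size, atol=1e-6)


# --- register shift and identity -----------------------------------------

def test_register_shift_mechanical_insertion():
    aln = RegionAlignment("ABCDEF", "ABCDEF")
    out = apply_register_shift(aln, "C3", gap_length=4)
    assert out.seq1 == "ABC----DEF"
    assert len(out.seq1) == len(out.seq2) == 10
    assert out.seq2.startswith("ABCDEF")


def test_register_shift_zero_gap_identity():
    aln = RegionAlignment("ABCDEF", "ABCDEF", {"r": (0, 6)})
    out = apply_register_shift(aln, "C3", gap_length=0)
    assert out.seq1 == aln.seq1 and out.seq2 == aln.seq2
    assert out.regions == aln.regions


def test_register_shift_after_last_column_appends_trailing_gaps():
    aln = RegionAlignment("ABC", "ABC")
    out = apply_register_shift(aln, "C3", gap_length=2)
    assert out.seq1 == "ABC--"
    assert out.seq2 == "ABC--"


def test_register_shift_round_trip():
    aln = RegionAlignment("MKWVFLAG", "MKYVFLAG", {"tm": (2, 7)})
    out = apply_register_shift(aln, "W3", gap_length=4)
    ins = 3
    restored1 = out.seq1[:ins] + out.seq1[ins + 4:]
    restored2 = out.seq2[:len(out.seq2) - 4]
    assert restored1 == aln.seq1 and restored2 == aln.seq2


def test_register_shift_remaps_regions():
    aln = RegionAlignment("ABCDEFGH", "ABCDEFGH",
                          {"pre": (0, 3), "post": (4, 8)})
    out = apply_register_shift(aln, "C3", gap_length=4)
    assert out.regions["pre"] == (0, 3)   # ends at the insertion point: fixed
    assert out.regions["post"] == (8, 12)  # downstream: shifted by the gap run


def test_register_shift_unknown_label_errors():
    with pytest.raises(AssessmentError):
        apply_register_shift(RegionAlignment("ABC", "ABC"), "Z9")


def test_identity_identical_sequences():
    aln = RegionAlignment("MKWVFL", "MKWVFL")
    assert percent_identity(aln) == pytest.approx(100.0)


def test_identity_half_match():
    assert percent_identity(RegionAlignment("AAAA", "AATT")) == pytest.approx(50.0)


def test_identity_region_restricted():
    aln = RegionAlignment("AAAATTTT", "AAAACCCC", {"head": (0, 4), "tail": (4, 8)})
    assert percent_identity(aln, "head") == pytest.approx(100.0)
    assert percent_identity(aln, "tail") == pytest.approx(0.0)


def test_identity_gap_columns_count_in_denominator():
    # gap-vs-residue columns are aligned but not identical
    assert percent_identity(RegionAlignment("AA--", "AAGG")) == pytest.approx(50.0)


def test_identity_invariant_to_double_gap_columns():
    a = RegionAlignment("AATT", "AAGT")
    b = RegionAlignment("AA--TT", "AA--GT")
    assert percent_identity(a) == pytest.approx(percent_identity(b))


def test_identity_empty_region_errors():
    aln = RegionAlignment("--", "--", {"none": (0, 2)})
    with pytest.raises(AssessmentError):
        percent_identity(aln, "none")
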