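# condock

Consensus analysis of small-molecule docking into pentameric ligand-gated ion
channel models — and the density-fit bookkeeping used to assess the receptor
models themselves.

## The problem

Allosteric modulators of the α7 nicotinic acetylcholine receptor bind in
transmembrane cavities where no experimental ligand structure exists. A
practical way to locate such sites is *consensus docking*: dock each compound
with two independent engines (e.g. GOLD and AutoDock Vina), keep only
placements on which both engines agree, and look for binding modes predicted
consistently across a whole chemical series. `condock` implements the
post-processing side of that protocol; it never runs the engines, it consumes
their pose files and score tables.

The pipeline stages, in order:

1. **Pose agreement.** For each ligand, every cross-engine pose pair is scored
   by a symmetry-corrected RMSD and kept when RMSD ≤ 2.0 Å. Because docked
   atom orders are arbitrary and many ligands are topologically symmetric,
   the RMSD is minimised over atom correspondences with the Hungarian
   algorithm, constrained to same-element pairs:

       RMSD(A,B) = min_σ sqrt( (1/N) Σ_i ‖a_i − b_σ(i)‖² ),  elem(a_i) = elem(b_σ(i))

   No superposition is applied — poses are compared as *placements* in the
   shared receptor frame.
2. **Search-region refinement.** The centroid of all atoms of all consensus
   poses defines a refined search volume (a sphere for one engine, a box for
   the other) that encloses every consensus atom; the initial seed region is
   an 18 Å-radius sphere / 32 Å cube about a chosen anchor residue's
   γ-carbon.
3. **Flexible side chains.** Ten residues inside the region are granted full
   flexibility for the second docking stage, chosen in priority tiers:
   experimentally mutated residues, then polar residues, then an even spatial
   spread (greedy farthest-point sampling).
4. **Rank aggregation.** Matched pairs are ranked by the Borda count over
   three scoring functions (Vina score, GoldScore, ChemPLP), each pair
   earning `n − rank` points per metric.
5. **Redundancy removal.** Greedy best-rank-first selection keeps at most 20
   pairs per ligand, each > 2.0 Å from every kept pair.
6. **Binding-mode clustering.** The top five pairs per compound are pooled
   across the chemical series and clustered hierarchically on the RMSD matrix
   (complete linkage, 2.0 Å cutoff; rectangular element-relaxed assignment
   across different molecules). The most populated clusters are the consensus
   binding modes.

Two further module groups serve the surrounding modelling work:
`condock.interactions` measures ligand–residue distances, geometric hydrogen
bonds and pocket composition on docked complexes, and
`condock.model_assessment` provides simulated density, global and
segment-based cross-correlation (SCCC), the segment-based Manders overlap
coefficient, loop-candidate ranking, register-shift alignment correction, and
region-restricted percent identity.

## Worked example

Everything is testable without downloads via the built-in synthetic fixture
generator, which plants consensus binding modes, atom permutations, decoy
poses and rank-structured score tables:

```
$ condock fixtures --preset two-mode --seed 7 --out demo/
wrote fixture set to demo/

$ condock match --engine-a demo/engine_a.sdf --engine-b demo/engine_b.sdf | head -8
[
 {
  "index_a": 12,
  "index_b": 6,
  "rmsd": 0.4605
 },
...
```

245 of the 1000 cross-engine pairs agree within 2.0 Å — exactly the pairs
whose two poses came from the same planted mode (the 30 % decoy poses never
match). Ranking plus redundancy removal collapses them to one representative
pair per mode:

```
$ condock rank --engine-a demo/engine_a.sdf --engine-b demo/engine_b.sdf \
               --scores demo/scores.csv --top 5
[
  { "index_a": 0, "index_b": 0, "rmsd": 0.8601 },
  { "index_a": 1, "index_b": 1, "rmsd": 0.751 }
]
```

The symmetry correction in one picture — a benzene-like carbon hexagon
rotated by 60° is the *same placement*, but index-wise RMSD reports the full
1.4 Å chord:

```python
>>> import condock
>>> from condock import fixtures as fx
>>> hexa = fx.make_symmetric_ligand(6, radius=1.4)
>>> rot = fx.rotate_pose(hexa, 60.0)
>>> condock.naive_rmsd(hexa, rot)
1.4
>>> condock.hungarian_rmsd(hexa, rot)
5.03e-16
```

The full pipeline (`condock run --config cfg.yaml`) writes a manifest,
per-stage JSON/TSV reports and the mode-representative poses as multi-MODEL
PDB; rerunning on identical inputs reproduces the same manifest hash.

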