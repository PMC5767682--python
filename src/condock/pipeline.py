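"""End-to-end consensus-docking pipeline with a serialised manifest.

Wires the stages together for one or more ligands from two engines:
match → Borda rank → de-duplicate → pool top-k per ligand → cluster →
consensus-mode report. Every stage's output is written as JSON/TSV/PDB and
listed in a manifest so any stage can be re-run in isolation; counts at each
filter are logged for protocol audits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import consensus, mol_io, ranking
from .clustering import cluster_poses, consensus_modes
from .ranking import MetricSpec

logger = logging.getLogger("condock")


@dataclass
class RunConfig:
    """All protocol constants and paths for one pipeline run."""

    ligands: list[dict] = field(default_factory=list)  # {id, engine_a, engine_b, format}
    scores_path: str | None = None
    out_dir: str = "condock_out"
    match_threshold: float = consensus.MATCH_THRESHOLD
    redundancy_rmsd: float = consensus.REDUNDANCY_RMSD
    max_pairs: int = consensus.MAX_CONSENSUS_PAIRS
    top_k: int = 5
    cluster_cutoff: float = 2.0
    linkage: str = "complete"
    min_population: int = 2
    metrics: list[dict] = field(default_factory=lambda: [
        {"name": "vina", "orientation": "lower_better"},
        {"name": "goldscore", "orientation": "higher_better"},
        {"name": "chemplp", "orientation": "higher_better"},
    ])
    region_pad: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("match_threshold", "redundancy_rmsd", "cluster_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def metric_specs(self) -> tuple[MetricSpec, ...]:
        return tuple(MetricSpec(m["name"], m["orientation"]) for m in self.metrics)


def _pair_record(pair, borda_rank=None):
    return {"index_a": pair.index_a, "index_b": pair.index_b,
            "rmsd": round(pair.rmsd, 4),
            "borda_rank": borda_rank}


def run_pipeline(config: RunConfig,
                 loaded: dict[str, tuple] | None = None) -> dict:
    """Execute the full protocol; returns the manifest dict.

    ``loaded`` optionally maps ligand_id -> (PoseSet_a, PoseSet_b) to bypass
    file reading (used by fixtures and tests); otherwise pose files and the
    score sidecar named in the config are read.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": config.__dict__.copy(), "status": "ok"}
    metrics = config.metric_specs()

    score_table = None
    if config.scores_path:
        score_table = mol_io.read_score_table(config.scores_path)

    per_ligand = {}
    if loaded is None:
        for entry in config.ligands:
            fmt = entry.get("format")
            sa = mol_io.read_poses(entry["engine_a"], format=fmt,
                                   engine="engine_A", ligand_id=entry["id"])
            sb = mol_io.read_poses(entry["engine_b"], format=fmt,
                                   engine="engine_B", ligand_id=entry["id"])
            per_ligand[entry["id"]] = (sa, sb)
    else:
        per_ligand = dict(loaded)

    pooled_poses, pooled_ranks, match_stage, dedup_stage = [], [], {}, {}
    for lig, (sa, sb) in per_ligand.items():
        if score_table:
            mol_io.attach_scores(sa, score_table)
            mol_io.attach_scores(sb, score_table)
        pairs = consensus.match_poses(sa, sb, threshold=config.match_threshold)
        match_stage[lig] = {"n_cross": len(sa) * len(sb), "n_matched": len(pairs)}
        if not pairs:
            continue
        result = ranking.borda_rank(pairs, metrics=metrics)
        kept = consensus.deduplicate_pairs(
            pairs, order=result.final_order, max_pairs=config.max_pairs,
            redundancy_rmsd=config.redundancy_rmsd)
        dedup_stage[lig] = {
            "n_in": len(pairs), "n_kept": len(kept),
            "pairs": [_pair_record(p) for p in kept],
        }
        top = kept[:config.top_k]
        for rank_pos, pair in enumerate(top):
            pooled_poses.append(pair.pose_a)   # clustering uses the engine-A pose
            pooled_ranks.append(float(rank_pos + 1))

    manifest["stages"]["match"] = match_stage
    manifest["stages"]["dedup"] = dedup_stage

    if len(pooled_poses) >= 2:
        cs = cluster_poses(pooled_poses, linkage_method=config.linkage,
                           cutoff=config.cluster_cutoff, borda_ranks=pooled_ranks)
        modes = consensus_modes(cs, min_population=config.min_population)
        manifest["stages"]["cluster"] = {
            "n_poses": len(pooled_poses),
            "populations": {str(k): v for k, v in cs.populations.items()},
        }
        manifest["stages"]["modes"] = [
            {"cluster_id": m.cluster_id, "population": m.population,
             "ligands": m.member_ligands,
             "mean_borda_rank": round(m.mean_borda_rank, 3)}
            for m in modes
        ]
        if modes:
            mol_io.write_poses_pdb([m.representative for m in modes],
                                   out / "mode_representatives.pdb")
        else:
            manifest["status"] = "no consensus"
    else:
        manifest["stages"]["cluster"] = {"n_poses": len(pooled_poses)}
        manifest["stages"]["modes"] = []
        manifest["status"] = "no consensus"

    # hash covers the computed results and protocol constants, not I/O paths,
    # so identical inputs hash identically regardless of output location
    hashed = {"stages": manifest["stages"], "status": manifest["status"],
              "config": {k: v for k, v in manifest["config"].items()
                         if k not in {"out_dir", "scores_path", "ligands"}}}
    payload = json.dumps(hashed, sort_keys=True, default=str)
    manifest["manifest_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    # flat TSV mode report
    lines = ["cluster_id\tpopulation\tligands\tmean_borda_rank"]
    for m in manifest["stages"]["modes"]:
        lines.append(f"{m['cluster_id']}\t{m['population']}\t"
                     f"{','.join(m['ligands'])}\t{m['mean_borda_rank']}")
    (out / "modes.tsv").write_text("\n".join(lines) + "\n")
    logger.info("pipeline: %s (%d pooled poses)", manifest["status"], len(pooled_poses))
    return manifest
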