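"""End-to-end driver: preprocessing -> multi-level segmentation -> traits.

:func:`run_pipeline` wires the stages together, optionally writing per-leaf
PLY meshes, a traits table (CSV + JSON), the final shape model and a run
log with per-level thresholds and cluster counts.  :func:`match_typical_to_ledger`
scores a segmentation against a synthetic scene's ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TriangleMesh, load_mesh, save_mesh
from .preprocessing import PreprocessConfig, detect_table_plane, remove_non_plant
from .segmentation import SegmentationConfig, SegmentationReport, multilevel_segment
from .synthetic import GroundTruthLedger

logger = logging.getLogger("leafmorph")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "traits_table", "match_typical_to_ledger"]


@dataclass
class PipelineConfig:
    """Aggregated configuration of the whole pipeline."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    out_dir: Path | None = None
    log_level: str = "INFO"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)
        # the pipeline's only stochastic stage is the RANSAC table fit
        self.preprocess.rng_seed = self.rng_seed


@dataclass
class PipelineResult:
    """Everything the pipeline produces for one input mesh."""

    plant_mesh: TriangleMesh
    report: SegmentationReport
    traits: pd.DataFrame


def traits_table(report: SegmentationReport) -> pd.DataFrame:
    """Per-leaf trait table: leaf_id, s_mm2, c_mm, l_mm, w_mm, x11..x16."""
    rows = []
    for i, leaf in enumerate(report.typical_leaves):
        row = {"leaf_id": i, **leaf.traits.as_dict()}
        rows.append(row)
    cols = ["leaf_id", "s_mm2", "c_mm", "l_mm", "w_mm",
            "x11", "x12", "x13", "x14", "x15", "x16"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(
    input_mesh: str | Path | TriangleMesh, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run non-plant removal, multi-level segmentation and trait extraction.

    ``input_mesh`` may be a PLY/OBJ path or an in-memory mesh; the input is
    never mutated.  With ``config.out_dir`` set, writes ``leaf_<k>.ply``,
    ``traits.csv``, ``traits.json``, ``model.json`` and ``run_log.json``.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    mesh = (
        input_mesh.copy()
        if isinstance(input_mesh, TriangleMesh)
        else load_mesh(input_mesh)
    )
    plane = detect_table_plane(mesh, config.preprocess)
    logger.info("table plane: normal=%s offset=%.2f inliers=%d",
                np.round(plane.normal, 4), plane.offset, plane.inlier_count)
    plant = remove_non_plant(mesh, plane, config.preprocess)
    logger.info("plant geometry: %d vertices, %d faces", plant.n_vertices, plant.n_faces)
    report = multilevel_segment(plant, config.segmentation)
    for rec in report.levels:
        logger.info("level %d: multiplier=%.2f eps_a=%.4f deg eps_b=%.6f "
                    "clusters=%d accepted=%d",
                    rec.level, rec.multiplier, rec.eps_a, rec.eps_b,
                    rec.n_clusters, rec.n_accepted)
    logger.info("typical leaves: %d (rejected clusters: %d)",
                len(report.typical_leaves), len(report.rejected))
    table = traits_table(report)

    if config.out_dir is not None:
        out = config.out_dir
        out.mkdir(parents=True, exist_ok=True)
        for i, leaf in enumerate(report.typical_leaves):
            save_mesh(leaf.submesh, out / f"leaf_{i}.ply")
        table.to_csv(out / "traits.csv", index=False)
        (out / "traits.json").write_text(
            json.dumps(table.to_dict(orient="records"), indent=2)
        )
        if report.final_model is not None:
            report.final_model.to_json(out / "model.json")
        log = {
            "levels_run": report.levels_run,
            "n_typical": len(report.typical_leaves),
            "n_rejected": len(report.rejected),
            "levels": [
                {"level": r.level, "multiplier": r.multiplier, "eps_a": r.eps_a,
                 "eps_b": r.eps_b, "n_clusters": r.n_clusters,
                 "n_accepted": r.n_accepted}
                for r in report.levels
            ],
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return PipelineResult(plant_mesh=plant, report=report, traits=table)


def match_typical_to_ledger(
    result: PipelineResult,
    ledger: GroundTruthLedger,
    purity: float = 0.9,
    coverage: float = 0.5,
) -> dict:
    """Match segmented typical leaves to ground-truth leaves of a synthetic
    scene.

    A cluster matches a ledger leaf when at least ``purity`` of its
    vertices belong to that leaf and it covers at least ``coverage`` of the
    leaf's vertices.  Returns per-leaf matches, the matched typical count
    ``n3``, and recall ``n3 / n1``.
    """
    src = result.plant_mesh.source_vertex_indices
    matches: dict[int, int] = {}  # ledger leaf id -> cluster index
    matched_traits: dict[int, "object"] = {}
    for ci, cluster in enumerate(result.report.typical_leaves):
        scene_ids = set(
            (src[cluster.vertex_ids] if src is not None else cluster.vertex_ids).tolist()
        )
        best_leaf, best_olap = None, 0
        for rec in ledger.leaves:
            olap = len(scene_ids & ledger.leaf_vertex_sets[rec.leaf_id])
            if olap > best_olap:
                best_leaf, best_olap = rec.leaf_id, olap
        if best_leaf is None:
            continue
        rec = ledger.leaves[best_leaf]
        leaf_set = ledger.leaf_vertex_sets[best_leaf]
        if (best_olap / max(len(scene_ids), 1) >= purity
                and best_olap / max(len(leaf_set), 1) >= coverage
                and best_leaf not in matches):
            matches[best_leaf] = ci
            matched_traits[best_leaf] = cluster.traits
    n3 = sum(1 for lid in matches if ledger.leaves[lid].is_typical)
    n1 = ledger.n1
    return {
        "matches": matches,
        "matched_traits": matched_traits,
        "n1": n1,
        "n2": ledger.n2,
        "n3": n3,
        "recall": n3 / n1 if n1 else float("nan"),
    }
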