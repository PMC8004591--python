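"""Region-growing leaf segmentation and the multi-level refinement loop.

Region growing expands clusters from low-curvature seed vertices: an
edge-adjacent vertex joins a cluster when its normal deviates from the
normal of the front vertex it is reached from by at most the smoothness
threshold ``eps_a`` (degrees), and it keeps growing the front only if its
own curvature is at most ``eps_b``.  Both thresholds adapt to the plant:
they are multiples of the mesh-wide mean smoothness and mean curvature.

The multi-level loop starts rough (multiplier 1.5) and tightens the
multiplier by 0.05 per level.  After each level every cluster is measured,
a leaf shape model is fitted on all accepted-so-far plus current clusters,
and clusters passing the typical-leaf test are accepted (previously
accepted clusters are re-tested and may be dropped).  Geometry belonging
to failing clusters is re-segmented at the next, finer level.  The loop
stops when every cluster passes, a threshold reaches its floor, or the
multiplier is exhausted (at most 30 levels); a final model fitted on all
survivors then re-screens them once more.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import InputError, LeafMorphError
from .mesh import TriangleMesh, VertexField, estimate_vertex_attributes, surface_stats, \
    vertex_adjacency
from .shape_model import ShapeModel, detect_typical, fit_shape_model
from .traits import LeafCluster, trait_vector

__all__ = ["SegmentationConfig", "SegmentationReport", "region_growing",
           "multilevel_segment"]


@dataclass
class SegmentationConfig:
    """Tunables of the multi-level segmentation.

    ``n_p`` neighbours feed the local surface fit; the threshold schedule
    is ``init_multiplier`` minus ``multiplier_step`` per level, applied to
    the plant-wide mean smoothness and curvature, with an absolute floor
    ``epsilon_floor`` on both thresholds.  Clusters smaller than
    ``min_cluster_vertices`` are discarded outright (stem fragments, dust).
    """

    n_p: int = 30
    init_multiplier: float = 1.5
    multiplier_step: float = 0.05
    epsilon_floor: float = 1e-4
    min_cluster_vertices: int = 50
    q_endpoint: float = 0.05
    k_width_slices: int = 20

    def __post_init__(self) -> None:
        if self.init_multiplier <= 0:
            raise InputError("init_multiplier must be positive")
        if not (0 < self.multiplier_step < self.init_multiplier):
            raise InputError("multiplier_step must be in (0, init_multiplier)")
        if self.epsilon_floor <= 0:
            raise InputError("epsilon_floor must be positive")


@dataclass
class LevelRecord:
    """Audit record of one segmentation level."""

    level: int
    multiplier: float
    eps_a: float
    eps_b: float
    n_clusters: int
    n_accepted: int


@dataclass
class SegmentationReport:
    """Outcome of :func:`multilevel_segment`."""

    typical_leaves: list[LeafCluster]
    rejected: list[LeafCluster]
    levels_run: int
    final_model: ShapeModel | None
    levels: list[LevelRecord] = dc_field(default_factory=list)


def region_growing(
    mesh: TriangleMesh,
    field: VertexField,
    eps_a: float,
    eps_b: float,
    min_cluster_vertices: int = 50,
    active: np.ndarray | None = None,
    adjacency: list[np.ndarray] | None = None,
    return_small: bool = False,
):
    """Greedy region growing over the (optionally masked) mesh vertices.

    Seeds are taken in order of increasing curvature (ties by vertex
    index), which makes the result fully deterministic.  Returns the
    clusters with at least ``min_cluster_vertices`` vertices; with
    ``return_small=True`` also returns the undersized ones.
    """
    if len(field) != mesh.n_vertices:
        raise InputError("vertex field does not match mesh")
    if eps_a <= 0 or eps_b <= 0:
        raise InputError("thresholds must be positive")
    n = mesh.n_vertices
    active_mask = np.ones(n, dtype=bool) if active is None else np.asarray(active, bool).copy()
    if adjacency is None:
        adjacency = vertex_adjacency(mesh)
    normals = field.normals
    curvature = field.curvature
    # unsigned normal angles never exceed 90 deg
    cos_thresh = -1.0 if eps_a >= 90.0 else float(np.cos(np.radians(eps_a)))
    order = np.lexsort((np.arange(n), curvature))
    assigned = ~active_mask
    regions: list[np.ndarray] = []
    for seed in order:
        if assigned[seed]:
            continue
        assigned[seed] = True
        region = [int(seed)]
        front = [int(seed)]
        head = 0
        while head < len(front):
            cur = front[head]
            head += 1
            ncur = normals[cur]
            for nb in adjacency[cur]:
                if assigned[nb]:
                    continue
                if abs(float(ncur @ normals[nb])) >= cos_thresh:
                    assigned[nb] = True
                    region.append(int(nb))
                    if curvature[nb] <= eps_b:
                        front.append(int(nb))
        regions.append(np.array(sorted(region), dtype=np.int64))

    kept: list[LeafCluster] = []
    small: list[LeafCluster] = []
    for ids in regions:
        cluster = LeafCluster(submesh=mesh.submesh_from_vertices(ids), vertex_ids=ids)
        if len(ids) >= min_cluster_vertices:
            kept.append(cluster)
        else:
            cluster.reason = "below_min_vertices"
            small.append(cluster)
    if return_small:
        return kept, small
    return kept


def multilevel_segment(
    plant_mesh: TriangleMesh, config: SegmentationConfig | None = None
) -> SegmentationReport:
    """Run the full multi-level loop on a preprocessed plant mesh."""
    config = config or SegmentationConfig()
    if plant_mesh.n_vertices == 0 or plant_mesh.n_faces == 0:
        raise InputError("empty plant mesh")
    field = estimate_vertex_attributes(plant_mesh, n_p=config.n_p)
    stats = surface_stats(field)
    adjacency = vertex_adjacency(plant_mesh)

    active = np.ones(plant_mesh.n_vertices, dtype=bool)
    accepted: list[LeafCluster] = []
    rejected: list[LeafCluster] = []
    levels: list[LevelRecord] = []
    prev_failed_hashes: set[int] = set()

    def hash_of(c: LeafCluster) -> int:
        return hash(c.vertex_ids.tobytes())

    t = 0
    while True:
        t += 1
        m = config.init_multiplier - config.multiplier_step * (t - 1)
        if m <= 0:
            break
        eps_a = m * stats.sigma_smooth
        eps_b = m * stats.rho_curv
        if eps_a <= config.epsilon_floor or eps_b <= config.epsilon_floor:
            break
        if not active.any():
            break
        clusters, small = region_growing(
            plant_mesh, field, eps_a, eps_b,
            min_cluster_vertices=config.min_cluster_vertices,
            active=active, adjacency=adjacency, return_small=True,
        )
        for c in small:
            active[c.vertex_ids] = False
            rejected.append(c)
        measurable: list[LeafCluster] = []
        for c in clusters:
            try:
                c.traits = trait_vector(
                    c.submesh, q=config.q_endpoint, k_slices=config.k_width_slices
                )
                measurable.append(c)
            except LeafMorphError as exc:
                c.reason = f"trait_measurement_failed: {exc}"
                active[c.vertex_ids] = False
                rejected.append(c)

        pool = accepted + measurable
        n_new_accept = 0
        failed: list[LeafCluster] = []
        stalled: list[LeafCluster] = []
        if pool:
            model = fit_shape_model([c.traits for c in pool])
            newly: list[LeafCluster] = []
            for c in measurable:
                if detect_typical(c.traits, model).is_typical:
                    newly.append(c)
                elif hash_of(c) in prev_failed_hashes:
                    # a finer level reproduced this cluster unchanged:
                    # further tightening can only shatter it into sub-leaf
                    # fragments, so retire it instead of re-segmenting
                    c.reason = "unsegmentable_at_finer_scale"
                    stalled.append(c)
                else:
                    failed.append(c)
            survivors: list[LeafCluster] = []
            for c in accepted:
                res = detect_typical(c.traits, model)
                if res.is_typical:
                    survivors.append(c)
                else:
                    c.reason = f"removed_by_level_{t}_model: {res.reason}"
                    rejected.append(c)
            accepted = survivors + newly
            for c in newly:
                active[c.vertex_ids] = False
            for c in stalled:
                active[c.vertex_ids] = False
                rejected.append(c)
            n_new_accept = len(newly)
            prev_failed_hashes = {hash_of(c) for c in failed}
        levels.append(
            LevelRecord(t, m, eps_a, eps_b, len(clusters) + len(small), n_new_accept)
        )
        if pool and not failed:
            break

    final_model: ShapeModel | None = None
    typical: list[LeafCluster] = []
    if accepted:
        final_model = fit_shape_model([c.traits for c in accepted])
        for c in accepted:
            res = detect_typical(c.traits, final_model)
            if res.is_typical:
                typical.append(c)
            else:
                c.reason = f"final_detection: {res.reason}"
                rejected.append(c)
    return SegmentationReport(
        typical_leaves=typical,
        rejected=rejected,
        levels_run=len(levels),
        final_model=final_model,
        levels=levels,
    )
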