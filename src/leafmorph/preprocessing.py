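"""Non-plant removal: detect the table plane and cut away the pot/soil slab.

A scanned potted plant stands on a planar table.  The dominant plane is
found by seeded RANSAC over vertex triples and refit by least squares on
its inliers; every face lying entirely below a vertical buffer of
``epsilon_mm`` (default 100 mm) above that plane — table, pot and soil —
is then removed, leaving the plant canopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InputError
from .mesh import TriangleMesh

__all__ = ["PlaneModel", "PreprocessConfig", "detect_table_plane", "remove_non_plant"]


@dataclass(frozen=True)
class PlaneModel:
    """Plane ``{p : normal . p = offset}`` with unit normal, oriented so the
    plant side has positive signed height."""

    normal: np.ndarray
    offset: float
    inlier_count: int

    def signed_height(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset


@dataclass
class PreprocessConfig:
    """Tunables of the non-plant removal step.

    ``epsilon_mm`` is the vertical buffer above the table inside which all
    geometry (pot, soil) is discarded.  RANSAC iteration count and inlier
    tolerance control the table fit; ``min_plane_fraction`` is the smallest
    inlier fraction accepted as a dominant plane.
    """

    epsilon_mm: float = 100.0
    ransac_iterations: int = 1000
    ransac_inlier_tol_mm: float = 2.0
    min_plane_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon_mm <= 0:
            raise InputError("epsilon_mm must be positive")
        if self.ransac_inlier_tol_mm <= 0:
            raise InputError("ransac_inlier_tol_mm must be positive")
        if self.ransac_iterations < 1:
            raise InputError("ransac_iterations must be >= 1")


def _plane_from_triples(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    """Unit normals and offsets for a batch of 3-point samples; degenerate
    samples get a zero normal."""
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    ok = norm[:, 0] > 1e-12
    n = np.where(norm > 1e-12, n / np.where(norm > 1e-12, norm, 1.0), 0.0)
    d = np.einsum("ij,ij->i", n, p0)
    return n, d, ok


def detect_table_plane(mesh: TriangleMesh, config: PreprocessConfig | None = None) -> PlaneModel:
    """Find the dominant plane of a scene by RANSAC over random vertex triples.

    The best-consensus plane is refit by total least squares (SVD) on its
    inliers and oriented so that the centroid of the off-plane vertices has
    positive signed height.
    """
    config = config or PreprocessConfig()
    verts = mesh.vertices
    n = len(verts)
    if n < 3:
        raise InputError("plane detection needs at least 3 vertices")
    rng = np.random.default_rng(config.rng_seed)
    iters = config.ransac_iterations
    triples = rng.integers(0, n, size=(iters, 3))
    normals, offsets, ok = _plane_from_triples(
        verts[triples[:, 0]], verts[triples[:, 1]], verts[triples[:, 2]]
    )
    tol = config.ransac_inlier_tol_mm
    best_count = -1
    best = None
    # chunked inlier counting keeps the distance matrix small
    chunk = max(1, int(5e6) // max(n, 1))
    for s in range(0, iters, chunk):
        e = min(iters, s + chunk)
        d = np.abs(verts @ normals[s:e].T - offsets[s:e])  # (n, chunk)
        counts = (d <= tol).sum(axis=0)
        counts[~ok[s:e]] = -1
        i = int(np.argmax(counts))
        if counts[i] > best_count:
            best_count = int(counts[i])
            best = (normals[s + i], offsets[s + i])
    if best is None or best_count < max(3, config.min_plane_fraction * n):
        raise GeometryError(
            f"no dominant plane: best inlier fraction "
            f"{max(best_count, 0) / n:.3f} < {config.min_plane_fraction}"
        )
    # least-squares refit on the consensus set
    normal, offset = best
    inliers = np.abs(verts @ normal - offset) <= tol
    pts = verts[inliers]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[-1]
    offset = float(normal @ centroid)
    # orient toward the plant: off-plane vertex centroid gets positive height
    h = verts @ normal - offset
    off_plane = np.abs(h) > tol
    if off_plane.any() and h[off_plane].mean() < 0:
        normal, offset = -normal, -offset
    return PlaneModel(normal=normal, offset=offset, inlier_count=int(inliers.sum()))


def remove_non_plant(
    mesh: TriangleMesh, plane: PlaneModel, config: PreprocessConfig | None = None
) -> TriangleMesh:
    """Drop every face lying entirely below ``epsilon_mm`` above the table.

    A face survives only if at least one of its vertices reaches signed
    height ``epsilon_mm``; everything lower — the table itself, the pot and
    the soil — is removed, and unreferenced vertices are dropped while
    preserving the relative order of the survivors.
    """
    config = config or PreprocessConfig()
    h = plane.signed_height(mesh.vertices)
    keep = (h[mesh.faces] >= config.epsilon_mm).any(axis=1)
    if not keep.any():
        raise GeometryError(
            f"no plant geometry above the {config.epsilon_mm} mm buffer"
        )
    return mesh.submesh_from_faces(np.where(keep)[0])
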