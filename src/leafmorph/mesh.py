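"""Triangle-mesh data model, file I/O, topology and local surface statistics.

The mesh is the universal geometry carrier of the pipeline: plant scans,
preprocessed plants and individual leaf submeshes are all
:class:`TriangleMesh` instances with vertex coordinates in millimetres.

Local differential quantities are estimated point-cloud style: the normal
and curvature of a vertex come from the covariance of its ``n_p`` nearest
vertices (Euclidean neighbours, not ring topology), and the per-vertex
smoothness is the mean unsigned angle between its normal and the normals
of its edge-adjacent vertices, in degrees.  The *curvature* here is the
surface-variation ratio lambda_min / (lambda_1 + lambda_2 + lambda_3),
which is 0 on a plane and at most 1/3 for isotropic scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

from .errors import InputError, MeshFormatError, TopologyError

__all__ = [
    "TriangleMesh",
    "VertexField",
    "SurfaceStats",
    "load_mesh",
    "save_mesh",
    "boundary_edges",
    "boundary_loops",
    "vertex_adjacency",
    "estimate_vertex_attributes",
    "surface_stats",
]


@dataclass
class TriangleMesh:
    """Indexed triangle mesh in millimetre coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        0-based vertex indices, three distinct indices per face.
    source_vertex_indices : (n,) int array, optional
        For submeshes: the index of each vertex in the parent mesh it was
        extracted from.  ``None`` for meshes loaded from file or generated
        directly.
    """

    vertices: np.ndarray
    faces: np.ndarray
    source_vertex_indices: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self) -> "TriangleMesh":
        """Check face-index bounds and non-degeneracy; return self.

        Raises
        ------
        MeshFormatError
            If the mesh has no faces, a face references a vertex that does
            not exist, or a face repeats a vertex.
        """
        if self.n_faces == 0:
            raise MeshFormatError("mesh has zero faces")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            bad = np.where(
                (self.faces < 0).any(axis=1) | (self.faces >= self.n_vertices).any(axis=1)
            )[0][0]
            raise MeshFormatError(
                f"face {bad} = {self.faces[bad].tolist()} references a vertex "
                f"outside [0, {self.n_vertices})"
            )
        degen = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degen.any():
            bad = int(np.where(degen)[0][0])
            raise MeshFormatError(
                f"face {bad} = {self.faces[bad].tolist()} repeats a vertex"
            )
        return self

    def copy(self) -> "TriangleMesh":
        src = None if self.source_vertex_indices is None else self.source_vertex_indices.copy()
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), src)

    def submesh_from_faces(self, face_indices: np.ndarray) -> "TriangleMesh":
        """Extract the faces in ``face_indices``, dropping unreferenced
        vertices and preserving the relative vertex order."""
        face_indices = np.asarray(face_indices, dtype=np.int64)
        faces = self.faces[face_indices]
        used = np.unique(faces)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        parent = (
            used
            if self.source_vertex_indices is None
            else self.source_vertex_indices[used]
        )
        return TriangleMesh(self.vertices[used], remap[faces], parent)

    def submesh_from_vertices(self, vertex_indices: np.ndarray) -> "TriangleMesh":
        """Extract the faces whose three vertices all lie in ``vertex_indices``."""
        keep = np.zeros(self.n_vertices, dtype=bool)
        keep[np.asarray(vertex_indices, dtype=np.int64)] = True
        face_mask = keep[self.faces].all(axis=1)
        return self.submesh_from_faces(np.where(face_mask)[0])

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class VertexField:
    """Per-vertex surface attributes.

    ``normals`` are unit vectors; ``curvature`` is the surface-variation
    ratio in [0, 1/3]; ``smoothness`` is the mean normal-deviation angle to
    edge-adjacent vertices in degrees.
    """

    normals: np.ndarray
    curvature: np.ndarray
    smoothness: np.ndarray

    def __len__(self) -> int:
        return len(self.curvature)

    def subset(self, idx: np.ndarray) -> "VertexField":
        return VertexField(self.normals[idx], self.curvature[idx], self.smoothness[idx])


@dataclass(frozen=True)
class SurfaceStats:
    """Mesh-wide means of the per-vertex attributes: ``sigma_smooth``
    (mean smoothness, degrees) and ``rho_curv`` (mean curvature)."""

    sigma_smooth: float
    rho_curv: float


# ---------------------------------------------------------------------------
# File I/O (delegated to trimesh; PLY ascii/binary-LE and OBJ)
# ---------------------------------------------------------------------------

def load_mesh(path: str | Path, fmt: str = "auto") -> TriangleMesh:
    """Load a PLY or OBJ triangle mesh, preserving vertex order.

    Polygonal OBJ faces are fan-triangulated by the loader.  Coordinates
    are interpreted as millimetres.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower() or "ply"
    if fmt not in ("ply", "obj"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (expected ply or obj)")
    try:
        raw = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # loader errors become format errors
        raise MeshFormatError(f"cannot parse {path.name} as {fmt}: {exc}") from exc
    if not isinstance(raw, _trimesh.Trimesh) or len(raw.faces) == 0:
        raise MeshFormatError(f"{path.name}: no triangle faces found")
    return TriangleMesh(np.asarray(raw.vertices), np.asarray(raw.faces)).validate()


def save_mesh(mesh: TriangleMesh, path: str | Path, fmt: str = "auto") -> Path:
    """Write a mesh as ASCII PLY or OBJ (chosen by extension by default)."""
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower() or "ply"
    tm = mesh.to_trimesh()
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    elif fmt == "obj":
        data = tm.export(file_type="obj")
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    return path


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _edge_counts(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Unique undirected edges and the number of faces incident to each."""
    e = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    edges, counts = np.unique(e, axis=0, return_counts=True)
    return edges, counts


def boundary_edges(mesh: TriangleMesh) -> np.ndarray:
    """Edges incident to exactly one face, as an (k, 2) index array.

    Raises :class:`TopologyError` on a non-manifold edge (three or more
    incident faces).
    """
    edges, counts = _edge_counts(mesh)
    if (counts > 2).any():
        bad = edges[np.argmax(counts > 2)]
        raise TopologyError(
            f"non-manifold edge ({bad[0]}, {bad[1]}) with {counts.max()} incident faces"
        )
    return edges[counts == 1]


def boundary_loops(mesh: TriangleMesh) -> list[list[int]]:
    """Closed cycles of boundary edges, each as a list of vertex indices.

    Returns an empty list for closed surfaces.  Cycles are vertex-disjoint
    for manifold-with-boundary meshes; at a pinch vertex the walk takes the
    lowest-index unused edge, which keeps the result deterministic.
    """
    b_edges = boundary_edges(mesh)
    if len(b_edges) == 0:
        return []
    nbrs: dict[int, list[int]] = {}
    for a, b in b_edges:
        nbrs.setdefault(int(a), []).append(int(b))
        nbrs.setdefault(int(b), []).append(int(a))
    for v in nbrs:
        nbrs[v].sort()
    used: set[tuple[int, int]] = set()
    loops: list[list[int]] = []
    for start in sorted(nbrs):
        if all((start, n) in used for n in nbrs[start]):
            continue
        loop = [start]
        cur = start
        while True:
            nxt = None
            for n in nbrs[cur]:
                if (cur, n) not in used:
                    nxt = n
                    break
            if nxt is None:
                break
            used.add((cur, nxt))
            used.add((nxt, cur))
            if nxt == start:
                break
            loop.append(nxt)
            cur = nxt
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """Edge-adjacent neighbours of every vertex, each sorted ascending."""
    edges, _ = _edge_counts(mesh)
    both = np.concatenate([edges, edges[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    out: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * mesh.n_vertices
    if len(both):
        starts = np.searchsorted(both[:, 0], np.arange(mesh.n_vertices))
        ends = np.searchsorted(both[:, 0], np.arange(mesh.n_vertices) + 1)
        for v in range(mesh.n_vertices):
            out[v] = both[starts[v]:ends[v], 1]
    return out


# ---------------------------------------------------------------------------
# Local surface statistics
# ---------------------------------------------------------------------------

def estimate_vertex_attributes(mesh: TriangleMesh, n_p: int = 30) -> VertexField:
    """Estimate per-vertex normal, curvature and smoothness.

    For each vertex the covariance of its ``n_p`` Euclidean nearest
    vertices (including itself) is eigen-decomposed: the normal is the
    eigenvector of the smallest eigenvalue, and the curvature is the
    surface-variation ratio lambda_min / (lambda_1+lambda_2+lambda_3).
    Normals are oriented to point away from the mesh centroid (sign kept
    when the dot product is zero).  Smoothness is the mean unsigned angle
    in degrees between a vertex normal and its edge-adjacent neighbours'
    normals.
    """
    n = mesh.n_vertices
    if n < n_p:
        raise InputError(f"mesh has {n} vertices but n_p={n_p} neighbours are required")
    verts = mesh.vertices
    tree = cKDTree(verts)
    _, idx = tree.query(verts, k=n_p)
    nbr = verts[idx]  # (n, k, 3)
    centered = nbr - nbr.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / n_p
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    total = evals.sum(axis=1)
    curvature = np.where(total > 0, evals[:, 0] / np.where(total > 0, total, 1.0), 0.0)
    normals = evecs[:, :, 0]
    # orient away from the centroid; exact ties keep the eigenvector sign
    outward = verts - verts.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)

    adjacency = vertex_adjacency(mesh)
    smoothness = np.zeros(n)
    for v, nb in enumerate(adjacency):
        if len(nb) == 0:
            continue
        d = np.abs(normals[nb] @ normals[v])
        smoothness[v] = np.degrees(np.arccos(np.clip(d, -1.0, 1.0))).mean()
    return VertexField(normals=normals, curvature=curvature, smoothness=smoothness)


def surface_stats(fld: VertexField) -> SurfaceStats:
    """Mesh-wide mean smoothness (degrees) and mean curvature."""
    if len(fld) == 0:
        raise InputError("empty vertex field")
    return SurfaceStats(
        sigma_smooth=float(fld.smoothness.mean()),
        rho_curv=float(fld.curvature.mean()),
    )
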