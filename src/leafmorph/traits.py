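"""Morphological trait measurement on a single leaf submesh.

Ten traits per leaf: four scale-related —

* ``s``  leaf area (mm^2): summed triangle areas,
* ``c``  leaf perimeter (mm): total length of the mesh boundary,
* ``l``  leaf length (mm): the longest on-surface shortest path between
  boundary vertices extremal along the first principal axis,
* ``w``  leaf width (mm): the widest surface transect perpendicular to the
  length path,

and six scale-invariant ratios s/c, s/l, s/w, c/l, c/w, l/w.  Geodesics
are edge-weighted graph shortest paths, which on leaf-scale triangulations
track true surface geodesics to within mesh resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import GeometryError, InputError, TopologyError
from .mesh import TriangleMesh, boundary_edges

__all__ = [
    "TraitVector",
    "LeafCluster",
    "leaf_area",
    "leaf_perimeter",
    "leaf_length",
    "leaf_length_path",
    "leaf_width",
    "trait_vector",
]

#: quantile of the principal-axis projection defining geodesic endpoint
#: candidates at either end of the leaf
DEFAULT_ENDPOINT_QUANTILE = 0.05
#: number of perpendicular slicing stations along the length path
DEFAULT_WIDTH_SLICES = 20


@dataclass(frozen=True)
class TraitVector:
    """The ten morphological traits of one leaf.

    Scale-related: area ``s`` (mm^2), perimeter ``c`` (mm), length ``l``
    (mm), width ``w`` (mm).  Scale-invariant: the six pairwise ratios,
    always derived from the stored scale traits.
    """

    s: float
    c: float
    l: float
    w: float

    @property
    def x11(self) -> float:  # area / perimeter, mm
        return self.s / self.c

    @property
    def x12(self) -> float:  # area / length, mm
        return self.s / self.l

    @property
    def x13(self) -> float:  # area / width, mm
        return self.s / self.w

    @property
    def x14(self) -> float:  # perimeter / length
        return self.c / self.l

    @property
    def x15(self) -> float:  # perimeter / width
        return self.c / self.w

    @property
    def x16(self) -> float:  # aspect ratio, length / width
        return self.l / self.w

    def scale_array(self) -> np.ndarray:
        return np.array([self.s, self.c, self.l, self.w])

    def ratio_array(self) -> np.ndarray:
        return np.array([self.x11, self.x12, self.x13, self.x14, self.x15, self.x16])

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.scale_array(), self.ratio_array()])

    def as_dict(self) -> dict[str, float]:
        return {
            "s_mm2": self.s,
            "c_mm": self.c,
            "l_mm": self.l,
            "w_mm": self.w,
            "x11": self.x11,
            "x12": self.x12,
            "x13": self.x13,
            "x14": self.x14,
            "x15": self.x15,
            "x16": self.x16,
        }

    def is_valid(self) -> bool:
        return all(v > 0 and np.isfinite(v) for v in (self.s, self.c, self.l, self.w))


@dataclass
class LeafCluster:
    """A candidate leaf: a connected submesh plus, once measured, its traits.

    ``vertex_ids`` index into the plant mesh the cluster was grown on;
    ``reason`` records why a cluster was rejected, if it was.
    """

    submesh: TriangleMesh
    vertex_ids: np.ndarray
    traits: TraitVector | None = None
    reason: str | None = None


# ---------------------------------------------------------------------------
# Scale-related traits
# ---------------------------------------------------------------------------

def leaf_area(submesh: TriangleMesh) -> float:
    """Total triangle area in mm^2."""
    if submesh.n_faces == 0:
        raise InputError("leaf submesh has no faces")
    v = submesh.vertices
    f = submesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    area = 0.5 * float(np.linalg.norm(cross, axis=1).sum())
    if area <= 0:
        raise GeometryError("leaf submesh has zero area (all faces degenerate)")
    return area


def leaf_perimeter(submesh: TriangleMesh) -> float:
    """Total length of all boundary edges in mm."""
    b = boundary_edges(submesh)
    if len(b) == 0:
        raise TopologyError("closed surface has no boundary to measure")
    seg = submesh.vertices[b[:, 1]] - submesh.vertices[b[:, 0]]
    return float(np.linalg.norm(seg, axis=1).sum())


def _edge_graph(submesh: TriangleMesh):
    f = submesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    w = np.linalg.norm(submesh.vertices[e[:, 0]] - submesh.vertices[e[:, 1]], axis=1)
    n = submesh.n_vertices
    g = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    return g


def _closest_points_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle of ``tri`` (m, 3, 3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom = va + vb + vc
    v = np.where(denom != 0, vb / np.where(denom != 0, denom, 1), 0.0)
    w = np.where(denom != 0, vc / np.where(denom != 0, denom, 1), 0.0)
    out = a + v[:, None] * ab + w[:, None] * ac  # interior case
    # vertex regions
    out = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, out)
    # edge AB
    t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1), 0.0)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(on_ab[:, None], a + np.clip(t, 0, 1)[:, None] * ab, out)
    # edge AC
    t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1), 0.0)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(on_ac[:, None], a + np.clip(t, 0, 1)[:, None] * ac, out)
    # edge BC
    t = np.where((d4 - d3) + (d5 - d6) != 0,
                 (d4 - d3) / np.where((d4 - d3) + (d5 - d6) != 0,
                                      (d4 - d3) + (d5 - d6), 1), 0.0)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(on_bc[:, None], b + np.clip(t, 0, 1)[:, None] * (c - b), out)
    return out


class _SurfaceProjector:
    """Batch-projects points onto the mesh via nearest vertices' faces."""

    def __init__(self, submesh: TriangleMesh, k_nearest: int = 6):
        from scipy.spatial import cKDTree

        self.verts = submesh.vertices
        self.tri = self.verts[submesh.faces]
        self.tree = cKDTree(self.verts)
        self.k = min(k_nearest, submesh.n_vertices)
        vf: list[list[int]] = [[] for _ in range(submesh.n_vertices)]
        for fi, f in enumerate(submesh.faces):
            for v in f:
                vf[v].append(fi)
        max_deg = max(len(x) for x in vf)
        pad = np.full((submesh.n_vertices, max_deg), -1, dtype=np.int64)
        for v, fs in enumerate(vf):
            pad[v, : len(fs)] = fs
        self.vf_pad = pad

    def project(self, p: np.ndarray) -> np.ndarray:
        """Closest surface points for (n, 3) query points."""
        p = np.atleast_2d(p)
        _, vidx = self.tree.query(p, k=self.k)
        vidx = np.atleast_2d(vidx)
        cand = self.vf_pad[vidx].reshape(len(p), -1)  # (n, k*max_deg)
        m = cand.shape[1]
        flat_p = np.repeat(p, m, axis=0)
        flat_f = np.where(cand >= 0, cand, 0).ravel()
        closest = _closest_points_on_triangles(flat_p, self.tri[flat_f])
        d = np.linalg.norm(closest - flat_p, axis=1)
        d[cand.ravel() < 0] = np.inf
        d = d.reshape(len(p), m)
        best = np.argmin(d, axis=1)
        return closest.reshape(len(p), m, 3)[np.arange(len(p)), best]


def _box_smooth_open(pts: np.ndarray, w: int) -> np.ndarray:
    """Box-filter a polyline with window half-width ``w``; endpoints fixed."""
    n = len(pts)
    out = pts.copy()
    csum = np.vstack([np.zeros(3), np.cumsum(pts, axis=0)])
    for i in range(1, n - 1):
        a, b = max(0, i - w), min(n, i + w + 1)
        out[i] = (csum[b] - csum[a]) / (b - a)
    return out


def _resample_polyline(pts: np.ndarray, n: int | None = None) -> np.ndarray:
    """Resample a polyline to ``n`` points uniformly spaced in arc length."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return pts.copy()
    n = n or len(pts)
    s = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, pts[:, d])
    return out


def _straighten_on_surface(
    submesh: TriangleMesh,
    pts: np.ndarray,
    projector: "_SurfaceProjector | None" = None,
) -> np.ndarray:
    """Pull a graph shortest path tight on the surface.

    Multiscale curve shortening: the polyline is resampled to uniform arc
    length, box-smoothed at geometrically decreasing window sizes and
    re-projected onto the mesh after each sweep (endpoints fixed), then
    polished with local midpoint relaxations.  On the near-developable
    surfaces of leaves this converges to the geodesic and removes the
    edge-scale zig-zag (and the taxicab inflation) of graph shortest paths.
    """
    n = len(pts)
    if n < 3:
        return pts
    proj = projector or _SurfaceProjector(submesh)
    pts = pts.copy()
    for _ in range(3):
        pts = _resample_polyline(pts)
        w = n
        while w >= 1:
            sm = _box_smooth_open(pts, w)
            pts[1:-1] = proj.project(sm[1:-1])
            w //= 2
    for _ in range(15):
        pts = _resample_polyline(pts)
        pts[1:-1] = proj.project(0.5 * (pts[:-2] + pts[2:]))
    return pts


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _principal_axis(submesh: TriangleMesh, boundary_verts: np.ndarray) -> np.ndarray:
    verts = submesh.vertices
    centered = verts - verts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = vt[0]
    # deterministic sign: point toward the boundary vertex of largest
    # coordinate sum
    ref = boundary_verts[np.argmax(verts[boundary_verts].sum(axis=1))]
    if u @ centered[ref] < 0:
        u = -u
    return u


def leaf_length_path(
    submesh: TriangleMesh, q: float = DEFAULT_ENDPOINT_QUANTILE
) -> tuple[float, list[int]]:
    """Leaf length and the realizing geodesic as a vertex-index path.

    Endpoint candidates are the boundary vertices within the bottom and top
    ``q`` quantiles of the projection onto the first principal axis (at
    least 3 at each end); the length is the maximum over candidate pairs of
    the edge-weighted shortest-path distance.
    """
    b = boundary_edges(submesh)
    bverts = np.unique(b)
    if len(bverts) < 2:
        raise InputError("need at least 2 boundary vertices for leaf length")
    g = _edge_graph(submesh)
    n_comp, _ = connected_components(g, directed=False)
    if n_comp > 1:
        raise TopologyError(f"leaf submesh is disconnected ({n_comp} components)")
    u = _principal_axis(submesh, bverts)
    proj = submesh.vertices[bverts] @ u
    order = np.argsort(proj, kind="stable")
    k = max(3, int(np.ceil(q * len(bverts))))
    lo = bverts[order[:k]]
    hi = bverts[order[-k:]]
    dist = dijkstra(g, directed=False, indices=lo)
    sub = np.where(np.isfinite(dist[:, hi]), dist[:, hi], -np.inf)
    if not np.isfinite(sub).any():
        raise TopologyError("no geodesic connects the endpoint candidates")
    # the graph metric overestimates diagonal routes, so shortlist pairs by
    # both graph distance and Euclidean chord (a geodesic lower bound),
    # straighten each onto the surface and keep the longest tightened path
    chord = np.linalg.norm(
        submesh.vertices[lo][:, None, :] - submesh.vertices[hi][None, :, :], axis=2
    )
    chord[~np.isfinite(sub)] = -np.inf
    n_top = min(2, sub.size)
    pairs = []
    for ranking in (sub, chord):
        flat = np.argsort(ranking, axis=None, kind="stable")[::-1][:n_top]
        for f in flat:
            if np.isfinite(sub.flat[f]):
                ij = np.unravel_index(f, sub.shape)
                if ij not in pairs:
                    pairs.append(ij)
    projector = _SurfaceProjector(submesh)
    pred_cache: dict[int, np.ndarray] = {}
    best_len, best_path = -np.inf, None
    for i, j in pairs:
        src = int(lo[i])
        if src not in pred_cache:
            _, pred = dijkstra(g, directed=False, indices=src,
                               return_predecessors=True)
            pred_cache[src] = pred
        pred = pred_cache[src]
        path = [int(hi[j])]
        while path[-1] != src:
            p = pred[path[-1]]
            if p < 0:
                raise TopologyError("geodesic path reconstruction failed")
            path.append(int(p))
        path.reverse()
        straight = _straighten_on_surface(
            submesh, submesh.vertices[np.array(path)], projector
        )
        length = _polyline_length(straight)
        if length > best_len:
            best_len, best_path = length, path
    return float(best_len), best_path


def leaf_length(submesh: TriangleMesh, q: float = DEFAULT_ENDPOINT_QUANTILE) -> float:
    """Leaf length in mm (see :func:`leaf_length_path`)."""
    return leaf_length_path(submesh, q=q)[0]


def _chain_component_length(segments: np.ndarray, anchor: np.ndarray) -> float:
    """Total length of the connected polyline component nearest ``anchor``.

    ``segments`` is the (k, 2, 3) output of a mesh/plane intersection; the
    segments are grouped by shared (quantized) endpoints.
    """
    k = len(segments)
    pts = segments.reshape(-1, 3)
    key = np.round(pts / 1e-6).astype(np.int64)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    endpoint_owner: dict[int, int] = {}
    for si in range(k):
        for e in (inv[2 * si], inv[2 * si + 1]):
            if e in endpoint_owner:
                ra, rb = find(endpoint_owner[e]), find(si)
                if ra != rb:
                    parent[rb] = ra
            else:
                endpoint_owner[e] = si
    seg_len = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
    mid = segments.mean(axis=1)
    d_anchor = np.linalg.norm(mid - anchor, axis=1)
    roots = np.array([find(i) for i in range(k)])
    nearest_root = roots[int(np.argmin(d_anchor))]
    return float(seg_len[roots == nearest_root].sum())


def leaf_width(
    submesh: TriangleMesh,
    length_path: list[int],
    k_slices: int = DEFAULT_WIDTH_SLICES,
) -> float:
    """Widest surface transect perpendicular to the length path, in mm.

    The path is resampled at ``k_slices`` evenly spaced stations; at each
    station the mesh is sliced by the plane through the station point with
    normal along the local path tangent, and the intersection polyline
    through the station is measured.  Stations whose slice is empty fall
    back to the widest chord among vertices near the plane.
    """
    if len(length_path) < 2:
        raise InputError("length path must contain at least 2 vertices")
    pts = submesh.vertices[np.asarray(length_path, dtype=np.int64)]
    # tighten the polyline first: a raw graph path may run along the leaf
    # margin near its endpoints, which would misorient the slicing planes
    pts = _straighten_on_surface(submesh, pts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise GeometryError("degenerate length path")
    tm = submesh.to_trimesh()

    def point_at(s: float) -> np.ndarray:
        s = float(np.clip(s, 0.0, total))
        i = min(int(np.searchsorted(cum, s, side="right") - 1), len(seg) - 1)
        t = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        return pts[i] * (1 - t) + pts[i + 1] * t

    best = 0.0
    any_slice = False
    stations = (np.arange(k_slices) + 0.5) / k_slices * total
    # the graph geodesic zig-zags at edge scale; take the tangent over an
    # arc-length window so slicing planes stay perpendicular to the leaf axis
    h = total / k_slices
    for s in stations:
        origin = point_at(s)
        tangent = point_at(s + h) - point_at(s - h)
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        segments = _trimesh.intersections.mesh_plane(tm, tangent, origin)
        if len(segments) > 0:
            any_slice = True
            best = max(best, _chain_component_length(np.asarray(segments), origin))
        else:
            near = np.abs((submesh.vertices - origin) @ tangent) < total / k_slices
            if near.sum() >= 2:
                p = submesh.vertices[near]
                p = p - (p - origin) @ tangent[:, None] * tangent  # project to plane
                d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
                best = max(best, float(d.max()))
    if best <= 0 and not any_slice:
        raise GeometryError("all width slices were empty")
    return best


def trait_vector(
    submesh: TriangleMesh,
    q: float = DEFAULT_ENDPOINT_QUANTILE,
    k_slices: int = DEFAULT_WIDTH_SLICES,
) -> TraitVector:
    """Measure all ten traits of a leaf submesh."""
    s = leaf_area(submesh)
    c = leaf_perimeter(submesh)
    length, path = leaf_length_path(submesh, q=q)
    w = leaf_width(submesh, path, k_slices=k_slices)
    tv = TraitVector(s=s, c=c, l=length, w=w)
    if not tv.is_valid():
        raise GeometryError(f"non-positive trait in {tv}")
    return tv
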