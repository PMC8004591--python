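"""Shared geometry builders for the test suite.

All fixtures construct meshes programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from leafmorph import TriangleMesh


def grid_strip(length: float, width: float, res: float) -> TriangleMesh:
    """Flat rectangular strip in the xy-plane, length along x."""
    nx = int(round(length / res)) + 1
    ny = int(round(width / res)) + 1
    xs = np.linspace(0.0, length, nx)
    ys = np.linspace(-width / 2, width / 2, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v0 = i * ny + j
            faces.append([v0, v0 + ny, v0 + 1])
            faces.append([v0 + 1, v0 + ny, v0 + ny + 1])
    return TriangleMesh(verts, np.array(faces))


def bent_strip(radius: float, angle: float, width: float, res: float) -> TriangleMesh:
    """Strip of arc length radius*angle bent over a cylinder of ``radius``."""
    flat = grid_strip(radius * angle, width, res)
    phi = flat.vertices[:, 0] / radius
    verts = np.column_stack([
        radius * np.sin(phi),
        flat.vertices[:, 1],
        radius * (1.0 - np.cos(phi)),
    ])
    return TriangleMesh(verts, flat.faces)


def disc_mesh(radius: float, n_boundary: int = 512, n_rings: int = 8) -> TriangleMesh:
    """Flat disc: ``n_boundary`` segments on the rim, concentric rings inside."""
    theta = np.linspace(0, 2 * np.pi, n_boundary, endpoint=False)
    verts = [np.zeros(3)]
    ring_start = [None]
    for r_i in range(1, n_rings + 1):
        r = radius * r_i / n_rings
        ring_start.append(len(verts))
        for t in theta:
            verts.append(np.array([r * np.cos(t), r * np.sin(t), 0.0]))
    verts = np.array(verts)
    faces = []
    # center fan
    s1 = ring_start[1]
    for j in range(n_boundary):
        faces.append([0, s1 + j, s1 + (j + 1) % n_boundary])
    for r_i in range(1, n_rings):
        a0, b0 = ring_start[r_i], ring_start[r_i + 1]
        for j in range(n_boundary):
            jn = (j + 1) % n_boundary
            faces.append([a0 + j, b0 + j, b0 + jn])
            faces.append([a0 + j, b0 + jn, a0 + jn])
    return TriangleMesh(verts, np.array(faces))


def annulus_mesh(r_in: float, r_out: float, n_seg: int = 64) -> TriangleMesh:
    """Flat annulus with two boundary loops."""
    theta = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    inner = np.column_stack([r_in * np.cos(theta), r_in * np.sin(theta), np.zeros(n_seg)])
    outer = np.column_stack([r_out * np.cos(theta), r_out * np.sin(theta), np.zeros(n_seg)])
    verts = np.vstack([inner, outer])
    faces = []
    for j in range(n_seg):
        jn = (j + 1) % n_seg
        faces.append([j, n_seg + j, n_seg + jn])
        faces.append([j, n_seg + jn, jn])
    return TriangleMesh(verts, np.array(faces))


def icosahedron() -> TriangleMesh:
    import trimesh

    ico = trimesh.creation.icosahedron()
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def sphere_mesh(subdivisions: int = 3) -> TriangleMesh:
    import trimesh

    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture
def unit_square() -> TriangleMesh:
    return TriangleMesh(
        np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float),
        np.array([[0, 1, 2], [0, 2, 3]]),
    )


@pytest.fixture
def single_triangle() -> TriangleMesh:
    return TriangleMesh(
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
        np.array([[0, 1, 2]]),
    )


def brute_force_boundary_edges(mesh: TriangleMesh) -> set[tuple[int, int]]:
    """Oracle: an edge is boundary iff exactly one face contains it."""
    from collections import Counter

    count: Counter = Counter()
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            count[tuple(sorted((int(a), int(b))))] += 1
    return {e for e, c in count.items() if c == 1}
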