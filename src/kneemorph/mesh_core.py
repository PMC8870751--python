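"""Triangle-mesh container and geometric primitives.

Everything downstream (wall thickness, curvature, hole detection) works on
:class:`TriSurface`, a thin immutable wrapper over vertex/face arrays in
millimetres.  STL input/output is delegated to :mod:`trimesh`; the geometric
queries used by the analyses (areas, enclosed volume, boundary loops, ray
casting) are implemented here so that their contracts are explicit and
oracle-checkable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: faces with area below this (mm^2) are dropped as degenerate
AREA_EPSILON = 1e-10
#: vertices closer than this (mm) are welded on STL import
WELD_TOLERANCE = 1e-6
#: ray hits closer than this (mm) to the origin are ignored
RAY_EPSILON = 1e-6


class MeshValidationError(ValueError):
    """Raised when a surface violates a structural precondition."""


@dataclass(frozen=True)
class BoundaryLoop:
    """An ordered closed cycle of boundary vertices.

    ``classification`` is ``"outer"`` for the loop with the largest
    projected area (the rim of an open patch) and ``"interior"`` for the
    rest (hole rims).
    """

    vertex_indices: np.ndarray
    length_mm: float
    classification: str  # "outer" | "interior"

    @property
    def n_vertices(self) -> int:
        return int(len(self.vertex_indices))


@dataclass(frozen=True)
class TriSurface:
    """Triangulated surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices

    Degenerate faces (area <= ``AREA_EPSILON``) are removed at
    construction with a logged count.  Derived quantities (areas,
    normals, centroids, adjacency) are cached lazily.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _: dataclass = field(default=None, repr=False, compare=False)

    def __init__(self, vertices, faces):
        vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if len(faces) == 0:
            raise MeshValidationError("mesh has no faces")
        if faces.min() < 0 or faces.max() >= len(vertices):
            raise MeshValidationError("face indices out of range")
        areas = _triangle_areas(vertices[faces])
        degenerate = areas <= AREA_EPSILON
        if degenerate.any():
            log.info("dropping %d degenerate faces", int(degenerate.sum()))
            faces = faces[~degenerate]
            if len(faces) == 0:
                raise MeshValidationError("all faces degenerate")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "faces", faces)

    # -- derived per-face quantities ------------------------------------
    @cached_property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) vertex coordinates of each face."""
        return self.vertices[self.faces]

    @cached_property
    def face_areas(self) -> np.ndarray:
        return _triangle_areas(self.triangles)

    @cached_property
    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @cached_property
    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    # -- topology --------------------------------------------------------
    @cached_property
    def _edge_data(self):
        """Sorted edge array, unique edges and per-edge face counts."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e_sorted = np.sort(e, axis=1)
        uniq, inverse, counts = np.unique(
            e_sorted, axis=0, return_inverse=True, return_counts=True
        )
        return e, uniq, inverse, counts

    @cached_property
    def n_edges(self) -> int:
        return int(len(self._edge_data[1]))

    @cached_property
    def boundary_edges(self) -> np.ndarray:
        """(k, 2) directed boundary edges (each belongs to exactly one face)."""
        e, uniq, inverse, counts = self._edge_data
        return e[np.isin(inverse, np.flatnonzero(counts == 1))]

    @cached_property
    def is_closed(self) -> bool:
        counts = self._edge_data[3]
        return bool((counts == 2).all())

    @cached_property
    def euler_characteristic(self) -> int:
        return int(len(self.vertices_used) - self.n_edges + len(self.faces))

    @cached_property
    def vertices_used(self) -> np.ndarray:
        return np.unique(self.faces)

    @cached_property
    def face_adjacency(self) -> list[np.ndarray]:
        """For each face, indices of faces sharing an edge with it."""
        e, uniq, inverse, counts = self._edge_data
        m = len(self.faces)
        face_of_edge = np.tile(np.arange(m), 3)
        order = np.argsort(inverse, kind="stable")
        neighbors: list[list[int]] = [[] for _ in range(m)]
        sorted_inv = inverse[order]
        sorted_face = face_of_edge[order]
        # group faces by shared undirected edge
        boundaries = np.flatnonzero(np.diff(sorted_inv)) + 1
        for group in np.split(sorted_face, boundaries):
            if len(group) > 1:
                for f in group:
                    for g in group:
                        if f != g:
                            neighbors[f].append(int(g))
        return [np.array(sorted(set(n)), dtype=np.int64) for n in neighbors]

    def validate_manifold(self) -> None:
        """Raise if any edge is shared by more than two faces."""
        e, uniq, inverse, counts = self._edge_data
        bad = uniq[counts > 2]
        if len(bad):
            raise MeshValidationError(
                f"{len(bad)} non-manifold edges (first: {bad[:5].tolist()})"
            )

    def validate_closed(self) -> None:
        self.validate_manifold()
        if not self.is_closed:
            raise MeshValidationError(
                f"surface is not closed: {len(self.boundary_edges)} boundary edges"
            )

    # -- conversion -------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def validation_report(self) -> dict:
        """Counts of structural defects, serializable to JSON."""
        _, uniq, _, counts = self._edge_data
        return {
            "n_vertices": int(len(self.vertices_used)),
            "n_faces": int(len(self.faces)),
            "n_edges": self.n_edges,
            "n_boundary_edges": int(len(self.boundary_edges)),
            "n_nonmanifold_edges": int((counts > 2).sum()),
            "n_boundary_loops": len(boundary_loops(self)) if not self.is_closed else 0,
            "closed": self.is_closed,
            "euler_characteristic": self.euler_characteristic,
        }


def _triangle_areas(tri: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )


# ---------------------------------------------------------------------------
# STL input / output
# ---------------------------------------------------------------------------

def read_stl(path: str | Path) -> TriSurface:
    """Load a binary or ASCII STL file, welding duplicate vertices.

    STL stores each triangle with its own vertex copies; vertices within
    ``WELD_TOLERANCE`` mm are merged so that adjacency is meaningful.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mesh = trimesh.load(path, file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshValidationError(f"empty or unreadable STL: {path}")
    verts, faces = weld_vertices(np.asarray(mesh.vertices), np.asarray(mesh.faces))
    return TriSurface(verts, faces)


def write_stl(surface: TriSurface, path: str | Path) -> None:
    """Write a binary STL file."""
    surface.to_trimesh().export(Path(path), file_type="stl")


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOLERANCE
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices that coincide within ``tol`` (grid rounding)."""
    key = np.round(vertices / tol).astype(np.int64)
    uniq, index, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    return vertices[index], inverse[faces]


# ---------------------------------------------------------------------------
# areas and volumes
# ---------------------------------------------------------------------------

def surface_area(surface: TriSurface) -> float:
    """Total surface area in mm^2 (sum of per-face areas)."""
    return float(surface.face_areas.sum())


def enclosed_volume(surface: TriSurface) -> float:
    """Volume (mm^3) enclosed by a closed, consistently oriented surface.

    Divergence theorem over signed tetrahedra.  Positive for outward
    orientation; an inward-oriented mesh is rejected.
    """
    surface.validate_closed()
    tri = surface.triangles
    vol = float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)
    if vol < 0:
        raise MeshValidationError(
            "surface is oriented inward (negative signed volume); flip face winding"
        )
    return vol


# ---------------------------------------------------------------------------
# boundary loops
# ---------------------------------------------------------------------------

def boundary_loops(surface: TriSurface) -> list[BoundaryLoop]:
    """Extract ordered boundary loops of an open surface.

    Every boundary edge (incident to exactly one face) belongs to exactly
    one returned loop.  The loop whose projection onto its best-fit plane
    has the largest area is classified ``outer``; the rest ``interior``.
    A closed surface yields an empty list.
    """
    surface.validate_manifold()
    edges = surface.boundary_edges
    if len(edges) == 0:
        return []
    nxt = {int(a): int(b) for a, b in edges}
    if len(nxt) != len(edges):
        raise MeshValidationError("boundary is not a disjoint union of simple cycles")
    loops_idx: list[np.ndarray] = []
    seen: set[int] = set()
    for start in nxt:
        if start in seen:
            continue
        cycle = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            cycle.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops_idx.append(np.array(cycle, dtype=np.int64))
    areas = [abs(_projected_loop_area(surface.vertices[idx])) for idx in loops_idx]
    outer = int(np.argmax(areas)) if len(loops_idx) > 1 else 0
    out = []
    for i, idx in enumerate(loops_idx):
        pts = surface.vertices[idx]
        length = float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())
        cls = "outer" if i == outer else "interior"
        if len(loops_idx) == 1:
            cls = "outer"
        out.append(BoundaryLoop(idx, length, cls))
    return out


def _projected_loop_area(points: np.ndarray) -> float:
    """Signed area of a 3D polygon projected onto its best-fit plane."""
    c = points.mean(axis=0)
    p = points - c
    # plane normal = smallest principal axis
    _, _, vt = np.linalg.svd(p, full_matrices=False)
    u, v = p @ vt[0], p @ vt[1]
    return 0.5 * float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v))


# ---------------------------------------------------------------------------
# ray casting (Moller-Trumbore, vectorized over triangles)
# ---------------------------------------------------------------------------

def _ray_triangle_distances(
    tri: np.ndarray, origin: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Distance along ray to each triangle's plane-hit; NaN where no hit."""
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 / a
        s = origin[None, :] - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ direction)
        t = f * np.einsum("ij,ij->i", e2, q)
    eps = 1e-12
    with np.errstate(invalid="ignore"):
        ok = (
            (np.abs(a) > eps)
            & (u >= -eps)
            & (v >= -eps)
            & (u + v <= 1 + eps)
            & (t > 0)
        )
    t = np.where(ok, t, np.nan)
    return t


def ray_first_hit(
    surface: TriSurface,
    origin: Sequence[float],
    direction: Sequence[float],
    excluded_faces: Sequence[int] = (),
    ray_epsilon: float = RAY_EPSILON,
) -> tuple[int, float] | None:
    """First intersection of a ray with the surface.

    Returns ``(face_index, distance_mm)`` for the nearest hit at distance
    greater than ``ray_epsilon`` whose face is not in ``excluded_faces``,
    or ``None`` when the ray misses.
    """
    origin = np.asarray(origin, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("ray direction must be nonzero")
    direction = direction / norm
    t = _ray_triangle_distances(surface.triangles, origin, direction)
    if len(excluded_faces):
        t[np.asarray(excluded_faces, dtype=np.int64)] = np.nan
    t[t <= ray_epsilon] = np.nan
    if np.all(np.isnan(t)):
        return None
    idx = int(np.nanargmin(t))
    return idx, float(t[idx])
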