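"""Per-element cartilage analyses: wall thickness, Gaussian curvature, holes.

Two scalar fields are computed per cartilage mesh element (triangle):

* **wall thickness** — the surface-to-surface distance across a closed
  shell, measured by casting a ray from each face centroid along the
  inward normal;
* **Gaussian curvature** — the intrinsic curvature (mm^-2) discretized by
  the vertex angle deficit, transferred to faces by averaging.

Through-defects ("holes") in an open cartilage patch are detected as
interior boundary loops and sized by a best-fit ellipse; compartments are
graded 0/1/2 by total ellipse area against a 20 mm^2 cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import EllipseModel

from .mesh_core import (
    RAY_EPSILON,
    BoundaryLoop,
    MeshValidationError,
    TriSurface,
    _ray_triangle_distances,
    boundary_loops,
    weld_vertices,
)

log = logging.getLogger(__name__)

#: compartment grade cutoff on total hole area (mm^2); at the boundary the
#: lower grade applies (area == cutoff -> grade 1)
GRADE_CUTOFF_MM2 = 20.0
#: thickness search ceiling (mm); beyond it, nearest-point fallback applies
MAX_THICKNESS_MM = 25.0


@dataclass
class ElementField:
    """One scalar per face of a surface (thickness mm or curvature mm^-2)."""

    surface: TriSurface
    values: np.ndarray
    analysis_kind: str  # "wall" | "curvature"
    valid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.values) != len(self.surface.faces):
            raise ValueError("value count must equal face count")
        if len(self.valid) != len(self.values):
            raise ValueError("validity flag count must equal face count")
        if self.analysis_kind == "wall" and np.any(self.values[self.valid] <= 0):
            raise ValueError("valid thickness values must be positive")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class HoleRecord:
    """A through-defect: one interior boundary loop with its fitted ellipse."""

    compartment: str
    loop: BoundaryLoop
    semi_axis_a: float  # mm, a >= b
    semi_axis_b: float
    grade: int | None = None

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.semi_axis_a * self.semi_axis_b)


# ---------------------------------------------------------------------------
# wall thickness
# ---------------------------------------------------------------------------

def wall_thickness(
    surface: TriSurface,
    max_thickness: float = MAX_THICKNESS_MM,
    ray_epsilon: float = RAY_EPSILON,
    chunk: int = 256,
) -> ElementField:
    """Surface-to-surface thickness for every face of a closed shell.

    For each face a ray is cast from the centroid along the inward normal;
    the face itself and its edge-neighbours are excluded from the hit set.
    If no hit lies within ``max_thickness`` the distance to the nearest
    point on any non-adjacent face is used; if that also exceeds
    ``max_thickness`` the element is flagged invalid.

    Raises on an open surface: thickness across a shell is only defined
    when an opposite wall exists (open patches go through the hole /
    boundary pathway instead).
    """
    try:
        surface.validate_closed()
    except MeshValidationError as err:
        raise MeshValidationError(
            f"wall thickness requires a closed shell ({err}); "
            "open patches are analysed via boundary loops, not thickness"
        ) from err

    tri = surface.triangles
    origins = surface.face_centroids
    directions = -surface.face_normals  # inward for outward-oriented shells
    m = len(tri)
    adjacency = surface.face_adjacency
    thickness = np.full(m, np.nan)

    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        for i in range(lo, hi):
            t = _ray_triangle_distances(tri, origins[i], directions[i])
            t[i] = np.nan
            t[adjacency[i]] = np.nan
            t[t <= ray_epsilon] = np.nan
            if not np.all(np.isnan(t)):
                thickness[i] = np.nanmin(t)

    # nearest-point fallback for rays that escaped (e.g. through a hole rim)
    missed = np.isnan(thickness) | (thickness > max_thickness)
    if missed.any():
        import trimesh.triangles as tt

        for i in np.flatnonzero(missed):
            keep = np.ones(m, dtype=bool)
            keep[i] = False
            keep[adjacency[i]] = False
            result = tt.closest_point(
                tri[keep], np.tile(origins[i], (int(keep.sum()), 1))
            )
            d = float(np.asarray(result[1]).min())
            thickness[i] = d if d <= max_thickness else np.nan

    valid = ~np.isnan(thickness) & (thickness > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("wall thickness: %d/%d elements invalid", n_bad, m)
    thickness = np.where(valid, thickness, 1.0)  # placeholder under invalid flag
    return ElementField(surface, thickness, "wall", valid)


# ---------------------------------------------------------------------------
# Gaussian curvature (angle deficit)
# ---------------------------------------------------------------------------

def gaussian_curvature(surface: TriSurface) -> ElementField:
    """Discrete Gaussian curvature per face (mm^-2).

    Per interior vertex ``K_v = (2*pi - sum of incident angles) / A_v``
    with ``A_v`` one third of the incident face areas (barycentric area).
    Boundary vertices are invalid; a face's value is the mean of its valid
    vertex values, invalid when none of its vertices are.
    """
    surface.validate_manifold()
    V, F = surface.vertices, surface.faces
    tri = surface.triangles
    angles = _corner_angles(tri)

    n = len(V)
    angle_sum = np.zeros(n)
    np.add.at(angle_sum, F.ravel(), angles.ravel())
    area_acc = np.zeros(n)
    np.add.at(area_acc, F.ravel(), np.repeat(surface.face_areas / 3.0, 3))

    on_boundary = np.zeros(n, dtype=bool)
    be = surface.boundary_edges
    if len(be):
        on_boundary[np.unique(be)] = True
    used = np.zeros(n, dtype=bool)
    used[surface.vertices_used] = True
    vertex_valid = used & ~on_boundary & (area_acc > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        K_v = (2 * np.pi - angle_sum) / area_acc
    K_v[~vertex_valid] = np.nan

    corner_K = K_v[F]  # (m, 3)
    corner_ok = ~np.isnan(corner_K)
    n_ok = corner_ok.sum(axis=1)
    face_valid = n_ok > 0
    face_K = np.where(corner_ok, corner_K, 0.0).sum(axis=1)
    face_K[face_valid] /= n_ok[face_valid]
    face_K[~face_valid] = 0.0
    return ElementField(surface, face_K, "curvature", face_valid)


def total_angle_deficit(surface: TriSurface) -> float:
    """Sum of vertex angle deficits; equals 2*pi*chi on a closed mesh."""
    angles = _corner_angles(surface.triangles)
    n = len(surface.vertices)
    angle_sum = np.zeros(n)
    np.add.at(angle_sum, surface.faces.ravel(), angles.ravel())
    used = surface.vertices_used
    return float(np.sum(2 * np.pi - angle_sum[used]))


def _corner_angles(tri: np.ndarray) -> np.ndarray:
    """(m, 3) interior angle at each triangle corner."""
    out = np.empty((len(tri), 3))
    for k in range(3):
        a = tri[:, (k + 1) % 3] - tri[:, k]
        b = tri[:, (k + 2) % 3] - tri[:, k]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        out[:, k] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# hole detection and grading
# ---------------------------------------------------------------------------

def fit_ellipse_3d(points: np.ndarray) -> tuple[float, float]:
    """Best-fit ellipse semi-axes (a >= b, mm) of a 3D loop.

    The loop is projected onto its best-fit plane (principal axes of the
    point cloud); a direct least-squares conic fit is attempted first and
    the second-moment (covariance) ellipse is used when the fit is
    degenerate or wildly inconsistent with the point spread.
    """
    points = np.asarray(points, dtype=np.float64)
    c = points.mean(axis=0)
    p = points - c
    _, _, vt = np.linalg.svd(p, full_matrices=False)
    uv = np.column_stack([p @ vt[0], p @ vt[1]])

    a = b = None
    if len(uv) >= 5:
        try:
            if hasattr(EllipseModel, "from_estimate"):
                model = EllipseModel.from_estimate(uv)
                axes = model.axis_lengths if model else None
            else:  # older scikit-image
                model = EllipseModel()
                axes = model.params[2:4] if model.estimate(uv) else None
        except Exception:  # pragma: no cover - numerical edge cases
            axes = None
        if axes is not None:
            ea, eb = float(axes[0]), float(axes[1])
            if np.isfinite(ea) and np.isfinite(eb) and ea > 0 and eb > 0:
                a, b = max(ea, eb), min(ea, eb)
    spread = float(np.abs(uv).max())
    if a is None or a > 10 * spread:
        # covariance fallback: for a uniformly sampled ellipse boundary the
        # second moments are a^2/2 and b^2/2 along the principal axes
        cov = np.cov(uv.T)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        evals = np.clip(evals, 0, None)
        a, b = float(np.sqrt(2 * evals[0])), float(np.sqrt(2 * evals[1]))
    return a, b


def detect_holes(open_patch: TriSurface, compartment: str = "") -> list[HoleRecord]:
    """One :class:`HoleRecord` per interior boundary loop of an open patch.

    A closed input cannot carry interior loops; an empty list is returned
    with a note (genus counting on the closed shell covers that case).
    """
    loops = boundary_loops(open_patch)
    if not loops:
        log.info("detect_holes: closed surface; use genus counting instead")
        return []
    records = []
    for loop in loops:
        if loop.classification != "interior":
            continue
        pts = open_patch.vertices[loop.vertex_indices]
        a, b = fit_ellipse_3d(pts)
        records.append(HoleRecord(compartment, loop, a, b))
    return records


def grade_compartment(
    holes: list[HoleRecord], cutoff: float = GRADE_CUTOFF_MM2
) -> tuple[int, float, int]:
    """Grade a compartment from its hole records.

    Returns ``(grade, total_area_mm2, n_holes)`` with grade 0 for no
    holes, 1 when the summed ellipse area is at most ``cutoff``
    (inclusive), and 2 above it.
    """
    n = len(holes)
    total = float(sum(h.area_mm2 for h in holes))
    if n == 0:
        return 0, 0.0, 0
    return (1 if total <= cutoff else 2), total, n


def grade_from_area(
    total_area: float, n_holes: int, cutoff: float = GRADE_CUTOFF_MM2
) -> int:
    """Grade from pre-summed hole area (tabular bookkeeping path)."""
    if n_holes == 0 or total_area <= 0:
        return 0
    return 1 if total_area <= cutoff else 2


# ---------------------------------------------------------------------------
# per-element text field files (3-Matic export dialect)
# ---------------------------------------------------------------------------

def write_field_file(field: ElementField, path: str | Path) -> None:
    """Write one line per element: 9 vertex coordinates then the value.

    Only valid elements are written (invalid ones carry no measurement).
    """
    tri = field.surface.triangles
    path = Path(path)
    with path.open("w") as fh:
        for i in np.flatnonzero(field.valid):
            coords = " ".join(f"{x:.6f}" for x in tri[i].ravel())
            fh.write(f"{coords} {field.values[i]:.9g}\n")


def read_field_file(path: str | Path, analysis_kind: str = "wall") -> ElementField:
    """Read a per-element field file back into an :class:`ElementField`.

    Each line must hold exactly 10 whitespace-separated numbers: three
    (x, y, z) element corners and the analysis value.  The surface is
    reconstructed from the element soup with vertex welding; element order
    is preserved.
    """
    path = Path(path)
    coords, values = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 10:
                raise ValueError(
                    f"{path}:{lineno}: expected 10 numbers, got {len(parts)}"
                )
            try:
                nums = [float(x) for x in parts]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from err
            coords.append(nums[:9])
            values.append(nums[9])
    if not values:
        raise ValueError(f"{path}: no elements")
    tri = np.asarray(coords).reshape(-1, 3, 3)
    verts = tri.reshape(-1, 3)
    faces = np.arange(len(verts)).reshape(-1, 3)
    verts, faces = weld_vertices(verts, faces)
    surface = TriSurface(verts, faces)
    values = np.asarray(values)
    if len(surface.faces) != len(values):  # degenerate lines dropped
        raise ValueError(f"{path}: degenerate elements present")
    return ElementField(surface, values, analysis_kind, np.ones(len(values), bool))
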