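"""Synthetic knee-joint cohort generator.

Stands in for a patient cohort of degenerative (D), traumatic (T) and
control (C) knees.  Each subject carries four cartilage compartments
(femoral, lateral tibial, medial tibial, patellar) realized as:

* a **closed shell** mesh — two offset spherical-cap surfaces joined at
  the rim, with optional through-holes (tunnels) and thinning patches;
* the **open outer patch** — the articulating surface alone, whose
  interior boundary loops are the holes;
* a **voxel volume** (HU) with disjoint bone and cartilage masks;
* exact **ground truth**: local thickness, hole count and per-hole
  ellipse semi-axes (area = pi*a*b), compartment densities.

Spherical caps are used deliberately: analytic area, curvature (1/R^2)
and offsets give exact oracles for every downstream analysis.  Group
archetypes default to the published cohort moments (group means/SDs of
densities, volumes and surfaces) with through-holes essentially confined
to the degenerative group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .densitometry import (
    BmdCalibration,
    LabeledVolume,
    default_calibration,
    invert_bmd,
)
from .mesh_core import MeshValidationError, TriSurface, boundary_loops, write_stl

log = logging.getLogger(__name__)

CARTILAGES = ("fem_cart", "tib_cart_lat", "tib_cart_med", "pat_cart")
BONES = ("femur", "tibia", "patella")
GROUPS = ("D", "T", "C")

#: base sphere radius (mm) per cartilage compartment; cap extent is then
#: chosen to match the drawn surface area
BASE_RADIUS_MM = {
    "fem_cart": 55.0,
    "tib_cart_lat": 22.0,
    "tib_cart_med": 22.0,
    "pat_cart": 20.0,
}

#: per-patient hole bookkeeping (count, total ellipse area mm^2) for the
#: nine patients that presented holes; used both as the empirical hole
#: distribution of the archetypes and as the tabular bookkeeping fixture
HOLE_TABLE: tuple[dict, ...] = (
    {"patient": 1, "group": "D", "fem_cart": (3, 50.11), "tib_cart_lat": (1, 1.18),
     "tib_cart_med": (7, 53.79), "pat_cart": (0, 0.00)},
    {"patient": 2, "group": "D", "fem_cart": (2, 186.83), "tib_cart_lat": (0, 0.00),
     "tib_cart_med": (0, 0.00), "pat_cart": (0, 0.00)},
    {"patient": 3, "group": "D", "fem_cart": (1, 29.57), "tib_cart_lat": (0, 0.00),
     "tib_cart_med": (1, 22.91), "pat_cart": (0, 0.00)},
    {"patient": 4, "group": "D", "fem_cart": (1, 3.06), "tib_cart_lat": (0, 0.00),
     "tib_cart_med": (0, 0.00), "pat_cart": (1, 2.97)},
    {"patient": 5, "group": "D", "fem_cart": (1, 10.52), "tib_cart_lat": (0, 0.00),
     "tib_cart_med": (0, 0.00), "pat_cart": (3, 4.03)},
    {"patient": 6, "group": "D", "fem_cart": (4, 19.80), "tib_cart_lat": (0, 0.00),
     "tib_cart_med": (0, 0.00), "pat_cart": (0, 0.00)},
    {"patient": 7, "group": "D", "fem_cart": (1, 0.78), "tib_cart_lat": (0, 0.00),
     "tib_cart_med": (0, 0.00), "pat_cart": (0, 0.00)},
    {"patient": 8, "group": "D", "fem_cart": (1, 4.60), "tib_cart_lat": (0, 0.00),
     "tib_cart_med": (0, 0.00), "pat_cart": (0, 0.00)},
    {"patient": 9, "group": "T", "fem_cart": (5, 488.81), "tib_cart_lat": (0, 0.00),
     "tib_cart_med": (0, 0.00), "pat_cart": (2, 1.87)},
)


# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------

@dataclass
class GroupArchetype:
    """Distributional description of one subject group.

    Scalar quantities are (mean, sd) of group-level Gaussians (the source
    tables report only mean/SD; Gaussian intra-group shape is an assumption,
    not an assertion).  Hole structure is empirical: a subject "has holes"
    with probability ``hole_subject_rate`` and then realizes one of the
    ``hole_rows`` (per-compartment count and total area).
    """

    group_label: str
    bone_bmd: dict  # bone -> (mean g/cm^3, sd)
    patella_volume: tuple  # (mean mm^3, sd)
    patella_surface: tuple  # (mean mm^2, sd)
    cart_density_hu: dict  # cartilage -> (mean HU, sd)
    cart_volume: dict  # cartilage -> (mean mm^3, sd)
    cart_surface: dict  # cartilage -> (mean mm^2, sd)
    thickness_mm: tuple = (2.0, 0.3)
    thinning_patch_rate: float = 0.0  # target fraction of cap area thinned
    thinning_depth_frac: float = 0.5  # patch depth as fraction of thickness
    roughness_mm: float = 0.0  # radial roughness amplitude
    hole_subject_rate: float = 0.0
    hole_rows: tuple = ()

    def __post_init__(self):
        for table in (self.bone_bmd, self.cart_density_hu,
                      self.cart_volume, self.cart_surface):
            for name, (_, sd) in table.items():
                if sd < 0:
                    raise ValueError(f"negative sd for {name}")
        for pair in (self.patella_volume, self.patella_surface, self.thickness_mm):
            if pair[1] < 0:
                raise ValueError("negative sd")
        if not 0 <= self.hole_subject_rate <= 1:
            raise ValueError("hole_subject_rate must be in [0, 1]")
        if self.group_label == "C" and (self.hole_subject_rate > 0 or self.hole_rows):
            raise ValueError("control archetype must carry zero hole mass")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroupArchetype":
        raw = json.loads(Path(path).read_text())
        for key in ("bone_bmd", "cart_density_hu", "cart_volume", "cart_surface"):
            raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        for key in ("patella_volume", "patella_surface", "thickness_mm"):
            raw[key] = tuple(raw[key])
        raw["hole_rows"] = tuple(
            {k: (tuple(v) if isinstance(v, list) else v) for k, v in row.items()}
            for row in raw["hole_rows"]
        )
        return cls(**raw)


def default_archetypes() -> dict[str, GroupArchetype]:
    """The three shipped archetypes, parameterized by the cohort group moments."""
    d_rows = tuple(r for r in HOLE_TABLE if r["group"] == "D")
    t_rows = tuple(r for r in HOLE_TABLE if r["group"] == "T")
    return {
        "D": GroupArchetype(
            group_label="D",
            bone_bmd={"femur": (1.25, 0.03), "tibia": (1.28, 0.02),
                      "patella": (1.34, 0.05)},
            patella_volume=(20368.41, 4486.86),
            patella_surface=(4867.88, 1614.10),
            cart_density_hu={"fem_cart": (88.55, 5.74), "tib_cart_lat": (88.45, 8.30),
                             "tib_cart_med": (104.20, 19.94),
                             "pat_cart": (78.98, 17.53)},
            cart_volume={"fem_cart": (20265.18, 6856.78),
                         "tib_cart_lat": (2075.11, 1515.56),
                         "tib_cart_med": (1526.14, 1226.54),
                         "pat_cart": (3241.89, 1164.37)},
            cart_surface={"fem_cart": (14737.79, 2866.13),
                          "tib_cart_lat": (1809.96, 922.87),
                          "tib_cart_med": (1702.80, 997.76),
                          "pat_cart": (2546.89, 469.92)},
            thickness_mm=(1.6, 0.25),
            thinning_patch_rate=0.40,
            roughness_mm=0.12,
            hole_subject_rate=8 / 24,
            hole_rows=d_rows,
        ),
        "T": GroupArchetype(
            group_label="T",
            bone_bmd={"femur": (1.29, 0.03), "tibia": (1.32, 0.03),
                      "patella": (1.41, 0.04)},
            patella_volume=(17747.93, 4389.93),
            patella_surface=(5648.82, 3180.33),
            cart_density_hu={"fem_cart": (88.64, 12.34), "tib_cart_lat": (91.78, 19.85),
                             "tib_cart_med": (101.32, 16.70),
                             "pat_cart": (79.19, 18.27)},
            cart_volume={"fem_cart": (13429.59, 2725.04),
                         "tib_cart_lat": (1110.60, 409.59),
                         "tib_cart_med": (981.93, 610.23),
                         "pat_cart": (2778.97, 656.93)},
            cart_surface={"fem_cart": (12270.98, 1378.72),
                          "tib_cart_lat": (1299.96, 437.06),
                          "tib_cart_med": (1233.47, 469.07),
                          "pat_cart": (2443.72, 480.52)},
            thickness_mm=(1.9, 0.25),
            thinning_patch_rate=0.15,
            roughness_mm=0.06,
            hole_subject_rate=1 / 15,
            hole_rows=t_rows,
        ),
        "C": GroupArchetype(
            group_label="C",
            bone_bmd={"femur": (1.27, 0.03), "tibia": (1.30, 0.03),
                      "patella": (1.41, 0.05)},
            patella_volume=(19375.79, 5009.31),
            patella_surface=(4105.83, 725.54),
            cart_density_hu={"fem_cart": (94.06, 7.45), "tib_cart_lat": (91.76, 3.10),
                             "tib_cart_med": (104.93, 7.65),
                             "pat_cart": (95.10, 16.47)},
            cart_volume={"fem_cart": (11764.49, 4479.56),
                         "tib_cart_lat": (757.59, 380.87),
                         "tib_cart_med": (555.76, 368.51),
                         "pat_cart": (2866.61, 715.97)},
            cart_surface={"fem_cart": (11968.50, 2663.58),
                          "tib_cart_lat": (1082.64, 371.60),
                          "tib_cart_med": (949.80, 400.35),
                          "pat_cart": (2517.28, 409.93)},
            thickness_mm=(2.3, 0.25),
            thinning_patch_rate=0.02,
            roughness_mm=0.02,
            hole_subject_rate=0.0,
            hole_rows=(),
        ),
    }


def separated_archetypes(sd_multiplier: float = 5.0) -> dict[str, GroupArchetype]:
    """Variant archetypes with group means pushed ``sd_multiplier`` pooled SDs
    apart (and within-group SDs tightened), for classifier sanity checks."""
    arch = default_archetypes()
    keys = ("cart_density_hu", "cart_volume", "cart_surface", "bone_bmd")
    for gi, g in enumerate(GROUPS):
        a = arch[g]
        for key in keys:
            table = getattr(a, key)
            for name, (mean, sd) in table.items():
                sd_new = max(sd, 1e-6) * 0.5
                table[name] = (mean + gi * sd_multiplier * max(sd, 0.05 * abs(mean)),
                               sd_new)
        a.patella_volume = (a.patella_volume[0] * (1 + 0.5 * gi),
                            a.patella_volume[1] * 0.5)
    return arch


# ---------------------------------------------------------------------------
# cap-patch geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseHole:
    """A through-hole on the cap: center in disk coordinates (mm), semi-axes
    a >= b (mm) and in-plane orientation (rad).  Analytic area = pi*a*b."""

    center: tuple[float, float]
    a: float
    b: float
    angle: float = 0.0

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.a * self.b)


@dataclass(frozen=True)
class ThinningPatch:
    """A geodesic-circular region of reduced thickness."""

    center: tuple[float, float]
    radius: float
    depth: float  # mm removed from the nominal thickness


@dataclass
class ShellCompartment:
    """One generated cartilage compartment with exact ground truth."""

    name: str
    closed_shell: TriSurface
    outer_patch: TriSurface
    base_radius: float
    cap_angle: float
    nominal_thickness: float
    holes: tuple[EllipseHole, ...]
    patches: tuple[ThinningPatch, ...]
    true_thickness: np.ndarray  # per outer-patch face; NaN on patch transitions
    face_class: np.ndarray  # per outer-patch face: 0 plain, 1 thinned, 2 transition

    @property
    def true_hole_count(self) -> int:
        return len(self.holes)

    @property
    def true_hole_areas(self) -> np.ndarray:
        return np.array([h.area_mm2 for h in self.holes])

    @property
    def patch_area_fraction(self) -> float:
        """Analytic thinned fraction of the cap (geodesic circle areas)."""
        R = self.base_radius
        cap = 2 * np.pi * R**2 * (1 - np.cos(self.cap_angle))
        patch = sum(
            2 * np.pi * R**2 * (1 - np.cos(p.radius / R)) for p in self.patches
        )
        return float(patch / cap)


def _tangent_frame(center: np.ndarray, R: float):
    """Local frame at a disk point with azimuthal metric compensation.

    The exponential map disk -> sphere is isometric radially but shrinks
    azimuthal lengths by ``lam = sin(s/R)/(s/R)``; constructing features in
    the tangent frame and dividing the azimuthal component by ``lam`` makes
    them metrically true on the sphere to first order.
    """
    s0 = float(np.linalg.norm(center))
    if s0 < 1e-9:
        return np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.0
    e_r = center / s0
    e_t = np.array([-e_r[1], e_r[0]])
    lam = float(np.sin(s0 / R) / (s0 / R))
    return e_r, e_t, lam


def _tangent_coords(points: np.ndarray, center: np.ndarray, R: float) -> np.ndarray:
    e_r, e_t, lam = _tangent_frame(center, R)
    d = points - center
    return np.column_stack([d @ e_r, (d @ e_t) * lam])


def _ellipse_boundary(hole: EllipseHole, R: float, n: int, phase: float = 0.0,
                      grow: float = 0.0) -> np.ndarray:
    c = np.asarray(hole.center, dtype=np.float64)
    e_r, e_t, lam = _tangent_frame(c, R)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    ca, sa = np.cos(hole.angle), np.sin(hole.angle)
    xi = (hole.a + grow) * np.cos(t)
    eta = (hole.b + grow) * np.sin(t)
    xr = ca * xi - sa * eta
    yr = sa * xi + ca * eta
    return c + np.outer(xr, e_r) + np.outer(yr / lam, e_t)


def _inside_ellipse(points: np.ndarray, hole: EllipseHole, R: float,
                    grow: float = 0.0) -> np.ndarray:
    c = np.asarray(hole.center, dtype=np.float64)
    uv = _tangent_coords(points, c, R)
    ca, sa = np.cos(-hole.angle), np.sin(-hole.angle)
    xi = ca * uv[:, 0] - sa * uv[:, 1]
    eta = sa * uv[:, 0] + ca * uv[:, 1]
    return (xi / (hole.a + grow)) ** 2 + (eta / (hole.b + grow)) ** 2 < 1.0


def _inside_circle(points: np.ndarray, patch: ThinningPatch, R: float) -> np.ndarray:
    uv = _tangent_coords(points, np.asarray(patch.center), R)
    return np.einsum("ij,ij->i", uv, uv) < patch.radius**2


def _hex_grid(radius: float, h: float, rng: np.random.Generator | None) -> np.ndarray:
    dy = h * np.sqrt(3) / 2
    rows = int(np.ceil(radius / dy))
    pts = []
    for j in range(-rows, rows + 1):
        y = j * dy
        xoff = 0.5 * h if j % 2 else 0.0
        cols = int(np.ceil(radius / h)) + 1
        for i in range(-cols, cols + 1):
            pts.append((i * h + xoff, y))
    pts = np.array(pts)
    pts = pts[np.linalg.norm(pts, axis=1) <= radius - 0.7 * h]
    if rng is not None and len(pts):
        pts = pts + rng.uniform(-0.08 * h, 0.08 * h, size=pts.shape)
    return pts


def _grid_step(disk_radius: float, refinement: int) -> float:
    return disk_radius / (6.0 * 2**refinement)


def min_refinement_for_holes(disk_radius: float, holes: Sequence[EllipseHole]) -> int:
    """Smallest refinement whose grid step still resolves the smallest hole."""
    if not holes:
        return 0
    min_axis = min(h.b for h in holes)
    r = 0
    while _grid_step(disk_radius, r) / 40.0 > min_axis:
        r += 1
    return r


def _build_cap_patch(R, cap_angle, refinement, holes, patches, roughness,
                     rng: np.random.Generator | None):
    """Triangulate the cap in disk coordinates and lift it to the sphere.

    Returns (verts3d, faces, disk_pts, radial_offset) with outward
    orientation (apex at +z, sphere centre at origin).
    """
    Rd = R * cap_angle
    h = _grid_step(Rd, refinement)
    for hole in holes:
        if hole.b < h / 40.0:
            need = min_refinement_for_holes(Rd, holes)
            raise MeshValidationError(
                f"refinement {refinement} too low to resolve hole with semi-axis "
                f"{hole.b:.3g} mm; use refinement >= {need}"
            )
    # pairwise hole overlap (conservative circumscribed-circle test)
    for i, hi_ in enumerate(holes):
        ci = np.asarray(hi_.center)
        if np.linalg.norm(ci) + hi_.a > 0.92 * Rd:
            raise MeshValidationError(f"hole {i} does not fit on the cap")
        for j in range(i + 1, len(holes)):
            cj = np.asarray(holes[j].center)
            if np.linalg.norm(ci - cj) <= hi_.a + holes[j].a + h:
                raise MeshValidationError(f"holes {i} and {j} overlap")

    pts = [_hex_grid(Rd, h, rng)]
    n_ring = max(24, int(np.ceil(2 * np.pi * Rd / h)))
    t = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    pts.append(Rd * np.column_stack([np.cos(t), np.sin(t)]))

    hole_growth = []
    for hole in holes:
        perim = np.pi * (3 * (hole.a + hole.b)
                         - np.sqrt((3 * hole.a + hole.b) * (hole.a + 3 * hole.b)))
        nb = max(32, int(np.ceil(perim / min(h, perim / 32))))
        hb = perim / nb
        pts.append(_ellipse_boundary(hole, R, nb))
        pts.append(_ellipse_boundary(hole, R, nb, phase=np.pi / nb, grow=1.1 * hb))
        hole_growth.append(2.2 * hb)

    # drop generic grid points that fall inside (or hug) a hole
    base = pts[0]
    keep = np.ones(len(base), dtype=bool)
    for hole, grow in zip(holes, hole_growth):
        keep &= ~_inside_ellipse(base, hole, R, grow=grow + 0.4 * h)
    pts[0] = base[keep]

    disk = np.vstack([p for p in pts if len(p)])
    tri = Delaunay(disk)
    faces = tri.simplices.copy()
    centroids = disk[faces].mean(axis=1)
    drop = np.zeros(len(faces), dtype=bool)
    for hole in holes:
        drop |= _inside_ellipse(centroids, hole, R)
    faces = faces[~drop]

    # compact unused vertices
    used = np.unique(faces)
    remap = np.full(len(disk), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    faces = remap[faces]
    disk = disk[used]

    # lift to sphere via the exponential map (radially isometric)
    s = np.linalg.norm(disk, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arctan2(disk[:, 1], disk[:, 0])
    phi = s / R
    unit = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )

    dr = np.zeros(len(disk))
    if roughness > 0 and rng is not None:
        # smooth undulation: three random plane waves
        for L in (0.6 * Rd, 0.4 * Rd, 0.25 * Rd):
            gamma = rng.uniform(0, 2 * np.pi)
            ph = rng.uniform(0, 2 * np.pi)
            proj = disk[:, 0] * np.cos(gamma) + disk[:, 1] * np.sin(gamma)
            dr += (roughness / np.sqrt(3)) * np.sin(2 * np.pi * proj / L + ph)
        # localized crater-like defects: sharp Gaussian bumps whose count
        # scales with the roughness amplitude (heavy curvature tails)
        n_bumps = int(round(roughness * 100))
        for _ in range(n_bumps):
            c = rng.uniform(-0.7, 0.7, size=2) * Rd
            w = rng.uniform(1.5, 3.0)
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 3.0) * roughness
            d2 = np.sum((disk - c) ** 2, axis=1)
            dr += amp * np.exp(-d2 / (2 * w**2))

    verts = (R + dr)[:, None] * unit
    return verts, faces, disk, dr, unit


def generate_shell(
    base_radius: float,
    nominal_thickness: float,
    thinning_patches: Sequence[ThinningPatch] = (),
    holes: Sequence[EllipseHole] = (),
    refinement: int = 2,
    seed: int = 0,
    cap_angle: float = np.pi / 3,
    roughness: float = 0.0,
    name: str = "shell",
    jitter: bool = True,
) -> ShellCompartment:
    """Generate one cartilage-like compartment with exact ground truth.

    The closed shell is two offset spherical caps joined at the rim (and
    at each hole rim, forming tunnels through the full thickness); the
    open outer patch is the articulating surface alone, whose interior
    boundary loops realize the same holes.
    """
    if nominal_thickness <= 0:
        raise ValueError("nominal_thickness must be positive")
    holes = tuple(h if isinstance(h, EllipseHole) else EllipseHole(*h) for h in holes)
    for h_ in holes:
        if not (h_.a >= h_.b > 0):
            raise ValueError("hole semi-axes must satisfy a >= b > 0")
    thinning_patches = tuple(
        p if isinstance(p, ThinningPatch) else ThinningPatch(*p)
        for p in thinning_patches
    )
    for p in thinning_patches:
        if not 0 < p.depth < nominal_thickness:
            raise ValueError("patch depth must be in (0, thickness)")
        for h_ in holes:
            if (np.linalg.norm(np.asarray(p.center) - np.asarray(h_.center))
                    <= p.radius + h_.a):
                raise MeshValidationError("thinning patch overlaps a hole")
    for i, p in enumerate(thinning_patches):
        for q in thinning_patches[i + 1:]:
            if (np.linalg.norm(np.asarray(p.center) - np.asarray(q.center))
                    <= p.radius + q.radius):
                raise MeshValidationError("thinning patches overlap")

    rng = np.random.default_rng(seed)
    verts, faces, disk, dr, unit = _build_cap_patch(
        base_radius, cap_angle, refinement, holes, thinning_patches, roughness,
        rng if (jitter or roughness > 0) else None,
    )

    # local thickness per vertex (binary step inside thinning patches)
    t_vert = np.full(len(disk), nominal_thickness)
    in_patch_vert = np.zeros(len(disk), dtype=bool)
    for p in thinning_patches:
        inside = _inside_circle(disk, p, base_radius)
        t_vert[inside] = nominal_thickness - p.depth
        in_patch_vert |= inside

    # per-face ground truth on the outer patch
    n_in = in_patch_vert[faces].sum(axis=1)
    face_class = np.where(n_in == 3, 1, np.where(n_in == 0, 0, 2)).astype(np.int8)
    true_thickness = np.where(
        face_class == 1,
        np.array([nominal_thickness - (thinning_patches[0].depth
                                        if thinning_patches else 0.0)]),
        nominal_thickness,
    ).astype(np.float64)
    if len(thinning_patches) > 1:
        # per-face depth when patches differ
        centroid = disk[faces].mean(axis=1)
        for p in thinning_patches:
            sel = (face_class == 1) & _inside_circle(centroid, p, base_radius)
            true_thickness[sel] = nominal_thickness - p.depth
    true_thickness = np.where(face_class == 2, np.nan, true_thickness)

    outer_patch = TriSurface(verts, faces)

    # inner surface: radial offset by the local thickness
    inner_verts = (base_radius + dr - t_vert)[:, None] * unit
    n = len(verts)
    inner_faces = faces[:, ::-1] + n

    wall_faces = []
    for loop in boundary_loops(outer_patch):
        idx = loop.vertex_indices
        for a, b in zip(idx, np.roll(idx, -1)):
            wall_faces.append((b, a, a + n))
            wall_faces.append((b, a + n, b + n))
    all_verts = np.vstack([verts, inner_verts])
    all_faces = np.vstack([faces, inner_faces, np.array(wall_faces, dtype=np.int64)])
    closed = TriSurface(all_verts, all_faces)

    return ShellCompartment(
        name=name,
        closed_shell=closed,
        outer_patch=outer_patch,
        base_radius=base_radius,
        cap_angle=cap_angle,
        nominal_thickness=nominal_thickness,
        holes=holes,
        patches=thinning_patches,
        true_thickness=true_thickness,
        face_class=face_class,
    )


# ---------------------------------------------------------------------------
# reference fixtures with exact analytic answers
# ---------------------------------------------------------------------------

def make_sphere_shell(r_out: float, thickness: float, subdivisions: int = 3
                      ) -> TriSurface:
    """Closed uniform shell: concentric icospheres (thickness exact everywhere)."""
    import trimesh

    outer = trimesh.creation.icosphere(subdivisions=subdivisions, radius=r_out)
    inner = trimesh.creation.icosphere(
        subdivisions=subdivisions, radius=r_out - thickness
    )
    verts = np.vstack([outer.vertices, inner.vertices])
    faces = np.vstack([outer.faces, inner.faces[:, ::-1] + len(outer.vertices)])
    return TriSurface(verts, faces)


def make_slab(width: float, thickness: float, n: int = 12) -> TriSurface:
    """Closed box of ``width x width x thickness`` with an n x n face grid."""
    xs = np.linspace(0, width, n + 1)
    top, bottom = [], []
    grid_idx = {}
    verts = []
    for z in (thickness, 0.0):
        for y in xs:
            for x in xs:
                grid_idx[(x, y, z)] = len(verts)
                verts.append((x, y, z))
    faces = []
    m = n + 1
    for j in range(n):
        for i in range(n):
            a, b, c, d = (j * m + i, j * m + i + 1, (j + 1) * m + i + 1,
                          (j + 1) * m + i)
            faces += [(a, b, c), (a, c, d)]  # top (z = t), outward +z
            off = m * m
            faces += [(a + off, c + off, b + off), (a + off, d + off, c + off)]
    # side walls
    def ring(j_i_list, off=0):
        return [j * m + i + off for j, i in j_i_list]

    edge_top = (
        [(0, i) for i in range(n)]
        + [(j, n) for j in range(n)]
        + [(n, n - i) for i in range(n)]
        + [(n - j, 0) for j in range(n)]
    )
    loop_t = ring(edge_top)
    loop_b = ring(edge_top, off=m * m)
    for k in range(len(loop_t)):
        a, b = loop_t[k], loop_t[(k + 1) % len(loop_t)]
        a2, b2 = loop_b[k], loop_b[(k + 1) % len(loop_b)]
        faces += [(b, a, a2), (b, a2, b2)]
    surf = TriSurface(np.asarray(verts, dtype=np.float64), np.asarray(faces))
    # ensure outward orientation
    tri = surf.triangles
    vol = np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    if vol < 0:
        surf = TriSurface(surf.vertices, surf.faces[:, ::-1])
    return surf


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSubject:
    subject_id: str
    group_label: str
    draws: dict  # realized scalar parameters
    compartments: dict | None  # name -> ShellCompartment
    volume: LabeledVolume | None
    ground_truth: dict


def _draw(rng, mean, sd, floor=None):
    x = float(rng.normal(mean, sd))
    if floor is not None:
        x = max(x, floor)
    return x


def _draw_subject_scalars(archetype: GroupArchetype, rng) -> dict:
    d = {"group": archetype.group_label}
    for bone, (m, s) in archetype.bone_bmd.items():
        d[f"{bone}_bmd"] = _draw(rng, m, s, floor=0.5)
    d["patella_volume"] = _draw(rng, *archetype.patella_volume, floor=2000.0)
    d["patella_surface"] = _draw(rng, *archetype.patella_surface, floor=500.0)
    for cart in CARTILAGES:
        d[f"{cart}_density"] = float(
            np.clip(_draw(rng, *archetype.cart_density_hu[cart]), 0.0, 300.0)
        )
        d[f"{cart}_volume"] = _draw(rng, *archetype.cart_volume[cart], floor=50.0)
        d[f"{cart}_surface"] = _draw(rng, *archetype.cart_surface[cart], floor=100.0)
    d["thickness"] = _draw(rng, *archetype.thickness_mm, floor=0.6)
    # hole realization: empirical row, or nothing
    if archetype.hole_subject_rate > 0 and rng.random() < archetype.hole_subject_rate:
        row = archetype.hole_rows[rng.integers(len(archetype.hole_rows))]
        d["hole_row"] = {c: tuple(row[c]) for c in CARTILAGES}
    else:
        d["hole_row"] = {c: (0, 0.0) for c in CARTILAGES}
    return d


def _place_holes(rng, Rd, R, count, total_area, grid_h) -> list[EllipseHole]:
    """Random non-overlapping elliptical holes realizing a (count, area) row."""
    if count == 0 or total_area <= 0:
        return []
    weights = rng.dirichlet(np.full(count, 2.0))
    weights = np.maximum(weights, 0.05)
    weights /= weights.sum()
    areas = weights * total_area
    b_floor = grid_h / 35.0
    holes: list[EllipseHole] = []
    for area in areas:
        q = rng.uniform(1.0, 2.0)  # axis ratio a/b
        q_max = area / (np.pi * b_floor**2)
        q = float(np.clip(q, 1.0, max(1.0, q_max)))
        a = float(np.sqrt(area * q / np.pi))
        b = a / q
        placed = False
        for _ in range(300):
            rad = rng.uniform(0, 0.70 * Rd)
            ang = rng.uniform(0, 2 * np.pi)
            c = (rad * np.cos(ang), rad * np.sin(ang))
            if rad + a > 0.85 * Rd:
                continue
            ok = all(
                np.linalg.norm(np.asarray(c) - np.asarray(h.center))
                > a + h.a + 2 * grid_h
                for h in holes
            )
            if ok:
                holes.append(EllipseHole(c, a, b, float(rng.uniform(0, np.pi))))
                placed = True
                break
        if not placed:
            log.warning("could not place a hole of %.2f mm^2; dropped", area)
    return holes


def _place_patches(rng, Rd, R, target_fraction, depth, holes, grid_h
                   ) -> list[ThinningPatch]:
    if target_fraction <= 0:
        return []
    cap_area = 2 * np.pi * R**2 * (1 - np.cos(Rd / R))
    patches: list[ThinningPatch] = []
    acc = 0.0
    for _ in range(60):
        if acc >= target_fraction * cap_area:
            break
        rho = rng.uniform(0.10, 0.24) * Rd
        for _ in range(200):
            rad = rng.uniform(0, 0.78 * Rd)
            ang = rng.uniform(0, 2 * np.pi)
            c = np.array([rad * np.cos(ang), rad * np.sin(ang)])
            if rad + rho > 0.92 * Rd:
                continue
            clear_holes = all(
                np.linalg.norm(c - np.asarray(h.center)) > rho + h.a + 2 * grid_h
                for h in holes
            )
            clear_patches = all(
                np.linalg.norm(c - np.asarray(p.center)) > rho + p.radius + grid_h
                for p in patches
            )
            if clear_holes and clear_patches:
                patches.append(ThinningPatch(tuple(c), rho, depth))
                acc += 2 * np.pi * R**2 * (1 - np.cos(rho / R))
                break
        else:
            break
    return patches


def generate_subject(
    archetype: GroupArchetype,
    seed: int,
    subject_id: str | None = None,
    spacing: float = 0.5,
    refinement: int = 1,
    include_meshes: bool = True,
    include_volume: bool = True,
    noise_sd_hu: float = 10.0,
    calibration: BmdCalibration | None = None,
    mesh_jitter: bool = True,
) -> SyntheticSubject:
    """Realize one subject from an archetype.

    ``include_meshes`` / ``include_volume`` allow a light mode carrying
    only the scalar draws (used for large-sample moment checks).
    """
    rng = np.random.default_rng(seed)
    cal = calibration or default_calibration()
    draws = _draw_subject_scalars(archetype, rng)
    sid = subject_id or f"{archetype.group_label}{seed:04d}"

    compartments = None
    if include_meshes:
        compartments = {}
        for cart in CARTILAGES:
            R = BASE_RADIUS_MM[cart]
            S = draws[f"{cart}_surface"]
            frac = min(S / (2 * np.pi * R**2), 1.8)
            cap_angle = float(np.arccos(1 - frac))
            Rd = R * cap_angle
            h = _grid_step(Rd, refinement)
            count, area = draws["hole_row"][cart]
            holes = _place_holes(rng, Rd, R, int(count), float(area), h)
            t = draws["thickness"]
            patches = _place_patches(
                rng, Rd, R, archetype.thinning_patch_rate,
                archetype.thinning_depth_frac * t, holes, h,
            )
            compartments[cart] = generate_shell(
                base_radius=R,
                nominal_thickness=t,
                thinning_patches=patches,
                holes=holes,
                refinement=refinement,
                seed=int(rng.integers(2**31 - 1)),
                cap_angle=cap_angle,
                roughness=archetype.roughness_mm,
                name=cart,
                jitter=mesh_jitter,
            )

    volume = None
    if include_volume:
        volume = _paint_volume(draws, spacing, noise_sd_hu, cal, rng)

    truth = {"subject_id": sid, "group": archetype.group_label}
    for key, val in draws.items():
        if key == "hole_row":
            for cart in CARTILAGES:
                cnt, area = val[cart]
                if compartments is not None:
                    cnt = compartments[cart].true_hole_count
                    area = float(compartments[cart].true_hole_areas.sum())
                truth[f"{cart}_n_holes"] = int(cnt)
                truth[f"{cart}_hole_area"] = round(float(area), 6)
        elif key != "group":
            truth[key] = round(float(val), 6)
    return SyntheticSubject(sid, archetype.group_label, draws, compartments,
                            volume, truth)


def _paint_volume(draws, spacing, noise_sd, cal: BmdCalibration, rng
                  ) -> LabeledVolume:
    """Paint disjoint compartment blobs into one HU grid.

    Bones are spheres (patella an ellipsoid sized to its drawn volume)
    painted at the HU equivalent of the drawn BMD; cartilages are spheres
    sized to the drawn volume at the drawn HU mean, plus Gaussian voxel
    noise everywhere.  Geometry is schematic; only densities, volumes and
    mask topology are meaningful.
    """
    ball_r = {"femur": 15.0, "tibia": 15.0}
    pat_k = (draws["patella_volume"] / ((4 / 3) * np.pi * 1.3 * 1.0 * 0.77)) ** (1 / 3)
    cart_r = {
        c: (3 * draws[f"{c}_volume"] / (4 * np.pi)) ** (1 / 3) for c in CARTILAGES
    }
    order = ["femur", "tibia", "patella", *CARTILAGES]
    extents = {
        "femur": ball_r["femur"], "tibia": ball_r["tibia"], "patella": 1.3 * pat_k,
        **{c: cart_r[c] for c in CARTILAGES},
    }
    gap, margin = 3.0, 3.0
    centers, cursor = {}, margin
    for name in order:
        r = extents[name]
        centers[name] = cursor + r
        cursor += 2 * r + gap
    length_x = cursor - gap + margin
    max_r = max(extents.values())
    length_yz = 2 * max_r + 2 * margin

    shape = (int(np.ceil(length_x / spacing)),
             int(np.ceil(length_yz / spacing)),
             int(np.ceil(length_yz / spacing)))
    hu = np.full(shape, 20.0, dtype=np.float32)  # generic soft tissue
    yc = zc = length_yz / 2
    ax_x = np.arange(shape[0], dtype=np.float32) * spacing + spacing / 2
    ax_y = np.arange(shape[1], dtype=np.float32) * spacing + spacing / 2
    ax_z = np.arange(shape[2], dtype=np.float32) * spacing + spacing / 2

    masks = {}
    for name in order:
        cx = centers[name]
        if name == "patella":
            radii = np.array([1.3, 1.0, 0.77]) * pat_k
        else:
            radii = np.full(3, extents[name])
        # compute only inside the compartment's bounding box
        sl = []
        for axis_vals, c, r in ((ax_x, cx, radii[0]), (ax_y, yc, radii[1]),
                                (ax_z, zc, radii[2])):
            idx = np.flatnonzero(np.abs(axis_vals - c) <= r + spacing)
            sl.append(slice(int(idx[0]), int(idx[-1] + 1)) if len(idx)
                      else slice(0, 0))
        dx = (ax_x[sl[0]] - cx) / radii[0]
        dy = (ax_y[sl[1]] - yc) / radii[1]
        dz = (ax_z[sl[2]] - zc) / radii[2]
        sub = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
               + dz[None, None, :] ** 2) <= 1.0
        mask = np.zeros(shape, dtype=bool)
        mask[sl[0], sl[1], sl[2]] = sub
        if name in BONES:
            level = invert_bmd(cal, draws[f"{name}_bmd"])
        else:
            level = draws[f"{name}_density"]
        hu[mask] = level
        masks[name] = mask

    hu += noise_sd * rng.standard_normal(shape, dtype=np.float32)
    return LabeledVolume(hu, (spacing,) * 3, masks)


def generate_cohort(
    n_D: int,
    n_T: int,
    n_C: int,
    seed: int,
    archetypes: dict[str, GroupArchetype] | None = None,
    **subject_kwargs,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate a full cohort plus its ground-truth manifest.

    Reproducible: a fixed seed yields byte-identical manifests.  Default
    cohort structure is (24, 15, 8).
    """
    if min(n_D, n_T, n_C) < 0:
        raise ValueError("group sizes must be nonnegative")
    archetypes = archetypes or default_archetypes()
    root = np.random.SeedSequence(seed)
    subjects = []
    counts = {"D": n_D, "T": n_T, "C": n_C}
    idx = 0
    for group in GROUPS:
        for k in range(counts[group]):
            child_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            sid = f"{group}{k + 1:03d}"
            subjects.append(
                generate_subject(archetypes[group], child_seed, subject_id=sid,
                                 **subject_kwargs)
            )
            idx += 1
    manifest = pd.DataFrame([s.ground_truth for s in subjects])
    return subjects, manifest


def export_subject(subject: SyntheticSubject, directory: str | Path) -> None:
    """Write STL meshes and NIfTI volumes for one subject."""
    directory = Path(directory) / subject.subject_id
    directory.mkdir(parents=True, exist_ok=True)
    if subject.compartments:
        for name, comp in subject.compartments.items():
            write_stl(comp.closed_shell, directory / f"{name}_shell.stl")
            write_stl(comp.outer_patch, directory / f"{name}_patch.stl")
    if subject.volume is not None:
        subject.volume.to_nifti(directory)
    (directory / "ground_truth.json").write_text(
        json.dumps(subject.ground_truth, indent=2)
    )
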