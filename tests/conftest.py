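"""Shared fixtures: analytic meshes and small generated compartments.

Everything is generated programmatically; expensive fixtures are
session-scoped so the geometry oracles reuse them.
"""

import numpy as np
import pytest
import trimesh

from kneemorph.mesh_core import TriSurface
from kneemorph.synthetic_knee import (
    EllipseHole,
    ThinningPatch,
    generate_shell,
    make_slab,
    make_sphere_shell,
)


@pytest.fixture(scope="session")
def unit_cube() -> TriSurface:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriSurface(box.vertices, box.faces)


@pytest.fixture(scope="session")
def icosphere_r10() -> TriSurface:
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return TriSurface(ico.vertices, ico.faces)


@pytest.fixture(scope="session")
def icosphere_coarse() -> TriSurface:
    ico = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    return TriSurface(ico.vertices, ico.faces)


@pytest.fixture(scope="session")
def sphere_shell() -> TriSurface:
    """Uniform closed shell, outer radius 40 mm, thickness 2 mm."""
    return make_sphere_shell(40.0, 2.0, subdivisions=3)


@pytest.fixture(scope="session")
def slab_3p5() -> TriSurface:
    return make_slab(width=20.0, thickness=3.5, n=10)


@pytest.fixture(scope="session")
def plain_cap():
    """Spherical-cap shell, r = 40 mm, t = 2 mm, no holes, no patches."""
    return generate_shell(40.0, 2.0, refinement=2, seed=11)


@pytest.fixture(scope="session")
def holed_cap():
    """Cap shell with three non-overlapping elliptical through-holes."""
    holes = [
        EllipseHole((6.0, 4.0), 3.0, 3.0),
        EllipseHole((-13.0, -6.0), 4.0, 2.0, angle=0.7),
        EllipseHole((2.0, -15.0), 2.523, 2.523),
    ]
    return generate_shell(40.0, 2.0, holes=holes, refinement=2, seed=12)


@pytest.fixture(scope="session")
def patched_cap():
    """Cap shell with one thinning patch (t = 2 mm, depth 1 mm)."""
    return generate_shell(
        40.0, 2.0,
        thinning_patches=[ThinningPatch((5.0, -3.0), 9.0, 1.0)],
        refinement=2, seed=13,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
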