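"""Shared fixtures: small synthetic meshes and archetype parameters."""

import numpy as np
import pytest
import trimesh

from footform import synthetic
from footform.types import ARCHETYPES, SurfaceMesh


@pytest.fixture(scope="session")
def nf_params():
    return ARCHETYPES["NF"]


@pytest.fixture(scope="session")
def fb_params():
    return ARCHETYPES["FB"]


@pytest.fixture(scope="session")
def unit_cube_surface() -> SurfaceMesh:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    box.apply_translation([0.5, 0.5, 0.5])
    return SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces), "cube")


@pytest.fixture(scope="session")
def sphere_surface() -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces), "sphere")


@pytest.fixture(scope="session")
def small_bone() -> SurfaceMesh:
    """A single asymmetric bone-like surface (coarse, fast for registration).

    A smooth radial modulation breaks the superellipsoid's 180-degree flip
    symmetries so rigid registration has a unique optimum.
    """
    prim = synthetic.Superellipsoid(
        center=np.array([5.0, -3.0, 2.0]),
        radii=np.array([12.0, 7.0, 4.0]),
        exponent=2.6,
        rotation=np.eye(3),
    )
    mesh = prim.mesh(subdivisions=2, label="bone")
    v = mesh.vertices
    rel = v - prim.center
    bump = 1.0 + 0.12 * np.sin(0.4 * v[:, 0] + 1.0) * np.cos(
        0.3 * v[:, 1] - 0.5
    ) * np.sin(0.5 * v[:, 2] + 0.2)
    mesh.vertices = prim.center + rel * bump[:, None]
    return mesh


@pytest.fixture(scope="session")
def bar_mesh():
    """10 x 10 x 100 mm column on a regular lattice."""
    return synthetic.lattice_tet_mesh(
        np.zeros(3),
        np.array([10.0, 10.0, 100.0]),
        (2, 2, 20),
        lambda p: np.ones(len(p), bool),
    )


@pytest.fixture(scope="session")
def nf_foot_model(nf_params):
    """Coarse NF archetype FE model shared across FE/remodel tests."""
    return synthetic.generate_foot_model(nf_params, target_edge=9.0)
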