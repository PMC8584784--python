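import numpy as np
import pytest
import trimesh

from epifold.io import CellRecord
from epifold.synthetic import Fold, SurfaceSpec, generate_scene


@pytest.fixture(scope="session")
def flat_scene():
    """Noise-free flat monolayer: every ground-truth normal is (0, 0, 1)."""
    return generate_scene(
        SurfaceSpec(radius_of_curvature=None, extent=60.0, seed=11), render=False
    )


@pytest.fixture(scope="session")
def cap_scene():
    """Spherical-cap monolayer (radius of curvature 106 um)."""
    return generate_scene(
        SurfaceSpec(radius_of_curvature=106.0, extent=100.0, seed=12), render=False
    )


@pytest.fixture(scope="session")
def twofold_scene():
    """Curved sheet with two folds of opposing orientation."""
    spec = SurfaceSpec(
        radius_of_curvature=150.0,
        folds=(Fold((35.0, 35.0), 12.0, 10.0), Fold((65.0, 65.0), -12.0, 10.0)),
        extent=100.0,
        seed=13,
    )
    return generate_scene(spec, render=False)


@pytest.fixture(scope="session")
def sphere_points():
    """200 points quasi-uniform on a sphere of radius 50 um (Fibonacci)."""
    n = 200
    idx = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / n)
    theta = np.pi * (1.0 + 5.0**0.5) * idx
    return 50.0 * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_cell(label: int, mesh: trimesh.Trimesh) -> CellRecord:
    return CellRecord(
        label=label,
        centroid=np.asarray(mesh.vertices, float).mean(axis=0),
        voxel_count=1,
        surface_vertices=np.asarray(mesh.vertices, float),
        surface_faces=np.asarray(mesh.faces, np.int64),
    )


@pytest.fixture(scope="session")
def extreme_cells():
    """Three cells with extreme, mutually distinct shape signatures:
    columnar (tall box, zero skew), small apically-constricted cell (cone,
    apex apical, positive skew) and a larger basally-constricted cell
    (inverted cone, negative skew); all three differ in longitudinal spread,
    transversal spread and skewness simultaneously."""
    up = np.array([0.0, 0.0, 1.0])
    col = trimesh.creation.box((4.0, 4.0, 14.0))
    apical = trimesh.creation.cone(radius=6.0, height=12.0, sections=32)
    basal = trimesh.creation.cone(radius=9.0, height=18.0, sections=32)
    basal.apply_transform(trimesh.transformations.rotation_matrix(np.pi, (1, 0, 0)))
    return [(make_cell(1, col), up), (make_cell(2, apical), up), (make_cell(3, basal), up)]
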