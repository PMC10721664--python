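"""Shared fixtures: programmatically generated meshes and maps."""

from __future__ import annotations

import numpy as np
import pytest

from crtsync.geometry import LV, RV, ActivationMap, TriSurfaceMesh
from crtsync.synthetic import make_biv_shell_mesh


@pytest.fixture(scope="session")
def shell_mesh() -> TriSurfaceMesh:
    """Ellipsoidal biventricular shell, 320 triangles."""
    return make_biv_shell_mesh(2)


@pytest.fixture(scope="session")
def fine_mesh() -> TriSurfaceMesh:
    """Finer shell (1280 triangles) for granularity-sensitive checks."""
    return make_biv_shell_mesh(3)


def chain_mesh_with_times(times, labels) -> tuple[TriSurfaceMesh, ActivationMap]:
    """Build a chain of equal-area triangles with exact per-triangle times.

    Triangle k is (spine_k, spine_{k+1}, apex_k); spine vertices all carry
    time 0 and apex k carries 3·t_k, so the mean vertex time of triangle k
    is exactly t_k.  Consecutive triangles share one spine vertex, keeping
    the edge-graph connected.  All triangles have base 1 and height 1
    (area 0.5), so area and vertex-count weighting coincide.
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    assert n == len(labels)
    spine = np.column_stack([np.arange(n + 1), np.zeros(n + 1), np.zeros(n + 1)])
    apex = np.column_stack([np.arange(n) + 0.5, np.ones(n), np.zeros(n)])
    vertices = np.vstack([spine, apex])
    triangles = np.array([[k, k + 1, n + 1 + k] for k in range(n)])
    mesh = TriSurfaceMesh(
        vertices=vertices, triangles=triangles, chamber_label=np.array(labels, object)
    )
    vertex_time = np.concatenate([np.zeros(n + 1), 3.0 * times])
    return mesh, ActivationMap(mesh=mesh, vertex_time=vertex_time)


@pytest.fixture()
def strip_map():
    """Three equal-area triangles (LV at 10 and 20 ms, RV at 15 ms)."""
    return chain_mesh_with_times([10.0, 20.0, 15.0], [LV, LV, RV])


def random_sphere_mesh(rng: np.random.Generator, n_vertices: int = 500) -> TriSurfaceMesh:
    """Random triangulated sphere: convex hull of random unit vectors."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n_vertices, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= 40.0
    hull = ConvexHull(pts)
    tris = hull.simplices
    centroids = pts[tris].mean(axis=1)
    labels = np.where(centroids[:, 0] > np.median(centroids[:, 0]), LV, RV).astype(object)
    return TriSurfaceMesh(vertices=pts, triangles=tris, chamber_label=labels)
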