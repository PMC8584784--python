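"""Independent numeric oracles used by the tests.

These deliberately avoid the code paths they check: moments are integrated
by brute-force column quadrature over half-space representations, never by
the facet-sum engine.
"""

import numpy as np
from scipy.spatial import ConvexHull

from epifold.moments import moment_orders


def column_moments(points: np.ndarray, centroid: np.ndarray, n: int = 256) -> dict:
    """Dense numeric moments of the convex hull of ``points``.

    Midpoint quadrature on an n x n grid in (x, y) with the z-integral of
    z^k carried out exactly between the hull's lower and upper facets."""
    hull = ConvexHull(points)
    A = hull.equations[:, :3]
    b = hull.equations[:, 3]
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    xs = lo[0] + (np.arange(n) + 0.5) * (hi[0] - lo[0]) / n
    ys = lo[1] + (np.arange(n) + 0.5) * (hi[1] - lo[1]) / n
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    X = X.ravel()
    Y = Y.ravel()
    zlo = np.full(X.shape, lo[2] - 1.0)
    zhi = np.full(X.shape, hi[2] + 1.0)
    ok = np.ones(X.shape, bool)
    for (ax, ay, az), bb in zip(A, b):
        rhs = -(bb + ax * X + ay * Y)
        if az > 1e-12:
            zhi = np.minimum(zhi, rhs / az)
        elif az < -1e-12:
            zlo = np.maximum(zlo, rhs / az)
        else:
            ok &= (ax * X + ay * Y + bb) <= 0
    ok &= zhi > zlo
    Xc = X[ok] - centroid[0]
    Yc = Y[ok] - centroid[1]
    zl = zlo[ok] - centroid[2]
    zh = zhi[ok] - centroid[2]
    dA = (hi[0] - lo[0]) * (hi[1] - lo[1]) / n / n
    out = {}
    for (i, j, k) in moment_orders(3):
        out[(i, j, k)] = float(
            np.sum(Xc**i * Yc**j * (zh ** (k + 1) - zl ** (k + 1)) / (k + 1))
        ) * dA
    return out


def monte_carlo_tetra(v1, v2, v3, i, j, k, n=400_000, seed=0) -> float:
    """Monte-Carlo estimate of the signed monomial integral over (0,v1,v2,v3)."""
    rng = np.random.default_rng(seed)
    # uniform barycentric sampling of the standard simplex
    e = -np.log(rng.random((n, 4)))
    bary = e[:, :3] / e.sum(axis=1, keepdims=True)
    pts = bary @ np.vstack([v1, v2, v3])
    det = float(np.linalg.det(np.column_stack([v1, v2, v3])))
    vol = det / 6.0
    return vol * float(np.mean(pts[:, 0] ** i * pts[:, 1] ** j * pts[:, 2] ** k))


def check_mesh_consistency(mesh) -> None:
    """Assert manifoldness and globally consistent winding of a SheetMesh."""
    directed = {}
    for face in mesh.faces:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            e = (int(face[a]), int(face[b]))
            directed[e] = directed.get(e, 0) + 1
    for (a, b), cnt in directed.items():
        assert cnt == 1, f"directed edge {(a, b)} used {cnt} times (non-manifold/fold)"
        assert directed.get((b, a), 0) <= 1
    # every interior edge traversed once in each direction
    uniq, counts = mesh.edge_face_counts()
    for (a, b), c in zip(uniq, counts):
        assert c <= 2
        if c == 2:
            assert directed.get((int(a), int(b)), 0) == 1
            assert directed.get((int(b), int(a)), 0) == 1
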