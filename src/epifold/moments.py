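"""Exact 3D geometric moments of closed triangle meshes and derived shape features.

A solid bounded by a closed, consistently outward-oriented triangle mesh is
decomposed into signed tetrahedra, one per facet, each spanned by a surface
triangle and the coordinate origin.  The monomial integral over every
tetrahedron has a closed form (map to the standard simplex, expand the
monomial multinomially in barycentric coordinates, apply the Dirichlet
integral ``a! b! c! / (a+b+c+3)!``), so every moment

    G_ijk = sum_c sign(Vol_c) * integral over T_c of x^i y^j z^k

is computed exactly, with no rasterization error, for shapes of arbitrary
topology.  With the origin at the volumetric centroid the G_ijk are central
moments: G000 is the volume, first-order moments vanish, second order is the
spread (covariance) tensor, third order the skew of the mass distribution.

Direction-variant features (longitudinal/transversal spread, skewness) are
read off after re-expressing the moments in an orthonormal frame whose third
axis is the cell's apico-basal polarity vector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MomentSet",
    "ShapeFeatures",
    "tetra_monomial_integral",
    "compute_moments",
    "rotate_moments",
    "shape_features",
    "surface_area",
    "moment_orders",
]


def moment_orders(max_order: int = 3) -> list[tuple[int, int, int]]:
    """All exponent triples (i, j, k) with i + j + k <= max_order, sorted."""
    return [
        (i, j, k)
        for total in range(max_order + 1)
        for i in range(total, -1, -1)
        for j in range(total - i, -1, -1)
        for k in (total - i - j,)
    ]


def _compositions(n: int):
    """Triples (p1, p2, p3) of non-negative integers summing to n."""
    for p1 in range(n + 1):
        for p2 in range(n - p1 + 1):
            yield p1, p2, n - p1 - p2


def _multinomial(n: int, p: tuple[int, int, int]) -> int:
    return math.factorial(n) // (
        math.factorial(p[0]) * math.factorial(p[1]) * math.factorial(p[2])
    )


def _term_table(i: int, j: int, k: int):
    """Expansion of x^i y^j z^k over a tetrahedron (0, v1, v2, v3).

    Substituting x = u*v1 + v*v2 + w*v3 (barycentric u, v, w on the standard
    simplex) and expanding multinomially gives a sum of terms

        coef * x1^p1 x2^p2 x3^p3 * y1^q1 ... * z3^r3 * D(a, b, c)

    with D the Dirichlet integral and (a, b, c) the collected barycentric
    powers.  Returns a list of (coef*D, (p1,p2,p3), (q1,q2,q3), (r1,r2,r3)).
    """
    terms = []
    for p in _compositions(i):
        cp = _multinomial(i, p)
        for q in _compositions(j):
            cq = _multinomial(j, q)
            for r in _compositions(k):
                cr = _multinomial(k, r)
                a, b, c = (p[0] + q[0] + r[0], p[1] + q[1] + r[1], p[2] + q[2] + r[2])
                dirichlet = (
                    math.factorial(a) * math.factorial(b) * math.factorial(c)
                ) / math.factorial(a + b + c + 3)
                terms.append((cp * cq * cr * dirichlet, p, q, r))
    return terms


_TERM_CACHE: dict[tuple[int, int, int], list] = {}


def _terms(i: int, j: int, k: int):
    key = (i, j, k)
    if key not in _TERM_CACHE:
        _TERM_CACHE[key] = _term_table(i, j, k)
    return _TERM_CACHE[key]


def tetra_monomial_integral(v1, v2, v3, i: int, j: int, k: int) -> float:
    """Signed integral of x^i y^j z^k over the tetrahedron (0, v1, v2, v3).

    Carries the sign of det[v1 v2 v3] / 6 (the oriented tetrahedron volume),
    so swapping two vertices negates the result and degenerate tetrahedra
    return exactly 0.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    v3 = np.asarray(v3, dtype=float)
    det = float(np.linalg.det(np.column_stack([v1, v2, v3])))
    if det == 0.0:
        return 0.0
    acc = 0.0
    for coef, p, q, r in _terms(i, j, k):
        acc += (
            coef
            * v1[0] ** p[0] * v2[0] ** p[1] * v3[0] ** p[2]
            * v1[1] ** q[0] * v2[1] ** q[1] * v3[1] ** q[2]
            * v1[2] ** r[0] * v2[2] ** r[1] * v3[2] ** r[2]
        )
    return det * acc


def _mesh_moments(vertices: np.ndarray, faces: np.ndarray, orders) -> dict:
    """Vectorised facet-sum of the tetra monomial integrals for each order."""
    v1 = vertices[faces[:, 0]]
    v2 = vertices[faces[:, 1]]
    v3 = vertices[faces[:, 2]]
    # det[v1 v2 v3] per face, columns = vertices
    det = (
        v1[:, 0] * (v2[:, 1] * v3[:, 2] - v2[:, 2] * v3[:, 1])
        - v2[:, 0] * (v1[:, 1] * v3[:, 2] - v1[:, 2] * v3[:, 1])
        + v3[:, 0] * (v1[:, 1] * v2[:, 2] - v1[:, 2] * v2[:, 1])
    )
    out = {}
    for (i, j, k) in orders:
        acc = np.zeros(len(faces))
        for coef, p, q, r in _terms(i, j, k):
            acc += (
                coef
                * v1[:, 0] ** p[0] * v2[:, 0] ** p[1] * v3[:, 0] ** p[2]
                * v1[:, 1] ** q[0] * v2[:, 1] ** q[1] * v3[:, 1] ** q[2]
                * v1[:, 2] ** r[0] * v2[:, 2] ** r[1] * v3[:, 2] ** r[2]
            )
        out[(i, j, k)] = float(np.sum(det * acc))
    return out


@dataclass
class MomentSet:
    """Central geometric moments G_ijk (i + j + k <= max order) of one cell.

    Units are um^(3 + i + j + k).  ``origin`` is the volumetric centroid the
    moments are taken about, in the image frame.  ``frame`` is 'image' or
    'polarity-aligned'.
    """

    values: dict = field(default_factory=dict)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: str = "image"

    def __getitem__(self, ijk: tuple[int, int, int]) -> float:
        return self.values[ijk]

    @property
    def volume(self) -> float:
        return self.values[(0, 0, 0)]

    def order(self) -> int:
        return max(sum(k) for k in self.values)


class MomentError(ValueError):
    """Raised for open or inverted surfaces."""


def compute_moments(
    vertices: np.ndarray,
    faces: np.ndarray,
    origin: np.ndarray | None = None,
    max_order: int = 3,
) -> MomentSet:
    """Exact central moments of the solid bounded by a closed oriented mesh.

    The origin is placed at the volumetric centroid: moments are computed
    about the provisional ``origin`` (default: vertex mean), the true centroid
    is read from the first-order moments, and one re-centering pass makes the
    first-order central moments vanish to machine precision.

    Raises :class:`MomentError` if the mesh is open (some edge not shared by
    exactly two faces) or encloses non-positive volume (inward winding).
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise MomentError("mesh is not closed: every edge must bound exactly 2 faces")

    provisional = np.asarray(origin, dtype=float) if origin is not None else vertices.mean(axis=0)
    orders = moment_orders(max_order)

    first = _mesh_moments(vertices - provisional, faces, moment_orders(1))
    vol = first[(0, 0, 0)]
    if vol <= 0:
        raise MomentError(f"non-positive enclosed volume ({vol:.3g}): check face orientation")
    centroid = provisional + np.array(
        [first[(1, 0, 0)], first[(0, 1, 0)], first[(0, 0, 1)]]
    ) / vol
    values = _mesh_moments(vertices - centroid, faces, orders)
    return MomentSet(values=values, origin=centroid, frame="image")


def polarity_frame(normal: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal frame (rows) with third axis = ``normal``.

    The first axis is the Gram-Schmidt completion of the canonical axis with
    the smallest |component| along the normal; the second closes a
    right-handed triad.
    """
    n = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("polarity vector must be unit-norm")
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(n)))] = 1.0
    t1 = seed - np.dot(seed, n) * n
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return np.vstack([t1, t2, n])


def rotate_moments(m: MomentSet, normal: np.ndarray) -> MomentSet:
    """Express moments in the polarity-aligned frame (third axis = ``normal``).

    Uses the tensor transformation law: with new coordinates x' = Q x
    (Q rows = frame axes), each G'_ijk is a polynomial in the image-frame
    moments of the same total order, obtained by expanding
    (Q1.x)^i (Q2.x)^j (Q3.x)^k multinomially.  Exact, so it agrees with
    recomputing moments on rotated vertices to machine precision.
    """
    Q = polarity_frame(normal)
    out: dict = {}
    for (i, j, k) in m.values:
        acc = 0.0
        for p in _compositions(i):
            cp = _multinomial(i, p) * Q[0, 0] ** p[0] * Q[0, 1] ** p[1] * Q[0, 2] ** p[2]
            if cp == 0.0:
                continue
            for q in _compositions(j):
                cq = _multinomial(j, q) * Q[1, 0] ** q[0] * Q[1, 1] ** q[1] * Q[1, 2] ** q[2]
                if cq == 0.0:
                    continue
                for r in _compositions(k):
                    cr = (
                        _multinomial(k, r)
                        * Q[2, 0] ** r[0] * Q[2, 1] ** r[1] * Q[2, 2] ** r[2]
                    )
                    if cr == 0.0:
                        continue
                    src = (p[0] + q[0] + r[0], p[1] + q[1] + r[1], p[2] + q[2] + r[2])
                    acc += cp * cq * cr * m.values[src]
        out[(i, j, k)] = acc
    return MomentSet(values=out, origin=m.origin.copy(), frame="polarity-aligned")


def surface_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Total triangle area of the mesh, in um^2."""
    v = np.asarray(vertices, dtype=float)
    a = v[faces[:, 1]] - v[faces[:, 0]]
    b = v[faces[:, 2]] - v[faces[:, 0]]
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


@dataclass
class ShapeFeatures:
    """Single-cell shape descriptors in the polarity-aligned frame.

    volume um^3; surface_area um^2; sphericity in (0, 1], 1 for a sphere
    (area of the volume-equivalent sphere over the actual area);
    longitudinal_spread = variance of mass along the apico-basal axis (um^2);
    transversal_spread = mean in-plane variance (um^2), with the two in-plane
    components also reported; skewness = standardized third moment along the
    apico-basal axis, positive for apical constriction / basal relaxation.
    """

    volume: float
    surface_area: float
    sphericity: float
    longitudinal_spread: float
    transversal_spread: float
    skewness: float
    transversal_components: tuple[float, float] = (0.0, 0.0)
    raw_skewness: float = 0.0
    flags: tuple[str, ...] = ()


def shape_features(m_aligned: MomentSet, area: float) -> ShapeFeatures:
    """Derive shape features from polarity-aligned central moments.

    ``m_aligned`` must be in the polarity-aligned frame (z = apico-basal
    axis) with origin at the cell centroid; ``area`` is the cell's own
    triangulated surface area.
    """
    g = m_aligned.values
    vol = g[(0, 0, 0)]
    if vol <= 0:
        raise MomentError("non-positive volume: inward-wound surface")
    lon = g[(0, 0, 2)] / vol
    tra_x = g[(2, 0, 0)] / vol
    tra_y = g[(0, 2, 0)] / vol
    flags: list[str] = []
    if lon > 0:
        skew = (g[(0, 0, 3)] / vol) / lon ** 1.5
    else:
        skew = 0.0
        flags.append("zero-longitudinal-spread")
    sphericity = math.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area
    return ShapeFeatures(
        volume=vol,
        surface_area=area,
        sphericity=sphericity,
        longitudinal_spread=lon,
        transversal_spread=0.5 * (tra_x + tra_y),
        skewness=skew,
        transversal_components=(tra_x, tra_y),
        raw_skewness=g[(0, 0, 3)],
        flags=tuple(flags),
    )


def cell_shape_features(
    vertices: np.ndarray, faces: np.ndarray, normal: np.ndarray, max_order: int = 3
) -> tuple[ShapeFeatures, MomentSet, MomentSet]:
    """Convenience: moments in both frames + features for one cell surface."""
    m = compute_moments(vertices, faces, max_order=max_order)
    m_aligned = rotate_moments(m, normal)
    feats = shape_features(m_aligned, surface_area(vertices, faces))
    return feats, m, m_aligned
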