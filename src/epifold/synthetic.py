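"""Synthetic folding-epithelium scenes with analytic ground truth.

The generator emulates the validation inputs: a curved epithelial monolayer
— a spherical-cap base of a chosen radius of curvature (106–200 um in the
study conditions) with superimposed Gaussian folds whose peak heights carry
a sign encoding the two opposing fold orientations — populated with a
quasi-uniform layer of prism-like cells, rasterized to a ground-truth label
volume, and rendered as a bright-membrane fluorescence image blurred with an
anisotropic PSF and corrupted with three incremental levels of Gaussian and
Poisson noise.  Because the surface is an explicit smooth function, every
cell carries an exact analytic unit normal as polarity ground truth.

Geometry is a height field z = f(x, y) over a square extent: the lateral
voxel pitch is 0.2 um (a 200 um radius of curvature spans 1000 px), the
axial pitch 1.0 um, reproducing typical light-sheet anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from epifold.io import LabelVolume

__all__ = [
    "Fold",
    "SurfaceSpec",
    "SyntheticScene",
    "GenerationError",
    "build_surface",
    "tessellate_cells",
    "render_membranes",
    "generate_scene",
]


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class Fold:
    """One Gaussian fold: center in the (x, y) plane, signed peak height
    (the sign is the fold orientation), and 1-sigma width, all in um."""

    center: tuple[float, float]
    peak_height: float
    width: float


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of one synthetic epithelium.

    radius_of_curvature: global sheet curvature in um (None = flat);
    folds: Gaussian bumps, peak height signed by orientation;
    extent: side length of the square (x, y) domain, um;
    cell_density: cells per um^2 of sheet;
    cell_height: apico-basal thickness of the monolayer, um.

    The extent should be comparable to the radius of curvature (default
    100 um for radii of 106-200 um): the lumen side of the sheet is defined
    by its global curvature, which must dominate the local folds over the
    field of view, as it does in a real vesicle.
    """

    radius_of_curvature: float | None = 150.0
    folds: tuple[Fold, ...] = ()
    extent: float = 100.0
    cell_density: float = 0.04
    cell_height: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.radius_of_curvature is not None and self.radius_of_curvature <= 0:
            raise GenerationError("radius_of_curvature must be > 0 or None (flat)")
        if any(f.width <= 0 for f in self.folds):
            raise GenerationError("fold widths must be > 0")
        if self.cell_density <= 0 or self.cell_height <= 0 or self.extent <= 0:
            raise GenerationError("density, cell height and extent must be > 0")


@dataclass
class SyntheticScene:
    """A generated scene: image + ground-truth labels + analytic normals."""

    membrane_image: np.ndarray | None
    label_volume: LabelVolume
    gt_normals: dict  # label -> unit 3-vector, oriented away from the curvature centre
    seeds: np.ndarray  # label order: seeds[i] belongs to label i+1, in um
    noise_level: int
    psf_sigma: tuple[float, float, float]
    params: SurfaceSpec


def build_surface(spec: SurfaceSpec):
    """Analytic height/normal functions of the sheet mid-surface.

    Returns ``(height, normal)``: ``height(x, y)`` in um and ``normal(x, y)``
    — the exact unit 'up' normal (away from the centre of curvature;
    (0, 0, 1) for a flat sheet), both vectorised over arrays.

    The surface is z = cap(rho) + sum_m h_m exp(-rho_m^2 / (2 w_m^2)) with
    cap(rho) = sqrt(R^2 - rho^2) - R (apex at the domain centre, sphere
    centre at (cx, cy, -R)).  Folds whose combined curvature would make the
    extruded monolayer self-intersect (bend radius < cell_height / 2) raise
    :class:`GenerationError`.
    """
    R = spec.radius_of_curvature
    cx = cy = spec.extent / 2.0
    half_diag = spec.extent / np.sqrt(2.0)
    if R is not None and R <= half_diag:
        raise GenerationError("radius of curvature too small for the extent")

    # injectivity of the extruded shell: max |curvature| of a 1D Gaussian of
    # amplitude h, width w is h / w^2 (at the peak); another fold's bending
    # only reaches ~3 of *its* widths, beyond that it adds nothing.
    max_curv = 0.0
    for f in spec.folds:
        c = abs(f.peak_height) / f.width**2
        for g in spec.folds:
            if g is f:
                continue
            dist = np.hypot(f.center[0] - g.center[0], f.center[1] - g.center[1])
            if dist < 3.0 * g.width:
                c += abs(g.peak_height) / g.width**2
        max_curv = max(max_curv, c)
    if R is not None:
        max_curv += 1.0 / R
    if max_curv * spec.cell_height / 2.0 >= 1.0:
        raise GenerationError(
            "fold curvature breaks injectivity of the extruded monolayer "
            f"(bend radius {1.0 / max_curv:.2f} um < cell_height/2)"
        )

    def height(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(np.broadcast(x, y).shape)
        if R is not None:
            z = z + np.sqrt(R**2 - (x - cx) ** 2 - (y - cy) ** 2) - R
        for f in spec.folds:
            rho2 = (x - f.center[0]) ** 2 + (y - f.center[1]) ** 2
            z = z + f.peak_height * np.exp(-rho2 / (2.0 * f.width**2))
        return z

    def gradient(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shape = np.broadcast(x, y).shape
        gx = np.zeros(shape)
        gy = np.zeros(shape)
        if R is not None:
            root = np.sqrt(R**2 - (x - cx) ** 2 - (y - cy) ** 2)
            gx = gx - (x - cx) / root
            gy = gy - (y - cy) / root
        for f in spec.folds:
            dx = x - f.center[0]
            dy = y - f.center[1]
            g = f.peak_height * np.exp(-(dx**2 + dy**2) / (2.0 * f.width**2)) / f.width**2
            gx = gx - g * dx
            gy = gy - g * dy
        return gx, gy

    def normal(x, y):
        gx, gy = gradient(x, y)
        n = np.stack([-gx, -gy, np.ones_like(gx)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    height.gradient = gradient  # exposed for shell-thickness rasterization
    return height, normal


def _poisson_disk(spec: SurfaceSpec, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform (x, y) seed layout by seeded dart throwing."""
    target = max(int(round(spec.cell_density * spec.extent**2)), 4)
    r_min = 0.75 / np.sqrt(spec.cell_density)
    margin = 0.5 * r_min
    lo, hi = margin, spec.extent - margin
    seeds: list[np.ndarray] = []
    attempts = 0
    while len(seeds) < target and attempts < 200 * target:
        p = rng.uniform(lo, hi, size=2)
        attempts += 1
        if all(np.hypot(*(p - q)) >= r_min for q in seeds):
            seeds.append(p)
    return np.asarray(seeds)


def tessellate_cells(
    spec: SurfaceSpec,
    lateral_pitch: float = 0.2,
    axial_pitch: float = 1.0,
) -> tuple[LabelVolume, dict, np.ndarray]:
    """Rasterize the monolayer to a ground-truth label volume.

    Seeds are sampled quasi-uniformly on the surface (Poisson disk, seeded
    RNG); the sheet shell — points within cell_height/2 of the surface along
    its local normal — is partitioned into cells by nearest seed in 3D,
    approximating prisms extruded along the normal.  The volume is sampled
    at ``lateral_pitch`` um in x/y (0.2 um default: radius 200 um <-> 1000
    px) and ``axial_pitch`` um in z.  Returns (labels, gt_normals, seeds);
    gt_normals[label] is the analytic 'up' unit normal at the seed.
    """
    rng = np.random.default_rng(spec.seed)
    height, normal = build_surface(spec)
    r_min = 0.75 / np.sqrt(spec.cell_density)
    if r_min / lateral_pitch < 3.0:
        raise GenerationError(
            f"cell density too high for voxel size: cells ~{r_min / lateral_pitch:.1f} voxels wide"
        )
    seeds_uv = _poisson_disk(spec, rng)
    seeds_z = height(seeds_uv[:, 0], seeds_uv[:, 1])
    seeds = np.column_stack([seeds_uv, seeds_z])  # (x, y, z) um

    nx = ny = int(np.ceil(spec.extent / lateral_pitch))
    xs = (np.arange(nx) + 0.5) * lateral_pitch
    ys = (np.arange(ny) + 0.5) * lateral_pitch
    X, Y = np.meshgrid(xs, ys, indexing="xy")  # (ny, nx)
    Z_surf = height(X, Y)
    gx, gy = height.gradient(X, Y)
    # normal-distance shell: |z - z_surf| * cos(theta) <= h/2
    half_thick = 0.5 * spec.cell_height * np.sqrt(1.0 + gx**2 + gy**2)

    zmin = float(Z_surf.min() - half_thick.max() - axial_pitch)
    zmax = float(Z_surf.max() + half_thick.max() + axial_pitch)
    nz = int(np.ceil((zmax - zmin) / axial_pitch)) + 1
    z0 = zmin  # physical z of the volume origin
    zs = z0 + (np.arange(nz) + 0.5) * axial_pitch

    labels = np.zeros((nz, ny, nx), dtype=np.uint16)
    tree = cKDTree(seeds)
    for kz, z in enumerate(zs):
        inside = np.abs(z - Z_surf) <= half_thick
        if not inside.any():
            continue
        jj, ii = np.nonzero(inside)  # (y, x) indices
        pts = np.column_stack([xs[ii], ys[jj], np.full(len(ii), z)])
        _, idx = tree.query(pts, workers=-1)
        labels[kz, jj, ii] = (idx + 1).astype(np.uint16)

    # cells thinner than 3 voxels in any surviving label are debris of the
    # shell clip at the domain edge; they are left in and filtered by
    # min_voxels downstream.
    nvec = normal(seeds_uv[:, 0], seeds_uv[:, 1])
    gt_normals = {i + 1: nvec[i] for i in range(len(seeds))}
    vol = LabelVolume(
        voxels=labels, spacing=(axial_pitch, lateral_pitch, lateral_pitch)
    )
    # seeds are reported in the volume's own physical frame (z measured from
    # the volume floor), matching the (x, y, z) centroids of extract_cells
    seeds_vol = seeds.copy()
    seeds_vol[:, 2] -= z0
    return vol, gt_normals, seeds_vol


# photon budgets and additive-noise fractions for the three incremental
# noise levels (level 0 = PSF blur only); free parameters of the harness.
_PHOTON_BUDGET = {1: 5000.0, 2: 1000.0, 3: 200.0}
_GAUSS_FRACTION = {1: 0.02, 2: 0.05, 3: 0.10}


def render_membranes(
    labels: LabelVolume,
    psf_sigma: tuple[float, float, float] = (1.0, 0.25, 0.25),
    noise_level: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Render a blurred, noisy membrane (boundary) image of a label volume.

    Membranes are all voxels adjacent to a differing label (cell-cell and
    cell-background interfaces), blurred with an anisotropic Gaussian PSF
    (sigma in um, (z, y, x), sigma_z > sigma_xy emulating light-sheet
    anisotropy).  Noise levels 1-3 apply Poisson resampling at decreasing
    photon budgets (5000/1000/200 photons at the brightest voxel) plus
    additive Gaussian read noise of increasing sigma (2/5/10% of the
    membrane peak); level 0 is blur only.  Fully deterministic given seed.
    """
    if noise_level not in (0, 1, 2, 3):
        raise ValueError("noise_level must be 0, 1, 2 or 3")
    lab = labels.voxels
    membrane = np.zeros(lab.shape, dtype=bool)
    for ax in range(3):
        a = np.diff(lab, axis=ax) != 0
        fg = (np.take(lab, range(0, lab.shape[ax] - 1), axis=ax) > 0) | (
            np.take(lab, range(1, lab.shape[ax]), axis=ax) > 0
        )
        b = a & fg
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, lab.shape[ax] - 1)
        sl_hi[ax] = slice(1, lab.shape[ax])
        membrane[tuple(sl_lo)] |= b
        membrane[tuple(sl_hi)] |= b
    img = membrane.astype(np.float32)
    if psf_sigma is not None and any(s > 0 for s in psf_sigma):
        sigma_vox = [s / d for s, d in zip(psf_sigma, labels.spacing)]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if noise_level == 0:
        return img
    rng = np.random.default_rng(seed)
    peak = float(img.max())
    if peak <= 0:
        return img
    budget = _PHOTON_BUDGET[noise_level]
    if budget <= 0:
        raise ValueError("photon budget must be positive")
    img = rng.poisson(img / peak * budget).astype(np.float32) / budget * peak
    img = img + rng.normal(0.0, _GAUSS_FRACTION[noise_level] * peak, size=img.shape).astype(
        np.float32
    )
    return img


def generate_scene(
    spec: SurfaceSpec,
    noise_level: int = 0,
    psf_sigma: tuple[float, float, float] = (1.0, 0.25, 0.25),
    lateral_pitch: float = 0.2,
    axial_pitch: float = 1.0,
    render: bool = True,
) -> SyntheticScene:
    """Full scene: tessellated ground-truth labels + optional rendered image."""
    vol, gt_normals, seeds = tessellate_cells(
        spec, lateral_pitch=lateral_pitch, axial_pitch=axial_pitch
    )
    img = (
        render_membranes(vol, psf_sigma=psf_sigma, noise_level=noise_level, seed=spec.seed)
        if render
        else None
    )
    return SyntheticScene(
        membrane_image=img,
        label_volume=vol,
        gt_normals=gt_normals,
        seeds=seeds,
        noise_level=noise_level,
        psf_sigma=tuple(psf_sigma),
        params=spec,
    )
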