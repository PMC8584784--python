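# Methods

## Coordinate convention

A label volume is indexed (z, y, x) with spacing (dz, dy, dx) in μm; voxel
(k, j, i) is centred at ((i+0.5)·dx, (j+0.5)·dy, (k+0.5)·dz) and all
geometry — centroids, meshes, moments, polarity vectors — lives in physical
(x, y, z) μm coordinates. Anisotropy is therefore absorbed before any mesh
or moment is computed. Cell surfaces are level-0.5 marching-cubes
isosurfaces of the padded per-label binary mask (padding closes cells that
touch the volume border); any closed, consistently oriented triangulation
is equivalent for the exact moment engine. Cells below `min_voxels`
(default 20) are treated as segmentation debris and dropped.

## Sheet reconstruction

The epithelium is reconstructed from the unorganized cell centroids with a
one-pass Crust: Voronoi poles of every sample are added to the point set,
the Delaunay tetrahedralization of samples ∪ poles is computed, and every
triangle whose three vertices are all samples is kept. For samples on the
convex hull (whose Voronoi cells are unbounded) the outer pole is placed
along the mean outward hull-facet normal. Near-coplanar inputs
(third/first singular value < 2%) use the 2D Delaunay triangulation in the
best-fit plane, which is the flat-sheet limit of the Crust.

Crust output on noisy, anisotropically quantized centroids is a triangle
*soup* around the true sheet, so refinement matters more than the candidate
generation:

1. duplicate vertices/faces and degenerate faces are removed;
2. faces with an edge longer than 3× the median centroid nearest-neighbour
   distance are discarded (spurious bridges across the sheet);
3. self-intersecting face pairs are removed (Möller triangle–triangle test,
   KD-tree broad phase);
4. non-manifold edges are resolved by greedy manifold extraction: faces are
   re-admitted in order of increasing circumradius, rejecting any face that
   would give an edge a third incident face or fold back onto an accepted
   neighbour (opposite vertices of a shared edge projecting to within ~45°
   of each other in the plane normal to that edge);
5. the gaps this leaves are re-meshed by a local ball-pivoting pass (pivot
   radius 1.5× the median nearest-neighbour distance — scale-free), growing
   triangles from open boundary edges whenever the circumscribed ball is
   empty and the result stays manifold.

Remaining boundary loops are classified: the largest loop is the sheet's
outer rim if its length is at least √(total mesh area); every other loop is
a hole, filled with its minimal-area triangulation and reported as a
warning, with rim cells flagged `hole-adjacent`. Face winding is then made
globally consistent by breadth-first propagation from the lowest-index face
of each connected component (deterministic; multiple components warn).

Every step is deterministic: identical inputs give identical meshes and
vectors.

## Polarity

The per-cell apico-basal vector is the angle-weighted average of the face
normals incident to the cell's vertex; cells whose centroid did not survive
refinement inherit the nearest face normal and are flagged `no-vertex`.

Sign convention: with orientation mode `in` every vector points to the side
of its local tangent plane that contains a *global convergent point* c,
with `out` away from it. c is defined as the centre of the sheet's overall
curvature, estimated by a Huber-reweighted algebraic (Coope) sphere fit to
all centroids. We deliberately do **not** use the least-squares
intersection point of the normal lines: on a sheet containing a concave
fold, that fold's normal lines focus *above* the surface and drag the
intersection point to the wrong side (measured: 17% flipping on a
two-opposing-fold sheet, versus 0% with the sphere fit). The robust sphere
fit tracks the base curvature and ignores local folds, provided the field
of view is comparable to the radius of curvature — in a small window around
a deep fold the "lumen side" is genuinely ambiguous, for the tool as for a
human. Near-flat sheets (planarity < 2%, or fitted radius > 5× the sheet
diagonal) fall back to the sheet centroid displaced along the sign-fixed
mean normal, so `in`/`out` remain deterministic there too. Ties
((c − p)·n̂ = 0) keep the propagated orientation and flag the cell.

Swapping `in` ↔ `out` negates every vector and changes nothing else.
Pre-assigned vectors (CSV: label, nx, ny, nz) are normalized and used
verbatim; `--flip-cells` applies manual per-cell sign overrides, replacing
interactive visual flipping with a scriptable, logged equivalent.

## Exact moments and features

For a closed, outward-oriented triangle mesh the monomial integral over the
tetrahedron (0, v1, v2, v3) has the closed form det[v1 v2 v3] · Σ (multinomial
expansion in barycentric coordinates) · a!b!c!/(a+b+c+3)!, and the moment of
the enclosed solid is the signed facet sum — exact for any topology,
including non-convex and genus > 0 cells. The origin is placed at the
volumetric centroid with one re-centering pass, so first-order central
moments vanish to machine precision. Rotation into the polarity frame uses
the tensor transformation law (expanding (Q·x)^(i,j,k) in image-frame
moments), which agrees with recomputing moments on rotated vertices to
1e-9 relative — both routes are tested against each other.

Feature definitions and the choices behind them:

* **sphericity** = π^(1/3)(6V)^(2/3)/A: area of the volume-equivalent
  sphere over the actual area, so the range is (0, 1] with 1 for a sphere.
  (The inverse ratio is sometimes quoted; we keep the bounded convention.)
* **longitudinal spread** = G002/G000, **transversal spread** =
  (G200+G020)/(2·G000), variances in μm². Averaging the two in-plane axes
  makes the transversal value rotation-invariant about the polarity axis;
  both in-plane components are also emitted.
* **skewness** = (G003/G000)/(G002/G000)^{3/2}: standardized, hence
  scale-free and comparable across cells of different size; the raw G003 is
  emitted alongside. Positive = mass shifted basally = apical constriction.
  Whether to normalize is a genuine open choice; emitting both covers
  either convention.
* **surface area** is summed from the cell's own triangulation, not derived
  from moments.

## Synthetic validation scenes

The generator emulates the validation design: a spherical-cap base surface
(radius of curvature R; the study conditions span 106–200 μm) with
superimposed Gaussian folds z += h·exp(−ρ²/2w²) whose signed peak height h
encodes the two opposing fold orientations. The surface and its unit
normal field are analytic, giving exact per-cell ground truth. Default
geometry: extent 100 μm, fold width 10 μm, |h| = 12 μm, monolayer thickness
10 μm, 0.04 cells/μm² (≈ 5 μm cells, 400 per scene). The extent is chosen
comparable to R because the lumen side is *defined* by the global
curvature; it must dominate the folds over the field of view, as in a real
vesicle. Fold combinations whose bending radius drops below half the cell
height would self-intersect the monolayer and are rejected.

Cells are seeded by Poisson-disk sampling on the surface and rasterized as
a normal-thickness shell partitioned by nearest seed in 3D — equivalent to
normal-extruded prisms at the shallow slopes generated. Sampling: 0.2 μm/px
lateral (a 200 μm radius spans 1000 px), 1.0 μm axial, reproducing
light-sheet anisotropy. Membrane images are label-interface shells blurred
with an anisotropic Gaussian PSF (σ = 1.0, 0.25, 0.25 μm in z, y, x) and
corrupted at three incremental noise levels: Poisson resampling at photon
budgets 5000/1000/200 per peak voxel plus additive Gaussian read noise at
2/5/10% of peak (level 0 = blur only). The noise magnitudes are free
parameters of the harness, chosen to span comfortable-to-poor confocal
SNR; the generator is deterministic given its seed.

What the synthetic scenes do *not* emulate: real membrane-segmentation
failure modes (the images are rendered but segmentation is out of scope —
see below), cell packing irregularity beyond Poisson-disk, intensity
variation along membranes, curved cell side-walls. Passing the harness
shows the geometry pipeline is correct and noise-robust *given labels of
stated quality*; it does not certify any particular segmentation algorithm.

## Evaluation metrics and the degradation stand-in

* flipping error: % of matched cells with n̂_pred·n̂_gt < 0;
* direction deviation: arccos |n̂_pred·n̂_gt| (sign-corrected, i.e.
  flipping excluded; the raw signed variant is also available);
* Dice: labels matched greedily one-to-one by overlap; the
  overlap-weighted mean of per-pair Dice is reported along with a global
  foreground Dice, covering both common aggregation readings.

Since the upstream segmentation tool is external, segmentation quality is
emulated by controlled degradation of the ground-truth labels: boundary
corruption (voxels within a (1,3,3)-voxel band of any interface resampled
from a random in-band offset), cell merging (membrane loss) and per-cell
erosion. Severity s maps to (boundary s, merge 0.4s², erode 0.2s) in the
validation harness, which sweeps Dice from 1.0 to ≈0.6.

A robustness note: with ground-truth-derived centroids the pipeline's
flipping error stays at 0% down to Dice ≈ 0.6 — boundary noise hardly moves
centroids, and the convergent point is a global fit. Flipping in practice
comes from gross segmentation failures (lost/merged regions of the sheet),
so the degradation harness asserts the well-segmented bound (≤1.5% flipping
at Dice ≥ 0.8, met with margin) and tracks accuracy degradation through the
direction-deviation metric, which does rise with severity.

* sensitivity experiment: polarity vectors of three extreme-shaped cells
  (columnar box; small apically-constricted cone; large basally-constricted
  cone) are perturbed n = 50 times with von Mises–Fisher noise whose κ is
  solved numerically so the mean deviation angle equals the measured mean
  error (10.6°); features are recomputed per draw. vMF is the canonical
  spherical noise model; the distribution family is otherwise unspecified.

## Problem sizes

Scenes are 100×100 μm (500×500 px lateral, ~45 axial slices, ~400 cells);
the direction-accuracy grid is 3 radii × 2 fold orientations × 3 seeds and
the degradation experiment 2 radii × 2 orientations × 5 seeds, sizes chosen
so the whole validation reruns from scratch in minutes on one CPU while
every grid axis of the study design is still exercised. On ground-truth
labels the rendered noise level does not alter the pipeline input (noise
enters via segmentation, which is external), so grid runs are
noise-invariant by construction and rendering is skipped there.

## Known limitations

* The Crust + manifold-extraction route assumes the centroid spacing
  resolves the sheet's folds (fold width ≳ 2 cell diameters); sharper folds
  alias.
* One connected epithelium is assumed; disconnected patches are oriented
  independently (with a warning), and their relative `in`/`out` sense is
  only as good as the shared convergent point.
* Multi-component labels are flagged, not split.
* The `in`/`out` decision needs either global curvature or a user-supplied
  polarity; for a perfectly flat isolated sheet the apical side is chosen
  by a deterministic axis convention, not biology.
* Moments are computed for order ≤ 3 only; no intensity weighting.
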