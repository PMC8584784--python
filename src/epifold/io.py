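"""Reading segmented label volumes and extracting per-cell geometry.

The input is a 3D integer label image (0 = background) from an external
membrane-based segmentation, with anisotropic voxel spacing supplied by the
user.  All downstream geometry lives in physical micrometre coordinates:
voxel index (k, j, i) maps to ((k + 0.5) dz, (j + 0.5) dy, (i + 0.5) dx), so
anisotropy is absorbed before any mesh or moment is computed.  Physical
points and vectors are ordered (x, y, z).

For each label we extract the voxel-weighted centroid and a closed,
consistently outward-oriented triangulated surface (marching cubes on the
padded binary mask, so cells touching the volume border still close).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import trimesh
from scipy import ndimage
from skimage import measure

log = logging.getLogger(__name__)

__all__ = ["LabelVolume", "CellRecord", "read_label_volume", "extract_cells", "save_mesh"]


class FormatError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


@dataclass
class LabelVolume:
    """3D non-negative integer label image with physical voxel spacing.

    ``voxels`` is indexed (z, y, x); ``spacing`` is (dz, dy, dx) in um.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = "zyx"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"label volume must be 3D, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError(f"label volume must be integer-typed, got {self.voxels.dtype}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.voxels.size and self.voxels.min() < 0:
            raise FormatError("labels must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of non-background labels present."""
        u = np.unique(self.voxels)
        return u[u > 0]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class CellRecord:
    """One segmented cell: geometry in physical um coordinates.

    ``surface_vertices``/``surface_faces`` form a closed triangle mesh with
    outward-consistent winding, or are None for cells flagged 'open-surface'
    (excluded from moment computation) or when surfaces were not requested.
    """

    label: int
    centroid: np.ndarray  # (x, y, z) um
    voxel_count: int
    surface_vertices: np.ndarray | None = None
    surface_faces: np.ndarray | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def has_surface(self) -> bool:
        return self.surface_vertices is not None and "open-surface" not in self.flags


def read_label_volume(path, spacing) -> LabelVolume:
    """Read a multi-page TIFF stack (or directory of 2D TIFFs) of labels.

    Raises FormatError for non-integer pixel types and EmptyInputError when
    only background is present.
    """
    path = Path(path)
    if path.is_dir():
        pages = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not pages:
            raise FormatError(f"no TIFF files in directory {path}")
        data = np.stack([tifffile.imread(p) for p in pages])
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"expected integer label TIFF, got dtype {data.dtype}")
    vol = LabelVolume(voxels=data, spacing=tuple(spacing))
    n = len(vol.labels)
    if n == 0:
        raise EmptyInputError(f"{path}: label volume contains only background")
    log.info("read %s: shape %s, %d labels", path, data.shape, n)
    return vol


def _close_check(faces: np.ndarray) -> bool:
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def _cell_surface(mask: np.ndarray, spacing, offset_idx) -> tuple[np.ndarray, np.ndarray] | None:
    """Closed outward-oriented isosurface of one cell mask, in um.

    The mask is padded by one background voxel so border cells close; the
    level-0.5 marching-cubes surface then lies half a voxel outside the
    outermost voxel centers, matching the voxel-center coordinate convention.
    """
    padded = np.pad(mask, 1).astype(np.uint8)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    # padded index p maps to original index p-1, physical ((p-1+0.5) * d + offset)
    verts = verts + (np.asarray(offset_idx, float) - 0.5) * np.asarray(spacing)
    verts = verts[:, ::-1]  # (z, y, x) -> (x, y, z)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not _close_check(mesh.faces):
        return None
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.int64)


def extract_cells(
    vol: LabelVolume, min_voxels: int = 20, with_surfaces: bool = True
) -> list[CellRecord]:
    """One CellRecord per label with at least ``min_voxels`` voxels.

    The centroid is the mean of member voxel centers in physical um.  Cells
    below ``min_voxels`` (segmentation debris) are dropped and logged; labels
    whose mask yields a non-closed surface are flagged 'open-surface';
    multi-component labels are flagged 'multi-component' but not split;
    cells touching the volume border are flagged 'touches-border'.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    spacing = np.asarray(vol.spacing)
    labels = vol.labels
    if len(labels) == 0:
        raise EmptyInputError("label volume contains only background")
    lab_img = vol.voxels
    counts = ndimage.sum_labels(np.ones(lab_img.shape, np.int64), lab_img, labels)
    centers = ndimage.center_of_mass(np.ones(lab_img.shape), lab_img, labels)
    slices = {lab: sl for lab, sl in zip(*_find_objects(lab_img, labels))}

    records: list[CellRecord] = []
    n_dropped = 0
    for lab, cnt, com in zip(labels, counts, centers):
        cnt = int(cnt)
        if cnt < min_voxels:
            n_dropped += 1
            continue
        centroid = ((np.asarray(com) + 0.5) * spacing)[::-1]  # (x, y, z) um
        rec = CellRecord(label=int(lab), centroid=centroid, voxel_count=cnt)
        sl = slices[int(lab)]
        mask = lab_img[sl] == lab
        if any(s.start == 0 or s.stop == dim for s, dim in zip(sl, lab_img.shape)):
            rec.flags.add("touches-border")
        if ndimage.label(mask)[1] > 1:
            rec.flags.add("multi-component")
        if cnt < 8:
            rec.flags.add("tiny")
        if with_surfaces:
            offset = [s.start for s in sl]
            surf = _cell_surface(mask, vol.spacing, offset)
            if surf is None:
                rec.flags.add("open-surface")
                log.warning("label %d: non-closed isosurface, excluded from moments", lab)
            else:
                rec.surface_vertices, rec.surface_faces = surf
        records.append(rec)
    if n_dropped:
        log.info("dropped %d labels below min_voxels=%d", n_dropped, min_voxels)
    return records


def save_mesh(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    """Export a triangle mesh (cell surface or sheet) as OFF/PLY/STL by suffix."""
    trimesh.Trimesh(vertices=vertices, faces=faces, process=False).export(path)


def _find_objects(lab_img: np.ndarray, labels: np.ndarray):
    objs = ndimage.find_objects(lab_img)
    out_labels, out_slices = [], []
    for lab in labels:
        sl = objs[int(lab) - 1]
        if sl is not None:
            out_labels.append(int(lab))
            out_slices.append(sl)
    return out_labels, out_slices
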