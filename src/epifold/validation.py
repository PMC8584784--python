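"""Evaluation metrics for the polarity pipeline and segmentation quality.

Implements the validation measures used on synthetic epithelia:

* orientation-flipping error — the percentage of per-cell polarity vectors
  whose sign opposes the ground truth (the vector points basally instead of
  apically);
* direction accuracy — mean/std deviation angle between the correctly
  oriented (sign-corrected) vectors and the ground-truth normals;
* Dice score between a segmentation and the ground-truth labels;
* controlled label degradation (boundary-voxel corruption plus per-cell
  erosion/dilation), the stand-in segmentation-quality axis;
* the vector-perturbation sensitivity experiment: von Mises-Fisher
  directional noise of a prescribed mean angle applied to the polarity
  vectors of example cells, with the direction-variant shape features
  recomputed per draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from epifold.io import CellRecord, LabelVolume
from epifold.moments import cell_shape_features
from epifold.reconstruct import PolarityField

__all__ = [
    "EvaluationReport",
    "flipping_error",
    "direction_deviation",
    "dice_score",
    "degrade_labels",
    "perturb_polarity_sensitivity",
    "vmf_kappa_for_mean_angle",
    "sample_vmf",
]


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationReport:
    """Summary of one validation run."""

    flipping_error_pct: float
    mean_deviation_deg: float
    std_deviation_deg: float
    dice_score: float
    n_cells: int
    per_cell: pd.DataFrame = field(repr=False, default=None)

    def to_json(self, path=None) -> str:
        payload = {
            "flipping_error_pct": self.flipping_error_pct,
            "mean_deviation_deg": self.mean_deviation_deg,
            "std_deviation_deg": self.std_deviation_deg,
            "dice_score": self.dice_score,
            "n_cells": self.n_cells,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_normals(field_) -> dict:
    if isinstance(field_, PolarityField):
        return field_.normals
    return {int(k): np.asarray(v, float) for k, v in dict(field_).items()}


def flipping_error(pred, gt) -> float:
    """Percentage of matched cells whose vector opposes the ground truth.

    A cell is flipped iff the dot product of its predicted and ground-truth
    unit vectors is negative; unmatched labels are excluded from the
    denominator.  Raises :class:`EvaluationError` with zero matched cells.
    """
    p = _as_normals(pred)
    g = _as_normals(gt)
    matched = sorted(set(p) & set(g))
    if not matched:
        raise EvaluationError("no labels in common between prediction and ground truth")
    flipped = sum(1 for lab in matched if float(np.dot(p[lab], g[lab])) < 0)
    return 100.0 * flipped / len(matched)


def direction_deviation(pred, gt, include_flipped: bool = False):
    """Mean and std deviation angle (degrees) of correctly oriented vectors.

    The per-cell angle is arccos(|n_pred . n_gt|): the comparison is made
    after sign correction, so orientation flips do not enter (they are
    counted separately by :func:`flipping_error`).  With
    ``include_flipped=True`` the raw signed angle arccos(n_pred . n_gt) is
    used instead.
    """
    p = _as_normals(pred)
    g = _as_normals(gt)
    matched = sorted(set(p) & set(g))
    if not matched:
        raise EvaluationError("no labels in common between prediction and ground truth")
    dots = np.array([float(np.dot(p[lab], g[lab])) for lab in matched])
    if not include_flipped:
        dots = np.abs(dots)
    ang = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    return float(ang.mean()), float(ang.std())


def dice_score(seg: LabelVolume, gt: LabelVolume):
    """Overlap between a segmentation and ground-truth labels.

    Labels are matched one-to-one by maximal voxel overlap (greedy, largest
    overlap first, ties to the smaller label pair); each matched pair scores
    Dice = 2|A∩B| / (|A| + |B|).  Returns (score, per_cell, global_dice):
    the overlap-weighted mean over matched pairs, a per-pair table, and the
    global foreground Dice (which unmatched voxels lower through its
    denominator).
    """
    a = seg.voxels
    b = gt.voxels
    if a.shape != b.shape:
        raise EvaluationError(f"shape mismatch {a.shape} vs {b.shape}")
    fg = (a > 0) | (b > 0)
    pair = np.stack([a[fg], b[fg]], axis=1)
    pairs, overlap = np.unique(pair, axis=0, return_counts=True)

    sizes_a = dict(zip(*np.unique(a[a > 0], return_counts=True)))
    sizes_b = dict(zip(*np.unique(b[b > 0], return_counts=True)))

    cand = [
        (int(o), int(pa), int(pb))
        for (pa, pb), o in zip(pairs, overlap)
        if pa > 0 and pb > 0
    ]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for o, pa, pb in cand:
        if pa in used_a or pb in used_b:
            continue
        used_a.add(pa)
        used_b.add(pb)
        d = 2.0 * o / (sizes_a[pa] + sizes_b[pb])
        rows.append({"seg_label": pa, "gt_label": pb, "overlap": o, "dice": d})
    per_cell = pd.DataFrame(rows)
    if len(per_cell):
        w = per_cell["overlap"].to_numpy(float)
        score = float(np.average(per_cell["dice"], weights=w))
    else:
        score = 0.0
    inter = int(((a == b) & (a > 0)).sum())
    global_dice = 2.0 * inter / max(int((a > 0).sum()) + int((b > 0).sum()), 1)
    return score, per_cell, float(global_dice)


def degrade_labels(
    vol: LabelVolume,
    boundary_fraction: float = 0.0,
    band: tuple[int, int, int] = (1, 3, 3),
    erode_fraction: float = 0.0,
    merge_fraction: float = 0.0,
    seed: int = 0,
) -> LabelVolume:
    """Controlled segmentation-error model for ground-truth labels.

    Three error modes, mirroring how membrane segmentation degrades:

    * interface noise — ``boundary_fraction`` of the voxels within ``band``
      voxels (z, y, x) of any label interface take the label found at a
      random offset inside the band (rough, displaced boundaries);
    * membrane loss — ``merge_fraction`` of adjacent cell pairs are merged
      into one label (under-segmentation);
    * signal loss — ``erode_fraction`` of the cells are eroded by one voxel
      shell to background.

    Deterministic given ``seed``; sweeping ``boundary_fraction`` (and
    ``merge_fraction`` at the heavy end) moves the Dice score down from 1.
    """
    rng = np.random.default_rng(seed)
    lab = vol.voxels.copy()
    src = vol.voxels
    if merge_fraction > 0:
        pairs = _adjacent_pairs(lab)
        chosen = [p for p in pairs if rng.random() < merge_fraction]
        remap = {}
        for a, b in chosen:
            ra = remap.get(a, a)
            rb = remap.get(b, b)
            if ra == rb:
                continue
            lo, hi = min(ra, rb), max(ra, rb)
            lab[lab == hi] = lo
            for k, v in list(remap.items()):
                if v == hi:
                    remap[k] = lo
            remap[hi] = lo
        src = lab.copy()
    if boundary_fraction > 0:
        boundary = np.zeros(lab.shape, dtype=bool)
        for ax in range(3):
            d = np.diff(lab, axis=ax) != 0
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, lab.shape[ax] - 1)
            sl_hi[ax] = slice(1, lab.shape[ax])
            boundary[tuple(sl_lo)] |= d
            boundary[tuple(sl_hi)] |= d
        bz, by, bx = band
        boundary = ndimage.binary_dilation(
            boundary, structure=np.ones((2 * bz + 1, 2 * by + 1, 2 * bx + 1), bool)
        )
        boundary &= (lab > 0)
        idx = np.flatnonzero(boundary.ravel())
        idx = idx[rng.random(len(idx)) < boundary_fraction]
        if len(idx):
            kji = np.column_stack(np.unravel_index(idx, lab.shape))
            steps = np.column_stack(
                [rng.integers(-b, b + 1, len(idx)) for b in band]
            )
            nbr = np.clip(kji + steps, 0, np.array(lab.shape) - 1)
            lab[kji[:, 0], kji[:, 1], kji[:, 2]] = src[nbr[:, 0], nbr[:, 1], nbr[:, 2]]
    if erode_fraction > 0:
        labels = np.unique(lab)
        labels = labels[labels > 0]
        chosen = labels[rng.random(len(labels)) < erode_fraction]
        for lb in chosen:
            mask = lab == lb
            eroded = ndimage.binary_erosion(mask)
            lab[mask & ~eroded] = 0
    return LabelVolume(voxels=lab, spacing=vol.spacing)


def _adjacent_pairs(lab: np.ndarray) -> list[tuple[int, int]]:
    """Sorted unique pairs of labels sharing a face-adjacent interface."""
    pairs: set[tuple[int, int]] = set()
    for ax in range(3):
        a = np.take(lab, range(0, lab.shape[ax] - 1), axis=ax)
        b = np.take(lab, range(1, lab.shape[ax]), axis=ax)
        m = (a != b) & (a > 0) & (b > 0)
        uu = np.unique(np.stack([a[m], b[m]], axis=1), axis=0) if m.any() else []
        for pa, pb in uu:
            pairs.add((int(min(pa, pb)), int(max(pa, pb))))
    return sorted(pairs)


# --------------------------------------------------------------------------
# von Mises-Fisher directional noise


def _vmf_mean_angle(kappa: float) -> float:
    """Mean deviation angle (radians) of a vMF distribution on S^2.

    E[theta] with density proportional to sin(theta) exp(kappa cos(theta)).
    """
    theta = np.linspace(0.0, np.pi, 20001)
    w = np.sin(theta) * np.exp(kappa * (np.cos(theta) - 1.0))  # stabilized
    return float(np.trapezoid(theta * w, theta) / np.trapezoid(w, theta))


def vmf_kappa_for_mean_angle(mean_deg: float) -> float:
    """Concentration kappa whose vMF mean deviation equals ``mean_deg``."""
    if mean_deg <= 0:
        return np.inf
    target = np.radians(mean_deg)
    if target >= _vmf_mean_angle(0.0):
        return 0.0
    return float(
        optimize.brentq(lambda k: _vmf_mean_angle(k) - target, 1e-6, 1e6, xtol=1e-9)
    )


def sample_vmf(mean_dir: np.ndarray, kappa: float, size: int, rng) -> np.ndarray:
    """Draw unit vectors from vMF(mean_dir, kappa) (inverse-CDF in cos theta)."""
    mu = np.asarray(mean_dir, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if np.isinf(kappa):
        return np.tile(mu, (size, 1))
    u = rng.random(size)
    if kappa < 1e-12:
        w = 1.0 - 2.0 * u
    else:
        # cos(theta) ~ 1 + log(u + (1-u) e^{-2 kappa}) / kappa
        w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.random(size) * 2.0 * np.pi
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    # orthonormal completion of mu
    seed_ax = np.zeros(3)
    seed_ax[int(np.argmin(np.abs(mu)))] = 1.0
    t1 = seed_ax - np.dot(seed_ax, mu) * mu
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(mu, t1)
    return (
        w[:, None] * mu
        + (s * np.cos(phi))[:, None] * t1
        + (s * np.sin(phi))[:, None] * t2
    )


def perturb_polarity_sensitivity(
    cells: list[tuple[CellRecord, np.ndarray]],
    mean_error_deg: float,
    n: int = 50,
    seed: int = 0,
) -> dict:
    """Shape-feature distributions under directional noise on the polarity.

    For each (cell, polarity vector) pair, ``n`` random unit vectors are
    drawn from a von Mises-Fisher distribution about the vector whose mean
    deviation angle equals ``mean_error_deg`` (kappa solved numerically),
    and the direction-variant features are recomputed per draw.  Returns
    {label: DataFrame} with one row per draw (longitudinal_spread,
    transversal_spread, skewness, deviation_deg).
    """
    kappa = vmf_kappa_for_mean_angle(mean_error_deg)
    rng = np.random.default_rng(seed)
    out: dict[int, pd.DataFrame] = {}
    for cell, nvec in cells:
        if not cell.has_surface:
            raise EvaluationError(f"cell {cell.label} has no closed surface")
        draws = sample_vmf(nvec, kappa, n, rng)
        rows = []
        for d in draws:
            feats, _, _ = cell_shape_features(
                cell.surface_vertices, cell.surface_faces, d
            )
            rows.append(
                {
                    "longitudinal_spread": feats.longitudinal_spread,
                    "transversal_spread": feats.transversal_spread,
                    "skewness": feats.skewness,
                    "deviation_deg": float(
                        np.degrees(np.arccos(np.clip(np.dot(d, nvec / np.linalg.norm(nvec)), -1, 1)))
                    ),
                }
            )
        out[cell.label] = pd.DataFrame(rows)
    return out
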