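"""End-to-end orchestration: label volume in, per-cell features + QC out.

``analyze_labels`` is the library entry point: it extracts cells, builds and
repairs the centroid crust, assigns polarity, and computes moment-based
shape features.  ``run_pipeline`` wraps it with file I/O for the CLI;
``run_validation`` runs the synthetic validation grid (surface specs x
noise levels x seeds x label degradations) and emits one tidy row per run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epifold import io as eio
from epifold import moments as emom
from epifold import reconstruct as erec
from epifold import synthetic as esyn
from epifold import validation as eval_
from epifold.reconstruct import ConfigurationError

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_labels", "run_pipeline", "run_validation"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (all paths resolved by the caller)."""

    input_path: str
    spacing: tuple[float, float, float]  # (dz, dy, dx) um
    orientation_mode: str | None = None  # 'in' | 'out'
    min_voxels: int = 20
    output_dir: str = "."
    polarity_csv: str | None = None  # pre-assigned per-cell vectors
    flip_cells: tuple[int, ...] = ()
    seed: int = 0
    verbosity: int = 0

    def validate(self):
        if self.orientation_mode is None and self.polarity_csv is None:
            raise ConfigurationError(
                "orientation_mode is mandatory unless a pre-assigned polarity CSV is given"
            )
        if self.orientation_mode is not None and self.orientation_mode not in ("in", "out"):
            raise ConfigurationError("orientation_mode must be 'in' or 'out'")


@dataclass
class AnalysisResult:
    cells: list
    mesh: erec.SheetMesh
    polarity: erec.PolarityField
    features: pd.DataFrame
    qc: dict = field(default_factory=dict)


def analyze_labels(
    vol: eio.LabelVolume,
    orientation_mode: str | None = "in",
    min_voxels: int = 20,
    pre_assigned: dict | None = None,
    flip_cells=(),
    with_features: bool = True,
) -> AnalysisResult:
    """Run the full analysis on an in-memory label volume.

    Cells on the sheet get a polarity vector; cells with a closed surface
    additionally get moment-based shape features (in the polarity-aligned
    frame).  QC lists hole warnings, repair log, flip candidates
    ('hole-adjacent', 'no-vertex', 'orientation-tie' flags) and cells
    excluded from moments, so downstream users can filter non-epithelial or
    suspect cells.
    """
    cells = eio.extract_cells(vol, min_voxels=min_voxels, with_surfaces=with_features)
    cents = np.array([c.centroid for c in cells])
    labels = [c.label for c in cells]
    mesh = erec.reconstruct_crust(cents, labels)
    mesh = erec.refine_mesh(mesh)
    mesh = erec.detect_and_repair_holes(mesh)
    mesh = erec.orient_faces(mesh)
    polarity = erec.assign_polarity(
        mesh, cells, orientation_mode, pre_assigned=pre_assigned, flip_cells=flip_cells
    )

    rows = []
    for cell in cells:
        row: dict = {
            "label": cell.label,
            "cx": cell.centroid[0],
            "cy": cell.centroid[1],
            "cz": cell.centroid[2],
            "voxel_count": cell.voxel_count,
        }
        nvec = polarity.normals.get(cell.label)
        if nvec is not None:
            row.update(nx=nvec[0], ny=nvec[1], nz=nvec[2])
        cell_flags = set(cell.flags) | set(polarity.flags.get(cell.label, ()))
        if with_features and cell.has_surface and nvec is not None:
            feats, m_img, m_pol = emom.cell_shape_features(
                cell.surface_vertices, cell.surface_faces, nvec
            )
            row.update(
                volume=feats.volume,
                surface_area=feats.surface_area,
                sphericity=feats.sphericity,
                longitudinal_spread=feats.longitudinal_spread,
                transversal_spread=feats.transversal_spread,
                skewness=feats.skewness,
                raw_skewness=feats.raw_skewness,
                transversal_xx=feats.transversal_components[0],
                transversal_yy=feats.transversal_components[1],
            )
            cell_flags.update(feats.flags)
            for (i, j, k), val in m_img.values.items():
                row[f"G{i}{j}{k}"] = val
        row["flags"] = ";".join(sorted(cell_flags))
        rows.append(row)
    features = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)

    qc = {
        "n_cells": len(cells),
        "repair_log": list(mesh.repair_log),
        "warnings": list(mesh.warnings),
        "hole_count": sum(1 for w in mesh.warnings if w.startswith("hole")),
        "flip_candidates": sorted(
            lab
            for lab, fl in polarity.flags.items()
            if fl & {"hole-adjacent", "no-vertex", "orientation-tie"}
        ),
        "open_surface_cells": sorted(c.label for c in cells if "open-surface" in c.flags),
        "convergent_point": [float(x) for x in polarity.convergent_point],
    }
    return AnalysisResult(cells=cells, mesh=mesh, polarity=polarity, features=features, qc=qc)


def run_pipeline(cfg: PipelineConfig) -> AnalysisResult:
    """File-to-file pipeline run: deterministic given the configuration.

    Writes features.csv, polarity.csv and qc_report.json into the output
    directory; on failure a failure marker with the stage name is written
    next to any partial output.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "config"
    try:
        cfg.validate()
        stage = "read"
        vol = eio.read_label_volume(cfg.input_path, cfg.spacing)
        stage = "analyze"
        pre = erec.load_polarity_csv(cfg.polarity_csv) if cfg.polarity_csv else None
        result = analyze_labels(
            vol,
            orientation_mode=cfg.orientation_mode,
            min_voxels=cfg.min_voxels,
            pre_assigned=pre,
            flip_cells=cfg.flip_cells,
        )
        stage = "write"
        result.features.to_csv(outdir / "features.csv", index=False)
        pol = result.polarity.to_frame()
        cent = result.features[["label", "cx", "cy", "cz"]]
        pol = cent.merge(pol, on="label", how="right")
        pol.to_csv(outdir / "polarity.csv", index=False)
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(result.qc, fh, indent=2)
        return result
    except Exception as exc:
        marker = outdir / "FAILED"
        marker.write_text(f"stage: {stage}\nerror: {exc!r}\n")
        raise


def run_validation(
    specs: list[esyn.SurfaceSpec],
    noise_levels=(0,),
    seeds=(0,),
    degradation=(0.0,),
    orientation_mode: str = "out",
    min_voxels: int = 50,
    render: bool = False,
) -> pd.DataFrame:
    """Synthetic validation harness: one tidy row per grid point.

    Cartesian product of surface specs x noise levels x seeds x label
    degradation severities.  Per run: generate the scene, optionally corrupt
    the ground-truth labels (the segmentation-quality axis: a severity s in
    [0, 1] applies boundary corruption s, cell merging 0.4 s^2 and erosion
    0.2 s), run the polarity pipeline on the labels, and record flipping
    error, deviation angle and Dice against ground truth with full parameter
    provenance.

    Ground-truth normals are 'up' (away from the curvature centre), so runs
    compare against ``orientation_mode='out'``.
    """
    rows = []
    for spec in specs:
        for seed in seeds:
            base = esyn.SurfaceSpec(
                radius_of_curvature=spec.radius_of_curvature,
                folds=spec.folds,
                extent=spec.extent,
                cell_density=spec.cell_density,
                cell_height=spec.cell_height,
                seed=int(seed),
            )
            scene = esyn.generate_scene(base, noise_level=0, render=False)
            for noise in noise_levels:
                if render:
                    esyn.render_membranes(
                        scene.label_volume, noise_level=int(noise), seed=int(seed)
                    )
                for corr in degradation:
                    vol = scene.label_volume
                    if corr > 0:
                        vol = eval_.degrade_labels(
                            vol,
                            boundary_fraction=float(corr),
                            merge_fraction=0.4 * float(corr) ** 2,
                            erode_fraction=0.2 * float(corr),
                            seed=int(seed),
                        )
                    dice, _, global_dice = eval_.dice_score(vol, scene.label_volume)
                    try:
                        res = analyze_labels(
                            vol,
                            orientation_mode=orientation_mode,
                            min_voxels=min_voxels,
                            with_features=False,
                        )
                    except Exception as exc:  # a run may fail at high corruption
                        log.warning("validation run failed: %s", exc)
                        rows.append(
                            _provenance(base, noise, seed, corr)
                            | {"failed": True, "error": str(exc)}
                        )
                        continue
                    flip = eval_.flipping_error(res.polarity, scene.gt_normals)
                    mean_dev, std_dev = eval_.direction_deviation(
                        res.polarity, scene.gt_normals
                    )
                    rows.append(
                        _provenance(base, noise, seed, corr)
                        | {
                            "failed": False,
                            "n_cells": len(res.cells),
                            "dice": dice,
                            "global_dice": global_dice,
                            "flipping_error_pct": flip,
                            "mean_deviation_deg": mean_dev,
                            "std_deviation_deg": std_dev,
                        }
                    )
    return pd.DataFrame(rows)


def _provenance(spec: esyn.SurfaceSpec, noise, seed, corr) -> dict:
    return {
        "radius_of_curvature": spec.radius_of_curvature,
        "folds": json.dumps(
            [[f.center[0], f.center[1], f.peak_height, f.width] for f in spec.folds]
        ),
        "extent": spec.extent,
        "cell_density": spec.cell_density,
        "cell_height": spec.cell_height,
        "noise_level": int(noise),
        "seed": int(seed),
        "degradation": float(corr),
    }
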