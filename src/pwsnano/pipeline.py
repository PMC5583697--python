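"""End-to-end pipeline runs: cube -> maps, and cohort -> comparison report.

Every run writes a JSON manifest (config, seed, library versions, inputs,
outputs) sufficient to reproduce it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    GroupComparison,
    PatientSummary,
    cohort_report,
    compare_groups,
    summaries_to_frame,
)
from .config import PipelineConfig
from .hypercube_io import read_cube, write_labels, write_map
from .segmentation import region_ld_stats, segment_nuclei
from .spectral_core import LdMap, compute_sigma_map, sigma_to_ld

__all__ = ["run_ld", "run_segment_compare", "write_manifest"]


def write_manifest(out_dir: Path, config: PipelineConfig, inputs: dict, outputs: dict) -> Path:
    import scipy
    import skimage

    manifest = {
        "pwsnano_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "skimage_version": skimage.__version__,
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "inputs": inputs,
        "outputs": outputs,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def run_ld(cube_path: str | Path, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Compute and write the Sigma and L_d maps for one cube.

    Writes ``sigma.tif``, ``ld.tif`` (each with a JSON sidecar recording the
    processing provenance) and ``manifest.json`` into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cube = read_cube(cube_path)
    sigma = compute_sigma_map(
        cube,
        filter=config.filter.to_spec(),
        poly_order=config.baseline_order,
        noise_floor=config.noise_floor,
    )
    ld = sigma_to_ld(
        sigma,
        config.thickness_um,
        cube.axis,
        convention=config.convention,
        calibration=config.calibration,
    )
    sigma_path = write_map(out_dir / "sigma.tif", sigma.values, {"provenance": sigma.provenance})
    ld_path = write_map(
        out_dir / "ld.tif",
        ld.values,
        {
            "convention": ld.convention,
            "calibration_constant": ld.calibration_constant,
            "thickness_um": config.thickness_um,
            "provenance": sigma.provenance,
        },
    )
    manifest = write_manifest(
        out_dir,
        config,
        inputs={"cube": str(cube_path)},
        outputs={"sigma": str(sigma_path), "ld": str(ld_path)},
    )
    return {"sigma": sigma_path, "ld": ld_path, "manifest": manifest, "ld_map": ld}


def _patient_summary(
    patient_id: str,
    group: str,
    cube_path: str | Path,
    transmission_path: str | Path | None,
    config: PipelineConfig,
) -> PatientSummary | None:
    """Segment one patient's image and average L_d over its nuclei."""
    import tifffile

    cube = read_cube(cube_path)
    sigma = compute_sigma_map(
        cube, filter=config.filter.to_spec(), poly_order=config.baseline_order,
        noise_floor=config.noise_floor,
    )
    ld = sigma_to_ld(
        sigma, config.thickness_um, cube.axis,
        convention=config.convention, calibration=config.calibration,
    )
    if transmission_path is None:
        raise ValueError(f"patient {patient_id}: no transmission image for segmentation")
    trans = np.asarray(tifffile.imread(transmission_path), dtype=float)
    mask = segment_nuclei(trans, config.segmentation.to_params(), cube.pixel_size_um)
    if mask.n_labels == 0:
        return None
    regions = region_ld_stats(ld, mask, annulus_width_px=config.segmentation.annulus_width_px)
    return PatientSummary(
        patient_id=patient_id,
        group=group,
        mean_nuclear_ld=float(np.mean([r.mean_ld for r in regions])),
        mean_cellular_ld=float(np.mean([r.cellular_mean_ld for r in regions])),
        n_nuclei=len(regions),
    )


def run_segment_compare(
    samples: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path,
    group_a: str | None = None,
    group_b: str | None = None,
) -> dict:
    """Full cohort run: per-patient segmentation + L_d, then a group contrast.

    ``samples`` needs columns patient_id, group, cube, transmission.  Writes
    ``summaries.csv``, ``comparison.json``, ``report.csv`` and a manifest.
    Each named group must contain at least two patients.
    """
    required = {"patient_id", "group", "cube", "transmission"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples table must have columns {sorted(required)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = list(pd.unique(samples["group"]))
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(
                f"found groups {groups}; pass group_a/group_b explicitly when not exactly two"
            )
        group_a, group_b = groups
    counts = samples["group"].value_counts()
    for g in (group_a, group_b):
        if counts.get(g, 0) < 2:
            raise ValueError(f"group {g!r} has {counts.get(g, 0)} patient(s); need >= 2")
    summaries = []
    for row in samples.itertuples(index=False):
        s = _patient_summary(str(row.patient_id), str(row.group), row.cube, row.transmission, config)
        if s is not None:
            summaries.append(s)
    comparison = compare_groups(
        summaries, group_a, group_b,
        test=config.stats.test, sd_convention=config.stats.sd_convention,
    )
    summaries_path = out_dir / "summaries.csv"
    summaries_to_frame(summaries).to_csv(summaries_path, index=False)
    comparison_path = out_dir / "comparison.json"
    comparison_path.write_text(json.dumps(comparison.__dict__, indent=1))
    report_path = cohort_report([comparison], out_dir / "report.csv")
    manifest = write_manifest(
        out_dir,
        config,
        inputs={"n_samples": len(samples), "group_a": group_a, "group_b": group_b},
        outputs={
            "summaries": str(summaries_path),
            "comparison": str(comparison_path),
            "report": str(report_path),
        },
    )
    return {
        "summaries": summaries_path,
        "comparison": comparison,
        "comparison_path": comparison_path,
        "report": report_path,
        "manifest": manifest,
    }
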