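"""End-to-end pipeline: phantom (or loaded structures) → plan → FIF →
evaluation, with a provenance manifest sufficient to regenerate the bundle."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .config import RunConfig
from .dose import DoseGrid
from .evaluation import compute_dvh, dvh_to_csv, embrace_report, report_to_json, report_to_table
from .fif import FIFResult, fif_reduce, suppress_exterior_dose
from .phantom import generate_phantom
from .plans import Plan, assemble_crt3d, assemble_fourfield, plan_target_mask
from .structures import StructureSet

__all__ = ["PipelineResult", "run_pipeline", "write_dose_nifti"]

log = logging.getLogger("autoplan")


@dataclass
class PipelineResult:
    out_dir: Path
    plan: Plan
    dose: DoseGrid
    structures: StructureSet
    fif: FIFResult | None
    files: dict[str, Path] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def write_dose_nifti(dose: DoseGrid, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(dose.values.astype(np.float32), dose.geometry.affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    return path


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full planning chain and write the artifact bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("structures"):
        if config.structures_dir:
            structures = StructureSet.load(config.structures_dir)
        else:
            phantom_spec = replace(config.phantom, random_seed=config.seed)
            structures = generate_phantom(phantom_spec)
        for name in config.drop_structures:
            if name in structures.masks:
                structures.masks[name] = np.zeros_like(structures.masks[name])

    with _stage("plan"):
        if config.technique == "fourfield":
            plan, dose = assemble_fourfield(structures, rx=config.rx, engine=config.engine)
        else:
            plan, dose = assemble_crt3d(
                structures,
                rx=config.rx,
                itv_margins=config.itv_margins,
                ptv_margin_mm=config.ptv_margin_mm,
                aperture_margin_mm=config.aperture_margin_mm,
                engine=config.engine,
                preset=config.preset,
            )

    fif_result: FIFResult | None = None
    warnings: list[str] = []
    if config.fif_enabled:
        with _stage("fif"):
            fif_result = fif_reduce(plan, structures, config.engine, config.fif)
            plan, dose = fif_result.plan, fif_result.dose
            if config.exterior_level is not None:
                ext = suppress_exterior_dose(
                    plan, structures, config.exterior_level, config.engine, config.fif
                )
                fif_result.trace.extend(ext.trace)
                fif_result.status = (
                    ext.status if fif_result.status == "ok" else fif_result.status
                )
                plan, dose = ext.plan, ext.dose
            warnings.extend(plan.warnings)

    with _stage("evaluate"):
        report = embrace_report(dose, structures, config.rx)
        curves = []
        for name in ("bladder", "rectum", "bowel_space", "spinal_cord"):
            if name in structures and structures[name].any():
                curves.append(compute_dvh(dose, structures[name], structure=name))
        target = plan_target_mask(plan, structures)
        curves.append(
            compute_dvh(dose, target, structure=plan.normalization.target_structure)
        )

    with _stage("write"):
        files: dict[str, Path] = {}
        files["plan"] = out_dir / "plan.json"
        files["plan"].write_text(plan.to_json())
        files["dose"] = write_dose_nifti(dose, out_dir / "dose.nii.gz")
        files["dvh"] = dvh_to_csv(curves, out_dir / "dvh.csv")
        files["report_json"] = out_dir / "report.json"
        files["report_json"].write_text(report_to_json(report))
        files["report_txt"] = out_dir / "report.txt"
        files["report_txt"].write_text(report_to_table(report) + "\n")
        if fif_result is not None:
            files["fif_trace"] = out_dir / "fif_trace.csv"
            _write_trace(fif_result, files["fif_trace"])
        manifest = {
            "format": "autoplan-manifest-v1",
            "config": config.provenance(),
            "normalization": {
                "target": plan.normalization.target_structure,
                "isodose_level": plan.normalization.isodose_level,
                "coverage": plan.normalization.coverage,
                "scale": plan.normalization.scale,
            },
            "fif_status": fif_result.status if fif_result else "disabled",
            "warnings": warnings,
            "outputs": {k: str(v) for k, v in files.items()},
        }
        files["manifest"] = out_dir / "manifest.json"
        files["manifest"].write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        out_dir=out_dir,
        plan=plan,
        dose=dose,
        structures=structures,
        fif=fif_result,
        files=files,
        warnings=warnings,
    )


def _write_trace(result: FIFResult, path: Path) -> None:
    import csv

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["iteration", "hotspot_cc", "hotspot_max_gy", "donor_beam", "segment", "delta_mu"]
        )
        for row in result.trace:
            writer.writerow(
                [
                    row["iteration"],
                    f"{row['hotspot_cc']:.3f}",
                    f"{row['hotspot_max_gy']:.3f}",
                    row["donor_beam"],
                    row["segment"],
                    f"{row['delta_mu']:.3f}",
                ]
            )
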