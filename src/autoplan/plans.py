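"""Plan assembly: beam setup, region-of-hot-spot-detection (RHD) and
synthetic-PTV construction, initial MU, and coverage-based normalization.

A plan is normalized by a pair (L, p): the dose is scaled so that the L×rx
isodose covers fraction p of a named target volume.  The 4-field-box default
is 100 %/97 % on the *synthetic PTV* (the intersection of all beam paths
shrunk 7 mm, a surrogate for a contoured target when only bony anatomy is
available); the 3D-CRT default is 100 %/95 % on the real PTV, with a cooler
95 %/99 % preset selectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .apertures import FourFieldParams, build_ptv, crt_aperture, fourfield_apertures
from .dose import Beam, DoseGrid, EngineParams, plan_dose
from .errors import PlanGeometryError
from .geometry import ImageGeometry, MarginSpec
from .morphology import BEVImage, backproject_aperture, shrink
from .structures import StructureSet

__all__ = [
    "RX_RANGE_GY",
    "PTV_MARGIN_RANGE_MM",
    "NORMALIZATION_PRESETS",
    "SYNTHETIC_PTV_SHRINK_MM",
    "NormalizationRecord",
    "Plan",
    "build_rhd",
    "build_synthetic_ptv",
    "coverage",
    "normalize",
    "renormalize_plan",
    "assemble_fourfield",
    "assemble_crt3d",
    "plan_target_mask",
]

RX_RANGE_GY = (43.2, 50.4)
PTV_MARGIN_RANGE_MM = (3.0, 10.0)
SYNTHETIC_PTV_SHRINK_MM = 7.0

# (isodose level L as fraction of rx, coverage fraction p of the target)
NORMALIZATION_PRESETS: dict[str, tuple[float, float]] = {
    "fourfield": (1.00, 0.97),
    "crt3d": (1.00, 0.95),
    "reviewer2": (0.95, 0.99),
}


def check_rx(rx: float) -> float:
    lo, hi = RX_RANGE_GY
    if not lo <= rx <= hi:
        raise PlanGeometryError(
            f"prescription dose {rx} Gy outside the accepted range {lo}-{hi} Gy"
        )
    return float(rx)


@dataclass
class NormalizationRecord:
    """How (and by how much) a plan was scaled."""

    target_structure: str
    isodose_level: float   # L, fraction of rx
    coverage: float        # p, fraction of target volume
    scale: float = 1.0     # cumulative scale applied to the raw equal-MU plan

    def __post_init__(self) -> None:
        if not 0 < self.isodose_level <= 1.1:
            raise ValueError("isodose level must be in (0, 1.1]")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage fraction must be in (0, 1)")
        if not self.scale > 0:
            raise ValueError("scale must be positive")


@dataclass
class Plan:
    """A complete plan: technique, prescription, beams and provenance."""

    technique: str  # "fourfield" | "crt3d"
    rx: float
    beams: list[Beam]
    normalization: NormalizationRecord
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.technique not in ("fourfield", "crt3d"):
            raise ValueError(f"unknown technique '{self.technique}'")
        ids = {b.id for b in self.beams}
        for b in self.beams:
            if b.parent_id is not None and b.parent_id not in ids:
                raise ValueError(f"subfield {b.id} references missing parent {b.parent_id}")

    @property
    def parents(self) -> list[Beam]:
        return [b for b in self.beams if b.parent_id is None]

    def subfields_of(self, parent_id: str) -> list[Beam]:
        return [b for b in self.beams if b.parent_id == parent_id]

    def beam_by_id(self, beam_id: str) -> Beam:
        for b in self.beams:
            if b.id == beam_id:
                return b
        raise KeyError(beam_id)

    def mu_per_angle(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for b in self.beams:
            out[b.gantry_angle] = out.get(b.gantry_angle, 0.0) + b.mu
        return out

    # ------------------------------------------------------------- JSON
    def to_json(self) -> str:
        doc = {
            "format": "autoplan-plan-v1",
            "technique": self.technique,
            "rx": self.rx,
            "beams": [
                {
                    "id": b.id,
                    "gantry_angle": b.gantry_angle,
                    "mu": b.mu,
                    "parent_id": b.parent_id,
                    "aperture": _encode_bev(b.aperture),
                }
                for b in self.beams
            ],
            "normalization": asdict(self.normalization),
            "provenance": self.provenance,
            "warnings": self.warnings,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Plan":
        doc = json.loads(text)
        beams = [
            Beam(
                id=b["id"],
                gantry_angle=b["gantry_angle"],
                aperture=_decode_bev(b["aperture"]),
                mu=b["mu"],
                parent_id=b.get("parent_id"),
            )
            for b in doc["beams"]
        ]
        return cls(
            technique=doc["technique"],
            rx=doc["rx"],
            beams=beams,
            normalization=NormalizationRecord(**doc["normalization"]),
            provenance=doc.get("provenance", {}),
            warnings=list(doc.get("warnings", [])),
        )


def _encode_bev(image: BEVImage) -> dict:
    flat = np.asarray(image.pixels, dtype=bool).ravel()
    runs: list[int] = []
    current, count = False, 0  # RLE starts with the number of leading zeros
    for v in flat:
        if bool(v) == current:
            count += 1
        else:
            runs.append(count)
            current, count = bool(v), 1
    runs.append(count)
    return {
        "gantry_angle": image.gantry_angle,
        "shape": list(image.pixels.shape),
        "pixel_spacing": list(image.pixel_spacing),
        "rle": runs,
    }


def _decode_bev(doc: dict) -> BEVImage:
    shape = tuple(doc["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in doc["rle"]:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return BEVImage(doc["gantry_angle"], flat.reshape(shape), tuple(doc["pixel_spacing"]))


# ------------------------------------------------------------------ targets
def build_rhd(beams: list[Beam], geometry: ImageGeometry) -> np.ndarray:
    """Region of hot-spot detection: intersection of all open beam paths."""
    parents = [b for b in beams if b.parent_id is None]
    if not parents:
        raise PlanGeometryError("RHD needs at least one open field")
    rhd = None
    for b in parents:
        path = backproject_aperture(b.aperture, geometry)
        rhd = path if rhd is None else (rhd & path)
    if not rhd.any():
        raise PlanGeometryError("beam paths do not intersect; apertures are inconsistent")
    return rhd


def build_synthetic_ptv(
    rhd: np.ndarray,
    shrink_mm: float = SYNTHETIC_PTV_SHRINK_MM,
    geometry: ImageGeometry | None = None,
) -> np.ndarray:
    """Synthetic PTV: the RHD uniformly shrunk (7 mm by default, matching the
    conformal aperture margin)."""
    if geometry is None:
        raise ValueError("geometry is required")
    if not np.asarray(rhd).any():
        raise PlanGeometryError("RHD is empty")
    sptv = shrink(rhd, shrink_mm, geometry)
    if not sptv.any():
        raise PlanGeometryError(
            f"synthetic PTV is empty after {shrink_mm} mm shrinkage; fields too small"
        )
    return sptv


# ------------------------------------------------------------ normalization
def coverage(dose_values: np.ndarray, mask: np.ndarray, threshold_gy: float) -> float:
    """Fraction of mask voxels with dose >= threshold."""
    vals = np.asarray(dose_values)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("coverage of an empty mask is undefined")
    return float(np.mean(vals >= threshold_gy))


def normalize(
    dose: DoseGrid,
    target: np.ndarray,
    rx: float,
    level: float,
    coverage_p: float,
) -> tuple[float, DoseGrid]:
    """Scale the dose so the level×rx isodose covers fraction p of the target.

    The covering dose D_p is the top-p percentile of target voxel doses with
    linear interpolation, so the result is exact rather than grid-quantised.
    """
    target = np.asarray(target, dtype=bool)
    if not target.any():
        raise PlanGeometryError("normalization target is empty")
    vals = dose.values[target]
    d_p = float(np.quantile(vals, 1.0 - coverage_p))
    if d_p <= 0:
        raise PlanGeometryError(
            "normalization failed: the target is (partly) outside all beams"
        )
    s = level * rx / d_p
    return s, dose.scaled(s)


def renormalize_plan(
    plan: Plan,
    dose: DoseGrid,
    target: np.ndarray,
    level: float | None = None,
    coverage_p: float | None = None,
    target_name: str | None = None,
) -> tuple[Plan, DoseGrid]:
    """Re-apply (or change) a plan's normalization; scales every beam MU."""
    rec = plan.normalization
    level = rec.isodose_level if level is None else level
    coverage_p = rec.coverage if coverage_p is None else coverage_p
    s, scaled = normalize(dose, target, plan.rx, level, coverage_p)
    for b in plan.beams:
        b.mu *= s
    plan.normalization = NormalizationRecord(
        target_structure=target_name or rec.target_structure,
        isodose_level=level,
        coverage=coverage_p,
        scale=rec.scale * s,
    )
    return plan, scaled


def plan_target_mask(plan: Plan, structures: StructureSet) -> np.ndarray:
    """Reconstruct the plan's normalization-target mask from its provenance."""
    geom = structures.geometry
    name = plan.normalization.target_structure
    if name == "synthetic_ptv":
        rhd = build_rhd(plan.beams, geom)
        return build_synthetic_ptv(rhd, plan.provenance.get("synthetic_ptv_shrink_mm", 7.0), geom)
    if name == "ptv":
        prov = plan.provenance
        itv_margins = MarginSpec(*prov["itv_margins"]) if "itv_margins" in prov else None
        _, ptv = build_ptv(
            structures["ctv_primary"],
            structures["ctv_nodal"],
            itv_margins=itv_margins,
            ptv_margin_mm=prov.get("ptv_margin_mm", 5.0),
            geometry=geom,
        )
        return ptv
    return structures[name]


# ------------------------------------------------------------- assembly
_ANGLE_ORDER = (0, 90, 180, 270)


def assemble_fourfield(
    structures: StructureSet,
    rx: float = 45.0,
    field_params: FourFieldParams | None = None,
    engine: EngineParams | None = None,
    initial_mu: float = 100.0,
    level: float | None = None,
    coverage_p: float | None = None,
    shrink_mm: float = SYNTHETIC_PTV_SHRINK_MM,
) -> tuple[Plan, DoseGrid]:
    """End-to-end 4-field-box plan: bony-landmark apertures, equal initial MU,
    RHD/synthetic-PTV construction and 100 %/97 % normalization."""
    rx = check_rx(rx)
    engine = engine or EngineParams()
    lvl_def, p_def = NORMALIZATION_PRESETS["fourfield"]
    level = lvl_def if level is None else level
    coverage_p = p_def if coverage_p is None else coverage_p
    geom = structures.geometry

    aps = fourfield_apertures(structures, geom, field_params)
    beams = [
        Beam(id=f"field_{a:03d}", gantry_angle=a, aperture=aps[a], mu=initial_mu)
        for a in _ANGLE_ORDER
    ]
    gas = structures.extras.get("rectum_gas")
    dose = plan_dose(beams, structures["body"], geom, engine, non_attenuating=gas)

    rhd = build_rhd(beams, geom)
    sptv = build_synthetic_ptv(rhd, shrink_mm, geom)
    s, dose = normalize(dose, sptv, rx, level, coverage_p)
    for b in beams:
        b.mu *= s

    plan = Plan(
        technique="fourfield",
        rx=rx,
        beams=beams,
        normalization=NormalizationRecord("synthetic_ptv", level, coverage_p, s),
        provenance={
            "field_params": asdict(field_params or FourFieldParams()),
            "engine_params": asdict(engine),
            "initial_mu": initial_mu,
            "synthetic_ptv_shrink_mm": shrink_mm,
        },
    )
    return plan, dose


def assemble_crt3d(
    structures: StructureSet,
    rx: float = 45.0,
    itv_margins: MarginSpec | None = None,
    ptv_margin_mm: float = 5.0,
    aperture_margin_mm: float = 7.0,
    engine: EngineParams | None = None,
    initial_mu: float = 100.0,
    preset: str = "crt3d",
) -> tuple[Plan, DoseGrid]:
    """End-to-end 3D-CRT plan: CTV→ITV→PTV expansion, conformal apertures
    (projected PTV + 7 mm), equal initial MU and 100 %/95 % normalization
    (or the cooler 95 %/99 % 'reviewer2' preset)."""
    rx = check_rx(rx)
    lo, hi = PTV_MARGIN_RANGE_MM
    if not lo <= ptv_margin_mm <= hi:
        raise PlanGeometryError(
            f"PTV margin {ptv_margin_mm} mm outside the accepted range "
            f"{lo / 10:.1f}-{hi / 10:.1f} cm"
        )
    if preset not in ("crt3d", "reviewer2"):
        raise ValueError(f"unknown normalization preset '{preset}'")
    engine = engine or EngineParams()
    itv_margins = itv_margins or MarginSpec.embrace_itv()
    geom = structures.geometry
    structures.require("ctv_primary", "ctv_nodal", "body")

    _, ptv = build_ptv(
        structures["ctv_primary"], structures["ctv_nodal"], itv_margins, ptv_margin_mm, geom
    )
    beams = [
        Beam(
            id=f"field_{a:03d}",
            gantry_angle=a,
            aperture=crt_aperture(ptv, a, aperture_margin_mm, geom),
            mu=initial_mu,
        )
        for a in _ANGLE_ORDER
    ]
    gas = structures.extras.get("rectum_gas")
    dose = plan_dose(beams, structures["body"], geom, engine, non_attenuating=gas)

    level, coverage_p = NORMALIZATION_PRESETS[preset]
    s, dose = normalize(dose, ptv, rx, level, coverage_p)
    for b in beams:
        b.mu *= s

    plan = Plan(
        technique="crt3d",
        rx=rx,
        beams=beams,
        normalization=NormalizationRecord("ptv", level, coverage_p, s),
        provenance={
            "itv_margins": list(itv_margins.as_tuple()),
            "ptv_margin_mm": ptv_margin_mm,
            "aperture_margin_mm": aperture_margin_mm,
            "engine_params": asdict(engine),
            "initial_mu": initial_mu,
            "preset": preset,
        },
    )
    return plan, dose
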