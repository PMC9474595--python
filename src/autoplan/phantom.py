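"""Deterministic synthetic pelvic phantom.

The phantom is schematic, not atlas-based: parameterised geometric primitives
(elliptic body cylinder, ring-shaped pelvis with obturator-foramen
through-holes, stacked L4/L5 vertebral blocks with a visible interspace,
femoral shafts and heads, ellipsoidal bladder, cylindrical rectum, target
volumes and a bowel space) placed in anatomically plausible relative
positions.  Only the geometric relations consumed by the planning algorithms
need to be faithful: bony landmark positions, target–organ spacing, and the
amount of soft tissue between the targets and the bowel.

Two habitus factors scale the anatomy: ``lateral_diameter`` and
``ap_diameter`` rescale the body outline and every structure position in the
axial plane, which reproduces the low-BMI failure mode of bony-landmark
planning (less clearance between the targets and the bowel, and a larger
fraction of the bowel inside the bone-defined fields).  An optional gas
cavity of configurable diameter can be placed inside the rectum; the dose
engine treats it as non-attenuating.

The superior–inferior layout is fixed in millimetres (femoral shafts from
z = 10 mm, pelvic ring 60–190 mm, sacrum 120–200 mm, L5 205–235 mm,
L4 240–270 mm, so the L4/L5 interspace midplane sits at z = 237.5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ImageGeometry, MarginSpec
from .morphology import expand, shrink
from .structures import REQUIRED_STRUCTURES, StructureSet, list_required_structures

__all__ = ["PhantomSpec", "generate_phantom", "list_required_structures"]

# Reference habitus the template coordinates were drawn for (mm).
_REF_LATERAL = 360.0
_REF_AP = 240.0
_MIN_SI = 280.0  # femoral shafts through L4 plus headroom
_AIR_MARGIN = 60.0  # air border around the body on each side, mm

L4L5_INTERSPACE_Z = 237.5


@dataclass(frozen=True)
class PhantomSpec:
    """Tunable phantom parameters.  All lengths in mm."""

    lateral_diameter: float = 360.0
    ap_diameter: float = 240.0
    si_length: float = 300.0
    voxel_spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    organ_scale: float = 1.0
    gas_filled_rectum: bool = False
    rectum_gas_diameter: float = 45.0
    random_seed: int = 0

    def validate(self) -> None:
        for name in ("lateral_diameter", "ap_diameter", "si_length", "organ_scale"):
            v = float(getattr(self, name))
            if not v > 0:
                raise ValueError(f"PhantomSpec.{name} must be strictly positive, got {v}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(
                f"PhantomSpec.voxel_spacing must be strictly positive, got {self.voxel_spacing}"
            )
        if self.si_length < _MIN_SI:
            raise ValueError(
                f"PhantomSpec.si_length must be >= {_MIN_SI} mm to cover L4 through the femurs, "
                f"got {self.si_length}"
            )
        if self.gas_filled_rectum and not self.rectum_gas_diameter > 0:
            raise ValueError(
                f"PhantomSpec.rectum_gas_diameter must be strictly positive, "
                f"got {self.rectum_gas_diameter}"
            )


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    cx, cy, cz = center
    ax_, ay, az = semi
    return ((x - cx) / ax_) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _zcyl(x, y, z, center_xy, semi_xy, z_lo, z_hi) -> np.ndarray:
    cx, cy = center_xy
    ax_, ay = semi_xy
    return (((x - cx) / ax_) ** 2 + ((y - cy) / ay) ** 2 <= 1.0) & (z >= z_lo) & (z <= z_hi)


def _box(x, y, z, x_lo, x_hi, y_lo, y_hi, z_lo, z_hi) -> np.ndarray:
    return (x >= x_lo) & (x <= x_hi) & (y >= y_lo) & (y <= y_hi) & (z >= z_lo) & (z <= z_hi)


def generate_phantom(spec: PhantomSpec | None = None) -> StructureSet:
    """Build the full 13-structure set for a :class:`PhantomSpec`.

    Deterministic: identical specs (including seed) yield voxel-identical
    output.  The seed drives only small (±1.5 mm) anterior–posterior and
    superior–inferior jitter of the soft-organ centres, so the phantom stays
    left–right symmetric.
    """
    spec = spec or PhantomSpec()
    spec.validate()

    fx = spec.lateral_diameter / _REF_LATERAL
    fy = spec.ap_diameter / _REF_AP
    g = spec.organ_scale
    sx, sy, sz = spec.voxel_spacing

    nx = int(np.ceil((spec.lateral_diameter + 2 * _AIR_MARGIN) / sx))
    ny = int(np.ceil((spec.ap_diameter + 2 * _AIR_MARGIN) / sy))
    nz = int(np.ceil(spec.si_length / sz))
    geom = ImageGeometry(shape=(nx, ny, nz), spacing=(sx, sy, sz))

    xw, yw, zw = geom.world_grids()
    xc = (nx - 1) * sx / 2.0
    yc = (ny - 1) * sy / 2.0
    x = xw - xc  # 0 at the patient midline
    y = yw - yc  # 0 at the AP midline
    z = zw       # inferior grid edge

    rng = np.random.default_rng(spec.random_seed)

    def jit() -> float:
        return float(rng.uniform(-1.5, 1.5))

    # Superellipse (exponent 4): an axial pelvis cross-section is boxy, not
    # elliptic; this keeps the four-field overlap region inside tissue at
    # more than build-up depth, as in patients.  The outline tapers 8 % from
    # hips (inferior) to waist (superior), so ray depths — and with them the
    # central dose — vary gently along the cranio-caudal axis as they do in
    # a real trunk.
    taper = 1.0 - 0.08 * z / spec.si_length
    body = (
        np.abs(x / (180.0 * fx * taper)) ** 4 + np.abs(y / (120.0 * fy * taper)) ** 4 <= 1.0
    )

    # --- bones (positions scale with habitus; no jitter, landmarks stay exact)
    outer = _zcyl(x, y, z, (0, 0), (95 * fx, 75 * fy), 60, 190)
    inner = _zcyl(x, y, z, (0, 0), (81 * fx, 61 * fy), 60, 190)
    pelvis = outer & ~inner
    for side in (-1.0, 1.0):  # obturator foramina: through-holes along y
        hole = ((x - side * 45 * fx) / (15 * fx)) ** 2 + ((z - 90.0) / 15.0) ** 2 <= 1.0
        pelvis &= ~hole
    sacrum = _box(x, y, z, -40 * fx, 40 * fx, 55 * fy, 80 * fy, 120, 200)
    pelvis &= ~sacrum
    l5 = _box(x, y, z, -30 * fx, 30 * fx, 10 * fy, 60 * fy, 205, 235)
    l4 = _box(x, y, z, -30 * fx, 30 * fx, 10 * fy, 60 * fy, 240, 270)
    femurs = {}
    for name, side in (("femur_l", 1.0), ("femur_r", -1.0)):
        shaft = _zcyl(x, y, z, (side * 65 * fx, 0), (12 * fx, 12 * fy), 10, 100)
        head = _ellipsoid(x, y, z, (side * 62 * fx, 0, 105), (18 * fx, 18 * fy, 18))
        femurs[name] = shaft | head

    # --- soft tissue (sizes scale with organ_scale; targets are fixed size)
    bladder = _ellipsoid(x, y, z, (0, -40 * fy + jit(), 120 + jit()), (35 * g, 28 * g, 30 * g))
    rectum_y = 40 * fy + jit()
    rectum = _zcyl(x, y, z, (0, rectum_y), (15 * g, 15 * g), 60, 155)
    gas = None
    if spec.gas_filled_rectum:
        r = spec.rectum_gas_diameter / 2.0
        gas = _ellipsoid(x, y, z, (0, rectum_y, 120.0), (r, r, r))
        rectum = rectum | gas
    # Primary CTV: uterus/cervix ellipsoid plus an upper-vaginal canal that
    # reaches down toward the inferior field border, as in patients: the
    # cold tail of the PTV DVH lives at the inferior field edge (bone-based
    # fields do not conform to the target there).
    ctv_y = jit()
    ctv_primary = _ellipsoid(x, y, z, (0, ctv_y, 140 + jit()), (25, 22, 45)) | _zcyl(
        x, y, z, (0, ctv_y), (16, 16), 92, 140
    )
    nodal_y = -5 * fy + jit()
    ctv_nodal = _zcyl(x, y, z, (60 * fx, nodal_y), (12, 12), 120, 212) | _zcyl(
        x, y, z, (-60 * fx, nodal_y), (12, 12), 120, 212
    )
    cord = _zcyl(x, y, z, (0, 67 * fy), (5 * g, 5 * g), 205, spec.si_length - 5)

    # Bowel space: body interior above the true pelvis, minus a habitus-scaled
    # clearance belt around the targets.  The clearance shrinks with the body
    # diameters: a slim patient has less tissue between target and bowel.
    clearance_mm = 16.0 * (fx + fy) / 2.0
    interior = shrink(body, 15.0, geom)
    bones_all = pelvis | sacrum | l4 | l5 | femurs["femur_l"] | femurs["femur_r"]
    targets = ctv_primary | ctv_nodal
    bowel = (
        interior
        & (z >= 160)
        & (z <= spec.si_length - 10)
        & (y <= 35 * fy)
        & ~expand(targets, MarginSpec.uniform(clearance_mm), geom)
        & ~bones_all
        & ~(bladder | rectum | cord)
    )

    masks = {
        "body": body,
        "pelvis": pelvis & body,
        "sacrum": sacrum & body,
        "femur_l": femurs["femur_l"] & body,
        "femur_r": femurs["femur_r"] & body,
        "L4": l4 & body,
        "L5": l5 & body,
        "bladder": bladder & body,
        "rectum": rectum & body,
        "bowel_space": bowel & body,
        "spinal_cord": cord & body,
        "ctv_primary": ctv_primary & body,
        "ctv_nodal": ctv_nodal & body,
    }
    assert tuple(masks.keys()) == REQUIRED_STRUCTURES

    extras = {}
    if gas is not None:
        extras["rectum_gas"] = gas & body

    metadata = {
        "phantom_spec": {
            "lateral_diameter": spec.lateral_diameter,
            "ap_diameter": spec.ap_diameter,
            "si_length": spec.si_length,
            "voxel_spacing": list(spec.voxel_spacing),
            "organ_scale": spec.organ_scale,
            "gas_filled_rectum": spec.gas_filled_rectum,
            "rectum_gas_diameter": spec.rectum_gas_diameter,
            "random_seed": spec.random_seed,
        },
        "l4l5_interspace_z_mm": L4L5_INTERSPACE_Z,
        "target_bowel_clearance_mm": clearance_mm,
        "habitus_factors": {"lateral": fx, "ap": fy},
    }
    return StructureSet(geometry=geom, masks=masks, extras=extras, metadata=metadata)
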