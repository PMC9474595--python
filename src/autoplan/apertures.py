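"""Beam aperture construction.

Two techniques are supported:

* **4-field box** — rectangular anterior/posterior/lateral fields shaped on
  projected bony landmarks: superior border at the L4/L5 interspace, inferior
  border below the obturator foramina, lateral borders at the widest pelvic
  brim, anterior border beyond the pubis and posterior border covering the
  sacrum.
* **3D-CRT** — conformal apertures: the projected PTV grown by a uniform
  in-plane margin (7 mm by default).

Subfield apertures for field-in-field blocking are the parent aperture minus
the dilated projection of a hot region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import LandmarkError, PlanGeometryError
from .geometry import ImageGeometry, MarginSpec
from .morphology import BEVImage, bev_axes, dilate_bev, expand, project_to_bev
from .structures import StructureSet

__all__ = [
    "FourFieldParams",
    "fourfield_apertures",
    "crt_aperture",
    "build_ptv",
    "block_region",
    "detect_l4l5_interspace",
]


@dataclass(frozen=True)
class FourFieldParams:
    """Offsets applied to the detected bony landmarks (mm)."""

    lateral_brim_margin: float = 18.0
    inferior_margin_below_obturator: float = 10.0
    anterior_margin_beyond_pubis: float = 10.0
    posterior_sacral_coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "lateral_brim_margin",
            "inferior_margin_below_obturator",
            "anterior_margin_beyond_pubis",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"FourFieldParams.{name} must be >= 0 mm")
        if not 0.0 <= self.posterior_sacral_coverage_fraction <= 1.0:
            raise ValueError("posterior_sacral_coverage_fraction must be in [0, 1]")


def _world_extent(mask: np.ndarray, geometry: ImageGeometry, axis: int) -> tuple[float, float]:
    idx = np.where(mask.any(axis=tuple(a for a in range(3) if a != axis)))[0]
    coords = geometry.axis_coords(axis)
    return float(coords[idx[0]]), float(coords[idx[-1]])


def detect_l4l5_interspace(structures: StructureSet, geometry: ImageGeometry) -> float:
    """Midplane (mm) between the lowest L4 voxel and the highest L5 voxel."""
    for name in ("L4", "L5"):
        if name not in structures or not structures[name].any():
            raise LandmarkError(
                f"landmark failure: {name} contour is missing or empty; "
                "the superior field border cannot be placed"
            )
    l4_lo, _ = _world_extent(structures["L4"], geometry, axis=2)
    _, l5_hi = _world_extent(structures["L5"], geometry, axis=2)
    if l5_hi >= l4_lo:
        raise LandmarkError(
            "landmark failure: L4/L5 interspace undetectable "
            f"(top of L5 at z={l5_hi:.1f} mm is not below bottom of L4 at z={l4_lo:.1f} mm)"
        )
    return (l5_hi + l4_lo) / 2.0


def _lowest_obturator_z(structures: StructureSet, geometry: ImageGeometry) -> float:
    """z (mm) of the lowest obturator-foramen pixel in the anterior projection.

    The foramina are the interior holes of the projected pelvis mask.
    """
    proj = project_to_bev(structures["pelvis"], 0, geometry)
    holes = ndimage.binary_fill_holes(proj.pixels) & ~proj.pixels
    if not holes.any():
        raise LandmarkError(
            "landmark failure: no obturator foramen found in the projected pelvis; "
            "the inferior field border cannot be placed"
        )
    v_idx = np.where(holes.any(axis=0))[0]
    return float(geometry.axis_coords(2)[v_idx[0]])


def _rect_aperture(
    angle: int,
    geometry: ImageGeometry,
    u_lo_mm: float,
    u_hi_mm: float,
    z_lo_mm: float,
    z_hi_mm: float,
) -> BEVImage:
    """Rectangular aperture from world-coordinate borders (borders inclusive)."""
    ax = bev_axes(angle)
    u_coords = geometry.axis_coords(ax.u_axis)
    z_coords = geometry.axis_coords(2)
    u_sel = (u_coords >= u_lo_mm) & (u_coords <= u_hi_mm)
    if ax.flip_u:
        u_sel = u_sel[::-1]
    z_sel = (z_coords >= z_lo_mm) & (z_coords <= z_hi_mm)
    pixels = np.ascontiguousarray(u_sel[:, None] & z_sel[None, :])
    spacing = (geometry.spacing[ax.u_axis], geometry.spacing[2])
    return BEVImage(angle, pixels, spacing)


def fourfield_apertures(
    structures: StructureSet,
    geometry: ImageGeometry | None = None,
    params: FourFieldParams | None = None,
) -> dict[int, BEVImage]:
    """Rectangular 4-field-box apertures for gantry angles 0/90/180/270.

    AP/PA fields: superior border at the L4/L5 interspace, inferior border a
    margin below the lowest obturator-foramen pixel, lateral borders at the
    widest projected pelvic brim plus a margin.  Lateral fields share the
    superior/inferior borders; the anterior border sits a margin beyond the
    most anterior pubis pixel and the posterior border covers the configured
    fraction of the projected sacrum's AP extent.
    """
    geometry = geometry or structures.geometry
    params = params or FourFieldParams()
    structures.require("pelvis", "sacrum", "femur_l", "femur_r")
    z_sup = detect_l4l5_interspace(structures, geometry)
    z_inf = _lowest_obturator_z(structures, geometry) - params.inferior_margin_below_obturator

    brim_lo, brim_hi = _world_extent(structures["pelvis"], geometry, axis=0)
    x_lo = brim_lo - params.lateral_brim_margin
    x_hi = brim_hi + params.lateral_brim_margin

    pubis_y, _ = _world_extent(structures["pelvis"], geometry, axis=1)
    y_lo = pubis_y - params.anterior_margin_beyond_pubis
    sac_lo, sac_hi = _world_extent(structures["sacrum"], geometry, axis=1)
    y_hi = sac_lo + params.posterior_sacral_coverage_fraction * (sac_hi - sac_lo)

    apertures: dict[int, BEVImage] = {}
    for angle in (0, 180):
        apertures[angle] = _rect_aperture(angle, geometry, x_lo, x_hi, z_inf, z_sup)
    for angle in (90, 270):
        apertures[angle] = _rect_aperture(angle, geometry, y_lo, y_hi, z_inf, z_sup)
    for angle, ap in apertures.items():
        if ap.is_empty:
            raise PlanGeometryError(f"4-field-box aperture at {angle} deg is empty")
    return apertures


def crt_aperture(
    ptv: np.ndarray,
    gantry_angle: int,
    margin_mm: float = 7.0,
    geometry: ImageGeometry | None = None,
) -> BEVImage:
    """Conformal aperture: projected PTV dilated by a uniform in-plane margin."""
    if geometry is None:
        raise ValueError("geometry is required")
    if margin_mm < 0:
        raise ValueError("aperture margin must be >= 0 mm")
    ptv = geometry.check_mask(ptv)
    if not ptv.any():
        raise PlanGeometryError("cannot build a conformal aperture from an empty PTV")
    return dilate_bev(project_to_bev(ptv, gantry_angle, geometry), margin_mm)


def build_ptv(
    ctv_primary: np.ndarray,
    ctv_nodal: np.ndarray,
    itv_margins: MarginSpec | None = None,
    ptv_margin_mm: float = 5.0,
    geometry: ImageGeometry | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CTV → (ITV, PTV).

    The primary CTV is expanded by the image-guided internal-motion margins
    (10 mm anterior/posterior/superior/inferior, 5 mm lateral by default) and
    united with the nodal CTV; a uniform setup margin (5 mm by default) then
    yields the PTV.
    """
    if geometry is None:
        raise ValueError("geometry is required")
    itv_margins = itv_margins or MarginSpec.embrace_itv()
    ctv_primary = geometry.check_mask(ctv_primary)
    ctv_nodal = geometry.check_mask(ctv_nodal)
    if not ctv_primary.any():
        raise PlanGeometryError("primary CTV is empty; cannot build a PTV")
    itv = expand(ctv_primary, itv_margins, geometry) | ctv_nodal
    ptv = expand(itv, MarginSpec.uniform(ptv_margin_mm), geometry)
    return itv, ptv


def block_region(
    parent: BEVImage,
    hot_projection: BEVImage,
    block_margin_mm: float = 3.0,
) -> BEVImage | None:
    """Subfield aperture: parent minus the dilated hot-region projection.

    Returns ``None`` when nothing of the parent remains (the optimizer then
    skips this beam).
    """
    if not parent.same_frame_as(hot_projection):
        raise ValueError("parent and hot projection must share angle, shape and spacing")
    blocked = dilate_bev(hot_projection, block_margin_mm)
    sub = parent.pixels.astype(bool) & ~blocked.pixels.astype(bool)
    if not sub.any():
        return None
    return parent.copy_with(sub)
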