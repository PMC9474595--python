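"""Simplified photon-dose surrogate for parallel cardinal beams.

This engine is intentionally minimal: it keeps exactly the properties the
planning logic relies on — dose is linear in monitor units (MU) and additive
over beams, falls off with depth like a 6 MV percent-depth-dose curve, and
has a finite Gaussian penumbra at the aperture edge.  Per monitor unit,

``dose(voxel) = dose_per_mu_at_dmax × F(p) × PDD(d)``

where ``F`` is the aperture indicator convolved with a 2D Gaussian of
``penumbra_sigma`` in the BEV plane, ``p`` the voxel's BEV pixel and ``d``
its water-equivalent depth along the (parallel) ray from body entry:

``PDD(d) = (d/d_max)²`` in the build-up region (d < d_max), and
``exp(-mu_lin (d - d_max))`` beyond.

Water-equivalent depth accumulates only over attenuating tissue: an optional
non-attenuating mask (a rectal gas cavity) pauses the depth along rays that
cross it, which raises the dose downstream of the cavity.  Dose is zero
outside the body.  No heterogeneity, scatter kernels, divergence or off-axis
softening are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import ImageGeometry
from .morphology import BEVImage, bev_axes, bev_to_volume

__all__ = ["Beam", "EngineParams", "DoseGrid", "unit_beam_dose", "plan_dose", "beam_travel"]

# Travel direction per gantry angle: (array axis, +1 increasing / -1 decreasing).
_TRAVEL = {0: (1, +1), 180: (1, -1), 90: (0, -1), 270: (0, +1)}


def beam_travel(angle: int) -> tuple[int, int]:
    """(axis, sign) of the beam travel direction for a cardinal gantry angle."""
    return _TRAVEL[int(angle)]


@dataclass
class Beam:
    """One treatment field or field-in-field segment."""

    id: str
    gantry_angle: int
    aperture: BEVImage
    mu: float
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.gantry_angle = int(self.gantry_angle)
        if self.gantry_angle not in _TRAVEL:
            raise ValueError(f"unsupported gantry angle {self.gantry_angle}")
        if self.mu < 0:
            raise ValueError(f"beam {self.id}: mu must be >= 0, got {self.mu}")
        if self.gantry_angle != self.aperture.gantry_angle:
            raise ValueError(f"beam {self.id}: aperture angle mismatch")

    @property
    def is_subfield(self) -> bool:
        return self.parent_id is not None


@dataclass(frozen=True)
class EngineParams:
    """Surrogate 6 MV beam model parameters."""

    mu_lin: float = 0.005            # linear attenuation, 1/mm (~5 %/cm falloff)
    d_max: float = 15.0              # build-up depth, mm
    penumbra_sigma: float = 3.0      # BEV Gaussian sigma, mm
    dose_per_mu_at_dmax: float = 0.01  # Gy/MU on the central axis at d_max

    def __post_init__(self) -> None:
        for name in ("mu_lin", "d_max", "penumbra_sigma", "dose_per_mu_at_dmax"):
            if not getattr(self, name) > 0:
                raise ValueError(f"EngineParams.{name} must be strictly positive")


@dataclass
class DoseGrid:
    """3D dose in Gy on an :class:`ImageGeometry`."""

    values: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"dose shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.values * factor, self.geometry)

    @property
    def max_gy(self) -> float:
        return float(self.values.max())


def _water_depth(
    angle: int, radiological: np.ndarray, geometry: ImageGeometry
) -> np.ndarray:
    """Water-equivalent depth (mm) at each voxel centre along the beam rays."""
    axis, sign = beam_travel(angle)
    rad = radiological.astype(np.float32)
    if sign < 0:
        rad = np.flip(rad, axis=axis)
    cs = np.cumsum(rad, axis=axis, dtype=np.float32)
    depth = (cs - 0.5 * rad) * np.float32(geometry.spacing[axis])
    if sign < 0:
        depth = np.flip(depth, axis=axis)
    return depth


def _pdd(depth: np.ndarray, params: EngineParams) -> np.ndarray:
    d = depth.astype(np.float32)
    buildup = (d / params.d_max) ** 2
    falloff = np.exp(-np.float32(params.mu_lin) * (d - np.float32(params.d_max)))
    return np.where(d < params.d_max, buildup, falloff)


def unit_beam_dose(
    beam: Beam,
    body: np.ndarray,
    geometry: ImageGeometry,
    params: EngineParams | None = None,
    non_attenuating: np.ndarray | None = None,
) -> DoseGrid:
    """Dose grid per 1 MU for one beam.

    ``non_attenuating`` marks voxels (inside the body) that do not accumulate
    water-equivalent depth, e.g. a gas-filled rectum.
    """
    params = params or EngineParams()
    body = geometry.check_mask(body)
    if not body.any():
        raise ValueError("body mask is empty")
    radiological = body
    if non_attenuating is not None:
        radiological = body & ~geometry.check_mask(non_attenuating)

    ax = bev_axes(beam.gantry_angle)
    su, sv = beam.aperture.pixel_spacing
    sigma_px = (params.penumbra_sigma / su, params.penumbra_sigma / sv)
    fluence2d = ndimage.gaussian_filter(
        beam.aperture.pixels.astype(np.float32), sigma=sigma_px, mode="constant"
    )
    fluence = bev_to_volume(beam.aperture.copy_with(fluence2d), geometry)

    depth = _water_depth(beam.gantry_angle, radiological, geometry)
    dose = np.float32(params.dose_per_mu_at_dmax) * fluence * _pdd(depth, params)
    dose[~body] = 0.0
    return DoseGrid(dose, geometry)


def plan_dose(
    beams: list[Beam],
    body: np.ndarray,
    geometry: ImageGeometry,
    params: EngineParams | None = None,
    non_attenuating: np.ndarray | None = None,
    cache: dict | None = None,
) -> DoseGrid:
    """Total dose Σ mu × unit dose over beams.

    ``cache`` (optional dict) memoises unit doses per (angle, aperture), which
    makes repeated evaluation during field-in-field iteration cheap.
    """
    params = params or EngineParams()
    total = np.zeros(geometry.shape, dtype=np.float64)
    for beam in beams:
        if beam.mu == 0:
            continue
        unit = None
        key = None
        if cache is not None:
            key = (beam.gantry_angle, beam.aperture.pixels.tobytes())
            unit = cache.get(key)
        if unit is None:
            unit = unit_beam_dose(beam, body, geometry, params, non_attenuating)
            if cache is not None:
                cache[key] = unit
        total += beam.mu * unit.values.astype(np.float64)
    return DoseGrid(total, geometry)
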