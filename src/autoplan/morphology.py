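"""Millimetre-true 3D mask morphology, beam's-eye-view projection and
connected-component analysis.

Expansion with per-direction margins is realised as binary dilation with an
octant-wise ellipsoidal structuring element built in physical millimetres, so
results are correct on anisotropic grids.  Uniform shrinkage thresholds the
Euclidean distance transform of the mask interior.

Beam's-eye-view (BEV) geometry is parallel (non-divergent): a BEV pixel is
set iff any voxel along its ray is set.  Gantry angles are restricted to the
four cardinal directions; the source sits anterior (0°), patient-left (90°),
posterior (180°) and patient-right (270°).  Opposed angles view the patient
from opposite sides, so their projections are mirror images across the
left-right axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .geometry import ImageGeometry, MarginSpec

__all__ = [
    "BEVImage",
    "HotSpot",
    "bev_axes",
    "expand",
    "shrink",
    "project_to_bev",
    "backproject_aperture",
    "bev_to_volume",
    "dilate_bev",
    "components_above",
    "volume_cc",
]

SUPPORTED_ANGLES = (0, 90, 180, 270)

# 26-connectivity: one contiguous hot region includes diagonal neighbours.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class BEVAxes:
    """How a gantry angle maps the volume onto the BEV pixel plane."""

    collapse_axis: int  # volume axis integrated along the beam
    u_axis: int         # volume axis mapped to BEV rows (transverse)
    flip_u: bool        # True when the view from the source reverses u
    # BEV columns are always the superior axis (z), never flipped.


def bev_axes(angle: int) -> BEVAxes:
    angle = int(angle)
    if angle not in SUPPORTED_ANGLES:
        raise ValueError(f"unsupported gantry angle {angle}; expected one of {SUPPORTED_ANGLES}")
    if angle in (0, 180):      # beam along y; BEV plane = (x, z)
        return BEVAxes(collapse_axis=1, u_axis=0, flip_u=(angle == 180))
    return BEVAxes(collapse_axis=0, u_axis=1, flip_u=(angle == 270))


@dataclass
class BEVImage:
    """2D image in the isocentre plane perpendicular to one cardinal beam.

    ``pixels[u, v]``: u runs along the transverse patient axis for that angle
    (x for anterior/posterior beams, y for lateral beams, possibly flipped so
    the image is as seen from the source), v runs along patient superior z.
    """

    gantry_angle: int
    pixels: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.gantry_angle = int(self.gantry_angle)
        if self.gantry_angle not in SUPPORTED_ANGLES:
            raise ValueError(
                f"unsupported gantry angle {self.gantry_angle}; expected one of {SUPPORTED_ANGLES}"
            )
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("BEV pixels must be a 2D array")
        su, sv = (float(s) for s in self.pixel_spacing)
        if su <= 0 or sv <= 0:
            raise ValueError("pixel_spacing must be positive")
        self.pixel_spacing = (su, sv)

    @property
    def is_empty(self) -> bool:
        return not bool(self.pixels.any())

    def copy_with(self, pixels: np.ndarray) -> "BEVImage":
        return BEVImage(self.gantry_angle, pixels, self.pixel_spacing)

    def same_frame_as(self, other: "BEVImage") -> bool:
        return (
            self.gantry_angle == other.gantry_angle
            and self.pixels.shape == other.pixels.shape
            and self.pixel_spacing == other.pixel_spacing
        )


@dataclass
class HotSpot:
    """One contiguous over-dosed region."""

    volume_cc: float
    max_dose_gy: float
    max_voxel: tuple[int, int, int]
    mask: np.ndarray = field(repr=False)


def _structuring_element(margins: MarginSpec, spacing: tuple[float, float, float]) -> np.ndarray:
    """Octant-wise ellipsoidal structuring element in voxel offsets.

    An offset (ox, oy, oz) in mm is included iff Σ (o_a / m_a±)² ≤ 1, where
    m_a± is the directional margin matching the sign of o_a.  A zero margin
    admits only zero offset along that direction.
    """
    axis_margins = margins.axis_margins()
    radii = [int(np.ceil(max(neg, pos) / spacing[a])) for a, (neg, pos) in enumerate(axis_margins)]
    offsets = [np.arange(-r, r + 1) * spacing[a] for a, r in enumerate(radii)]
    ox = offsets[0][:, None, None]
    oy = offsets[1][None, :, None]
    oz = offsets[2][None, None, :]
    total = np.zeros((len(offsets[0]), len(offsets[1]), len(offsets[2])))
    for a, o in enumerate((ox, oy, oz)):
        neg, pos = axis_margins[a]
        m = np.where(o >= 0, pos, neg)
        term = np.full(np.broadcast_shapes(o.shape, total.shape), np.inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.broadcast_to(o, term.shape) / np.broadcast_to(m, term.shape)
        zero_off = np.broadcast_to(o == 0, term.shape)
        ok = np.broadcast_to(m > 0, term.shape)
        term[ok] = ratio[ok] ** 2
        term[zero_off] = 0.0
        total = total + term
    return total <= 1.0 + 1e-9


def _binary_dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Dilation via FFT convolution (cost independent of element size)."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    if se.size == 1:
        return mask.astype(bool).copy()
    conv = fftconvolve(mask.astype(np.float32), se.astype(np.float32), mode="same")
    return conv >= 0.5


def expand(mask: np.ndarray, margins: MarginSpec, geometry: ImageGeometry) -> np.ndarray:
    """Grow ``mask`` by per-direction physical margins.  Output ⊇ input."""
    mask = geometry.check_mask(mask)
    if margins.max_margin == 0:
        return mask.copy()
    se = _structuring_element(margins, geometry.spacing)
    out = _binary_dilate(mask, se)
    out |= mask  # guard against FFT round-off at isolated voxels
    return out


def shrink(mask: np.ndarray, margin_mm: float, geometry: ImageGeometry) -> np.ndarray:
    """Uniform erosion by ``margin_mm`` in physical mm.  Output ⊆ input."""
    mask = geometry.check_mask(mask)
    margin_mm = float(margin_mm)
    if margin_mm < 0:
        raise ValueError(f"shrink margin must be >= 0 mm, got {margin_mm}")
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    # pad with foreground so the image border is not treated as background
    # (a mask reaching the grid edge represents anatomy beyond the FOV)
    pad = [int(np.ceil(margin_mm / s)) + 1 for s in geometry.spacing]
    padded = np.pad(mask, [(p, p) for p in pad], mode="constant", constant_values=True)
    depth = ndimage.distance_transform_edt(padded, sampling=geometry.spacing)
    depth = depth[pad[0] : -pad[0], pad[1] : -pad[1], pad[2] : -pad[2]]
    # strict: a voxel survives only if strictly deeper than the margin, which
    # keeps shrink(expand(M, m), m) ⊇ M exact on the lattice
    return mask & (depth > margin_mm)


def project_to_bev(mask: np.ndarray, gantry_angle: int, geometry: ImageGeometry) -> BEVImage:
    """Parallel projection along the beam axis onto the BEV plane."""
    mask = geometry.check_mask(mask)
    ax = bev_axes(gantry_angle)
    pixels = mask.any(axis=ax.collapse_axis)  # remaining axes in order -> (u, v=z)
    if ax.flip_u:
        pixels = pixels[::-1, :]
    spacing = (geometry.spacing[ax.u_axis], geometry.spacing[2])
    return BEVImage(gantry_angle, np.ascontiguousarray(pixels), spacing)


def bev_to_volume(image: BEVImage, geometry: ImageGeometry) -> np.ndarray:
    """Broadcast a BEV image (boolean or real) back along its beam axis."""
    ax = bev_axes(image.gantry_angle)
    expected = (geometry.shape[ax.u_axis], geometry.shape[2])
    if image.pixels.shape != expected:
        raise ValueError(
            f"BEV image shape {image.pixels.shape} does not match grid plane {expected} "
            f"for angle {image.gantry_angle}"
        )
    pixels = image.pixels[::-1, :] if ax.flip_u else image.pixels
    if ax.collapse_axis == 1:
        vol = np.broadcast_to(pixels[:, None, :], geometry.shape)
    else:
        vol = np.broadcast_to(pixels[None, :, :], geometry.shape)
    return np.ascontiguousarray(vol)


def backproject_aperture(aperture: BEVImage, geometry: ImageGeometry) -> np.ndarray:
    """3D beam-path mask: voxel set iff its BEV pixel is inside the aperture."""
    return bev_to_volume(aperture.copy_with(aperture.pixels.astype(bool)), geometry)


def dilate_bev(image: BEVImage, margin_mm: float) -> BEVImage:
    """Uniform 2D dilation of a BEV mask by a physical margin (EDT-based)."""
    margin_mm = float(margin_mm)
    if margin_mm < 0:
        raise ValueError("BEV dilation margin must be >= 0 mm")
    pix = image.pixels.astype(bool)
    if margin_mm == 0 or not pix.any():
        return image.copy_with(pix.copy())
    dist = ndimage.distance_transform_edt(~pix, sampling=image.pixel_spacing)
    return image.copy_with(dist <= margin_mm)


def volume_cc(mask: np.ndarray, geometry: ImageGeometry) -> float:
    """Mask volume in cc (voxel count × voxel volume)."""
    mask = geometry.check_mask(mask)
    return float(mask.sum()) * geometry.voxel_volume_cc


def components_above(
    dose_values: np.ndarray,
    geometry: ImageGeometry,
    threshold_gy: float,
    min_volume_cc: float = 0.0,
    search_mask: np.ndarray | None = None,
) -> list[HotSpot]:
    """26-connected components of {dose > threshold}, larger than ``min_volume_cc``.

    Thresholds are strict (">", matching the 'more than' wording of hot-spot
    definitions).  Components are sorted by volume, largest first.
    """
    values = np.asarray(dose_values)
    if values.shape != geometry.shape:
        raise ValueError(f"dose shape {values.shape} does not match geometry {geometry.shape}")
    if threshold_gy <= 0:
        raise ValueError("threshold must be positive")
    above = values > threshold_gy
    if search_mask is not None:
        above &= geometry.check_mask(search_mask)
    if not above.any():
        return []
    labels, n = ndimage.label(above, structure=_CONN26)
    counts = np.bincount(labels.ravel())
    vox_cc = geometry.voxel_volume_cc
    spots: list[HotSpot] = []
    for lab in range(1, n + 1):
        vol = counts[lab] * vox_cc
        if vol <= min_volume_cc:
            continue
        comp = labels == lab
        masked = np.where(comp, values, -np.inf)
        flat_idx = int(np.argmax(masked))
        max_voxel = tuple(int(i) for i in np.unravel_index(flat_idx, values.shape))
        spots.append(
            HotSpot(
                volume_cc=float(vol),
                max_dose_gy=float(values[max_voxel]),
                max_voxel=max_voxel,
                mask=comp,
            )
        )
    spots.sort(key=lambda h: h.volume_cc, reverse=True)
    return spots
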