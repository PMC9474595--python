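"""Voxel-grid geometry and per-direction margin specifications.

Axis convention (fixed throughout the package):

* array axis 0 → patient left  (+x, mm)
* array axis 1 → patient posterior (+y, mm)
* array axis 2 → patient superior (+z, mm)

World coordinates are in millimetres; the centre of voxel ``(i, j, k)`` is at
``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGeometry", "MarginSpec"]


@dataclass(frozen=True)
class ImageGeometry:
    """Regular 3D voxel grid shared by all masks and dose grids of a case."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def world_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) world-coordinate arrays for the full grid."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def index_of(self, axis: int, world_mm: float) -> int:
        """Nearest voxel index along ``axis`` for a world coordinate."""
        idx = round((world_mm - self.origin[axis]) / self.spacing[axis])
        return int(np.clip(idx, 0, self.shape[axis] - 1))

    def affine(self) -> np.ndarray:
        """4x4 index→world affine (for NIfTI export)."""
        aff = np.eye(4)
        for a in range(3):
            aff[a, a] = self.spacing[a]
            aff[a, 3] = self.origin[a]
        return aff

    def check_mask(self, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.shape:
            raise ValueError(f"mask shape {mask.shape} does not match geometry {self.shape}")
        return mask.astype(bool, copy=False)


@dataclass(frozen=True)
class MarginSpec:
    """Per-direction expansion margins in mm (patient directions, all >= 0).

    ``anterior``/``posterior`` act along -y/+y, ``superior``/``inferior``
    along +z/-z and ``left``/``right`` along +x/-x.
    """

    anterior: float = 0.0
    posterior: float = 0.0
    superior: float = 0.0
    inferior: float = 0.0
    left: float = 0.0
    right: float = 0.0

    def __post_init__(self) -> None:
        for name in ("anterior", "posterior", "superior", "inferior", "left", "right"):
            v = float(getattr(self, name))
            if v < 0:
                raise ValueError(f"margin '{name}' must be >= 0 mm, got {v}")
            object.__setattr__(self, name, v)

    @classmethod
    def uniform(cls, margin_mm: float) -> "MarginSpec":
        m = float(margin_mm)
        return cls(m, m, m, m, m, m)

    @classmethod
    def embrace_itv(cls) -> "MarginSpec":
        """Image-guided CTV→ITV margins: 10 mm ant/post/sup/inf, 5 mm lateral."""
        return cls(anterior=10.0, posterior=10.0, superior=10.0, inferior=10.0, left=5.0, right=5.0)

    @property
    def is_uniform(self) -> bool:
        vals = self.as_tuple()
        return all(v == vals[0] for v in vals)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.anterior, self.posterior, self.superior, self.inferior, self.left, self.right)

    def axis_margins(self) -> list[tuple[float, float]]:
        """Margins as [(negative, positive)] per array axis (x, y, z) in mm.

        -x is patient right, +x left; -y anterior, +y posterior;
        -z inferior, +z superior.
        """
        return [
            (self.right, self.left),
            (self.anterior, self.posterior),
            (self.inferior, self.superior),
        ]

    @property
    def max_margin(self) -> float:
        return max(self.as_tuple())
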