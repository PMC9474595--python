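"""Structure sets: named binary masks on one shared voxel grid, with
NIfTI-per-mask + JSON-manifest persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import ImageGeometry

__all__ = ["REQUIRED_STRUCTURES", "StructureSet", "list_required_structures"]

# Canonical structure names, fixed order: bones used for 4-field-box landmark
# detection, organs at risk, and the two clinical target volumes.
REQUIRED_STRUCTURES: tuple[str, ...] = (
    "body",
    "pelvis",
    "sacrum",
    "femur_l",
    "femur_r",
    "L4",
    "L5",
    "bladder",
    "rectum",
    "bowel_space",
    "spinal_cord",
    "ctv_primary",
    "ctv_nodal",
)

BONE_STRUCTURES: tuple[str, ...] = ("pelvis", "sacrum", "femur_l", "femur_r", "L4", "L5")


def list_required_structures() -> list[str]:
    """The 13 canonical structure names, in fixed order."""
    return list(REQUIRED_STRUCTURES)


@dataclass
class StructureSet:
    """Co-registered boolean masks on one :class:`ImageGeometry`.

    ``masks`` holds exactly the required structures; auxiliary masks that are
    not part of the canonical set (e.g. a rectal gas cavity) live in
    ``extras``.  ``metadata`` records analytic facts about the construction
    (phantom parameters, landmark planes) for tests and provenance.
    """

    geometry: ImageGeometry
    masks: dict[str, np.ndarray]
    extras: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in {**self.masks, **self.extras}.items():
            arr = self.geometry.check_mask(m)
            if name in self.masks:
                self.masks[name] = arr
            else:
                self.extras[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        if name in self.masks:
            return self.masks[name]
        return self.extras[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks or name in self.extras

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self or not self[n].any()]
        if missing:
            raise KeyError(f"required structure(s) missing or empty: {', '.join(missing)}")

    @property
    def femurs(self) -> np.ndarray:
        """Pooled left+right femur mask (metrics are reported for 'femurs')."""
        return self.masks["femur_l"] | self.masks["femur_r"]

    # ---------------------------------------------------------------- I/O
    def save(self, directory: str | Path) -> Path:
        """Write one NIfTI per mask plus a JSON manifest; returns the directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = self.geometry.affine()
        all_masks = {**self.masks, **{f"extra__{k}": v for k, v in self.extras.items()}}
        for name, mask in all_masks.items():
            img = nib.Nifti1Image(mask.astype(np.uint8), aff)
            nib.save(img, directory / f"{name}.nii.gz")
        manifest = {
            "format": "autoplan-structures-v1",
            "geometry": {
                "shape": list(self.geometry.shape),
                "spacing": list(self.geometry.spacing),
                "origin": list(self.geometry.origin),
            },
            "structures": list(self.masks.keys()),
            "extras": list(self.extras.keys()),
            "metadata": _jsonable(self.metadata),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "StructureSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        geom = ImageGeometry(
            shape=tuple(manifest["geometry"]["shape"]),
            spacing=tuple(manifest["geometry"]["spacing"]),
            origin=tuple(manifest["geometry"]["origin"]),
        )
        masks = {
            name: np.asarray(nib.load(directory / f"{name}.nii.gz").dataobj).astype(bool)
            for name in manifest["structures"]
        }
        extras = {
            name: np.asarray(nib.load(directory / f"extra__{name}.nii.gz").dataobj).astype(bool)
            for name in manifest.get("extras", [])
        }
        return cls(geometry=geom, masks=masks, extras=extras, metadata=manifest.get("metadata", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
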