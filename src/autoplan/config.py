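"""Run configuration: structured-text (YAML/JSON) parsing with unit-explicit
range gating.

Customization is deliberately fenced: the prescription dose must lie in
43.2–50.4 Gy and the PTV margin in 0.3–1.0 cm, so a typo or misread unit is
rejected with a message naming the field, its value and the accepted range
instead of silently producing a wrong plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .dose import EngineParams
from .errors import ConfigError
from .fif import FIFConfig
from .geometry import MarginSpec
from .phantom import PhantomSpec
from .plans import PTV_MARGIN_RANGE_MM, RX_RANGE_GY

__all__ = ["RunConfig", "validate_config", "load_config_file"]

_TECHNIQUES = ("fourfield", "crt3d")
_PRESETS = ("crt3d", "reviewer2")


@dataclass
class RunConfig:
    """Validated end-to-end pipeline configuration."""

    technique: str = "fourfield"
    rx: float = 45.0
    itv_margins: MarginSpec = field(default_factory=MarginSpec.embrace_itv)
    ptv_margin_mm: float = 5.0
    aperture_margin_mm: float = 7.0
    preset: str = "crt3d"
    fif_enabled: bool = True
    fif: FIFConfig = field(default_factory=FIFConfig)
    engine: EngineParams = field(default_factory=EngineParams)
    phantom: PhantomSpec | None = field(default_factory=PhantomSpec)
    structures_dir: str | None = None
    drop_structures: tuple[str, ...] = ()
    exterior_level: float | None = None  # e.g. 0.70 to suppress spill outside the RHD
    seed: int = 0
    out_dir: str = "autoplan_out"

    def provenance(self) -> dict:
        doc = {
            "technique": self.technique,
            "rx": self.rx,
            "itv_margins": list(self.itv_margins.as_tuple()),
            "ptv_margin_mm": self.ptv_margin_mm,
            "aperture_margin_mm": self.aperture_margin_mm,
            "preset": self.preset,
            "fif_enabled": self.fif_enabled,
            "fif": asdict(self.fif),
            "engine": asdict(self.engine),
            "phantom": asdict(self.phantom) if self.phantom else None,
            "structures_dir": self.structures_dir,
            "drop_structures": list(self.drop_structures),
            "exterior_level": self.exterior_level,
            "seed": self.seed,
        }
        doc["phantom"] = _listify(doc["phantom"])
        return doc


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _reject_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown {section} field(s): {', '.join(sorted(unknown))}; "
            f"accepted fields are {', '.join(sorted(allowed))}"
        )


def validate_config(raw_text: str) -> RunConfig:
    """Parse and range-check a YAML/JSON configuration document."""
    try:
        doc = yaml.safe_load(raw_text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"configuration is not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping of field: value")

    allowed = {
        "technique", "rx", "itv_margins", "ptv_margin_mm", "aperture_margin_mm",
        "preset", "fif_enabled", "fif", "engine", "phantom", "structures_dir",
        "drop_structures", "exterior_level", "seed", "out_dir",
    }
    _reject_unknown("configuration", doc, allowed)

    technique = doc.get("technique", "fourfield")
    if technique not in _TECHNIQUES:
        raise ConfigError(f"technique '{technique}' not recognised; use one of {_TECHNIQUES}")

    rx = float(doc.get("rx", 45.0))
    lo, hi = RX_RANGE_GY
    if not lo <= rx <= hi:
        raise ConfigError(
            f"rx = {rx} Gy is outside the accepted prescription range {lo}-{hi} Gy"
        )

    ptv_margin = float(doc.get("ptv_margin_mm", 5.0))
    mlo, mhi = PTV_MARGIN_RANGE_MM
    if not mlo <= ptv_margin <= mhi:
        raise ConfigError(
            f"ptv_margin_mm = {ptv_margin} mm is outside the accepted PTV margin range "
            f"{mlo / 10:.1f}-{mhi / 10:.1f} cm ({mlo:.0f}-{mhi:.0f} mm)"
        )

    aperture_margin = float(doc.get("aperture_margin_mm", 7.0))
    if not 0 <= aperture_margin <= 20:
        raise ConfigError(
            f"aperture_margin_mm = {aperture_margin} mm is outside the accepted range 0-20 mm"
        )

    preset = doc.get("preset", "crt3d")
    if preset not in _PRESETS:
        raise ConfigError(f"preset '{preset}' not recognised; use one of {_PRESETS}")

    margins_doc = doc.get("itv_margins")
    if margins_doc is None:
        itv_margins = MarginSpec.embrace_itv()
    else:
        _reject_unknown(
            "itv_margins", margins_doc,
            {"anterior", "posterior", "superior", "inferior", "left", "right"},
        )
        try:
            itv_margins = MarginSpec(**{k: float(v) for k, v in margins_doc.items()})
        except ValueError as exc:
            raise ConfigError(f"itv_margins: {exc}") from exc
    if itv_margins.max_margin > 30:
        raise ConfigError(
            f"itv_margins: largest margin {itv_margins.max_margin} mm exceeds the "
            "accepted maximum of 30 mm"
        )

    try:
        fif = FIFConfig(**doc.get("fif", {}))
        engine = EngineParams(**doc.get("engine", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"fif/engine section: {exc}") from exc

    structures_dir = doc.get("structures_dir")
    phantom = None
    if structures_dir is None:
        ph_doc = doc.get("phantom") or {}
        if "voxel_spacing" in ph_doc:
            ph_doc = {**ph_doc, "voxel_spacing": tuple(ph_doc["voxel_spacing"])}
        try:
            phantom = PhantomSpec(**ph_doc)
            phantom.validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"phantom section: {exc}") from exc
    elif not Path(structures_dir).is_dir():
        raise ConfigError(f"structures_dir '{structures_dir}' does not exist")

    exterior_level = doc.get("exterior_level")
    if exterior_level is not None:
        exterior_level = float(exterior_level)
        if not 0 < exterior_level <= 1.1:
            raise ConfigError(
                f"exterior_level = {exterior_level} is outside the accepted range (0, 1.1] "
                "(fraction of rx)"
            )

    return RunConfig(
        technique=technique,
        rx=rx,
        itv_margins=itv_margins,
        ptv_margin_mm=ptv_margin,
        aperture_margin_mm=aperture_margin,
        preset=preset,
        fif_enabled=bool(doc.get("fif_enabled", True)),
        fif=fif,
        engine=engine,
        phantom=phantom,
        structures_dir=structures_dir,
        drop_structures=tuple(doc.get("drop_structures", ())),
        exterior_level=exterior_level,
        seed=int(doc.get("seed", 0)),
        out_dir=str(doc.get("out_dir", "autoplan_out")),
    )


def load_config_file(path: str | Path) -> RunConfig:
    return validate_config(Path(path).read_text())
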