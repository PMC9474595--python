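"""Automated field-in-field (FIF) hot-spot reduction.

Forward-planned FIF: whenever the normalized dose contains a contiguous
region larger than ``min_hot_volume_cc`` above ``hot_threshold`` × rx, a
subfield is carved from the beam that contributes the most dose at the hot
spot's maximum voxel.  The subfield aperture is the parent aperture minus
the dilated projection of the hot spot; monitor units are shifted from the
parent to the subfield by the closed-form amount that brings the hot voxel
down to the threshold (dose is linear in MU, so no line search is needed),
clipped so every segment keeps at least ``min_segment_mu``.  One subfield is
added per iteration, largest hot spot first; the plan is renormalized back
to its recorded coverage once no hot spot remains, and the search repeats
until the renormalized dose is clean or budgets are exhausted.

The same machinery, run with no minimum volume against the region outside
the RHD, removes unwanted dose spill (e.g. everything above 70 % of the
prescription outside the main treatment region).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .apertures import block_region
from .dose import Beam, DoseGrid, EngineParams, plan_dose, unit_beam_dose
from .geometry import ImageGeometry
from .morphology import HotSpot, components_above, project_to_bev
from .plans import Plan, build_rhd, plan_target_mask, renormalize_plan
from .structures import StructureSet

__all__ = ["FIFConfig", "FIFResult", "detect_hot_spots", "select_donor_beam",
           "fif_reduce", "suppress_exterior_dose"]


@dataclass(frozen=True)
class FIFConfig:
    """Configuration of the FIF automation (all dose levels relative to rx)."""

    hot_threshold: float = 1.07        # hot spot: dose > threshold × rx ...
    min_hot_volume_cc: float = 2.0     # ... in a contiguous region larger than this
    min_segment_mu: float = 7.0        # hard floor for every segment's MU
    max_subfields_per_beam: int = 6
    max_iterations: int = 60
    block_margin_mm: float = 3.0       # must exceed the penumbra sigma
    renormalize_after: bool = True     # restore recorded coverage when clean

    def __post_init__(self) -> None:
        if not self.hot_threshold > 1.0:
            raise ValueError("hot_threshold must exceed 1 (it is a fraction of rx)")
        if not self.min_segment_mu > 0:
            raise ValueError("min_segment_mu must be positive")
        if self.max_subfields_per_beam < 1 or self.max_iterations < 1:
            raise ValueError("subfield and iteration budgets must be >= 1")
        if self.min_hot_volume_cc < 0 or self.block_margin_mm < 0:
            raise ValueError("volumes and margins must be >= 0")


@dataclass
class FIFResult:
    plan: Plan
    dose: DoseGrid
    trace: list[dict] = field(default_factory=list)
    status: str = "ok"   # ok | max-iterations | no-eligible-beam
    n_subfields_added: int = 0


def detect_hot_spots(
    dose: DoseGrid,
    rx: float,
    config: FIFConfig | None = None,
    search_mask: np.ndarray | None = None,
) -> list[HotSpot]:
    """Contiguous regions larger than the configured volume above threshold×rx."""
    config = config or FIFConfig()
    return components_above(
        dose.values,
        dose.geometry,
        threshold_gy=config.hot_threshold * rx,
        min_volume_cc=config.min_hot_volume_cc,
        search_mask=search_mask,
    )


def _unit(beam: Beam, body, geometry, params, gas, cache: dict) -> np.ndarray:
    key = (beam.gantry_angle, beam.aperture.pixels.tobytes())
    if key not in cache:
        cache[key] = unit_beam_dose(beam, body, geometry, params, non_attenuating=gas)
    return cache[key].values


def select_donor_beam(
    plan: Plan,
    hotspot: HotSpot,
    unit_doses: dict[str, np.ndarray],
    config: FIFConfig | None = None,
) -> str:
    """Open field contributing the most dose at the hot spot's max voxel.

    Only parents that can still donate (remaining subfield budget or an
    identical-aperture subfield to top up, and MU above the floor) are
    considered; ties break toward the lower beam id.
    """
    config = config or FIFConfig()
    v = hotspot.max_voxel
    best_id, best_contrib = None, -np.inf
    for parent in sorted(plan.parents, key=lambda b: b.id):
        if parent.mu - config.min_segment_mu <= 0:
            continue
        if len(plan.subfields_of(parent.id)) >= config.max_subfields_per_beam:
            continue
        contrib = parent.mu * float(unit_doses[parent.id][v])
        if contrib > best_contrib:
            best_id, best_contrib = parent.id, contrib
    if best_id is None:
        raise LookupError("no eligible donor beam for this hot spot")
    return best_id


def _try_transfer(
    plan: Plan,
    spot: HotSpot,
    threshold_gy: float,
    dose: DoseGrid,
    body,
    geometry: ImageGeometry,
    params: EngineParams,
    gas,
    cache: dict,
    config: FIFConfig,
) -> dict | None:
    """Create/top-up one subfield for the largest hot spot.  Returns a trace
    row, or None when no beam can donate."""
    v = spot.max_voxel
    excess = float(dose.values[v]) - threshold_gy
    if excess <= 0:
        return None

    candidates = []
    for parent in sorted(plan.parents, key=lambda b: b.id):
        u_p = _unit(parent, body, geometry, params, gas, cache)
        candidates.append((parent.mu * float(u_p[v]), parent))
    candidates.sort(key=lambda t: (-t[0], t[1].id))

    for _, parent in candidates:
        headroom = parent.mu - config.min_segment_mu
        if headroom <= 0:
            continue
        hot_proj = project_to_bev(spot.mask, parent.gantry_angle, geometry)
        sub_ap = block_region(parent.aperture, hot_proj, config.block_margin_mm)
        if sub_ap is None:
            continue
        sub_beam = Beam(
            id=f"{parent.id}_sub{len(plan.subfields_of(parent.id)) + 1}",
            gantry_angle=parent.gantry_angle,
            aperture=sub_ap,
            mu=0.0,
            parent_id=parent.id,
        )
        u_p = _unit(parent, body, geometry, params, gas, cache)
        u_s = _unit(sub_beam, body, geometry, params, gas, cache)
        denom = float(u_p[v]) - float(u_s[v])
        if denom <= 1e-12:
            continue
        delta_needed = excess / denom

        # Prefer topping up an existing subfield with the identical aperture:
        # no new segment, so the 7 MU floor only binds on the parent side.
        twin = next(
            (
                s
                for s in plan.subfields_of(parent.id)
                if np.array_equal(s.aperture.pixels, sub_ap.pixels)
            ),
            None,
        )
        if twin is not None:
            delta = min(delta_needed, headroom)
            if delta <= 0:
                continue
            twin.mu += delta
            parent.mu -= delta
            target_id = twin.id
        else:
            if len(plan.subfields_of(parent.id)) >= config.max_subfields_per_beam:
                continue
            if headroom < config.min_segment_mu:
                continue  # cannot give a new segment its minimum MU
            delta = float(np.clip(delta_needed, config.min_segment_mu, headroom))
            sub_beam.mu = delta
            parent.mu -= delta
            plan.beams.append(sub_beam)
            target_id = sub_beam.id
        return {
            "hotspot_cc": spot.volume_cc,
            "hotspot_max_gy": spot.max_dose_gy,
            "donor_beam": parent.id,
            "segment": target_id,
            "delta_mu": delta,
            "new_subfield": twin is None,
        }
    return None


def _reduce(
    plan: Plan,
    structures: StructureSet,
    threshold_gy: float,
    min_volume_cc: float,
    search_mask: np.ndarray | None,
    renorm_target: np.ndarray | None,
    engine_params: EngineParams,
    config: FIFConfig,
) -> FIFResult:
    geometry = structures.geometry
    body = structures["body"]
    gas = structures.extras.get("rectum_gas")
    plan = copy.deepcopy(plan)
    cache: dict = {}
    dose = plan_dose(plan.beams, body, geometry, engine_params, non_attenuating=gas, cache=cache)

    result = FIFResult(plan=plan, dose=dose)
    pending_renorm = False
    iterations = 0
    while True:
        spots = components_above(
            dose.values, geometry, threshold_gy, min_volume_cc, search_mask=search_mask
        )
        if not spots:
            if config.renormalize_after and renorm_target is not None and pending_renorm:
                plan, dose = renormalize_plan(plan, dose, renorm_target)
                pending_renorm = False
                continue  # re-check: scaling may push regions back over threshold
            result.status = "ok"
            break
        if iterations >= config.max_iterations:
            result.status = "max-iterations"
            plan.warnings.append(
                f"FIF stopped after {iterations} iterations with "
                f"{len(spots)} region(s) above {threshold_gy:.2f} Gy remaining"
            )
            break
        row = _try_transfer(
            plan, spots[0], threshold_gy, dose, body, geometry, engine_params, gas, cache, config
        )
        if row is None:
            result.status = "no-eligible-beam"
            plan.warnings.append(
                f"FIF terminated: no eligible donor beam for a "
                f"{spots[0].volume_cc:.2f} cc region above {threshold_gy:.2f} Gy"
            )
            break
        iterations += 1
        row["iteration"] = iterations
        if row["new_subfield"]:
            result.n_subfields_added += 1
        result.trace.append(row)
        pending_renorm = True
        dose = plan_dose(
            plan.beams, body, geometry, engine_params, non_attenuating=gas, cache=cache
        )

    if pending_renorm and config.renormalize_after and renorm_target is not None:
        plan, dose = renormalize_plan(plan, dose, renorm_target)
    result.plan, result.dose = plan, dose
    return result


def fif_reduce(
    plan: Plan,
    structures: StructureSet,
    engine_params: EngineParams | None = None,
    config: FIFConfig | None = None,
) -> FIFResult:
    """Remove hot spots from a normalized plan.

    Hot spots are searched inside the body — restricted to the RHD when the
    plan is normalized on the synthetic PTV, since dose outside the beam
    overlap is handled by the separate exterior-spill rule.  The returned
    plan either has no hot spot per the configuration or carries a recorded
    termination reason; per-angle MU totals are conserved up to the final
    renormalization scale.
    """
    engine_params = engine_params or EngineParams()
    config = config or FIFConfig()
    geometry = structures.geometry
    target = plan_target_mask(plan, structures)
    if plan.normalization.target_structure == "synthetic_ptv":
        search = build_rhd(plan.beams, geometry) & structures["body"]
    else:
        search = structures["body"]
    return _reduce(
        plan,
        structures,
        threshold_gy=config.hot_threshold * plan.rx,
        min_volume_cc=config.min_hot_volume_cc,
        search_mask=search,
        renorm_target=target if config.renormalize_after else None,
        engine_params=engine_params,
        config=config,
    )


def suppress_exterior_dose(
    plan: Plan,
    structures: StructureSet,
    level: float = 0.70,
    engine_params: EngineParams | None = None,
    config: FIFConfig | None = None,
) -> FIFResult:
    """Remove dose spill above ``level`` × rx outside the main treatment
    region (the RHD).  No minimum volume: every offending component counts."""
    engine_params = engine_params or EngineParams()
    config = config or FIFConfig()
    geometry = structures.geometry
    rhd = build_rhd(plan.beams, geometry)
    exterior = structures["body"] & ~rhd
    target = plan_target_mask(plan, structures)
    return _reduce(
        plan,
        structures,
        threshold_gy=level * plan.rx,
        min_volume_cc=0.0,
        search_mask=exterior,
        renorm_target=target if config.renormalize_after else None,
        engine_params=engine_params,
        config=config,
    )
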