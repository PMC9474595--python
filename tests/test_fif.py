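"""Field-in-field optimizer: hot-spot detection, donor selection, MU
accounting, convergence and the exterior-spill rule."""

import copy

import numpy as np
import pytest

from autoplan.dose import Beam, DoseGrid, plan_dose
from autoplan.fif import (
    FIFConfig,
    detect_hot_spots,
    fif_reduce,
    select_donor_beam,
    suppress_exterior_dose,
)
from autoplan.geometry import ImageGeometry
from autoplan.morphology import components_above
from autoplan.plans import (
    build_rhd,
    build_synthetic_ptv,
    coverage,
    renormalize_plan,
)

RX = 45.0


def _engineered_hot_plan(phantom, fourfield):
    """Clean 4-field plan with the anterior field boosted until a contiguous
    region of a few cc exceeds 107 % of rx (verified by construction)."""
    plan, _ = fourfield
    geom = phantom.geometry
    base = fif_reduce(plan, phantom)
    hot_plan = copy.deepcopy(base.plan)
    rhd = build_rhd(hot_plan.beams, geom)
    sptv = build_synthetic_ptv(rhd, 7.0, geom)
    for factor in (1.02, 1.04, 1.06, 1.08, 1.10, 1.15, 1.25):
        trial = copy.deepcopy(hot_plan)
        for b in trial.beams:
            if b.gantry_angle == 0:
                b.mu *= factor
        dose = plan_dose(trial.beams, phantom["body"], geom)
        trial, dose = renormalize_plan(trial, dose, sptv)
        spots = components_above(dose.values, geom, 1.07 * RX, 0.0,
                                 search_mask=phantom["body"] & rhd)
        if spots and spots[0].volume_cc >= 3.5:
            return trial, dose, rhd, sptv, spots[0].volume_cc
    raise AssertionError("could not engineer a hot region")


class TestDetection:
    def test_uniform_dose_at_rx_is_clean(self, mm_grid):
        dose = DoseGrid(np.full(mm_grid.shape, RX), mm_grid)
        assert detect_hot_spots(dose, RX) == []

    def test_constructed_blob_detected_then_cleared_by_threshold(self):
        geom = ImageGeometry((40, 40, 40), (2.5, 2.5, 2.5))
        vals = np.full(geom.shape, RX)
        vals[10:18, 10:18, 10:15] = 1.10 * RX  # 320 voxels = 5 cc
        dose = DoseGrid(vals, geom)
        spots = detect_hot_spots(dose, RX, FIFConfig(hot_threshold=1.07))
        assert len(spots) == 1 and spots[0].volume_cc == pytest.approx(5.0)
        assert detect_hot_spots(dose, RX, FIFConfig(hot_threshold=1.12)) == []


class TestDonorSelection:
    def test_single_beam_plan_selects_it(self, fourfield_coarse, coarse_phantom):
        plan, dose = fourfield_coarse
        plan = copy.deepcopy(plan)
        plan.beams = [plan.beams[0]]
        from autoplan.dose import unit_beam_dose

        unit = {plan.beams[0].id: unit_beam_dose(
            plan.beams[0], coarse_phantom["body"], coarse_phantom.geometry).values}
        spots = detect_hot_spots(dose, RX, FIFConfig(min_hot_volume_cc=0.0),
                                 search_mask=coarse_phantom["body"])
        assert select_donor_beam(plan, spots[0], unit) == plan.beams[0].id

    def test_entrance_hotspot_selects_entering_beam(self, fourfield_coarse,
                                                    coarse_phantom):
        """A hot voxel near the anterior entrance is dominated by the
        anterior field (entrance dose beats exit dose by construction)."""
        from autoplan.dose import unit_beam_dose
        from autoplan.morphology import HotSpot

        plan, _ = fourfield_coarse
        geom = coarse_phantom.geometry
        body = coarse_phantom["body"]
        units = {b.id: unit_beam_dose(b, body, geom).values for b in plan.beams}
        ys = np.where(body[geom.shape[0] // 2, :, 30])[0]
        voxel = (geom.shape[0] // 2, ys[0] + 6, 30)  # ~15 mm deep, anterior
        mask = np.zeros(geom.shape, bool)
        mask[voxel] = True
        spot = HotSpot(0.1, 50.0, voxel, mask)
        assert select_donor_beam(plan, spot, units) == "field_000"


class TestFIFReduce:
    def test_clean_plan_returned_unchanged(self, coarse_phantom):
        """With an unreachable threshold there is nothing to do."""
        from autoplan.plans import assemble_fourfield

        plan, dose = assemble_fourfield(coarse_phantom, rx=RX)
        res = fif_reduce(plan, coarse_phantom,
                         config=FIFConfig(hot_threshold=2.0))
        assert res.status == "ok"
        assert res.n_subfields_added == 0
        assert [b.mu for b in res.plan.beams] == [b.mu for b in plan.beams]

    def test_engineered_hotspot_removed_with_mu_floor(self, default_phantom,
                                                      fourfield_default):
        plan, dose, rhd, sptv, pre_cc = _engineered_hot_plan(
            default_phantom, fourfield_default)
        assert pre_cc >= 3.5  # verified hot before FIF
        res = fif_reduce(plan, default_phantom)
        assert res.status == "ok"
        remaining = components_above(res.dose.values, default_phantom.geometry,
                                     1.07 * RX, 0.0,
                                     search_mask=default_phantom["body"] & rhd)
        largest = remaining[0].volume_cc if remaining else 0.0
        assert largest <= 2.0
        assert min(b.mu for b in res.plan.beams) >= 7.0
        # coverage restored to the normalization record within 0.5 pp
        assert 100 * coverage(res.dose.values, sptv, RX) == pytest.approx(97.0, abs=0.5)

    def test_tighter_threshold_needs_at_least_as_many_subfields(
        self, default_phantom, fourfield_default
    ):
        plan, _ = fourfield_default
        res107 = fif_reduce(plan, default_phantom, config=FIFConfig(hot_threshold=1.07))
        res105 = fif_reduce(plan, default_phantom, config=FIFConfig(hot_threshold=1.05))
        assert res105.n_subfields_added >= res107.n_subfields_added

    def test_per_iteration_max_dose_decrease_and_mu_conservation(
        self, default_phantom, fourfield_default
    ):
        plan, dose, rhd, sptv, _ = _engineered_hot_plan(default_phantom,
                                                        fourfield_default)
        mu_before = copy.deepcopy(plan).mu_per_angle()
        res = fif_reduce(plan, default_phantom,
                         config=FIFConfig(renormalize_after=False))
        assert res.trace, "expected at least one iteration"
        # every recorded iteration targeted a region hotter than threshold
        maxima = [row["hotspot_max_gy"] for row in res.trace]
        assert all(m > 1.07 * RX for m in maxima)
        # without renormalization, per-angle MU totals are conserved exactly
        mu_after = res.plan.mu_per_angle()
        for angle, total in mu_before.items():
            assert mu_after[angle] == pytest.approx(total, rel=1e-9)

    def test_subfields_are_subsets_of_parents(self, default_phantom,
                                              fourfield_default):
        plan, *_ = _engineered_hot_plan(default_phantom, fourfield_default)
        res = fif_reduce(plan, default_phantom)
        for sub in [b for b in res.plan.beams if b.is_subfield]:
            parent = res.plan.beam_by_id(sub.parent_id)
            assert not (sub.aperture.pixels & ~parent.aperture.pixels).any()


class TestExteriorSuppression:
    def test_plan_below_level_unchanged(self, fourfield_coarse, coarse_phantom):
        plan, _ = fourfield_coarse
        res = suppress_exterior_dose(plan, coarse_phantom, level=1.1)
        assert res.n_subfields_added == 0 and res.status == "ok"

    def test_constructed_exterior_streak_is_suppressed(self, default_phantom,
                                                       fourfield_default):
        """AP/PA fields extended 30 mm above the lateral fields' superior
        border create a dose streak outside the RHD.  The exterior-spill rule
        strictly shrinks the volume above 70 % of rx outside the RHD and
        lowers the streak itself, conserving per-angle MU (renormalization
        disabled to make the monotonicity exact)."""
        plan, _ = fourfield_default
        plan = copy.deepcopy(fif_reduce(plan, default_phantom).plan)
        geom = default_phantom.geometry
        for b in plan.parents:
            if b.gantry_angle in (0, 180):
                pix = b.aperture.pixels.copy()
                cols = np.where(pix.any(axis=0))[0]
                rows = np.where(pix.any(axis=1))[0]
                pix[rows[0]: rows[-1] + 1, cols[-1]: cols[-1] + 12] = True  # +30 mm
                b.aperture = b.aperture.copy_with(pix)
        dose = plan_dose(plan.beams, default_phantom["body"], geom)
        # lateral fields still cap the RHD at the old superior border
        sptv = build_synthetic_ptv(build_rhd(plan.beams, geom), 7.0, geom)
        plan, dose = renormalize_plan(plan, dose, sptv)
        exterior = default_phantom["body"] & ~build_rhd(plan.beams, geom)
        streak = exterior.copy()
        streak[:, :, : int(240.0 / geom.spacing[2])] = False
        assert dose.values[streak].max() > 0.70 * RX  # streak exists pre-run
        mu_before = plan.mu_per_angle()
        level = 0.70
        res = suppress_exterior_dose(plan, default_phantom, level=level,
                                     config=FIFConfig(renormalize_after=False))
        assert res.trace  # spill was found and worked on
        assert all(row["hotspot_max_gy"] > level * RX for row in res.trace)
        vol_before = int((dose.values[exterior] > level * RX).sum())
        vol_after = int((res.dose.values[exterior] > level * RX).sum())
        assert vol_after < vol_before
        assert res.dose.values[streak].max() < dose.values[streak].max()
        mu_after = res.plan.mu_per_angle()
        for angle, total in mu_before.items():
            assert mu_after[angle] == pytest.approx(total, rel=1e-9)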