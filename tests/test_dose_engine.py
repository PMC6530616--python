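"""Dose engine: ray tracing, beam geometry, plan summation, calibration."""

import numpy as np
import pytest

from mvctdose import (
    BeamInstance,
    PointOfInterest,
    beam_frame_coords,
    build_static_plan,
    calibrate_output,
    compute_beam_dose,
    compute_plan_dose,
    eval_ocr,
    eval_pdd,
    make_cheese_phantom,
    make_hetero_phantom,
    make_slab_phantom,
    percent_difference,
    point_dose,
    radiological_depth,
    summarize_differences,
)
from mvctdose.dose_engine import DoseGrid, write_dose_nrrd
from mvctdose.phantoms import read_dose_nrrd


class TestRadiologicalDepth:
    def test_uniform_density_equals_geometric_path(self, water_cube):
        # ray enters the 10-cm cube at z=+5 and runs to its center
        d = radiological_depth(water_cube, [0.1, 0.1, 50.0], [0.1, 0.1, 0.1])
        assert d == pytest.approx(4.9, abs=1e-9)

    def test_half_density_halves_the_path(self, water_cube):
        half = make_hetero_phantom(
            water_cube, (water_cube.origin, water_cube.origin + 10.0), 0.5
        )
        d = radiological_depth(half, [0.1, 0.1, 50.0], [0.1, 0.1, 0.1])
        assert d == pytest.approx(4.9 / 2, abs=1e-9)

    def test_two_layer_slab_against_midpoint_rule_oracle(self):
        base = make_slab_phantom(10, 10, 10, spacing=0.5)
        layered = make_hetero_phantom(base, ((-6, -6, 0), (6, 6, 6)), 0.3)
        src = np.array([1.7, -2.3, 40.0])
        dst = np.array([-0.9, 1.1, -3.3])

        # independent oracle: 10^4-step midpoint-rule line integral
        ts = (np.arange(10_000) + 0.5) / 10_000
        pts = src[None, :] + ts[:, None] * (dst - src)[None, :]
        idx = ((pts - layered.origin) / layered.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(layered.dims)), axis=1)
        rho = np.zeros(len(ts))
        rho[inside] = layered.density[tuple(idx[inside].T)]
        oracle = rho.sum() * np.linalg.norm(dst - src) / 10_000

        assert radiological_depth(layered, src, dst) == pytest.approx(oracle, abs=1e-3)

    def test_oblique_diagonal_ray_in_uniform_cube(self, water_cube):
        src = np.array([30.0, 30.0, 30.0])
        dst = np.array([0.25, 0.25, 0.25])
        # cube spans [-5,5]^3; entry at the corner along the diagonal
        entry = np.array([5.0, 5.0, 5.0])
        expected = np.linalg.norm(dst - entry)
        assert radiological_depth(water_cube, src, dst) == pytest.approx(expected, abs=1e-6)

    def test_point_outside_grid_rejected(self, water_cube):
        with pytest.raises(ValueError):
            radiological_depth(water_cube, [0, 0, 50], [0, 0, 50])


class TestBeamFrameCoords:
    def test_isocenter_maps_to_origin_at_sad(self):
        beam = BeamInstance([1.0, 2.0, 3.0], 0.0, 1.0)
        x, y, r = beam_frame_coords([1.0, 2.0, 3.0], beam, 85.0)
        assert (x, y) == (0.0, 0.0)
        assert r == pytest.approx(85.0)

    def test_lateral_offset_at_isocenter_plane_gantry_zero(self):
        beam = BeamInstance([0.0, 0.0, 0.0], 0.0, 1.0)
        x, y, r = beam_frame_coords([2.0, 0.0, 0.0], beam, 85.0)
        assert x == pytest.approx(2.0)
        assert y == pytest.approx(0.0)

    def test_longitudinal_offset_is_gantry_invariant(self):
        for g in (0.0, 45.0, 180.0, 270.0):
            beam = BeamInstance([0.0, 0.0, 0.0], g, 1.0)
            _, y, _ = beam_frame_coords([0.0, 1.3, 0.0], beam, 85.0)
            assert y == pytest.approx(1.3)

    def test_gantry_180_mirrors_gantry_0(self):
        b0 = BeamInstance([0.0, 0.0, 0.0], 0.0, 1.0)
        b180 = BeamInstance([0.0, 0.0, 0.0], 180.0, 1.0)
        # +z displacement seen from below mirrors -z seen from above
        x0, y0, r0 = beam_frame_coords([1.0, 0.0, 2.0], b0, 85.0)
        x1, y1, r1 = beam_frame_coords([-1.0, 0.0, -2.0], b180, 85.0)
        assert x1 == pytest.approx(x0)
        assert y1 == pytest.approx(y0)
        assert r1 == pytest.approx(r0)

    def test_divergence_back_projection(self):
        beam = BeamInstance([0.0, 0.0, 0.0], 0.0, 1.0)
        # point 2 cm lateral at 10 cm downstream of the isocenter plane
        x, _, _ = beam_frame_coords([2.0, 0.0, -10.0], beam, 85.0)
        assert x == pytest.approx(2.0 * 85.0 / 95.0)

    def test_point_at_source_is_singular(self):
        beam = BeamInstance([0.0, 0.0, 0.0], 0.0, 1.0)
        with pytest.raises(ValueError):
            beam_frame_coords([0.0, 0.0, 85.0], beam, 85.0)


class TestBeamDose:
    def test_zero_mu_gives_zero_dose(self, water_cube, model):
        dose = compute_beam_dose(water_cube, BeamInstance([0, 0, 0], 0.0, 0.0), model)
        assert not dose.dose.any()

    def test_mu_linearity(self, water_cube, model):
        d1 = compute_beam_dose(water_cube, BeamInstance([0, 0, 0], 0.0, 1.0), model)
        d2 = compute_beam_dose(water_cube, BeamInstance([0, 0, 0], 0.0, 2.0), model)
        assert np.allclose(d2.dose, 2.0 * d1.dose, rtol=1e-12)

    def test_air_upstream_of_phantom_gets_no_dose(self, model):
        grid = make_slab_phantom(10, 10, 4, spacing=0.5, air_margin=2.0)
        dose = compute_beam_dose(grid, BeamInstance([0, 0, 0], 0.0, 10.0), model)
        # air voxels above the slab (beam side, gantry 0) have no upstream density
        above = grid.density[grid.dims[0] // 2, grid.dims[1] // 2, -1]
        assert above == 0.0
        assert dose.dose[grid.dims[0] // 2, grid.dims[1] // 2, -1] == 0.0
        assert dose.dose.max() > 0.0

    def test_kernel_matches_python_composition_oracle(self, model):
        """The compiled kernel reproduces the factorized model assembled
        from the public geometry and curve operations."""
        grid = make_cheese_phantom(spacing=1.0)
        beam = BeamInstance([0.0, 0.5, 0.0], 30.0, 3.0)
        dose = compute_beam_dose(grid, beam, model)
        src = beam.isocenter + 85.0 * np.array(
            [np.sin(np.radians(30.0)), 0.0, np.cos(np.radians(30.0))]
        )
        ref = float(eval_pdd(model, model.reference_depth))
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            idx = tuple(rng.integers(0, n) for n in grid.dims)
            p = grid.voxel_center(idx)
            x_iso, y_iso, _ = beam_frame_coords(p, beam, 85.0)
            t = float((p - src) @ ((beam.isocenter - src) / 85.0))
            d_rad = radiological_depth(grid, src, p)
            if d_rad <= 0:
                expected = 0.0
            else:
                expected = (
                    beam.mu
                    * model.output_cal
                    * float(eval_pdd(model, d_rad)) / ref
                    * float(eval_ocr(model, x_iso, y_iso))
                    * (85.0 / t) ** 2
                )
            assert dose.dose[idx] == pytest.approx(expected, rel=1e-9, abs=1e-12)
            checked += 1
        assert checked == 200

    def test_central_axis_reference_condition(self, model):
        """At the reference depth on the central axis of a water slab at
        SSD = SAD - d_ref, one MU delivers output_cal cGy (within 0.5%)."""
        from mvctdose import VoxelGrid

        # all-water lattice with a voxel center exactly on the axis at
        # z = 3.5 cm, i.e. 1.5 cm below the surface at z = 5.0
        spacing = 0.2
        grid = VoxelGrid(
            origin=[-10.1, -10.1, -5.0],
            spacing=[spacing] * 3,
            density=np.ones((101, 101, 50)),
        )
        beam = BeamInstance([0.0, 0.0, 3.5], 0.0, 1.0)
        cal_model = model.with_output_cal(0.4)
        dose = compute_beam_dose(grid, beam, cal_model)
        assert np.allclose(grid.voxel_center((50, 50, 42)), [0.0, 0.0, 3.5])
        assert dose.dose[50, 50, 42] == pytest.approx(0.4, rel=0.005)

    def test_off_field_falloff_bounded_by_profile_tail(self, model):
        grid = make_slab_phantom(70, 10, 10, spacing=0.5)
        beam = BeamInstance([0.0, 0.0, 0.0], 0.0, 5.0)
        dose = compute_beam_dose(grid, beam, model)
        central = point_dose(dose, PointOfInterest([0.0, 0.0, 0.0]))
        far = point_dose(dose, PointOfInterest([30.0, 0.0, 0.0]))
        tail = model.ocr_x.values[-1]  # 0 for the synthetic model
        assert central > 0
        assert far <= tail * central + 1e-12


class TestPlanDose:
    def test_plan_equals_brute_force_beam_sum(self, water_cube, model):
        plan = build_static_plan(-1.0, 2.0, couch_speed=0.1, isocenter_interval=0.5)
        total = compute_plan_dose(water_cube, plan, model)
        brute = np.zeros(water_cube.dims)
        for beam in plan.beams:
            brute += compute_beam_dose(water_cube, beam, model).dose
        assert np.allclose(total.dose, brute, rtol=1e-12)

    def test_additive_over_plan_partitions(self, water_cube, model):
        plan = build_static_plan(-1.0, 2.0, couch_speed=0.1, isocenter_interval=0.5)
        front = plan.beams[:2]
        back = plan.beams[2:]
        full = compute_plan_dose(water_cube, plan, model).dose
        parts = np.zeros_like(full)
        for b in front + back:
            parts += compute_beam_dose(water_cube, b, model).dose
        assert np.allclose(full, parts, rtol=1e-12)

    def test_metadata_records_plan_settings(self, water_cube, model):
        plan = build_static_plan(-1.0, 2.0, couch_speed=0.1, isocenter_interval=0.5)
        dose = compute_plan_dose(water_cube, plan, model)
        assert dose.metadata["mode"] == "static"
        assert dose.metadata["beams"] == 4
        assert dose.metadata["total_mu"] == pytest.approx(plan.total_mu)


class TestHeterogeneityClosedForm:
    def test_half_density_slab_matches_water_at_half_depth(self, model):
        """Central-axis dose at geometric depth d in a half-density slab
        equals the water dose at depth d/2 when the evaluation point and
        source geometry are held fixed (radiological-depth engine)."""
        water = make_slab_phantom(20, 20, 10, spacing=0.25)  # surface z=+5
        half = make_hetero_phantom(water, ((-10, -10, -5), (10, 10, 5)), 0.5)
        # same world point z=0: depth 5 cm in the half slab; shift the water
        # slab down 2.5 cm so the same point sits at water depth 2.5 cm
        water_shifted = water.translated([0.0, 0.0, -2.5])
        beam = BeamInstance([0.0, 0.0, 0.0], 0.0, 10.0)
        poi = PointOfInterest([0.0, 0.0, 0.0])
        d_half = point_dose(compute_beam_dose(half, beam, model), poi)
        d_water = point_dose(compute_beam_dose(water_shifted, beam, model), poi)
        assert d_half == pytest.approx(d_water, rel=2e-3)


@pytest.fixture(scope="module")
def reference_setup(model):
    grid = make_cheese_phantom(spacing=0.5, split=True)
    plan = build_static_plan(-3.0, 6.0, couch_speed=0.1, gantry_angle=0.0)
    poi = PointOfInterest([0.0, 0.0, 13.5], averaging_length=0.44)  # 1.5 cm deep
    return grid, plan, poi


class TestCalibration:
    def test_calibrate_then_recompute_reproduces_measurement(self, model, reference_setup):
        grid, plan, poi = reference_setup
        measured = 0.80
        cal = calibrate_output(model, plan, grid, poi, measured)
        dose = compute_plan_dose(grid, plan, cal)
        assert point_dose(dose, poi) == pytest.approx(measured, rel=1e-3)

    def test_measured_equal_to_uncalibrated_gives_unity(self, model, reference_setup):
        grid, plan, poi = reference_setup
        d_cal = point_dose(compute_plan_dose(grid, plan, model.with_output_cal(1.0)), poi)
        cal = calibrate_output(model, plan, grid, poi, d_cal)
        assert cal.output_cal == pytest.approx(1.0, rel=1e-12)

    def test_factor_is_measured_over_calculated(self, model, reference_setup):
        grid, plan, poi = reference_setup
        d_cal = point_dose(compute_plan_dose(grid, plan, model.with_output_cal(1.0)), poi)
        cal = calibrate_output(model, plan, grid, poi, 0.4 * d_cal)
        assert cal.output_cal == pytest.approx(0.4, rel=1e-12)

    def test_poi_outside_beam_raises(self, model, reference_setup):
        grid, plan, _ = reference_setup
        # far beyond the scan range + longitudinal profile extent: no dose
        outside = PointOfInterest([0.0, 8.0, 13.5])
        with pytest.raises(ValueError, match="zero"):
            calibrate_output(model, plan, grid, outside, 0.8)

    def test_non_positive_measurement_rejected(self, model, reference_setup):
        grid, plan, poi = reference_setup
        with pytest.raises(ValueError):
            calibrate_output(model, plan, grid, poi, 0.0)


class TestPointDose:
    def _uniform_dose(self, value=2.5):
        origin = np.array([-5.0, -5.0, -5.0])
        spacing = np.array([0.5, 0.5, 0.5])
        return DoseGrid(origin, spacing, np.full((20, 20, 20), value))

    def test_uniform_field_any_averaging_length(self):
        dose = self._uniform_dose()
        for L in (0.0, 0.44, 2.0):
            assert point_dose(dose, PointOfInterest([0.3, -0.7, 1.1], L)) == pytest.approx(2.5)

    def test_point_sample_at_voxel_center(self):
        dose = self._uniform_dose()
        arr = dose.dose.copy()
        arr[10, 10, 10] = 7.0
        dose = DoseGrid(dose.origin, dose.spacing, arr)
        center = dose.origin + (np.array([10, 10, 10]) + 0.5) * dose.spacing
        assert point_dose(dose, PointOfInterest(center)) == pytest.approx(7.0)

    def test_linear_field_segment_average_equals_center_value(self):
        origin = np.array([-5.0, -5.0, -5.0])
        spacing = np.array([0.5, 0.5, 0.5])
        ys = origin[1] + (np.arange(20) + 0.5) * spacing[1]
        arr = np.broadcast_to(2.0 + 0.3 * ys[None, :, None], (20, 20, 20)).copy()
        dose = DoseGrid(origin, spacing, arr)
        p = [0.0, 1.0, 0.0]
        assert point_dose(dose, PointOfInterest(p, 2.0)) == pytest.approx(
            point_dose(dose, PointOfInterest(p, 0.0))
        )

    def test_segment_outside_lattice_rejected(self):
        dose = self._uniform_dose()
        with pytest.raises(ValueError):
            point_dose(dose, PointOfInterest([0.0, 4.9, 0.0], 1.0))


class TestDifferenceStatistics:
    @pytest.mark.parametrize(
        "calc,meas,expected",
        [(1.70, 1.70, 0.0), (1.0, 0.5, 100.0), (0.92, 0.98, pytest.approx(-6.122, abs=1e-3))],
    )
    def test_percent_difference(self, calc, meas, expected):
        assert percent_difference(calc, meas) == expected

    def test_percent_difference_sign_convention(self):
        assert percent_difference(0.9, 1.0) < 0

    def test_non_positive_measurement_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)

    @pytest.mark.parametrize(
        "diffs,mean,sd",
        [
            ([0.10, -1.85, -2.50], -1.42, 1.35),  # static central points
            ([-1.23, 3.48, 3.24], 1.83, 2.65),  # helical fine pitch
            ([4.0, 4.0], 4.0, 0.0),
        ],
    )
    def test_summary_statistics(self, diffs, mean, sd):
        m, s = summarize_differences(diffs)
        assert m == mean
        assert s == sd

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_differences([])


class TestDoseIO:
    def test_dose_nrrd_roundtrip(self, tmp_path, water_cube, model):
        dose = compute_beam_dose(water_cube, BeamInstance([0, 0, 0], 0.0, 2.0), model)
        write_dose_nrrd(dose, tmp_path / "dose.nrrd")
        arr, origin, spacing = read_dose_nrrd(tmp_path / "dose.nrrd")
        assert np.allclose(arr, dose.dose)
        assert np.allclose(origin, dose.origin)
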