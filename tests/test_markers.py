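"""Plane markers, wall shear stress decomposition, SSR and error accounting."""

import numpy as np
import pytest

from aortassr.fields import FlowWaveform, VelocityField4D
from aortassr.geometry import SectionPlane, local_frame
from aortassr.markers import (
    PlaneSeries,
    error_reduction,
    extract_plane_series,
    flow_displacement,
    flow_rate,
    interpolate_inlet,
    jet_angle,
    max_velocity,
    peak_systole,
    percentage_error,
    scale_invariance_check,
    ssr,
    wall_shear,
)
from aortassr.synthetic import FlowParams, generate_waveform, sample_field

from conftest import MU, analytic_tube_field, interior_vertices, straight_tube

R_M = 0.0125  # tube radius in metres


@pytest.fixture(scope="module")
def geo():
    return straight_tube()


@pytest.fixture(scope="module")
def mid_plane(geo):
    return local_frame(geo, 20.0)


class TestFlowRate:
    def test_uniform_axial_flow(self):
        g = straight_tube(radius_mm=10.0)
        field = analytic_tube_field(g, 0.5, Q_m3_s=np.pi * 1e-4 / 2, parabolic=False)
        # plug flow at 1 m/s through a 10 mm radius lumen
        field.velocities[..., 2] = np.where(field.lumen_mask, 1.0, 0.0)
        q = flow_rate(field, local_frame(g, 20.0))
        assert q.flow_m3_s[0] == pytest.approx(np.pi * 1e-4, rel=0.02)

    def test_reversal_negates_exactly(self, geo, mid_plane):
        field = analytic_tube_field(geo, 0.8)
        q1 = flow_rate(field, mid_plane)
        q2 = flow_rate(field.scaled(-1.0), mid_plane)
        assert q2.flow_ml_s[0] == pytest.approx(-q1.flow_ml_s[0], rel=1e-12)

    def test_poiseuille_recovered(self, geo, mid_plane):
        field = analytic_tube_field(geo, 0.25)
        q = flow_rate(field, mid_plane, spacing_mm=0.25)
        assert q.flow_m3_s[0] == pytest.approx(1e-4, rel=0.01)

    def test_plane_outside_grid(self, geo):
        field = analytic_tube_field(geo, 1.5)
        plane = SectionPlane(
            origin=[500.0, 500.0, 500.0],
            tangent=[0, 0, 1.0],
            in_plane_axes=[[1.0, 0, 0], [0, 1.0, 0]],
            lumen_radius=12.5,
        )
        with pytest.raises(ValueError):
            flow_rate(field, plane)


class TestPeakSystole:
    def test_constant_flagged(self):
        t = np.arange(0, 900, 25.0)
        t_pk, flat = peak_systole(FlowWaveform(times_ms=t, flow_ml_s=np.full_like(t, 5.0)))
        assert flat and t_pk == 0.0

    def test_triangular_peak(self):
        t = np.arange(0, 900, 30.0)
        q = np.maximum(0, 1 - np.abs(t - 120.0) / 60.0)
        t_pk, flat = peak_systole(FlowWaveform(times_ms=t, flow_ml_s=q))
        assert not flat and t_pk == pytest.approx(120.0, abs=1e-9)

    def test_coarse_sampling_near_dense_argmax(self):
        wf_params = FlowParams(systolic_fraction=0.33)
        dense = generate_waveform(wf_params, 3600, 900.0)
        coarse = generate_waveform(wf_params, 36, 900.0)  # 25 ms frames
        t_dense, _ = peak_systole(dense)
        t_coarse, _ = peak_systole(coarse)
        assert abs(t_coarse - t_dense) <= 5.0


class TestJetMarkers:
    def test_axisymmetric_profile_centred(self, geo, mid_plane):
        field = analytic_tube_field(geo, 0.4)
        assert flow_displacement(field, mid_plane, 0.0) <= 0.2

    def test_displacement_fine_grid(self):
        g = straight_tube()
        flow = FlowParams(jet_offset=3.0)
        wf = generate_waveform(flow, 64, 900.0)
        field = sample_field(g, flow, 0.25, frame_times_ms=[150.0], waveform=wf)
        fd = flow_displacement(field, local_frame(g, 20.0), 150.0)
        assert fd == pytest.approx(3.0, abs=0.15)

    def test_angle_trivial_cases(self, geo, mid_plane):
        field = analytic_tube_field(geo, 0.4)
        assert jet_angle(field, mid_plane, 0.0) == pytest.approx(0.0, abs=0.5)
        # 45-degree vector field: v = (w, 0, w)
        tilted = field.scaled(1.0)
        tilted.velocities[..., 0] = tilted.velocities[..., 2]
        assert jet_angle(tilted, mid_plane, 0.0) == pytest.approx(45.0, abs=1.0)

    def test_max_velocity_poiseuille_and_homogeneity(self, geo, mid_plane):
        field = analytic_tube_field(geo, 0.4)
        vmax = max_velocity(field, mid_plane, 0.0)
        assert vmax == pytest.approx(2e-4 / (np.pi * R_M**2), rel=0.02)
        assert max_velocity(field.scaled(2.0), mid_plane, 0.0) == pytest.approx(
            2 * vmax, rel=1e-12
        )

    def test_retrograde_region_ignored(self, geo, mid_plane):
        # retrograde flow confined near the wall must not move the forward max
        field = analytic_tube_field(geo, 0.4)
        fd0 = flow_displacement(field, mid_plane, 0.0)
        mv0 = max_velocity(field, mid_plane, 0.0)
        x, y, _ = np.meshgrid(*field.axes_mm(), indexing="ij")
        ring = (np.hypot(x, y) > 10.0) & field.lumen_mask
        field.velocities[0, ring, 2] = -0.3
        assert flow_displacement(field, mid_plane, 0.0) == pytest.approx(fd0, abs=1e-9)
        assert max_velocity(field, mid_plane, 0.0) == pytest.approx(mv0, rel=1e-9)

    def test_no_forward_flow_errors(self, geo, mid_plane):
        field = analytic_tube_field(geo, 0.8).scaled(-1.0)
        with pytest.raises(ValueError, match="forward"):
            flow_displacement(field, mid_plane, 0.0)


class TestWallShear:
    def test_poiseuille_axial_oracle(self, geo):
        # WSS_ax = 4 mu Q / (pi R^3) = 2.28 Pa for Q = 1e-4 m^3/s, R = 12.5 mm
        field = analytic_tube_field(geo, 0.25)
        w = wall_shear(field, geo, mu=MU, frame=0)
        sel = interior_vertices(geo, w.valid)
        truth = 4 * MU * 1e-4 / (np.pi * R_M**3)
        assert truth == pytest.approx(2.28, abs=0.005)
        assert np.mean(w.wss_axial[sel]) == pytest.approx(truth, rel=0.05)
        assert np.mean(w.wss_axial[sel]) > 0  # fluid drags the wall downstream
        assert np.max(np.abs(w.wss_circ[sel])) < 0.05 * truth

    def test_solid_body_rotation_zero_shear(self, geo):
        field = analytic_tube_field(geo, 0.25, Q_m3_s=0.0, solid_omega=50.0)
        w = wall_shear(field, geo, mu=MU, frame=0)
        sel = interior_vertices(geo, w.valid)
        # mu*omega would be the naive-slope answer; true shear is zero
        assert np.max(np.abs(w.wss_circ[sel])) < 0.1 * MU * 50.0

    def test_quadratic_swirl_oracle(self, geo):
        k = 5e3
        field = analytic_tube_field(geo, 0.25, Q_m3_s=0.0, swirl_k=k)
        w = wall_shear(field, geo, mu=MU, frame=0)
        sel = interior_vertices(geo, w.valid)
        assert np.mean(w.wss_circ[sel]) == pytest.approx(MU * k * R_M, rel=0.05)

    def test_single_depth_error_shrinks_with_refinement(self, geo):
        # the raw (unextrapolated) estimator converges monotonically
        truth = 4 * MU * 1e-4 / (np.pi * R_M**3)
        errs = []
        for h in (0.5, 0.4, 0.25):
            field = analytic_tube_field(geo, h)
            w = wall_shear(field, geo, mu=MU, frame=0, extrapolate=False)
            sel = interior_vertices(geo, w.valid)
            errs.append(abs(np.mean(w.wss_axial[sel]) - truth))
        assert errs[0] > errs[1] > errs[2]

    def test_vertices_without_lumen_support_flagged(self, geo):
        # starve the stencil by cropping the lumen at the inlet end
        field = analytic_tube_field(geo, 1.0)
        field.lumen_mask[:, :, :8] = False
        field.velocities[0, ~field.lumen_mask] = 0.0
        w = wall_shear(field, geo, mu=MU, frame=0)
        assert 0 < w.valid.sum() < len(geo.vertices)
        assert np.all(w.wss_axial[~w.valid] == 0.0)


class TestSSR:
    def test_trivial_ratios(self, geo):
        field = analytic_tube_field(geo, 0.4)
        w = ssr(wall_shear(field, geo, mu=MU, frame=0))
        sel = interior_vertices(geo, w.valid) & ~w.ssr_flagged
        assert np.allclose(w.ssr[sel], 0.0, atol=0.03)

    def test_combined_flow_matches_analytic_ratio(self, geo):
        k = 5e3
        field = analytic_tube_field(geo, 0.25, Q_m3_s=1e-4, swirl_k=k)
        w = ssr(wall_shear(field, geo, mu=MU, frame=0))
        sel = interior_vertices(geo, w.valid) & ~w.ssr_flagged
        truth = (MU * k * R_M) / (4 * MU * 1e-4 / (np.pi * R_M**3))
        assert np.mean(w.ssr[sel]) == pytest.approx(truth, rel=0.05)

    def test_floor_flagging(self, geo):
        field = analytic_tube_field(geo, 0.4, Q_m3_s=0.0, swirl_k=5e3)
        w = ssr(wall_shear(field, geo, mu=MU, frame=0))
        sel = interior_vertices(geo, w.valid)
        assert np.all(w.ssr_flagged[sel])  # zero axial shear everywhere

    def test_scale_invariance(self, geo, mid_plane):
        flow = FlowParams(jet_offset=2.0, helical_strength=4e3)
        wf = generate_waveform(flow, 64, 900.0)
        field = sample_field(straight_tube(), flow, 0.8, frame_times_ms=[150.0], waveform=wf)
        report = scale_invariance_check(field, mid_plane, geo, 2.0, 150.0, mu=MU)
        assert report["max_abs_ssr_diff"] <= 1e-12
        assert report["flow_displacement"][0] == report["flow_displacement"][1]
        assert report["jet_angle"][0] == pytest.approx(report["jet_angle"][1], abs=1e-9)
        assert report["max_velocity"][1] == pytest.approx(
            2 * report["max_velocity"][0], rel=1e-12
        )
        half = scale_invariance_check(field, mid_plane, geo, 0.5, 150.0, mu=MU)
        assert half["max_rel_wss_scale_err"] <= 1e-12


class TestInterpolateInlet:
    def test_resolution_factors(self, geo):
        flow = FlowParams()
        wf = generate_waveform(flow, 36, 900.0)  # 25 ms frames
        field = sample_field(geo, flow, 2.5, frame_times_ms=np.arange(0, 900, 25.0),
                             waveform=wf)
        series = extract_plane_series(field, local_frame(geo, 20.0))
        fine = interpolate_inlet(series, spatial_factor=10, dt_out_ms=10.0)
        assert fine.u_mm[1] - fine.u_mm[0] == pytest.approx(0.25, rel=1e-6)
        assert fine.times_ms[1] - fine.times_ms[0] == pytest.approx(10.0)
        assert len(fine.times_ms) == 90

    def test_linear_field_reproduced_exactly(self, mid_plane):
        # constant in time, linear in space: cubic splines reproduce it
        u = np.arange(-10, 10.5, 2.5)
        t = np.array([0.0, 25.0, 50.0, 75.0])
        uu, vv = np.meshgrid(u, u, indexing="ij")
        vel = np.zeros((len(t), len(u), len(u), 3))
        vel[..., 2] = (0.02 * uu + 0.01 * vv + 0.5)[None]
        mask = np.ones((len(u), len(u)), dtype=bool)
        series = PlaneSeries(plane=mid_plane, u_mm=u, v_mm=u, times_ms=t,
                             velocities=vel, mask=mask)
        fine = interpolate_inlet(series, spatial_factor=4, dt_out_ms=25.0)
        uu_f, vv_f = np.meshgrid(fine.u_mm, fine.v_mm, indexing="ij")
        expect = 0.02 * uu_f + 0.01 * vv_f + 0.5
        assert np.allclose(fine.velocities[0, :, :, 2], expect, atol=1e-9)

    def test_band_limited_rms_error(self, geo):
        # smooth analytic jet (centred: no profile kink inside the probed
        # region): refined series vs direct analytic evaluation
        flow = FlowParams(jet_offset=0.0)
        wf = generate_waveform(flow, 36, 900.0)
        field = sample_field(geo, flow, 2.5, frame_times_ms=np.arange(0, 900, 25.0),
                             waveform=wf)
        plane = local_frame(geo, 20.0)
        series = extract_plane_series(field, plane)
        fine = interpolate_inlet(series, spatial_factor=5, dt_out_ms=10.0)
        from aortassr.synthetic import analytic_velocity

        pts = fine.grid_points()
        inside = np.hypot(*np.meshgrid(fine.u_mm, fine.v_mm, indexing="ij")).ravel() < 9.0
        k = int(np.argmin(np.abs(fine.times_ms - 150.0)))
        v_true = analytic_velocity(geo, flow, pts[inside], fine.times_ms[k], waveform=wf)
        v_int = fine.velocities[k].reshape(-1, 3)[inside]
        peak = np.abs(v_true[:, 2]).max()
        rms = np.sqrt(np.mean((v_int[:, 2] - v_true[:, 2]) ** 2))
        assert rms < 0.02 * peak

    def test_single_frame_rejected(self, mid_plane):
        u = np.arange(-5, 5.5, 2.5)
        series = PlaneSeries(
            plane=mid_plane, u_mm=u, v_mm=u, times_ms=np.array([0.0]),
            velocities=np.zeros((1, len(u), len(u), 3)),
            mask=np.ones((len(u), len(u)), dtype=bool),
        )
        with pytest.raises(ValueError):
            interpolate_inlet(series)


class TestErrorAccounting:
    @pytest.mark.parametrize(
        "sim,ref,mode,expect",
        [(10.0, 10.0, "relative", 0.0), (8.5, 10.0, "relative", 15.0),
         (14.0, 10.0, "absolute", 4.0)],
    )
    def test_percentage_error(self, sim, ref, mode, expect):
        assert percentage_error(sim, ref, mode) == pytest.approx(expect)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percentage_error(1.0, 0.0, "relative")

    def test_error_reduction(self):
        # a drop from 18.5% to 10.0% error is a 45.9% reduction
        assert error_reduction(18.5, 10.0) == pytest.approx(45.9, abs=0.05)
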