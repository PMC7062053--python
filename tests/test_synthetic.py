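"""Synthetic generator: waveforms, analytic fields, MRI degradation, cohorts."""

import numpy as np
import pytest

from aortassr.geometry import local_frame
from aortassr.markers import flow_displacement, flow_rate, jet_angle, max_velocity
from aortassr.synthetic import (
    Case,
    CohortSpec,
    FlowParams,
    acquisition_matrix,
    analytic_velocity,
    degrade_to_mri,
    generate_cohort,
    generate_waveform,
    sample_field,
    womersley_profile,
)

from conftest import straight_tube


class TestWaveform:
    def test_degenerate_shape_constant(self):
        wf = generate_waveform(FlowParams(peak_mean_ratio=1.0), 32, 800.0)
        assert np.allclose(wf.flow_ml_s, 83.0)

    @pytest.mark.parametrize("pm,frac", [(3.5, 0.35), (2.0, 0.25), (4.0, 0.4)])
    def test_cycle_mean_normalised(self, pm, frac):
        params = FlowParams(mean_flow=100.0, peak_mean_ratio=pm, systolic_fraction=frac)
        wf = generate_waveform(params, 48, 900.0)
        assert wf.cycle_mean() == pytest.approx(100.0, rel=1e-3)
        assert np.all(wf.flow_ml_s >= 0)

    def test_peak_in_systolic_fraction(self):
        params = FlowParams(systolic_fraction=0.35)
        wf = generate_waveform(params, 64, 900.0)
        # dense-grid argmax oracle on the periodic interpolant
        t_dense = np.linspace(0, 0.9, 20001)
        q_dense = wf.interp_m3_s(t_dense)
        assert t_dense[np.argmax(q_dense)] <= 0.35 * 0.9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_waveform(FlowParams(peak_mean_ratio=0.9), 32, 900.0)
        with pytest.raises(ValueError):
            generate_waveform(FlowParams(), 4, 900.0)


class TestAnalyticVelocity:
    def test_poiseuille_axis_peak(self, straight_geo):
        flow = FlowParams(peak_mean_ratio=1.0, mean_flow=100.0)
        v = analytic_velocity(straight_geo, flow, [[0.0, 0.0, 20.0]], 0.0)
        R = 0.0125
        assert v[0, 2] == pytest.approx(2 * 100e-6 / (np.pi * R**2), rel=1e-9)
        assert abs(v[0, 0]) < 1e-12 and abs(v[0, 1]) < 1e-12

    def test_no_slip_at_wall(self, straight_geo):
        flow = FlowParams(peak_mean_ratio=1.0)
        v = analytic_velocity(straight_geo, flow, [[12.5, 0.0, 20.0]], 0.0)
        assert np.linalg.norm(v) == 0.0
        # 0.1 um inside the wall: velocity already down to O(u0 * 2 dr / R)
        v_in = analytic_velocity(straight_geo, flow, [[12.4999, 0.0, 20.0]], 0.0)
        assert np.linalg.norm(v_in) < 1e-5

    def test_outside_lumen_zero(self, straight_geo):
        flow = FlowParams(peak_mean_ratio=1.0)
        v = analytic_velocity(straight_geo, flow, [[14.0, 0.0, 20.0], [0, 0, 200.0]], 0.0)
        assert np.all(v == 0)

    def test_womersley_profile_against_sympy_bessel(self):
        # independent high-precision evaluation of the oscillatory pipe-flow
        # Bessel series at alpha = 10
        import sympy as sp

        alpha = 10.0
        lam_s = sp.exp(sp.I * 3 * sp.pi / 4) * alpha
        j0l = sp.besselj(0, lam_s)
        denom = 1 - 2 * sp.besselj(1, lam_s) / (lam_s * j0l)
        for xi in (0.0, 0.3, 0.7, 0.95):
            phi_s = complex(((1 - sp.besselj(0, lam_s * xi) / j0l) / denom).evalf(30))
            phi = womersley_profile(xi, alpha)
            assert abs(phi - phi_s) < 1e-6

    def test_womersley_field_no_slip_and_flow(self, straight_geo):
        flow = FlowParams(womersley_harmonics=3)
        wf = generate_waveform(flow, 64, 900.0)
        v_wall = analytic_velocity(straight_geo, flow, [[12.499, 0, 20.0]], 150.0, waveform=wf)
        assert np.linalg.norm(v_wall) < 5e-3


class TestSampleField:
    def test_inlet_flow_matches_waveform(self, straight_geo):
        flow = FlowParams()
        wf = generate_waveform(flow, 64, 900.0)
        field = sample_field(straight_geo, flow, 0.8, frame_times_ms=[150.0], waveform=wf)
        plane = local_frame(straight_geo, 20.0)
        q = flow_rate(field, plane)
        q_true = wf.interp_m3_s(0.150) * 1e6
        assert q.flow_ml_s[0] == pytest.approx(q_true, rel=0.02)

    def test_masked_voxels_zero(self, straight_geo):
        flow = FlowParams(helical_strength=5e3)
        field = sample_field(straight_geo, flow, 1.5, frame_times_ms=[150.0])
        assert np.all(field.velocities[:, ~field.lumen_mask] == 0)

    def test_interpolation_error_shrinks_with_refinement(self, straight_geo):
        # RMS velocity error at interior probes vs the analytic profile:
        # strictly decreasing over three halvings (the net-flow error is not
        # a clean convergence measure because midpoint-rule boundary errors
        # change sign with grid alignment)
        from aortassr.markers import sample_velocity

        flow = FlowParams(jet_offset=2.0, helical_strength=3e3)
        wf = generate_waveform(flow, 64, 900.0)
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 8.0, 200)
        th = rng.uniform(0, 2 * np.pi, 200)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), rng.uniform(10, 30, 200)])
        v_true = analytic_velocity(straight_geo, flow, pts, 150.0, waveform=wf)
        errs = []
        for sp_mm in (3.2, 1.6, 0.8):
            field = sample_field(straight_geo, flow, sp_mm, frame_times_ms=[150.0], waveform=wf)
            v, _ = sample_velocity(field, pts, 0)
            errs.append(np.sqrt(np.mean((v - v_true) ** 2)))
        assert errs[0] > errs[1] > errs[2]

    def test_bad_spacing(self, straight_geo):
        with pytest.raises(ValueError):
            sample_field(straight_geo, FlowParams(), 0.0, frame_times_ms=[0.0])


class TestDegradeToMri:
    def test_acquisition_matrix_paper_protocol(self):
        assert acquisition_matrix(400.0, 2.5) == 160

    def test_noise_free_average_of_uniform(self, straight_geo):
        field = sample_field(straight_geo, FlowParams(peak_mean_ratio=1.0), 1.25,
                             frame_times_ms=[0.0])
        mri = degrade_to_mri(field, voxel=2.5, dt=25.0, snr=np.inf)
        # interior coarse voxels fully inside the lumen: block average of the
        # smooth profile stays within the fine-field range
        assert mri.lumen_mask.sum() > 0
        assert np.max(np.abs(mri.velocities)) <= np.max(np.abs(field.velocities)) + 1e-12
        assert np.allclose(mri.spacing, 2.5)

    def test_seed_determinism(self, straight_geo):
        field = sample_field(straight_geo, FlowParams(), 1.25, frame_times_ms=[150.0])
        a = degrade_to_mri(field, seed=7)
        b = degrade_to_mri(field, seed=7)
        c = degrade_to_mri(field, seed=8)
        assert np.array_equal(a.velocities, b.velocities)
        assert not np.array_equal(a.velocities, c.velocities)

    def test_wrap_aliasing(self, straight_geo):
        field = sample_field(straight_geo, FlowParams(mean_flow=900.0, peak_mean_ratio=1.0),
                             1.25, frame_times_ms=[0.0])
        assert field.velocities.max() > 2.0  # exceeds the 200 cm/s venc
        mri = degrade_to_mri(field, snr=np.inf, wrap_enabled=True)
        assert mri.velocities.max() <= 2.0
        assert mri.velocities.min() < -1.0  # aliased voxels wrapped negative

    def test_invalid_venc(self, straight_geo):
        field = sample_field(straight_geo, FlowParams(), 2.5, frame_times_ms=[0.0])
        with pytest.raises(ValueError):
            degrade_to_mri(field, venc=0.0)


class TestCohort:
    def test_study_layout(self):
        cases, manifest = generate_cohort(CohortSpec(seed=1))
        assert len(cases) == 12
        assert [c.group for c in cases].count("control") == 4
        assert [c.group for c in cases].count("stable") == 4
        assert [c.group for c in cases].count("dilating") == 4
        assert manifest["seed"] == 1 and len(manifest["cases"]) == 12
        pwvs = [c.target_pwv for c in cases]
        assert min(pwvs) >= 6.2 and max(pwvs) <= 20.7

    def test_minimal_cohort_control_level(self):
        cases, _ = generate_cohort(CohortSpec(n_control=1, n_stable=0, n_dilating=0, seed=0))
        assert len(cases) == 1 and cases[0].group == "control"
        spec = cases[0].spec
        assert cases[0].flow.helical_strength <= 1.2 * spec.helical_base

    def test_group_effect_ordering(self):
        cases, _ = generate_cohort(CohortSpec(seed=5))
        k = {g: np.mean([c.flow.helical_strength for c in cases if c.group == g])
             for g in ("control", "stable", "dilating")}
        assert k["dilating"] > k["stable"] > k["control"]

    def test_seed_reproducibility(self):
        m1 = generate_cohort(CohortSpec(seed=42))[1]
        m2 = generate_cohort(CohortSpec(seed=42))[1]
        assert m1 == m2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(n_control=0, n_stable=0, n_dilating=0))


@pytest.fixture(scope="module")
def jet_case():
    geo = straight_tube(n_stations=27, length_mm=40.0)
    flow = FlowParams(jet_offset=3.0, jet_angle_true=15.0, jet_azimuth_deg=60.0)
    wf = generate_waveform(flow, 64, 900.0)
    fine = sample_field(geo, flow, 0.8, frame_times_ms=[150.0], waveform=wf)
    plane = local_frame(geo, 20.0)
    return geo, flow, fine, plane


class TestGroundTruthRecoverability:
    def test_fine_grid_marker_recovery(self, jet_case):
        _, flow, fine, plane = jet_case
        fd = flow_displacement(fine, plane, 150.0)
        ja = jet_angle(fine, plane, 150.0)
        assert abs(fd - flow.jet_offset) <= 0.4  # half a fine voxel
        assert abs(ja - flow.jet_angle_true) <= 1.0

    def test_degradation_only_removes_information(self, jet_case):
        geo, flow, fine, plane = jet_case
        fd_f = abs(flow_displacement(fine, plane, 150.0) - flow.jet_offset)
        mv_f = max_velocity(fine, plane, 150.0)
        errs_fine, errs_mri, mv_mri = [], [], []
        for seed in range(10):
            mri = degrade_to_mri(fine, voxel=2.4, dt=25.0, seed=seed)
            errs_mri.append(abs(flow_displacement(mri, plane, 150.0) - flow.jet_offset))
            errs_fine.append(fd_f)
            mv_mri.append(max_velocity(mri, plane, 150.0))
        assert np.mean(errs_mri) >= np.mean(errs_fine)
        assert np.mean(errs_mri) <= 1.25  # within half a coarse voxel on average
        # box averaging can only blunt the jet peak
        assert np.mean(mv_mri) <= mv_f
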