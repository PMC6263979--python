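"""Thermoelastic chain tests: heat conduction oracle, strain linearity,
surface-drive behaviour and acoustic wave kinematics."""

import numpy as np
import pytest

from pasim.optical_transport import InvalidParameterError, PulseProfile
from pasim.pa_generation import (
    GRAPHITE,
    LIPOFUNDIN_TM,
    SphericalTargetScene,
    ThermoMechanicalMaterial,
    boundary_acceleration_source,
    heat_source_density,
    peak_pressure,
    run_chain,
    solve_acoustic_wave,
    solve_acoustic_wave_xz,
    solve_heat,
    thermal_strain,
)


@pytest.fixture(scope="module")
def scene():
    return SphericalTargetScene()


@pytest.fixture(scope="module")
def pulse():
    return PulseProfile()


@pytest.fixture(scope="module")
def chain_unit(scene, pulse):
    """Full chain at unit peak fluence, shared across tests."""
    return run_chain(scene, pulse, peak_fluence_w_cm2=1.0)


class TestHeatSource:
    def test_zero_fluence(self):
        assert heat_source_density(0.0, GRAPHITE) == 0.0

    def test_linearity_in_mu_a(self):
        m1 = GRAPHITE
        m2 = ThermoMechanicalMaterial(
            heat_capacity=m1.heat_capacity,
            thermal_conductivity=m1.thermal_conductivity,
            density=m1.density, thermal_expansion=m1.thermal_expansion,
            sound_speed=m1.sound_speed, mu_a=2 * m1.mu_a,
            heat_yield=1.0)
        assert heat_source_density(1.0, m2) == \
            pytest.approx(2 * heat_source_density(1.0, m1))

    def test_negative_fluence_rejected(self):
        with pytest.raises(InvalidParameterError):
            heat_source_density(-1.0, GRAPHITE)


class TestHeat:
    def test_no_drive_stays_at_reference(self, scene, pulse):
        hist = solve_heat(scene, pulse, peak_fluence_w_cm2=0.0)
        assert np.allclose(hist.T, scene.T_ref)

    def test_enthalpy_oracle_insulated(self, pulse):
        """With negligible conduction, the target enthalpy rise equals the
        time-integral of the deposited power (quadrature oracle)."""
        tiny_k = 1e-9
        target = ThermoMechanicalMaterial(
            heat_capacity=709.0, thermal_conductivity=tiny_k, density=2210.0,
            thermal_expansion=7.9e-6, sound_speed=3260.0, mu_a=1e4)
        mediu = ThermoMechanicalMaterial(
            heat_capacity=4180.0, thermal_conductivity=tiny_k, density=1000.0,
            thermal_expansion=7e-5, sound_speed=1480.0, mu_a=0.026)
        scn = SphericalTargetScene(target_material=target,
                                   medium_material=mediu)
        hist = solve_heat(scn, pulse, peak_fluence_w_cm2=1.0)
        r = hist.r_um[hist.target_mask] * 1e-6
        dr = (hist.r_um[1] - hist.r_um[0]) * 1e-6
        vol_cells = ((r + dr / 2) ** 3 - np.maximum(r - dr / 2, 0.0) ** 3) \
            * 4 * np.pi / 3
        rho_c = target.density * target.heat_capacity
        enthalpy = (rho_c * (hist.T[-1, hist.target_mask] - scn.T_ref)
                    * vol_cells).sum()
        q_peak = heat_source_density(1.0, target)
        shape = pulse.shape(hist.t_ns) / pulse.shape(pulse.tau_center)
        v_target = 4 / 3 * np.pi * (scn.target_radius_um * 1e-6) ** 3
        deposited = q_peak * v_target * np.trapezoid(shape, hist.t_ns) * 1e-9
        assert enthalpy == pytest.approx(deposited, rel=0.02)

    def test_peak_after_pulse_center(self, scene, pulse):
        hist = solve_heat(scene, pulse, peak_fluence_w_cm2=1.0)
        t_peak = hist.t_ns[int(np.argmax(hist.T[:, 0]))]
        assert t_peak >= pulse.tau_center

    def test_time_step_precondition(self, scene, pulse):
        with pytest.raises(InvalidParameterError):
            solve_heat(scene, pulse, dt_ns=pulse.tau_p)


class TestStrain:
    def test_reference_temperature(self):
        assert thermal_strain(293.15, 293.15, 7.9e-6) == 0.0

    def test_zero_expansion(self):
        assert thermal_strain(400.0, 293.15, 0.0) == 0.0

    def test_linear_in_delta_t(self):
        s1 = thermal_strain(303.15, 293.15, 7.9e-6)
        s2 = thermal_strain(313.15, 293.15, 7.9e-6)
        assert s2 == pytest.approx(2 * s1)


class TestSurfaceDrive:
    def test_constant_temperature_zero_acceleration(self, scene, pulse):
        hist = solve_heat(scene, pulse, peak_fluence_w_cm2=0.0)
        drive = boundary_acceleration_source(scene, hist)
        assert np.allclose(drive.accel_m_s2, 0.0)

    def test_displacement_linear_in_energy(self, scene):
        d1 = boundary_acceleration_source(
            scene, solve_heat(scene, PulseProfile(Wp=20.0),
                              peak_fluence_w_cm2=1.0))
        d2 = boundary_acceleration_source(
            scene, solve_heat(scene, PulseProfile(Wp=20.0),
                              peak_fluence_w_cm2=2.0))
        assert d2.u_m.max() == pytest.approx(2 * d1.u_m.max(), rel=1e-9)

    def test_acceleration_bipolar(self, chain_unit):
        _, drive = chain_unit
        assert drive.accel_m_s2.max() > 0
        assert drive.accel_m_s2.min() < 0


class TestAcousticWave:
    def test_zero_drive_zero_field(self, scene, pulse):
        hist = solve_heat(scene, pulse, peak_fluence_w_cm2=0.0)
        drive = boundary_acceleration_source(scene, hist)
        field = solve_acoustic_wave(scene, drive)
        assert np.allclose(field.p, 0.0)

    def test_one_over_r_decay(self, chain_unit):
        field, _ = chain_unit
        p1 = peak_pressure(field, 50.0)
        p2 = peak_pressure(field, 100.0)
        assert p1 / p2 == pytest.approx(2.0, rel=0.05)

    def test_wavefront_speed(self, scene, chain_unit):
        """The wavefront radius grows at the medium sound speed."""
        field, _ = chain_unit
        c = scene.medium_material.sound_speed * 1e-3  # um/ns
        radii = []
        t_probe = [80.0, 120.0]
        for t in t_probe:
            it = int(np.argmin(np.abs(field.t_ns - t)))
            prof = np.abs(field.p[it])
            radii.append(field.r_um[int(np.argmax(prof))])
        dr_dt = (radii[1] - radii[0]) / (t_probe[1] - t_probe[0])
        assert dr_dt == pytest.approx(c, abs=1.0)

    def test_causality(self, scene, pulse, chain_unit):
        field, _ = chain_unit
        r_obs = 200.0
        arrival = (r_obs - scene.target_radius_um) / \
            (scene.medium_material.sound_speed * 1e-3)
        early = field.t_ns < arrival - 2 * pulse.tau_p
        trace = field.trace_at(r_obs)
        assert np.max(np.abs(trace[early])) <= 1e-6 * np.max(np.abs(trace))

    def test_linearity_of_chain(self, scene, pulse, chain_unit):
        f1, _ = chain_unit
        f2, _ = run_chain(scene, pulse, peak_fluence_w_cm2=3.0)
        obs = scene.target_radius_um + scene.observation_offset_um
        assert peak_pressure(f2, obs) == \
            pytest.approx(3 * peak_pressure(f1, obs), rel=1e-2)

    def test_radiated_energy_bounded_by_thermal(self, scene, pulse):
        """No gain: the radiated acoustic energy stays far below the
        deposited thermal energy for a realistic drive."""
        flu = 1.0
        hist = solve_heat(scene, pulse, peak_fluence_w_cm2=flu)
        drive = boundary_acceleration_source(scene, hist)
        field = solve_acoustic_wave(scene, drive)
        rho = scene.medium_material.density
        c = scene.medium_material.sound_speed
        r_obs = 250.0
        trace = field.trace_at(r_obs)
        dt = (field.t_ns[1] - field.t_ns[0]) * 1e-9
        area = 4 * np.pi * (r_obs * 1e-6) ** 2
        radiated = (trace**2 / (rho * c)).sum() * dt * area
        q_peak = heat_source_density(flu, scene.target_material)
        v_target = 4 / 3 * np.pi * (scene.target_radius_um * 1e-6) ** 3
        shape = pulse.shape(hist.t_ns) / pulse.shape(pulse.tau_center)
        thermal = q_peak * v_target * np.trapezoid(shape, hist.t_ns) * 1e-9
        assert radiated < thermal

    def test_xz_snapshots_render(self, scene, chain_unit):
        _, drive = chain_unit
        out = solve_acoustic_wave_xz(scene, drive, half_width_um=120.0,
                                     dx_um=3.0,
                                     snapshot_times_ns=np.array([60.0, 90.0]))
        assert len(out["snapshots"]) == 2
        snap = out["snapshots"][90.0]
        assert np.isfinite(snap).all() and np.abs(snap).max() > 0


class TestSceneValidation:
    def test_target_inside_medium(self):
        with pytest.raises(InvalidParameterError):
            SphericalTargetScene(target_radius_um=400.0,
                                 medium_radius_um=300.0)

    def test_material_invariants(self):
        with pytest.raises(InvalidParameterError):
            ThermoMechanicalMaterial(
                heat_capacity=-1.0, thermal_conductivity=1.0, density=1.0,
                thermal_expansion=1.0, sound_speed=1.0, mu_a=1.0)
        with pytest.raises(InvalidParameterError):
            ThermoMechanicalMaterial(
                heat_capacity=1.0, thermal_conductivity=1.0, density=1.0,
                thermal_expansion=1.0, sound_speed=1.0, mu_a=1.0,
                heat_yield=1.5)
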