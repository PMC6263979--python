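"""Diffusion-model unit and property tests: scalar optics operations,
source rasterization, and the finite-difference solver against analytic
oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasim.optical_transport import (
    CartesianGrid,
    IlluminationGeometry,
    InvalidParameterError,
    LIPOFUNDIN_1PCT,
    OpticalMedium,
    PulseProfile,
    build_dual_arm_sources,
    diverged_source_footprint,
    effective_internal_reflection,
    energy_balance,
    fluence_at_depth,
    fluence_depth_profile,
    gaussian_pulse_power,
    reduced_scattering,
    robin_boundary_coefficient,
    solve_fluence,
    sweep_arm_interval,
    transport_mean_free_path,
)
from pasim.optical_transport import _assemble_operator, _cg_solve


class TestScalarOptics:
    @pytest.mark.parametrize("mu_s, g, expected", [
        (100.0, 0.9, 10.0),
        (6.31, 0.0, 6.31),
        (50.0, 1.0, 0.0),
    ])
    def test_reduced_scattering(self, mu_s, g, expected):
        assert reduced_scattering(mu_s, g) == pytest.approx(expected)

    def test_reduced_scattering_domain(self):
        with pytest.raises(InvalidParameterError):
            reduced_scattering(-1.0, 0.5)
        with pytest.raises(InvalidParameterError):
            reduced_scattering(10.0, 1.5)

    @pytest.mark.parametrize("mu_a, musp, expected", [
        (0.026, 6.31, 0.15783),   # 1% Lipofundin: Z0 ~ 1.578 mm
        (1.0, 0.0, 1.0),
        (0.0, 10.0, 0.1),
    ])
    def test_transport_mean_free_path(self, mu_a, musp, expected):
        med = OpticalMedium(mu_a=mu_a, mu_s_prime=musp)
        assert transport_mean_free_path(med) == pytest.approx(expected,
                                                              rel=1e-4)

    def test_transport_mfp_zero_denominator(self):
        med = OpticalMedium(mu_a=0.0, mu_s_prime=0.0)
        with pytest.raises(InvalidParameterError):
            transport_mean_free_path(med)

    def test_effective_internal_reflection_values(self):
        # hand-evaluated four-term polynomial
        assert effective_internal_reflection(1.0) == pytest.approx(0.0017,
                                                                   abs=1e-4)
        assert effective_internal_reflection(1.35) == pytest.approx(0.4897,
                                                                    abs=2e-4)
        assert effective_internal_reflection(1.5) > \
            effective_internal_reflection(1.2)
        with pytest.raises(InvalidParameterError):
            effective_internal_reflection(0.0)

    def test_robin_coefficient_values(self):
        assert robin_boundary_coefficient(1.0) == pytest.approx(0.4992,
                                                                abs=1e-3)
        assert robin_boundary_coefficient(1.35) == pytest.approx(0.1713,
                                                                 abs=1e-3)

    def test_robin_coefficient_reflecting_limit(self):
        # R_eff -> 1 gives a perfectly internally reflecting wall (h -> 0);
        # R_eff grows with n, so h must shrink
        assert robin_boundary_coefficient(3.0) < \
            robin_boundary_coefficient(1.1) < robin_boundary_coefficient(1.0)

    def test_gaussian_pulse_peak_and_tails(self, medium, pulse):
        peak = gaussian_pulse_power(pulse.tau_center, medium, pulse)
        assert gaussian_pulse_power(pulse.tau_center + 1.0, medium,
                                    pulse) < peak
        assert gaussian_pulse_power(pulse.tau_center + 100.0, medium,
                                    pulse) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_pulse_integral(self, medium, pulse):
        # quadrature oracle: integral of the printed form is mu_s' Wp / pi
        t = np.linspace(0.0, 60.0, 20001)
        integral = np.trapezoid(gaussian_pulse_power(t, medium, pulse), t)
        expected = medium.mu_s_prime * pulse.Wp / math.pi
        assert integral == pytest.approx(expected, rel=1e-6)


class TestFootprint:
    def test_paper_inputs(self):
        z0 = 10.0 * transport_mean_free_path(LIPOFUNDIN_1PCT)
        w, h = diverged_source_footprint(16.5, 0.8, 0.22, 1.35, z0)
        assert round(w, 2) == 16.76
        assert round(h, 2) == 1.06

    def test_no_divergence_cases(self):
        assert diverged_source_footprint(16.5, 0.8, 0.0, 1.35, 1.6) == \
            (16.5, 0.8)
        assert diverged_source_footprint(16.5, 0.8, 0.22, 1.35, 0.0) == \
            (16.5, 0.8)

    def test_na_exceeding_index(self):
        with pytest.raises(InvalidParameterError):
            diverged_source_footprint(16.5, 0.8, 1.4, 1.35, 1.6)


class TestSources:
    def test_mirror_symmetry_at_zero_angle(self, medium, coarse_grid):
        geom = IlluminationGeometry(incident_angle_deg=0.0, arm_interval=14.0)
        src = build_dual_arm_sources(geom, medium, coarse_grid)
        nx, ny, nz = coarse_grid.shape
        w = np.zeros(nx * ny * nz)
        np.add.at(w, src.indices, src.weights)
        w3 = w.reshape(coarse_grid.shape)
        assert np.allclose(w3, w3[::-1, :, :])

    def test_full_reflection_kills_source(self, medium, coarse_grid):
        geom = IlluminationGeometry(surface_reflection=0.999999)
        src = build_dual_arm_sources(geom, medium, coarse_grid)
        assert src.injected_fraction == pytest.approx(0.0, abs=1e-5)

    def test_weights_normalized(self, medium, coarse_grid):
        src = build_dual_arm_sources(IlluminationGeometry(), medium,
                                     coarse_grid)
        assert src.weights.sum() == pytest.approx(1.0)
        assert src.star_interval_mm > 14.0  # outward tilt displacement

    def test_footprint_exceeding_grid(self, medium):
        small = CartesianGrid(extents=(10.0, 10.0, 10.0), spacing=1.0)
        with pytest.raises(Exception):
            build_dual_arm_sources(IlluminationGeometry(arm_interval=30.0),
                                   medium, small)


class TestSteadySolver:
    def test_greens_function_oracle(self, medium):
        """Steady solve with a point source matches the infinite-medium
        diffusion Green's function phi = P exp(-mu_eff r)/(4 pi D r) to
        within 5% for r in [2, 15] mm."""
        grid = CartesianGrid(extents=(60.0, 60.0, 60.0), spacing=0.75)
        a_mat = _assemble_operator(medium, grid)
        xs, ys, zs = grid.axis(0), grid.axis(1), grid.axis(2)
        ic = (int(np.argmin(np.abs(xs))), int(np.argmin(np.abs(ys))),
              int(np.argmin(np.abs(zs - 30.0))))
        s = np.zeros(a_mat.shape[0])
        flat = (ic[0] * grid.shape[1] + ic[1]) * grid.shape[2] + ic[2]
        s[flat] = 1.0 / grid.cell_volume
        phi = _cg_solve(a_mat, s).reshape(grid.shape)
        d_mm = medium.diffusion_coefficient * 10.0
        mueff = medium.mu_eff / 10.0
        X, Y, Z = np.meshgrid(xs - xs[ic[0]], ys - ys[ic[1]], zs - zs[ic[2]],
                              indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        sel = (r >= 2.0) & (r <= 15.0)
        analytic = np.exp(-mueff * r[sel]) / (4 * np.pi * d_mm * r[sel])
        rel = np.abs(phi[sel] - analytic) / analytic
        assert rel.max() < 0.05

    def test_energy_balance(self, medium, pulse, coarse_grid, steady_field):
        eb = energy_balance(medium, pulse, IlluminationGeometry(),
                            coarse_grid, steady_field)
        assert abs(eb["relative_error"]) < 1e-6

    def test_non_negative(self, steady_field):
        assert steady_field.values.min() >= 0.0

    def test_linearity_in_pulse_energy(self, medium, coarse_grid):
        geom = IlluminationGeometry()
        f1 = solve_fluence(medium, PulseProfile(Wp=20.0), geom, coarse_grid)
        f2 = solve_fluence(medium, PulseProfile(Wp=40.0), geom, coarse_grid)
        ratio = f2.values[f1.values > 0] / f1.values[f1.values > 0]
        assert np.allclose(ratio, 2.0, rtol=1e-7)

    def test_symmetry_zero_angle(self, medium, pulse, coarse_grid):
        geom = IlluminationGeometry(incident_angle_deg=0.0)
        fld = solve_fluence(medium, pulse, geom, coarse_grid)
        v = fld.values
        assert np.allclose(v, v[::-1, :, :], rtol=1e-6, atol=v.max() * 1e-9)

    def test_absorption_monotonicity(self, pulse, coarse_grid):
        geom = IlluminationGeometry()
        vals = []
        for mu_a in (0.026, 0.26, 1.0):
            med = OpticalMedium(mu_a=mu_a, mu_s_prime=6.31, n=1.35)
            fld = solve_fluence(med, pulse, geom, coarse_grid)
            vals.append(fluence_at_depth(fld, 10.0))
        assert vals[0] > vals[1] > vals[2]

    def test_grid_convergence(self, medium, pulse):
        geom = IlluminationGeometry()
        f2 = fluence_at_depth(
            solve_fluence(medium, pulse, geom, CartesianGrid(spacing=2.0)),
            10.0)
        f1 = fluence_at_depth(
            solve_fluence(medium, pulse, geom, CartesianGrid(spacing=1.0)),
            10.0)
        assert abs(f1 - f2) / f1 < 0.02

    def test_spacing_precondition(self, medium, pulse):
        thick = OpticalMedium(mu_a=10.0, mu_s_prime=500.0, n=1.35)
        with pytest.raises(InvalidParameterError):
            solve_fluence(thick, pulse, IlluminationGeometry(),
                          CartesianGrid(spacing=2.0))


class TestTransient:
    def test_snapshot_peak_follows_pulse(self, medium, pulse):
        grid = CartesianGrid(extents=(60.0, 40.0, 30.0), spacing=2.0)
        times = [10.0, 20.0, 30.0, 40.0, 60.0]
        fld = solve_fluence(medium, pulse, IlluminationGeometry(), grid,
                            mode="transient", times=times)
        peaks = fld.values.reshape(len(times), -1).max(axis=1)
        # diffusion is quasi-static at these scales: the field tracks the
        # 30 ns pulse peak and decays afterwards
        assert np.argmax(peaks) == 2
        assert peaks[-1] < peaks[2]
        assert fld.values.min() >= 0.0

    def test_transient_integral_matches_steady(self, medium, pulse):
        """Time-integrating the transient solution reproduces the steady
        (time-integrated) solve at the observation point."""
        grid = CartesianGrid(extents=(40.0, 40.0, 24.0), spacing=2.0)
        geom = IlluminationGeometry()
        times = np.arange(2.0, 120.0, 2.0)
        trans = solve_fluence(medium, pulse, geom, grid, mode="transient",
                              times=times)
        steady = solve_fluence(medium, pulse, geom, grid, mode="steady")
        ix = trans.values.shape[1] // 2
        iy = trans.values.shape[2] // 2
        iz = int(np.argmin(np.abs(grid.axis(2) - 10.0)))
        integ = np.trapezoid(trans.values[:, ix, iy, iz], times) * 1e-9
        # W/cm^2 * ns -> J/cm^2
        assert integ == pytest.approx(steady.values[ix, iy, iz], rel=0.05)


class TestProfilesAndSweeps:
    def test_profile_non_negative_and_shape(self, steady_field):
        prof = fluence_depth_profile(steady_field)
        assert (prof["fluence"] >= 0).all()
        assert prof["depth_mm"].iloc[-1] <= 20.0

    def test_profile_outside_grid(self, steady_field):
        with pytest.raises(Exception):
            fluence_depth_profile(steady_field, lateral_midpoint_mm=500.0)

    def test_interval_sweep_monotone(self, medium, pulse, coarse_grid):
        table = sweep_arm_interval([10.0, 20.0, 30.0], grid=coarse_grid,
                                   medium=medium, pulse=pulse)
        sub = table[table.index <= 20.0]
        assert (sub[10.0] > sub[20.0]).all()
        assert (sub[20.0] > sub[30.0]).all()

    def test_equal_intervals_identical(self, medium, pulse, coarse_grid):
        table = sweep_arm_interval([14.0, 14.0], grid=coarse_grid,
                                   medium=medium, pulse=pulse)
        np.testing.assert_array_equal(table.iloc[:, 0], table.iloc[:, 1])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(mu_s=st.floats(0.0, 500.0), g=st.floats(-1.0, 1.0))
def test_reduced_scattering_bounds(mu_s, g):
    """0 <= (1-g) mu_s <= 2 mu_s for any admissible anisotropy."""
    out = reduced_scattering(mu_s, g)
    assert 0.0 <= out <= 2.0 * mu_s + 1e-9


@settings(deadline=None, max_examples=25, derandomize=True)
@given(n=st.floats(1.0, 2.0))
def test_robin_coefficient_positive(n):
    assert 0.0 < robin_boundary_coefficient(n) <= 0.5
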