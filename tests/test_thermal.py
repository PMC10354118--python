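"""Radial heat-conduction solver, Abel projection, and design metrics."""

import math

import numpy as np
import pytest
from scipy.special import erf

from mipqpi.core import PhaseProfile, TemperatureField
from mipqpi.materials import CAF2, WATER, Medium
from mipqpi.thermal import (
    HeatingProfile,
    RadialGrid,
    cw_resolution_plateau,
    decay_time,
    default_grid,
    deposited_energy,
    e2_radius,
    estimate_temperature_rise,
    probe_delay_metrics,
    project_phase,
    resolution_degradation,
    saturation_curve,
    saturation_time,
    solve_radial,
    steady_state_sphere,
    thermal_energy,
)

NU = WATER.thermal_diffusivity


def sphere_impulse_exact(r, t, radius):
    """Closed-form free diffusion of a uniformly heated sphere (unit ΔT)."""
    s = math.sqrt(4.0 * NU * t)
    r = np.where(r == 0, 1e-12, r)
    return 0.5 * (erf((radius - r) / s) + erf((radius + r) / s)) - math.sqrt(
        NU * t / math.pi
    ) / r * (np.exp(-((radius - r) ** 2) / (4 * NU * t)) - np.exp(-((radius + r) ** 2) / (4 * NU * t)))


class TestMedium:
    def test_consistent_properties_accepted(self):
        Medium("w", 0.146, 0.618, 997.0, 4247.0)

    def test_inconsistent_triplet_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Medium("bad", 0.146, 0.618, 997.0, 3000.0)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            Medium("bad", -1.0)

    def test_volumetric_heat_capacity_from_ratio(self):
        # K/ν for water lands on the familiar ~4.2 MJ m⁻³ K⁻¹
        assert WATER.volumetric_heat_capacity == pytest.approx(4.23e6, rel=0.01)


class TestSolver:
    def test_gaussian_green_function(self):
        """An impulsive Gaussian initial field spreads as σ² = σ₀² + 2νt
        per axis with energy-conserving amplitude (3-D)."""
        sigma0 = 0.4
        grid = RadialGrid(dr=0.05, n_r=200)  # σ₀ = 8 dr
        r = grid.r
        init = np.exp(-(r**2) / (2 * sigma0**2))
        t = 0.5
        fields = solve_radial(HeatingProfile(mode="impulse", sphere_radius=1.0),
                              WATER, grid, t_end=t, initial_field=init)
        T = fields[-1].values
        sig_t2 = sigma0**2 + 2 * NU * t
        exact = (sigma0**2 / sig_t2) ** 1.5 * np.exp(-(r**2) / (2 * sig_t2))
        assert np.max(np.abs(T - exact)) < 0.01 * exact[0]

    def test_zero_source_stays_zero(self):
        grid = RadialGrid(dr=0.02, n_r=100)
        prof = HeatingProfile(mode="constant_power", pulse_duration=0.1,
                              sphere_radius=0.25, deposition_rate=0.0)
        fields = solve_radial(prof, WATER, grid, t_end=0.2, snapshot_times=[0.05, 0.2])
        for f in fields:
            assert np.all(f.values == 0.0)

    def test_energy_bookkeeping_during_pulse(self):
        """Deposited thermal energy matches the analytic dose within 0.5%."""
        grid = default_grid(0.25, 0.01)
        prof = HeatingProfile(mode="constant_power", pulse_duration=0.01, sphere_radius=0.25)
        fields = solve_radial(prof, WATER, grid, t_end=0.01)
        assert thermal_energy(fields[-1], WATER) == pytest.approx(
            deposited_energy(prof, WATER), rel=0.005
        )

    def test_energy_conserved_without_source(self):
        """Adiabatic boundaries: ∫ρc_pΔT dV constant to 0.1%."""
        grid = RadialGrid(dr=0.05, n_r=150)
        init = np.exp(-(grid.r**2) / (2 * 0.5**2))
        fields = solve_radial(HeatingProfile(mode="impulse", sphere_radius=1.0),
                              WATER, grid, t_end=2.0,
                              snapshot_times=[0.0, 0.5, 1.0, 2.0], initial_field=init)
        energies = [thermal_energy(f, WATER) for f in fields]
        assert max(energies) - min(energies) < 1e-3 * energies[0]

    def test_unstable_dt_rejected_with_bound(self):
        grid = RadialGrid(dr=0.01, n_r=100, dt=1.0)
        with pytest.raises(ValueError, match="stability bound"):
            solve_radial(HeatingProfile(sphere_radius=0.25), WATER, grid, t_end=0.1)

    def test_negative_times_rejected(self):
        grid = RadialGrid(dr=0.01, n_r=100)
        with pytest.raises(ValueError):
            solve_radial(HeatingProfile(sphere_radius=0.25), WATER, grid, t_end=-1.0)
        with pytest.raises(ValueError):
            solve_radial(HeatingProfile(sphere_radius=0.25), WATER, grid,
                         t_end=0.1, snapshot_times=[-0.05])

    def test_constant_energy_center_phase_monotone(self):
        """At fixed pulse energy, longer pulses only lose contrast."""
        centers = []
        for dur in [0.01, 0.05, 0.2]:
            grid = default_grid(0.25, dur)
            prof = HeatingProfile(mode="constant_energy", pulse_duration=dur,
                                  sphere_radius=0.25, reference_duration=0.01)
            fields = solve_radial(prof, WATER, grid, t_end=dur)
            centers.append(project_phase(fields[-1], x=np.array([0.0])).values[0])
        assert centers[0] >= centers[1] >= centers[2]


class TestProjection:
    def test_uniform_sphere_chord_profile(self):
        """At t = 0 the projection is the chord length 2√(R² − x²)."""
        R = 0.25
        grid = RadialGrid(dr=0.0005, n_r=1200)
        T = (grid.r <= R).astype(float)
        prof = project_phase(TemperatureField(grid.r, T, 0.0), wavelength=0.532, dn_dT=1.4e-4)
        inside = grid.r < 0.85 * R
        chord = 2.0 * np.sqrt(R**2 - grid.r[inside] ** 2)
        ratio = prof.values[inside] / (prof.values[0] / (2 * R) * chord)
        assert np.allclose(ratio, 1.0, atol=0.02)
        assert e2_radius(prof) / R == pytest.approx(math.sqrt(1 - math.exp(-4)), abs=0.002)

    def test_zero_field_projects_to_zero(self):
        grid = RadialGrid(dr=0.01, n_r=100)
        prof = project_phase(TemperatureField(grid.r, np.zeros(100), 0.0))
        assert np.all(prof.values == 0.0)

    def test_gaussian_marginalization(self):
        """A radial Gaussian keeps its lateral σ; peak gains √(2π)σ."""
        sigma = 0.5
        grid = RadialGrid(dr=0.01, n_r=600)
        T = np.exp(-grid.r**2 / (2 * sigma**2))
        prof = project_phase(TemperatureField(grid.r, T, 0.0), wavelength=0.532, dn_dT=1.4e-4)
        scale = 2 * math.pi / 0.532 * 1.4e-4 * 1e3
        assert prof.values[0] == pytest.approx(scale * math.sqrt(2 * math.pi) * sigma, rel=1e-3)
        x = grid.r[grid.r < 3 * sigma]
        expected = prof.values[0] * np.exp(-(x**2) / (2 * sigma**2))
        assert np.allclose(prof.values[: x.size], expected, rtol=1e-3)

    def test_nonfinite_field_rejected(self):
        grid = RadialGrid(dr=0.01, n_r=10)
        vals = np.zeros(10)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            TemperatureField(grid.r, vals, 0.0)


class TestE2Radius:
    def test_gaussian_analytic(self):
        x = np.linspace(0, 5, 2000)
        prof = PhaseProfile(x, np.exp(-(x / 1.3) ** 2))
        assert e2_radius(prof) == pytest.approx(1.3 * math.sqrt(2), rel=1e-4)

    def test_monotone_increasing_rejected(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="maximum at x = 0"):
            e2_radius(PhaseProfile(x, x.copy()))

    def test_domain_too_small_rejected(self):
        x = np.linspace(0, 0.5, 50)
        prof = PhaseProfile(x, np.exp(-(x / 2.0) ** 2))  # never reaches e⁻²
        with pytest.raises(ValueError, match="enlarge the domain"):
            e2_radius(prof)


class TestDesignMetrics:
    def test_resolution_short_pulse_limit_is_projection_geometry(self):
        assert resolution_degradation(0.25, 1e-4) == pytest.approx(0.991, abs=0.01)

    def test_resolution_100ns_pulse(self):
        """A 100-ns pulse blurs a 500-nm object by ~1.3×."""
        assert resolution_degradation(0.25, 0.1) == pytest.approx(1.3, rel=0.10)

    def test_probe_delay_against_exact_green_function(self):
        """Solver metrics at 100-ns delay match the closed-form diffusing
        sphere: radius ratio ≈ 1.69, remaining center phase ≈ 0.48."""
        (r0, p0), (r1, p1) = probe_delay_metrics(0.25, [0.0, 0.1])
        assert p0 == 1.0
        assert 0.98 < r0 < 1.06
        assert r1 == pytest.approx(1.685, rel=0.02)
        assert p1 == pytest.approx(0.480, rel=0.02)

    def test_probe_delay_monotone(self):
        metrics = probe_delay_metrics(0.25, [0.0, 0.02, 0.05, 0.1])
        ratios = [m[0] for m in metrics]
        phases = [m[1] for m in metrics]
        assert ratios == sorted(ratios)
        assert phases == sorted(phases, reverse=True)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            probe_delay_metrics(0.25, [-0.01])

    def test_saturation_curve_normalized_and_monotone(self):
        durations = [0.01, 0.03, 0.1, 0.3, 1.0]
        vals = saturation_curve(0.25, durations)
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals) >= 0)

    def test_saturation_slope_decreases(self):
        """The center-phase build-up decelerates monotonically: the
        logarithmic growth rate falls well below the early linear regime."""
        durations = np.geomspace(0.01, 1.0, 7)
        vals = saturation_curve(0.25, list(durations))
        slope = np.diff(np.log(vals)) / np.diff(np.log(durations))
        assert np.all(np.diff(slope) < 0)
        assert slope[-1] < 0.5 < slope[0]

    def test_empty_durations_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve(0.25, [])

    def test_saturation_time_scales_with_radius_squared(self):
        """Self-similarity: t_sat ∝ R² (checked on deliberately
        non-proportional grids)."""
        t_small = saturation_time(0.25, points_per_radius=25)
        t_big = saturation_time(1.0, points_per_radius=18)
        t_huge = saturation_time(5.0, points_per_radius=12)
        assert t_big / t_small == pytest.approx(16.0, rel=0.20)
        assert t_huge / t_small == pytest.approx(400.0, rel=0.20)

    def test_cw_limit_matches_steady_state_analytics(self):
        """Steady uniformly heated sphere: e⁻² radius → (2/3)e² R in an
        unbounded bath; ~4.8 with the default finite sink distance."""
        grid = RadialGrid(dr=0.01, n_r=round(2000 * 0.25 / 0.01) + 1)  # bath at 2000 R
        far = cw_resolution_plateau(0.25, grid=grid)
        assert far == pytest.approx((2.0 / 3.0) * math.e**2, rel=0.01)
        assert cw_resolution_plateau(0.25) == pytest.approx(4.8, rel=0.05)

    def test_steady_state_matches_conduction_analytics(self):
        """Outside the sphere the steady solution is ∝ 1/r − 1/r_max."""
        field = steady_state_sphere(0.25)
        r = field.coordinates
        sel = (r > 0.5) & (r < 0.9 * r[-1])
        model = 1.0 / r[sel] - 1.0 / r[-1]
        scale = field.values[sel][0] / model[0]
        assert np.allclose(field.values[sel], scale * model, rtol=1e-3)

    def test_grid_refinement_stable(self):
        """Halving dr moves the headline pulse/delay metrics by < 3%."""
        coarse = RadialGrid(dr=0.01, n_r=501)
        fine = RadialGrid(dr=0.005, n_r=1001)
        res = [resolution_degradation(0.25, 0.1, grid=g) for g in (coarse, fine)]
        assert abs(res[1] - res[0]) < 0.03 * res[0]
        met = [probe_delay_metrics(0.25, [0.1], grid=g)[0] for g in (coarse, fine)]
        assert abs(met[1][0] - met[0][0]) < 0.03 * met[0][0]
        assert abs(met[1][1] - met[0][1]) < 0.03 * met[0][1]


class TestDecayTimeAndTemperature:
    def test_exponential_crossings(self):
        t = np.linspace(0, 300, 3001)
        y = np.exp(-t / 50.0)
        assert decay_time(t, y) == pytest.approx(50.0, rel=1e-3)
        assert decay_time(t, y, level=0.03) == pytest.approx(-50.0 * math.log(0.03), rel=1e-3)

    def test_flat_curve_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError, match="never crosses"):
            decay_time(t, np.ones_like(t))

    def test_temperature_rise_closed_form(self):
        # Δθ λ / (2π |dn/dT| d): the ~8 K lipid-droplet and ~2 K nucleolus regimes
        assert estimate_temperature_rise(40.0, 3.0) == pytest.approx(8.07, abs=0.05)
        assert estimate_temperature_rise(14.0, 5.0) == pytest.approx(1.70, abs=0.02)
        assert estimate_temperature_rise(0.0, 3.0) == 0.0

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            estimate_temperature_rise(10.0, 0.0)


class TestHeatingProfile:
    def test_exactly_one_geometry(self):
        with pytest.raises(ValueError):
            HeatingProfile(sphere_radius=0.25, lateral_fwhm=91.0)
        with pytest.raises(ValueError):
            HeatingProfile()

    def test_constant_energy_rate_scales_inversely(self):
        p = HeatingProfile(mode="constant_energy", pulse_duration=0.1,
                           sphere_radius=0.25, deposition_rate=2.0, reference_duration=0.01)
        assert p.rate() == pytest.approx(0.2)
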