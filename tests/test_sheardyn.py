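import numpy as np
import pytest

from oculotamp import equilibrium as E, metrics as M, sheardyn as S
from oculotamp.saccade import SaccadeWave


@pytest.fixture(scope="module")
def wave():
    return SaccadeWave()


@pytest.fixture(scope="module")
def standing_state(eye_geom):
    return E.solve_flat_interface(eye_geom, 0.9, E.Posture.standing())


class TestStokesClosedForms:
    def test_step_history_matches_rayleigh_solution(self):
        dt = 1e-3
        t = np.arange(0, 0.1 + dt / 2, dt)
        u = np.full_like(t, 0.1)
        u[0] = 0.0
        tau = S.stokes_wall_stress(u, dt, viscosity=1.0, density=980.0)
        exact = 0.1 * np.sqrt(980.0 / (np.pi * 0.1))
        assert tau[-1] == pytest.approx(exact, rel=0.01)

    def test_oscillating_plate_amplitude_and_phase(self):
        dt = 1e-3
        omega = 2 * np.pi * 20.0
        t = np.arange(0, 1.0 + dt / 2, dt)
        u = 0.1 * np.sin(omega * t)
        tau = S.stokes_wall_stress(u, dt, viscosity=1.0, density=980.0)
        tail = slice(len(t) // 2, None)
        assert np.abs(tau[tail]).max() == pytest.approx(0.1 * np.sqrt(980.0 * omega), rel=0.01)
        # 45 deg phase lead: tau peaks a eighth-period before u
        tu = t[tail][np.argmax(u[tail])]
        ttau = t[tail][np.argmax(tau[tail])]
        period = 2 * np.pi / omega
        lead = (tu - ttau) % period
        assert lead == pytest.approx(period / 8, abs=dt)

    def test_zero_history_gives_zero_stress(self):
        tau = S.stokes_wall_stress(np.zeros(100), 1e-3, 1.0, 980.0)
        assert np.all(tau == 0.0)

    def test_history_must_start_at_rest(self):
        with pytest.raises(ValueError):
            S.stokes_wall_stress(np.ones(10), 1e-3, 1.0, 980.0)

    def test_convolution_converges_in_time_step(self, wave):
        peaks = []
        for dt in (1e-3, 5e-4):
            t = wave.time_grid(dt)
            u = 0.012 * np.radians(wave.omega(t))
            peaks.append(np.abs(S.stokes_wall_stress(u, dt, 1.0, 980.0)).max())
        assert abs(peaks[0] / peaks[1] - 1) < 0.01


class TestFiniteSlab:
    def test_long_time_step_response_approaches_couette(self):
        dt, gap = 1e-3, 0.002
        t = np.arange(0, 3.0 + dt / 2, dt)
        u = np.full_like(t, 0.05)
        u[0] = 0.0
        tau = S.finite_slab_wall_stress(u, dt, viscosity=1.0, density=980.0, gap=gap)
        # stress-free far wall: steady state is a uniform moving block, tau -> 0,
        # after an initial transient matching the half-space response
        assert tau[-1] < 0.05 * tau[1:50].max()

    def test_early_times_match_half_space(self):
        dt, gap = 1e-4, 0.01
        t = np.arange(0, 0.01 + dt / 2, dt)
        u = np.full_like(t, 0.1)
        u[0] = 0.0
        slab = S.finite_slab_wall_stress(u, dt, 1.0, 980.0, gap, n_cells=400)
        half = S.stokes_wall_stress(u, dt, 1.0, 980.0)
        assert slab[-1] == pytest.approx(half[-1], rel=0.05)


class TestWallKinematics:
    def test_axis_vertices_do_not_move(self, eye_geom):
        # rotate about an axis through an actual mesh vertex
        v0 = eye_geom.vertices[7] / np.linalg.norm(eye_geom.vertices[7])
        wave = SaccadeWave(rotation_axis=v0)
        times, speed, direction = S.wall_velocity_series(eye_geom, wave)
        assert np.all(speed[:, 7] < 1e-12)
        assert np.allclose(direction[7], 0.0)
        assert np.allclose(speed[0], 0.0)

    def test_equatorial_speed_at_peak_velocity(self, eye_geom, wave):
        times, speed, _ = S.wall_velocity_series(eye_geom, wave)
        # furthest vertex from the axis: d = 12 mm, omega_peak = 547 deg/s
        expected = np.radians(547.0) * 0.012
        assert speed.max() == pytest.approx(expected, rel=0.01)

    def test_directions_are_unit_tangents(self, eye_geom, wave):
        _, _, direction = S.wall_velocity_series(eye_geom, wave)
        norms = np.linalg.norm(direction, axis=1)
        moving = norms > 0
        assert np.allclose(norms[moving], 1.0)
        radial = np.einsum("ij,ij->i", direction, eye_geom.vertices)
        assert np.abs(radial).max() < 1e-6 * eye_geom.eye_radius


class TestSaccadeShear:
    def test_viscosity_scaling_is_sqrt_rho_mu(self, eye_geom, wave, standing_state):
        s1 = S.simulate_saccade_shear(eye_geom, standing_state, E.SIO1000, wave)
        s5 = S.simulate_saccade_shear(eye_geom, standing_state, E.SIO5000, wave)
        oil = standing_state.wet
        ratio = s5.magnitude()[:, oil] - np.sqrt(5.0) * s1.magnitude()[:, oil]
        assert np.abs(ratio).max() < 1e-9
        assert np.all(s5.magnitude() >= s1.magnitude() - 1e-12)

    def test_region_maximum_is_bimodal(self, eye_geom, wave, standing_state):
        series = S.simulate_saccade_shear(eye_geom, standing_state, E.SIO1000, wave)
        im = M.imss(series, eye_geom, "retina")
        assert M.count_local_maxima(im) == 2

    def test_aqueous_contact_keeps_stress_negligible(self, eye_geom, wave, standing_state):
        series = S.simulate_saccade_shear(eye_geom, standing_state, E.SIO1000, wave)
        aqueous_max = series.magnitude()[:, ~standing_state.wet].max()
        oil_max = series.magnitude()[:, standing_state.wet].max()
        assert aqueous_max < 0.05 * oil_max

    def test_traction_opposes_wall_during_acceleration(self, eye_geom, wave, standing_state):
        series = S.simulate_saccade_shear(eye_geom, standing_state, E.SIO1000, wave)
        early = (series.times > 0) & (series.times < 0.02)
        moving = series.magnitude().max(axis=0) > 0
        assert np.all(series.signed_magnitude[early][:, moving] <= 1e-15)

    def test_mismatched_state_rejected(self, eye_geom, wave):
        from oculotamp import geometry as G

        small = G.segment_regions(G.build_chamber_mesh(lens_radius=None, lens_center_offset=None, resolution=2.5))
        state = E.solve_flat_interface(small, 0.9, E.Posture.standing())
        with pytest.raises(S.ConsistencyError):
            S.simulate_saccade_shear(eye_geom, state, E.SIO1000, wave)

    def test_magnitudes_in_tens_of_pascal_decade(self, eye_geom, wave, standing_state):
        series = S.simulate_saccade_shear(eye_geom, standing_state, E.SIO5000, wave)
        peak = M.imss(series, eye_geom, "retina").max()
        assert 10.0 < peak < 100.0
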