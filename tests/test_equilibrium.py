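import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from oculotamp import equilibrium as E


def whole_wall_coverage(state, geom):
    df = E.contact_fractions(state, geom)
    rows = df[(df.hemisphere == "both") & (df.region != "retina")]
    return rows.wetted_area_mm2.sum() / rows.area_mm2.sum()


def cap_ratio_oracle(fill):
    # independent route to x in x^2 (3 - x) = 4 fill: polynomial roots
    roots = np.roots([-1.0, 3.0, 0.0, -4.0 * fill])
    real = roots[np.isreal(roots)].real
    return float(real[(real > 0) & (real < 2)][0])


class TestFluidPair:
    def test_defaults_are_physical(self):
        f = E.FluidPair()
        assert f.density_difference == 20.0
        assert f.receding_contact_angle <= f.static_contact_angle <= f.advancing_contact_angle

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(oil_density=1100.0),  # heavier than aqueous
            dict(static_contact_angle=5.0),  # below receding
            dict(contact_angle_convention="sideways"),
        ],
    )
    def test_invalid_pairs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            E.FluidPair(**kwargs)


class TestPosture:
    def test_gravity_directions(self):
        assert np.allclose(E.Posture.standing().gravity, [0, -1, 0])
        assert np.allclose(E.Posture.supine().gravity, [0, 0, -1])
        t = E.Posture.tilt45().gravity
        assert np.allclose(t, -np.array([0, 1, 1]) / np.sqrt(2))
        with pytest.raises(ValueError):
            E.Posture.from_name("prone")


class TestFlatInterface:
    def test_half_fill_covers_half_the_sphere(self, sphere_geom):
        state = E.solve_flat_interface(sphere_geom, 0.5, E.Posture.standing())
        assert whole_wall_coverage(state, sphere_geom) == pytest.approx(0.5, abs=0.005)

    def test_ninety_percent_fill_matches_cap_oracle(self, sphere_geom):
        state = E.solve_flat_interface(sphere_geom, 0.9, E.Posture.tilt45())
        assert whole_wall_coverage(state, sphere_geom) == pytest.approx(
            cap_ratio_oracle(0.9) / 2, abs=0.005
        )

    def test_full_fill_wets_everything(self, sphere_geom):
        state = E.solve_flat_interface(sphere_geom, 1.0, E.Posture.standing())
        assert state.wet.all()
        df = E.contact_fractions(state, sphere_geom)
        assert np.allclose(df.fraction, 1.0)

    @pytest.mark.parametrize("fill", [0.0, -0.2, 1.5])
    def test_fill_domain_errors(self, sphere_geom, fill):
        with pytest.raises(ValueError):
            E.solve_flat_interface(sphere_geom, fill, E.Posture.standing())

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(fill=st.floats(0.05, 0.99))
    def test_volume_conservation_property(self, sphere_geom, fill):
        state = E.solve_flat_interface(sphere_geom, fill, E.Posture.supine(), tol=1e-4)
        assert abs(state.fill_achieved - fill) < 1e-4

    def test_contact_fractions_monotone_in_fill(self, eye_geom):
        prev = None
        for fill in (0.8, 0.85, 0.9, 0.95, 1.0):
            df = E.contact_fractions(E.solve_flat_interface(eye_geom, fill, E.Posture.standing()), eye_geom)
            cur = df.set_index(["region", "hemisphere"]).fraction
            if prev is not None:
                assert np.all(cur.values >= prev.values - 5e-3)
            prev = cur


class TestAnalyticSupineCoverage:
    @pytest.mark.parametrize(
        "fill,expected",
        [(0.5, 0.5), (0.8, 0.7129), (0.9, 0.8042)],
    )
    def test_flat_variant_against_cubic_oracle(self, fill, expected):
        got = E.analytic_supine_coverage(fill)
        assert got == pytest.approx(cap_ratio_oracle(fill) / 2, abs=1e-9)
        assert got == pytest.approx(expected, abs=5e-4)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(fill=st.floats(0.05, 0.95))
    def test_flat_variant_monotone(self, fill):
        assert E.analytic_supine_coverage(fill + 0.04) > E.analytic_supine_coverage(fill)

    def test_capillary_variant_reduces_coverage(self):
        for fill in (0.8, 0.9):
            assert E.analytic_supine_coverage(fill, contact_angle=16.2) < E.analytic_supine_coverage(fill)

    def test_capillary_variant_approaches_flat_as_tension_vanishes(self):
        near_flat = E.analytic_supine_coverage(0.9, contact_angle=16.2, interfacial_tension=1e-7)
        assert near_flat == pytest.approx(E.analytic_supine_coverage(0.9), abs=0.01)


class TestCapillaryInterface:
    def test_vanishing_tension_recovers_flat_solution(self, sphere_geom):
        fluids = E.FluidPair(interfacial_tension=1e-7)
        cap = E.solve_capillary_interface(sphere_geom, 0.85, E.Posture.supine(), fluids)
        flat = E.solve_flat_interface(sphere_geom, 0.85, E.Posture.supine())
        assert whole_wall_coverage(cap, sphere_geom) == pytest.approx(
            whole_wall_coverage(flat, sphere_geom), abs=0.01
        )

    def test_supine_matches_axisymmetric_oracle(self, sphere_geom):
        state = E.solve_capillary_interface(sphere_geom, 0.9, E.Posture.supine())
        oracle = E.analytic_supine_coverage(0.9, contact_angle=16.2)
        assert whole_wall_coverage(state, sphere_geom) == pytest.approx(oracle, abs=0.048)

    def test_equilibrium_independent_of_oil_viscosity(self, sphere_geom):
        s1 = E.solve_capillary_interface(sphere_geom, 0.85, E.Posture.standing(), E.SIO1000)
        s5 = E.solve_capillary_interface(sphere_geom, 0.85, E.Posture.standing(), E.SIO5000)
        assert np.array_equal(s1.wet, s5.wet)

    def test_solved_interface_is_contact_line_admissible(self, sphere_geom):
        state = E.solve_capillary_interface(sphere_geom, 0.9, E.Posture.supine())
        cos_app = E._apparent_contact_cosine(state.interface, sphere_geom.eye_radius)
        assert cos_app is not None
        assert np.degrees(np.arccos(cos_app)) >= 16.2 - 0.1

    def test_uppermost_point_wet_and_volume_met(self, eye_geom):
        state = E.solve_capillary_interface(eye_geom, 0.8, E.Posture.standing())
        top = np.argmax(eye_geom.vertices @ E.Posture.standing().up)
        assert state.wet[top]
        assert abs(state.fill_achieved - 0.8) < 5e-4

    def test_supine_macula_dry_at_95_percent(self, sphere_geom):
        state = E.solve_capillary_interface(sphere_geom, 0.95, E.Posture.supine())
        assert E.contact_fraction(state, sphere_geom, "macula") == 0.0


class TestContactFractions:
    def test_all_wet_state_gives_unit_fractions(self, eye_geom):
        state = E.solve_flat_interface(eye_geom, 1.0, E.Posture.supine())
        df = E.contact_fractions(state, eye_geom)
        assert np.allclose(df.fraction, 1.0)

    def test_missing_region_raises(self, sphere_geom):
        state = E.solve_flat_interface(sphere_geom, 0.9, E.Posture.standing())
        with pytest.raises(E.DegenerateRegionError):
            E.contact_fraction(state, sphere_geom, "lens")

    def test_retina_aggregate_is_area_weighted_mean_of_parts(self, eye_geom):
        state = E.solve_flat_interface(eye_geom, 0.85, E.Posture.standing())
        df = E.contact_fractions(state, eye_geom).set_index(["region", "hemisphere"])
        parts = df.loc[[("macula", "both"), ("postequatorial", "both"), ("preequatorial", "both")]]
        agg = parts.wetted_area_mm2.sum() / parts.area_mm2.sum()
        assert df.loc[("retina", "both")].fraction == pytest.approx(agg, abs=1e-12)
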