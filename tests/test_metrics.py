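import numpy as np
import pytest

from oculotamp import fixtures as F, geometry as G, metrics as M
from oculotamp.sheardyn import TractionSeries


@pytest.fixture(scope="module")
def separable(sphere_geom):
    return F.separable_traction_fixture(sphere_geom, seed=11)


def make_series(times, signed, direction, viscosity=1.0):
    nv = signed.shape[1]
    return TractionSeries(
        times=np.asarray(times, dtype=float),
        signed_magnitude=np.asarray(signed, dtype=float),
        direction=np.asarray(direction, dtype=float),
        viscosity=np.full(nv, float(viscosity)),
        density=np.full(nv, 980.0),
    )


class TestSeparableOracle:
    @pytest.mark.parametrize("region", ["macula", "postequatorial", "preequatorial", "retina"])
    @pytest.mark.parametrize("hemisphere", ["both", "superior", "inferior"])
    def test_all_region_metrics_match_closed_forms(self, sphere_geom, separable, region, hemisphere):
        series, oracle = separable
        np.testing.assert_allclose(
            M.imss(series, sphere_geom, region, hemisphere), oracle["imss"][(region, hemisphere)], rtol=1e-12
        )
        np.testing.assert_allclose(
            M.arss(series, sphere_geom, region, hemisphere), oracle["arss"][(region, hemisphere)], rtol=1e-10
        )
        np.testing.assert_allclose(
            M.imsr(series, sphere_geom, region, hemisphere), oracle["imsr"][(region, hemisphere)], rtol=1e-12
        )

    def test_pointwise_fields_match_closed_forms(self, sphere_geom, separable):
        series, oracle = separable
        np.testing.assert_allclose(M.pmss(series), oracle["pmss"], rtol=1e-12)
        np.testing.assert_allclose(M.vass(series, G.SUPERIOR), oracle["vass"], rtol=1e-10, atol=1e-15)


class TestElementaryProperties:
    def test_mean_never_exceeds_max(self, sphere_geom, separable):
        series, _ = separable
        assert np.all(
            M.arss(series, sphere_geom, "retina") <= M.imss(series, sphere_geom, "retina") + 1e-12
        )

    def test_imss_of_union_is_max_of_parts(self, sphere_geom, separable):
        series, _ = separable
        parts = np.maximum.reduce(
            [M.imss(series, sphere_geom, r) for r in ("macula", "postequatorial", "preequatorial")]
        )
        np.testing.assert_allclose(M.imss(series, sphere_geom, "retina"), parts, rtol=1e-12)

    def test_pmss_invariant_under_time_reordering(self, sphere_geom, separable, rng):
        series, _ = separable
        perm = rng.permutation(len(series.times))
        shuffled = make_series(series.times, series.signed_magnitude[perm], series.direction)
        np.testing.assert_array_equal(M.pmss(series), M.pmss(shuffled))

    def test_single_sample_pmss_is_that_sample(self, sphere_geom, separable):
        series, _ = separable
        single = make_series(series.times[:1], series.signed_magnitude[:1], series.direction)
        np.testing.assert_array_equal(M.pmss(single), np.abs(series.signed_magnitude[0]))

    def test_uniform_field_arss_equals_the_value(self, sphere_geom):
        nv = len(sphere_geom.vertices)
        series = make_series([0.0, 1e-3], np.full((2, nv), 3.5), np.tile([0, 1, 0.0], (nv, 1)))
        np.testing.assert_allclose(M.arss(series, sphere_geom, "retina"), 3.5, rtol=1e-12)


class TestVass:
    def test_horizontal_tractions_average_to_zero(self, sphere_geom):
        nv = len(sphere_geom.vertices)
        series = make_series([0.0, 1e-3], np.ones((2, nv)), np.tile([1, 0, 0.0], (nv, 1)))
        np.testing.assert_allclose(M.vass(series, vertical_axis=[0, 1, 0]), 0.0, atol=1e-15)

    def test_constant_vertical_traction_recovered(self, sphere_geom):
        nv = len(sphere_geom.vertices)
        series = make_series([0.0, 1e-3, 2e-3], np.full((3, nv), 2.0), np.tile([0, 1, 0.0], (nv, 1)))
        np.testing.assert_allclose(M.vass(series, vertical_axis=[0, 1, 0]), 2.0, rtol=1e-12)

    def test_time_antisymmetric_traction_cancels(self, sphere_geom):
        nv = len(sphere_geom.vertices)
        signed = np.vstack([np.ones(nv), -np.ones(nv)])
        series = make_series([0.0, 1e-3], signed, np.tile([0, 1, 0.0], (nv, 1)))
        np.testing.assert_allclose(M.vass(series, vertical_axis=[0, 1, 0]), 0.0, atol=1e-15)


class TestShearRate:
    def test_rate_is_stress_over_viscosity(self, sphere_geom, separable):
        series, _ = separable
        np.testing.assert_allclose(
            M.imsr(series, sphere_geom, "retina"),
            M.imss(series, sphere_geom, "retina") / series.viscosity[0],
            rtol=1e-12,
        )

    def test_five_fold_viscosity_gives_fifth_rate(self, sphere_geom, separable):
        series, _ = separable
        thick = make_series(series.times, series.signed_magnitude, series.direction, viscosity=5.0)
        np.testing.assert_allclose(
            M.imsr(series, sphere_geom, "retina"), 5.0 * M.imsr(thick, sphere_geom, "retina"), rtol=1e-12
        )

    def test_convention_factor_two_halves_rates(self, sphere_geom, separable):
        series, _ = separable
        np.testing.assert_allclose(
            M.imsr(series, sphere_geom, "retina", rate_convention_factor=2.0),
            0.5 * M.imsr(series, sphere_geom, "retina"),
            rtol=1e-12,
        )

    def test_zero_viscosity_rejected(self, sphere_geom, separable):
        series, _ = separable
        bad = make_series(series.times, series.signed_magnitude, series.direction, viscosity=0.0)
        with pytest.raises(ValueError):
            M.imsr(bad, sphere_geom, "retina")


class TestErrorsAndBundle:
    def test_empty_region_rejected(self, sphere_geom, separable):
        series, _ = separable
        with pytest.raises(M.EmptyRegionError):
            M.imss(series, sphere_geom, "lens")

    def test_bundle_is_tidy_and_complete(self, sphere_geom, separable):
        series, _ = separable
        bundle = M.compute_metrics(series, sphere_geom, vertical_axis=[0, 1, 0])
        regions = set(bundle.timeseries.region)
        assert "retina" in regions and "lens" not in regions
        assert set(bundle.timeseries.columns) == {
            "time_s", "region", "hemisphere", "imss_Pa", "arss_Pa", "imsr_per_s",
        }
        assert len(bundle.pmss) == len(sphere_geom.vertices)
        assert np.all(bundle.timeseries.imss_Pa >= bundle.timeseries.arss_Pa - 1e-12)
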