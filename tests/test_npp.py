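"""NPP accumulation, yield regression and calibration tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lueyield import (
    CompositeObservation,
    CropStressParams,
    DegenerateDataError,
    InvalidInputError,
    RegressionConstants,
    StressFactors,
    accumulate_npp,
    calibrate_yield_regression,
    run_semi_physical,
    yield_from_npp,
)
from lueyield.npp import SEMI_PHYSICAL_MODEL_NAME


def _comp(par=10.0, n_days=8, fapar=0.5):
    return CompositeObservation(
        start_doy=1, n_days=n_days, par_daily_mean=par, fapar=fapar, nir=0.3, swir=0.1
    )


def _sf(i=0, eps=0.34):
    return StressFactors(composite_index=i, lswi=0.5, ws=1.0, ts=1.0, ps=1.0, epsilon=eps)


class TestAccumulateNpp:
    def test_single_composite_arithmetic(self):
        assert accumulate_npp([_comp()], [_sf()]) == pytest.approx(13.6)

    def test_empty_sum(self):
        assert accumulate_npp([], []) == 0.0

    def test_linearity_in_par(self):
        comps = [_comp(par=p) for p in (5.0, 8.0, 11.0)]
        doubled = [_comp(par=2 * p) for p in (5.0, 8.0, 11.0)]
        stress = [_sf(i) for i in range(3)]
        assert accumulate_npp(doubled, stress) == pytest.approx(
            2 * accumulate_npp(comps, stress)
        )

    def test_permutation_invariance(self):
        comps = [_comp(par=p, fapar=f) for p, f in [(5, 0.2), (9, 0.7), (12, 0.5)]]
        stress = [_sf(i, eps) for i, eps in enumerate((0.1, 0.2, 0.3))]
        perm = [2, 0, 1]
        assert accumulate_npp(
            [comps[i] for i in perm], [stress[i] for i in perm]
        ) == pytest.approx(accumulate_npp(comps, stress))

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            accumulate_npp([_comp()], [])


class TestYieldFromNpp:
    @pytest.mark.parametrize(
        "sum_npp,crop,expected",
        [
            (0.0, "soybean", 1.298),
            (100.0, "corn", 12.739),
            (40.0, "soybean", 4.218),
            (0.0, "corn", 0.739),
        ],
    )
    def test_published_constants(self, sum_npp, crop, expected):
        constants = RegressionConstants.for_crop(crop)
        assert yield_from_npp(sum_npp, constants) == pytest.approx(expected)

    @given(st.floats(0, 500), st.floats(1e-3, 100))
    def test_strictly_increasing_for_positive_slope(self, x, dx):
        c = RegressionConstants.for_crop("corn")
        assert yield_from_npp(x + dx, c) > yield_from_npp(x, c)


def _ols_normal_equations(x, y):
    """Closed-form normal-equations oracle for simple linear regression."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = np.sum(x * x) - np.sum(x) ** 2 / n
    sxy = np.sum(x * y) - np.sum(x) * np.sum(y) / n
    a = sxy / sxx
    return a, y.mean() - a * x.mean()


class TestCalibration:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(10, 120, 25)
        y = 0.12 * x + 0.739
        c = calibrate_yield_regression(list(zip(x, y)))
        assert c.a == pytest.approx(0.12, abs=1e-8)
        assert c.b == pytest.approx(0.739, abs=1e-8)

    def test_two_point_line(self):
        c = calibrate_yield_regression([(0.0, 1.298), (40.0, 4.218)], crop="soybean")
        assert c.a == pytest.approx(0.073)
        assert c.b == pytest.approx(1.298)

    def test_intercept_shift_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 30)
        y = 0.1 * x + rng.normal(0, 1, 30)
        c0 = calibrate_yield_regression(list(zip(x, y)))
        c1 = calibrate_yield_regression(list(zip(x, y + 2.5)))
        assert c1.a == pytest.approx(c0.a)
        assert c1.b == pytest.approx(c0.b + 2.5)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 20)
            x = rng.uniform(0, 200, n)
            y = rng.normal(0, 5, n) + rng.uniform(-1, 1) * x
            c = calibrate_yield_regression(list(zip(x, y)))
            a, b = _ols_normal_equations(x, y)
            assert c.a == pytest.approx(a, abs=1e-10)
            assert c.b == pytest.approx(b, abs=1e-10)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDataError):
            calibrate_yield_regression([(5.0, 1.0), (5.0, 2.0)])
        with pytest.raises(DegenerateDataError):
            calibrate_yield_regression([(5.0, 1.0)])


class TestRunSemiPhysical:
    def test_composition_identity(self, toy_season):
        from lueyield import season_stress_factors

        params = CropStressParams()
        constants = RegressionConstants.for_crop("corn")
        records = run_semi_physical([toy_season], params, constants)
        assert len(records) == 1
        stress = season_stress_factors(toy_season, params)
        manual = yield_from_npp(
            accumulate_npp(toy_season.composites, stress), constants
        )
        assert records[0].predictions[SEMI_PHYSICAL_MODEL_NAME] == pytest.approx(manual)
        assert records[0].sum_npp == pytest.approx(
            accumulate_npp(toy_season.composites, stress)
        )

    def test_zero_par_predicts_intercept(self, toy_season):
        import dataclasses

        comps = tuple(
            dataclasses.replace(c, par_daily_mean=0.0) for c in toy_season.composites
        )
        season = dataclasses.replace(toy_season, composites=comps)
        constants = RegressionConstants.for_crop("soybean")
        records = run_semi_physical([season], constants=constants)
        assert records[0].predictions[SEMI_PHYSICAL_MODEL_NAME] == pytest.approx(1.298)

    def test_npp_scale_applies_before_regression(self, toy_season):
        c = RegressionConstants.for_crop("corn")
        base = run_semi_physical([toy_season], constants=c)[0]
        scaled = run_semi_physical([toy_season], constants=c, npp_scale=2.0)[0]
        assert scaled.predictions[SEMI_PHYSICAL_MODEL_NAME] == pytest.approx(
            c.a * 2.0 * base.sum_npp + c.b
        )
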