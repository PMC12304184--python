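"""Stress-scalar unit tests: analytic examples, invariants, loop oracle."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lueyield import (
    CompositeObservation,
    CropStressParams,
    DomainError,
    InvalidConfigError,
    InvalidInputError,
    compute_lswi,
    light_use_efficiency,
    season_stress_factors,
    seasonal_lswi_max,
    temperature_stress,
    vegetation_growth_scalar,
    water_stress,
)

positive = st.floats(min_value=1e-3, max_value=1.0)


class TestLswi:
    @pytest.mark.parametrize(
        "nir,swir,expected",
        [(0.3, 0.1, 0.5), (0.4, 0.4, 0.0), (0.5, 0.0, 1.0), (0.0, 0.5, -1.0)],
    )
    def test_hand_arithmetic(self, nir, swir, expected):
        assert compute_lswi(nir, swir) == pytest.approx(expected)

    @given(positive, positive)
    def test_antisymmetry_and_bounds(self, a, b):
        assert compute_lswi(a, b) == pytest.approx(-compute_lswi(b, a))
        assert -1.0 <= compute_lswi(a, b) <= 1.0

    def test_zero_sum_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_lswi(0.0, 0.0)

    def test_seasonal_maximum(self):
        def comp(lswi):
            return CompositeObservation(
                start_doy=1, n_days=8, par_daily_mean=1.0, fapar=0.5,
                nir=0.5 * (1 + lswi) / 2 + 0.25, swir=0.5 * (1 - lswi) / 2 + 0.25,
            )

        # (nir-swir)/(nir+swir) = 0.5*lswi/1.0 here; max preserved
        comps = [comp(v) for v in (0.1, 0.6, 0.4)]
        assert seasonal_lswi_max(comps) == pytest.approx(0.3)
        assert seasonal_lswi_max([comps[1]]) == pytest.approx(0.3)
        with pytest.raises(InvalidInputError):
            seasonal_lswi_max([])


class TestWaterStress:
    @pytest.mark.parametrize(
        "lswi,lswi_max,expected",
        [(1.0, 1.0, 0.0), (0.0, 0.6, 0.625), (-1.0, 0.0, 1.0)],
    )
    def test_as_printed_examples(self, lswi, lswi_max, expected):
        assert water_stress(lswi, lswi_max, "as_printed") == pytest.approx(expected)

    def test_vpm_standard(self):
        assert water_stress(0.6, 0.6, "vpm_standard") == pytest.approx(1.0)
        assert water_stress(-1.0, 0.6, "vpm_standard") == pytest.approx(0.0)

    @given(st.floats(-0.5, 0.5), st.floats(-0.4, 0.4), st.floats(1e-3, 0.3))
    def test_monotonicity(self, lswi, lswi_max, delta):
        """as_printed decreases with LSWI; vpm_standard increases."""
        hi = min(1.0, lswi + delta)
        assert water_stress(lswi, lswi_max, "as_printed") >= water_stress(
            hi, lswi_max, "as_printed"
        )
        assert water_stress(lswi, lswi_max, "vpm_standard") <= water_stress(
            hi, lswi_max, "vpm_standard"
        )

    def test_degenerate_denominator(self):
        with pytest.raises(DomainError):
            water_stress(0.0, -1.0)


class TestTemperatureStress:
    @pytest.mark.parametrize(
        "t,tmin,tmax,topt,expected",
        [
            (30.0, 10.0, 40.0, 30.0, 1.0),
            (10.0, 10.0, 40.0, 30.0, 0.0),
            (40.0, 10.0, 40.0, 30.0, 0.0),
            (20.0, 10.0, 40.0, 30.0, 2.0 / 3.0),
            (5.0, 10.0, 40.0, 30.0, 0.0),   # below viable range
            (45.0, 10.0, 40.0, 30.0, 0.0),  # above viable range
        ],
    )
    def test_examples(self, t, tmin, tmax, topt, expected):
        assert temperature_stress(t, tmin, tmax, topt) == pytest.approx(expected)

    def test_dense_grid_properties(self):
        """Symmetric Topt: Ts is in [0,1], continuous, and peaks only at Topt."""
        tmin, tmax, topt = 10.0, 40.0, 25.0
        grid = np.linspace(tmin + 1e-6, tmax - 1e-6, 4001)
        ts = np.array([temperature_stress(t, tmin, tmax, topt) for t in grid])
        assert np.all((ts >= 0) & (ts <= 1))
        assert np.max(np.abs(np.diff(ts))) < 5e-3  # continuity on the grid
        peak = grid[np.argmax(ts)]
        assert peak == pytest.approx(topt, abs=0.01)
        assert np.sum(ts > 1 - 1e-9) <= 3  # =1 only in a vanishing neighbourhood

    def test_invalid_range(self):
        with pytest.raises(InvalidInputError):
            temperature_stress(20.0, 30.0, 10.0, 25.0)


class TestGrowthScalarAndEpsilon:
    def test_phase_values(self):
        assert vegetation_growth_scalar("leaf_growth", -0.7) == 1.0
        assert vegetation_growth_scalar("grain_ripening", 1.0) == pytest.approx(1.0)
        assert vegetation_growth_scalar("grain_ripening", 0.2) == pytest.approx(0.6)

    def test_epsilon_examples(self):
        p = CropStressParams()
        assert light_use_efficiency(1, 1, 1, p) == pytest.approx(0.34)
        assert light_use_efficiency(0, 0.5, 0.5, p) == 0.0
        assert light_use_efficiency(2 / 3, 0.625, 1.0, p) == pytest.approx(
            0.141667, abs=1e-6
        )

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0.05, 2.0))
    def test_linear_in_eps_max_and_bounded(self, ts, ws, ps, eps_max):
        p = CropStressParams(eps_max=eps_max)
        eps = light_use_efficiency(ts, ws, ps, p)
        assert 0.0 <= eps <= eps_max + 1e-12
        assert eps == pytest.approx(
            2 * light_use_efficiency(ts, ws, ps, CropStressParams(eps_max=eps_max / 2))
        )

    def test_contract_violation(self):
        with pytest.raises(InvalidInputError):
            light_use_efficiency(1.2, 0.5, 0.5)


def _oracle_season_loop(season, params):
    """Independent term-by-term evaluation of the stress chain."""
    lswis = [
        (c.nir - c.swir) / (c.nir + c.swir) for c in season.composites
    ]
    lswi_max = max(lswis)
    rows = []
    for i, comp in enumerate(season.composites):
        lswi = lswis[i]
        if params.ws_formula == "as_printed":
            ws = min(1.0, max(0.0, (1 - lswi) / (1 + lswi_max)))
        else:
            ws = min(1.0, max(0.0, (1 + lswi) / (1 + lswi_max)))
        days = season.composite_meteo(i)
        t = sum(d.mean_temperature for d in days) / len(days)
        tn = sum(d.tmin for d in days) / len(days)
        tx = sum(d.tmax for d in days) / len(days)
        if t <= tn or t >= tx:
            ts = 0.0
        else:
            num = (t - tn) * (t - tx)
            ts = min(1.0, max(0.0, num / (num - (t - params.t_opt) ** 2)))
        if comp.start_doy < params.phase_transition_doy:
            ps = 1.0
        else:
            ps = (1 + lswi) / 2
        rows.append((lswi, ws, ts, ps, params.eps_max * ts * ws * ps))
    return rows


class TestSeasonStressFactors:
    @pytest.mark.parametrize("ws_formula", ["as_printed", "vpm_standard"])
    def test_matches_handcoded_loop(self, toy_season, ws_formula):
        params = CropStressParams(ws_formula=ws_formula, phase_transition_doy=180)
        got = season_stress_factors(toy_season, params)
        expected = _oracle_season_loop(toy_season, params)
        assert len(got) == len(toy_season.composites)
        for sf, (lswi, ws, ts, ps, eps) in zip(got, expected):
            assert sf.lswi == pytest.approx(lswi)
            assert sf.ws == pytest.approx(ws)
            assert sf.ts == pytest.approx(ts)
            assert sf.ps == pytest.approx(ps)
            assert sf.epsilon == pytest.approx(eps)

    def test_all_scalars_unity_gives_eps_max(self, toy_season):
        comps = tuple(
            dataclasses.replace(c, nir=0.5, swir=0.0) for c in toy_season.composites
        )
        meteo = tuple(
            dataclasses.replace(d, tmax=36.0, tmin=24.0, tavg=30.0)
            for d in toy_season.meteo
        )
        season = dataclasses.replace(toy_season, composites=comps, meteo=meteo)
        params = CropStressParams(ws_formula="vpm_standard", phase_transition_doy=365)
        for sf in season_stress_factors(season, params):
            assert sf.epsilon == pytest.approx(0.34)

    def test_phase_boundary_locality(self, toy_season):
        """Moving the phase transition only changes Ps/ε of crossing composites."""
        a = season_stress_factors(toy_season, CropStressParams(phase_transition_doy=180))
        b = season_stress_factors(toy_season, CropStressParams(phase_transition_doy=170))
        for sa, sb, comp in zip(a, b, toy_season.composites):
            assert (sa.lswi, sa.ws, sa.ts) == (sb.lswi, sb.ws, sb.ts)
            crosses = 170 <= comp.start_doy < 180
            if crosses:
                assert sa.ps != sb.ps
            else:
                assert sa.ps == sb.ps
                assert sa.epsilon == sb.epsilon

    def test_crop_constants_mode(self, toy_season):
        params = CropStressParams(
            temp_limit_mode="crop_constants", t_min_const=10.0, t_max_const=40.0
        )
        got = season_stress_factors(toy_season, params)
        days = toy_season.composite_meteo(0)
        t = sum(d.mean_temperature for d in days) / len(days)
        assert got[0].ts == pytest.approx(temperature_stress(t, 10.0, 40.0, 30.0))

    def test_invalid_crop_constants(self):
        with pytest.raises(InvalidConfigError):
            CropStressParams(
                temp_limit_mode="crop_constants", t_min_const=35.0, t_max_const=40.0
            )
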