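"""Tests of the host crop model: phenology, water balance, canopy
temperature, CO2 response and yield formation."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import constant_weather
from wheatstress.crop import (
    CultivarParams,
    HostConstants,
    Management,
    SoilParams,
    WaterState,
    anthesis_day,
    apply_profile,
    canopy_tmax,
    daily_water_balance,
    priestley_taylor_et,
    rue_co2_multiplier,
    run_season,
)
from wheatstress.errors import ParameterError, SeasonFailureError
from wheatstress.weather import DAYS_PER_YEAR, generate_series

CONST = HostConstants()


class TestRueCo2:
    @pytest.mark.parametrize(
        "co2, ref, expected",
        [
            (363.8, 363.8, 1.0),
            (727.6, 363.8, 1.30),  # doubling: +30%
            (562.8, 363.8, 1.0 + 0.30 * (562.8 / 363.8 - 1.0)),  # ~1.164
        ],
    )
    def test_linear_response(self, co2, ref, expected):
        assert rue_co2_multiplier(co2, ref) == pytest.approx(expected)

    def test_nonpositive_co2_rejected(self):
        with pytest.raises(ParameterError):
            rue_co2_multiplier(-1.0, 363.8)


class TestAnthesis:
    def test_constant_temperature_closed_form(self):
        w = constant_weather(365, tmax=25.0, tmin=15.0)  # Tmean = 20
        c = CultivarParams(tt_sowing_to_anthesis=1000.0, base_temp=0.0)
        assert anthesis_day(w, c) == 50  # 1000 / 20

    def test_warming_accelerates_development(self):
        rng = np.random.default_rng(5)
        w = constant_weather(365, tmax=22.0, tmin=10.0)
        w["tmax_c"] += rng.normal(0, 3, 365)
        w["tmin_c"] = w["tmax_c"] - 12.0
        c = CultivarParams()
        warm = w.copy()
        warm["tmax_c"] += 2.0
        warm["tmin_c"] += 2.0
        assert anthesis_day(warm, c) < anthesis_day(w, c)

    def test_matches_day_by_day_accumulation_oracle(self):
        rng = np.random.default_rng(11)
        w = constant_weather(365, tmax=20.0, tmin=8.0)
        w["tmax_c"] += rng.normal(0, 5, 365)
        w["tmin_c"] = w["tmax_c"] - 10.0
        c = CultivarParams(tt_sowing_to_anthesis=900.0, base_temp=2.0)
        # independent oracle: explicit day loop
        cum, das = 0.0, None
        for i in range(365):
            tmean = (w["tmax_c"].iloc[i] + w["tmin_c"].iloc[i]) / 2
            cum += max(0.0, tmean - c.base_temp)
            if cum >= c.tt_sowing_to_anthesis:
                das = i + 1
                break
        assert anthesis_day(w, c) == das

    def test_unreachable_requirement_raises(self):
        w = constant_weather(365, tmax=2.0, tmin=-6.0)
        with pytest.raises(SeasonFailureError):
            anthesis_day(w, CultivarParams(tt_sowing_to_anthesis=5000.0))


class TestWaterBalance:
    def test_unstressed_limit(self):
        soil = SoilParams(sawc=150.0)
        state = WaterState(store=150.0)
        d = daily_water_balance(state, 18.0, 25.0, 0.0, 15.0, 4.0, 1.0, soil, 0.45)
        assert d["ta"] == pytest.approx(d["tp"])
        assert d["supply_ratio"] == 1.0

    def test_exhaustion_limit(self):
        soil = SoilParams(sawc=60.0)
        state = WaterState(store=60.0)
        last = None
        for _ in range(200):
            last = daily_water_balance(state, 25.0, 32.0, 0.0, 20.0, 5.0, 1.0, soil, 0.45)
        assert last["raw"] < 1.0
        assert last["ta"] < 0.01

    def test_conservation_ledger_30_day_toy(self):
        """Initial store + rain = final store + ET + drainage, exactly."""
        rng = np.random.default_rng(2)
        soil = SoilParams(sawc=100.0, initial_smd=30.0)
        state = WaterState(store=soil.sawc - soil.initial_smd)
        s0 = state.store
        for day in range(30):
            daily_water_balance(
                state,
                tmean=float(rng.uniform(5, 25)),
                tmax=25.0,
                precip=float(rng.choice([0.0, 0.0, 5.0, 40.0])),
                radiation=float(rng.uniform(5, 25)),
                lai=3.0,
                root_frac=min(1.0, (day + 1) / 20),
                soil=soil,
                k_light=0.45,
            )
        lhs = s0 + state.cum_precip
        rhs = state.store + state.cum_eta + state.cum_drainage
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_eta_never_exceeds_etp(self):
        rng = np.random.default_rng(3)
        soil = SoilParams(sawc=80.0)
        state = WaterState(store=50.0)
        for _ in range(120):
            d = daily_water_balance(
                state, float(rng.uniform(0, 30)), 25.0, float(rng.choice([0.0, 8.0])),
                float(rng.uniform(2, 28)), float(rng.uniform(0, 6)), 1.0, soil, 0.45,
            )
            assert d["eta"] <= d["etp"] + 1e-12
        assert state.cum_eta <= state.cum_etp + 1e-9


class TestCanopyTemperature:
    def test_fully_transpiring_canopy_at_air_temperature(self):
        assert canopy_tmax(28.0, 1.0, 30.0) == 28.0

    def test_fully_stressed_upper_bound(self):
        assert canopy_tmax(30.0, 0.0, 100.0) == pytest.approx(35.0)

    def test_intermediate_linear_interpolation(self):
        t_half = canopy_tmax(30.0, 0.5, 100.0)
        assert t_half == pytest.approx((canopy_tmax(30.0, 0.0, 100.0) + canopy_tmax(30.0, 1.0, 100.0)) / 2)

    def test_invalid_supply_ratio_rejected(self):
        with pytest.raises(ParameterError):
            canopy_tmax(25.0, 1.5, 10.0)

    def test_priestley_taylor_positive_and_increasing_in_radiation(self):
        lo = priestley_taylor_et(18.0, 5.0)
        hi = priestley_taylor_et(18.0, 25.0)
        assert 0 < lo < hi


class TestRunSeason:
    def test_tolerant_profile_has_unit_reduction_factors(self, benign_weather, soil):
        hot = benign_weather.copy()
        hot.loc[100:130, "tmax_c"] = 42.0  # extremes around likely anthesis
        hot.loc[100:130, "precip_mm"] = 0.0
        tol = apply_profile(CultivarParams(), "tolerant")
        res = run_season(hot, tol, soil, Management(sowing_doy=1))
        assert res.r_d == res.r_h == res.r_w == 1.0

    def test_benign_year_sensitive_equals_tolerant(self, benign_weather, soil):
        c = CultivarParams()
        res_s = run_season(benign_weather, apply_profile(c, "sensitive_both"), soil, Management())
        res_t = run_season(benign_weather, apply_profile(c, "tolerant"), soil, Management())
        assert res_s.yield_t_ha == pytest.approx(res_t.yield_t_ha)
        assert res_s.r_d == res_s.r_h == res_s.r_w == 1.0

    def test_co2_doubling_scales_biomass_by_1_30(self, benign_weather, soil):
        c = CultivarParams()
        base = run_season(benign_weather, c, soil, Management(co2=363.8, co2_ref=363.8))
        doubled = run_season(benign_weather, c, soil, Management(co2=727.6, co2_ref=363.8))
        assert doubled.biomass_at_maturity / base.biomass_at_maturity == pytest.approx(1.30, rel=1e-12)
        assert doubled.anthesis_das == base.anthesis_das

    def test_yield_ordering_sensitive_below_tolerant(self, soil):
        """Reduction factors are <= 1, so the sensitive profile can never
        out-yield the tolerant one on identical weather."""
        from conftest import benign_site_params

        params = benign_site_params()
        params.monthly_mean_tmax += 12.0  # push some years over the heat thresholds
        params.monthly_mean_tmin += 12.0
        params.p_wet_given_dry[:] = 0.15
        params.p_wet_given_wet[:] = 0.3
        series = generate_series(params, 21, seed=17)
        c = CultivarParams()
        for y in range(20):
            season = series.iloc[y * DAYS_PER_YEAR : (y + 1) * DAYS_PER_YEAR + 1]
            res_s = run_season(season, apply_profile(c, "sensitive_both"), soil, Management())
            res_t = run_season(season, apply_profile(c, "tolerant"), soil, Management())
            assert res_s.yield_t_ha <= res_t.yield_t_ha + 1e-12
            assert res_s.anthesis_das == res_t.anthesis_das

    def test_season_diagnostics_are_consistent(self, benign_weather, soil):
        res = run_season(benign_weather, CultivarParams(), soil, Management())
        assert res.maturity_das > res.anthesis_das
        assert 0.0 <= res.dsf <= 1.0
        assert res.eta_at_flowering <= res.etp_at_flowering + 1e-9
        assert res.grain_number > 0 and res.grain_weight > 0
        assert res.yield_t_ha == pytest.approx(res.grain_number * res.grain_weight * 0.01)

    def test_short_weather_rejected(self, soil):
        with pytest.raises(SeasonFailureError):
            run_season(constant_weather(200), CultivarParams(), soil, Management())

    def test_unknown_profile_rejected(self):
        with pytest.raises(ParameterError, match="unknown cultivar profile"):
            apply_profile(CultivarParams(), "super_wheat")


class TestDroughtEscape:
    def test_uniform_warming_advances_anthesis_and_cuts_etp_demand(self):
        """Warming shortens the vegetative phase, so cumulative potential
        evapotranspiration at flowering falls despite warmer days."""
        from wheatstress.synthetic import default_management, default_soil, make_site_params, site_spec
        from wheatstress.weather import ClimateDelta, apply_delta

        params = make_site_params(site_spec("dry_continental", "dc", latitude=48.0))
        soil = default_soil("dry_continental")
        mgmt = default_management("dry_continental")
        d = ClimateDelta.identity(co2=562.8)
        d.d_tmax = d.d_tmax + 2.0
        d.d_tmin = d.d_tmin + 2.0
        c = apply_profile(CultivarParams(), "tolerant")

        def ensemble(p, n=30, seed=21):
            series = generate_series(p, n + 1, seed)
            anth, etp = [], []
            for y in range(n):
                s = series.iloc[y * DAYS_PER_YEAR + mgmt.sowing_doy - 1 :]
                r = run_season(s, c, soil, mgmt)
                anth.append(r.anthesis_das)
                etp.append(r.etp_at_flowering)
            return np.mean(anth), np.mean(etp)

        anth_b, etp_b = ensemble(params)
        anth_w, etp_w = ensemble(apply_delta(params, d))
        assert anth_w < anth_b
        assert etp_w < etp_b
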