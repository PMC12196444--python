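"""Nitrogen process kinetics against closed-form oracles, plus the daily
step's ordering, pool limits, and mass conservation."""

import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

import paddynsim as ps
from paddynsim.nitrogen import (FertilizerEvent, NitrogenPools, StrawPools,
                                ammonia_fraction, daily_nitrogen_step,
                                denitrification_rate, initial_nitrogen_pools,
                                nh3_volatilization, nitrification_rate,
                                straw_decomposition_step, temperature_function,
                                urea_hydrolysis_rate)


def _pka(t):
    return 0.09018 + 2729.92 / (t + 273.15)


def _no_water_fluxes(ponding_mm):
    return {"ponding_mm": ponding_mm, "infiltration": 0.0, "f12": 0.0,
            "f23": 0.0, "percolation": 0.0, "runoff": 0.0}


class TestUreaHydrolysis:
    @pytest.mark.parametrize("n_urea,wfps,kh,expected", [
        (0.0, 0.8, 0.05, 0.0),
        (50.0, 0.0, 0.05, 0.0),
        (100.0, 1.0, 0.05, 100.0 * (1 - math.exp(-0.25))),  # ~22.12
        (40.0, 0.5, 0.007, 40.0 * (1 - math.exp(-5 * 0.5 * 0.007))),
    ])
    def test_closed_form(self, n_urea, wfps, kh, expected):
        assert urea_hydrolysis_rate(n_urea, wfps, kh) \
            == pytest.approx(expected, abs=1e-12)

    def test_rejects_percent_scale_wfps(self):
        with pytest.raises(ValueError):
            urea_hydrolysis_rate(10.0, 60.0, 0.05)

    @settings(max_examples=60, deadline=None)
    @given(n=st.floats(0.01, 1e3), w=st.floats(0.01, 1.0),
           k=st.floats(1e-4, 0.5))
    def test_bounded_and_monotone(self, n, w, k):
        r = urea_hydrolysis_rate(n, w, k)
        assert 0 <= r <= n
        assert urea_hydrolysis_rate(n * 1.1, w, k) > r
        assert urea_hydrolysis_rate(n, min(1.0, w * 1.1), k) >= r
        assert urea_hydrolysis_rate(n, w, k * 1.1) > r


class TestAmmoniaFraction:
    def test_half_at_pka(self):
        for t in (5.0, 25.0, 35.0):
            assert ammonia_fraction(t, _pka(t)) == pytest.approx(0.5, abs=1e-12)

    def test_asymptote(self):
        assert ammonia_fraction(25.0, 14.0) > 0.999

    def test_closed_form_value(self):
        expected = 1.0 / (1.0 + 10 ** (_pka(25.0) - 8.5))  # ~0.15
        assert ammonia_fraction(25.0, 8.5) == pytest.approx(expected, abs=1e-12)
        assert 0.14 < expected < 0.16

    def test_monotone_in_t_and_ph(self):
        assert ammonia_fraction(30.0, 8.0) > ammonia_fraction(20.0, 8.0)
        assert ammonia_fraction(25.0, 9.0) > ammonia_fraction(25.0, 8.0)


class TestVolatilization:
    def test_no_substrate_or_no_pond(self, params):
        assert nh3_volatilization(params, 0.0, 25.0, 8.0, 30.0) == 0.0
        assert nh3_volatilization(params, 10.0, 25.0, 8.0, 0.0) == 0.0

    def test_temperature_function_at_zero(self, params):
        assert temperature_function(0.0) == pytest.approx(0.25, abs=1e-15)
        flux = nh3_volatilization(params, 10.0, 0.0, 8.5, 30.0)
        expected = params.Kv * 10.0 * 0.25 * ammonia_fraction(0.0, 8.5) \
            * 30.0 * 0.01
        assert flux == pytest.approx(expected, abs=1e-12)

    def test_composed_oracle(self, params):
        # Kv=0.095, Cp=10, T=25, pH=8.5, depth 30 mm -> ~0.06 kg N/ha/d
        f_t = 0.25 * math.exp(0.0693 * 25.0)
        frac = 1.0 / (1.0 + 10 ** (_pka(25.0) - 8.5))
        expected = 0.095 * 10.0 * f_t * frac * 30.0 * 0.01
        flux = nh3_volatilization(params, 10.0, 25.0, 8.5, 30.0)
        assert flux == pytest.approx(expected, abs=1e-12)
        assert 0.05 < flux < 0.07

    def test_capped_at_pond_mass(self, params):
        flux = nh3_volatilization(params, 1000.0, 40.0, 14.0, 50.0,
                                  pond_mineral_kgha=0.5)
        assert flux == 0.5

    @settings(max_examples=40, deadline=None)
    @given(cp=st.floats(0, 100), t=st.floats(0, 40), ph=st.floats(6, 10),
           depth=st.floats(0.1, 60))
    def test_monotone_in_all_drivers(self, params, cp, t, ph, depth):
        base = nh3_volatilization(params, cp, t, ph, depth)
        assert nh3_volatilization(params, cp + 1, t, ph, depth) >= base
        assert nh3_volatilization(params, cp, t + 1, ph, depth) >= base
        assert nh3_volatilization(params, cp, t, ph + 0.1, depth) >= base
        assert nh3_volatilization(params, cp, t, ph, depth + 1) >= base
        big_kv = dataclasses.replace(params, Kv=params.Kv * 2)
        assert nh3_volatilization(big_kv, cp, t, ph, depth) >= base


class TestNitrification:
    def test_zero_and_half_saturation(self, params):
        assert nitrification_rate(0.0, params, 0.6) == 0.0
        # NH4 = Kn = 70 at optimal moisture -> exactly Vn/2 = 35
        assert nitrification_rate(70.0, params, 0.6) == pytest.approx(35.0)

    def test_saturation_limit(self, params):
        assert nitrification_rate(1e9, params, 0.6) \
            == pytest.approx(70.0, rel=1e-6)

    def test_anoxia_suppression(self, params):
        optimal = nitrification_rate(70.0, params, 0.6)
        flooded = nitrification_rate(70.0, params, 1.0)
        assert flooded == pytest.approx(0.1 * optimal)


class TestDenitrification:
    def test_inactive_below_threshold(self, params):
        assert denitrification_rate(50.0, 100.0, params, 0.5) == 0.0
        assert denitrification_rate(0.0, 100.0, params, 1.0) == 0.0

    def test_carbon_limited_branch(self, params):
        # Ad * resp_C = 0.02 * 10 = 0.2 kg/ha/d with NO3 in excess
        assert denitrification_rate(1e6, 10.0, params, 1.0) \
            == pytest.approx(0.2, abs=1e-12)

    def test_nitrate_limited_branch(self, params):
        # Kd * NO3 areal: 0.1 ug/cm3 over 20 cm = 0.2 kg/ha; Kd = 0.5
        assert denitrification_rate(0.1, 1e6, params, 1.0) \
            == pytest.approx(0.1, abs=1e-12)


class TestStrawDecomposition:
    def test_zero_straw_is_inert(self, params):
        pools = StrawPools()
        resp, net, new = straw_decomposition_step(pools, 25.0, 1.0, params)
        assert resp == 0.0 and net == 0.0 and new == pools

    def test_cn_20_balance_point(self, params):
        """Organic C:N = microbial C:N / E = 8 / 0.4 = 20 -> net flux 0."""
        pools = StrawPools(c_fast=600.0, c_slow=400.0, organic_n=50.0)
        _, net, _ = straw_decomposition_step(pools, 25.0, 0.5, params)
        assert net == pytest.approx(0.0, abs=1e-12)

    def test_rapeseed_straw_immobilizes(self, params):
        """3 t/ha rapeseed straw (C:N ~97) against a spreadsheet-style
        evaluation of the stated pool rules at 25 C, WFPS 1."""
        pools = StrawPools.from_straw(3.0, params)
        c_total = 3000 * 0.406
        assert pools.c_fast + pools.c_slow == pytest.approx(c_total)
        assert pools.organic_n == pytest.approx(3000 * 0.0042)
        resp, net, new = straw_decomposition_step(pools, 25.0, 1.0, params)
        fw = 0.5  # saturation halves turnover
        d_fast = c_total * 0.6 * 0.05 * fw
        d_slow = c_total * 0.4 * 0.002 * fw
        release = (d_fast + d_slow) * pools.organic_n / c_total
        demand = 0.4 * (d_fast + d_slow) / 8.0
        assert net == pytest.approx(release - demand, abs=1e-9)
        assert net < 0  # immobilization
        assert resp == pytest.approx(0.6 * (d_fast + d_slow), abs=1e-9)
        assert new.microbial_n == pytest.approx(demand, abs=1e-9)

    def test_n_is_conserved_across_pools(self, params):
        pools = StrawPools.from_straw(5.0, params)
        for _ in range(30):
            _, net, new = straw_decomposition_step(pools, 28.0, 1.0, params)
            assert new.total_n() + net == pytest.approx(pools.total_n(),
                                                        abs=1e-9)
            pools = new


class TestDailyStep:
    def test_nothing_in_nothing_happens(self, params):
        params0 = dataclasses.replace(
            params, init_nh4_by_layer=(0.0,) * 3, init_no3_by_layer=(0.0,) * 3,
            humus_min_rate=0.0)
        pools = initial_nitrogen_pools(params0)
        straw = StrawPools()
        theta = list(params0.theta_s_by_layer)
        new, _, flux = daily_nitrogen_step(pools, straw,
                                           _no_water_fluxes(50.0), theta,
                                           25.0, [], params0)
        assert new.inventory() == 0.0
        for key in ("nh3", "nitrif", "denit", "leach", "runoff_n", "net_min"):
            assert flux[key] == 0.0

    def test_unknown_fertilizer_kind(self, params):
        pools = initial_nitrogen_pools(params)
        with pytest.raises(ValueError, match="manure"):
            daily_nitrogen_step(pools, StrawPools(), _no_water_fluxes(50.0),
                                list(params.theta_s_by_layer), 25.0,
                                [FertilizerEvent(10.0, kind="manure")], params)

    def test_ui_slows_cumulative_nh3(self, params):
        """60 kg urea-N, identical forcing: 10-day NH3 strictly lower
        with the inhibitor (Kh 0.007 vs 0.05)."""
        totals = {}
        for ui in (False, True):
            pools = initial_nitrogen_pools(params)
            straw = StrawPools()
            theta = list(params.theta_s_by_layer)
            events = [FertilizerEvent(60.0, ui=ui)]
            for day in range(10):
                pools, straw, _ = daily_nitrogen_step(
                    pools, straw, _no_water_fluxes(50.0), theta, 25.0,
                    events if day == 0 else [], params)
            totals[ui] = pools.cum_nh3
        assert 0 < totals[True] < totals[False]

    def test_daily_mass_balance(self, params):
        pools = initial_nitrogen_pools(params)
        straw = StrawPools.from_straw(4.0, params)
        theta = list(params.theta_s_by_layer)
        fluxes = {"ponding_mm": 45.0, "infiltration": 10.0, "f12": 6.0,
                  "f23": 6.0, "percolation": 6.0, "runoff": 2.0}
        start = pools.inventory() + straw.total_n()
        events = [FertilizerEvent(60.0, ui=False)]
        new_p, new_s, f = daily_nitrogen_step(pools, straw, fluxes, theta,
                                              28.0, events, params,
                                              straw_return_t_ha=4.0)
        end = new_p.inventory() + new_s.total_n()
        balance = start + f["fertilizer_n"] + f["humus_min"] \
            - (f["nh3"] + f["denit"] + f["leach"] + f["runoff_n"]) - end
        assert abs(balance) < 1e-9

    def test_hydrolysis_matches_geometric_decay(self, params):
        """Repeated hydrolysis at constant WFPS equals the closed-form
        geometric decay of the urea pool."""
        params0 = dataclasses.replace(
            params, init_nh4_by_layer=(0.0,) * 3, init_no3_by_layer=(0.0,) * 3,
            humus_min_rate=0.0, Vn=0.0)
        pools = initial_nitrogen_pools(params0)
        theta = [0.8 * t for t in params0.theta_s_by_layer]  # WFPS 0.8, dry field
        pools.urea_std[0] = 30.0
        n_days = 7
        for _ in range(n_days):
            pools, _, _ = daily_nitrogen_step(pools, StrawPools(),
                                              _no_water_fluxes(0.0), theta,
                                              20.0, [], params0)
        frac = 1 - math.exp(-5.0 * 0.8 * params0.Kh)
        assert pools.urea_std[0] == pytest.approx(30.0 * (1 - frac) ** n_days,
                                                  rel=1e-9)

    def test_drained_field_does_not_volatilize(self, params):
        pools = initial_nitrogen_pools(params)
        pools.pond_mineral = 5.0
        new, _, flux = daily_nitrogen_step(pools, StrawPools(),
                                           _no_water_fluxes(0.0),
                                           list(params.theta_s_by_layer),
                                           30.0, [], params)
        assert flux["nh3"] == 0.0
        assert new.pond_mineral == 0.0  # merged into the top layer
        assert flux["cp_mgl"] == 0.0
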