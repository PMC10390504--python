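"""Leaf-senescence models: triggers, accumulations, SOS-adjusted variants."""

import numpy as np
import pytest

from leafphen import NOT_REACHED, SiteMeta, build_climatology, build_window, get_model
from leafphen.base import WindowBatch
from leafphen.drivers import climatology_window
from leafphen.senescence import (
    SOLSTICE_DOY,
    adjust_threshold_by_sos,
    run_delpierre,
    run_dms,
    run_dpdi,
    run_jeong,
    run_white,
)
from leafphen.study import TRUE_PARAMS
from leafphen.synth import WeatherGenSpec, gen_weather

from conftest import random_windows
from oracles import SENESCENCE_ORACLES, SOS_ADJUSTED_ORACLES


def constant_year(temp, latitude=45.0):
    site = SiteMeta("c1", latitude)
    w = gen_weather(
        WeatherGenSpec(annual_mean=float(temp), seasonal_amplitude=0.0, noise_sd=0.0),
        site, [2020],
    )
    return build_window(w, site, 2020, "senescence")


class TestWhite:
    def test_always_true_frost_fires_at_solstice(self):
        win = constant_year(15.0)
        pred = run_white(win, dict(L_crit=10.0, T_crit=0.0, T_frost=60.0))
        assert pred.doy == SOLSTICE_DOY

    def test_mild_autumn_not_reached(self):
        win = constant_year(15.0)
        pred = run_white(win, dict(L_crit=8.0, T_crit=5.0, T_frost=-30.0))
        assert pred.doy is NOT_REACHED

    def test_winter_daylength_cannot_trigger(self):
        # photoperiod is short in January too; the scan must start at the
        # solstice so the trigger fires in autumn
        win = constant_year(-2.0)
        pred = run_white(win, dict(L_crit=10.0, T_crit=0.0, T_frost=-30.0))
        assert pred.doy >= SOLSTICE_DOY


class TestDelpierre:
    def test_unit_rates_count_qualifying_days(self):
        win = constant_year(10.0)
        p = dict(start=182, T_b=20.0, L_b=24.0, x=0, y=0, Y_star=15.0)
        pred = run_delpierre(win, p)
        assert pred.doy == 182 + 14  # 15th qualifying day, start inclusive

    def test_uniform_warming_never_advances_eos(self):
        windows, batch = random_windows("senescence", 20, seed=31)
        model = get_model("DM")
        base = model.predict_batch(TRUE_PARAMS["DM"], batch)
        warmer = WindowBatch(phenophase="senescence", T=batch.T + 2.0, L=batch.L)
        shifted = model.predict_batch(TRUE_PARAMS["DM"], warmer)
        both = ~(np.isnan(base) | np.isnan(shifted))
        assert np.all(shifted[both] >= base[both])

    def test_uniform_cooling_never_delays_eos(self):
        windows, batch = random_windows("senescence", 20, seed=32)
        for name in ("DM", "JM", "DPDI"):
            model = get_model(name)
            base = model.predict_batch(TRUE_PARAMS[name], batch)
            cooler = WindowBatch(phenophase="senescence", T=batch.T - 2.0, L=batch.L)
            shifted = model.predict_batch(TRUE_PARAMS[name], cooler)
            both = ~(np.isnan(base) | np.isnan(shifted))
            assert np.all(shifted[both] <= base[both]), name


class TestJeong:
    def test_open_gate_starts_at_solstice_scan(self):
        win = constant_year(10.0)
        p = dict(P_crit=24.0, T_b=12.0, Y_star=20.0)
        pred = run_jeong(win, p)
        # gate nominally open everywhere; the autumn scan anchors it at 172
        assert pred.doy == SOLSTICE_DOY + 9  # 2 cold-degree-days/day

    def test_accumulation_after_gate(self):
        win = constant_year(10.0, latitude=47.0)
        p = dict(P_crit=13.0, T_b=11.0, Y_star=20.0)
        gate = int(np.argmax((win.daylength < 13.0) & (win.day_axis >= SOLSTICE_DOY))) + 1
        pred = run_jeong(win, p)
        assert pred.doy == gate + 19  # 1 cold-degree-day per day


class TestDpdi:
    def test_double_midpoint_quarter_rate(self):
        win = constant_year(12.0)
        win.daylength = np.full(365, 13.0)
        p = dict(start=182, a=0.2, b=12.0, c=13.0, D_star=5.0)
        pred = run_dpdi(win, p)
        assert pred.doy == 182 + 19  # rate 0.25/day -> 20th day

    def test_zero_threshold_fires_at_start(self):
        win = constant_year(12.0)
        pred = run_dpdi(win, dict(start=200, a=0.2, b=12.0, c=13.0, D_star=0.0))
        assert pred.doy == 200


class TestSosAdjustment:
    def test_zero_anomaly_keeps_threshold(self):
        assert adjust_threshold_by_sos(100.0, 140, 140, alpha=0.05) == 100.0

    def test_positive_alpha_early_spring_shrinks_threshold(self):
        early = adjust_threshold_by_sos(100.0, 130, 140, alpha=0.02)
        late = adjust_threshold_by_sos(100.0, 150, 140, alpha=0.02)
        assert early < 100.0 < late

    def test_floor_is_positive(self):
        assert adjust_threshold_by_sos(100.0, 40, 140, alpha=1.0) > 0


def _sos_context(annual_mean=7.0, clim_mean=None, seed=1):
    site = SiteMeta("s1", 45.0)
    w = gen_weather(WeatherGenSpec(annual_mean=annual_mean, noise_sd=0.0), site, [2019, 2020])
    win = build_window(w, site, 2020, "senescence")
    em = build_window(w, site, 2020, "emergence")
    wc = (
        w
        if clim_mean is None
        else gen_weather(WeatherGenSpec(annual_mean=clim_mean, noise_sd=0.0), site, [2019, 2020])
    )
    clim = build_climatology(wc, "s1")
    cw = climatology_window(clim, site, 2020, "emergence")
    return win, em, cw


class TestSosAdjustedModels:
    PTTS = TRUE_PARAMS["PTTs"]

    def test_alpha_zero_collapses_to_base_model(self):
        win, em, cw = _sos_context()
        p = {**TRUE_PARAMS["DMs"], "alpha": 0.0}
        adj = run_dms(win, p, emergence_window=em, climatology_window=cw,
                      sos_params=self.PTTS)
        base = run_delpierre(win, TRUE_PARAMS["DM"])
        assert adj.doy == base.doy

    def test_climatology_equal_to_focal_year_matches_base(self):
        win, em, cw = _sos_context()  # climatology built from the same year
        adj = run_dms(win, TRUE_PARAMS["DMs"], emergence_window=em,
                      climatology_window=cw, sos_params=self.PTTS)
        base = run_delpierre(win, TRUE_PARAMS["DM"])
        assert adj.doy == base.doy

    def test_warm_spring_with_positive_alpha_advances_eos(self):
        # focal year warmer than climatology -> earlier SOS -> smaller
        # threshold -> EOS at or before the base model's date
        win, em, cw = _sos_context(annual_mean=10.0, clim_mean=5.0)
        adj = run_dms(win, TRUE_PARAMS["DMs"], emergence_window=em,
                      climatology_window=cw, sos_params=self.PTTS)
        base = run_delpierre(win, TRUE_PARAMS["DM"])
        assert adj.reached and adj.doy <= base.doy

    def test_missing_context_is_an_error(self):
        win, em, cw = _sos_context()
        with pytest.raises(ValueError, match="PTTs"):
            run_dms(win, TRUE_PARAMS["DMs"])


class TestOracleEquivalence:
    @pytest.mark.parametrize("name", sorted(SENESCENCE_ORACLES))
    def test_batch_matches_naive_daily_loop(self, name):
        windows, batch = random_windows("senescence", 30, seed=41)
        model = get_model(name)
        pred = model.predict_batch(TRUE_PARAMS[name], batch)
        for i, w in enumerate(windows):
            expected = SENESCENCE_ORACLES[name](
                list(w.tmean), list(w.daylength), TRUE_PARAMS[name]
            )
            got = None if np.isnan(pred[i]) else int(pred[i])
            assert got == expected, f"{name} window {i}: {got} != {expected}"

    @pytest.mark.parametrize("name", sorted(SOS_ADJUSTED_ORACLES))
    def test_sos_adjusted_matches_naive_loop(self, name):
        rng = np.random.default_rng(51)
        model = get_model(name)
        ptts = TRUE_PARAMS["PTTs"]
        for i in range(10):
            site = SiteMeta(f"s{i}", float(rng.uniform(43, 48)))
            spec = WeatherGenSpec(
                annual_mean=float(rng.uniform(3, 11)),
                noise_sd=float(rng.uniform(0.5, 3.5)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            w = gen_weather(spec, site, [2018, 2019, 2020])
            win = build_window(w, site, 2020, "senescence")
            em = build_window(w, site, 2020, "emergence")
            clim = build_climatology(w, site.site_id, years=[2018, 2019])
            cw = climatology_window(clim, site, 2020, "emergence")
            runner = {"DMs": run_dms}.get(name)
            pred = model.predict(
                win, TRUE_PARAMS[name], emergence_window=em,
                climatology_window=cw, sos_params=ptts,
            )
            expected = SOS_ADJUSTED_ORACLES[name](
                list(win.tmean), list(win.daylength), TRUE_PARAMS[name],
                list(em.tmean), list(em.daylength),
                list(cw.tmean), list(cw.daylength), ptts,
            )
            got = pred.doy if pred.reached else None
            assert got == expected, f"{name} case {i}: {got} != {expected}"
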