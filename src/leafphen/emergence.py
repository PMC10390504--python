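"""Leaf-emergence models.

Eight daily accumulation state machines over an emergence driver window
(1 September of the preceding year through 31 August).  Four simulate
ecodormancy release only (TT, TTs, PTT, PTTs, M1 use forcing, optionally
photoperiod-weighted); AT and SQ add chilling (concurrently and
sequentially, respectively); DP simulates dormancy induction, chilling and
photoperiod/forcing-driven release in three phases.

Predictions are calendar days of year of the focal year (window index minus
122); accumulations never attaining their threshold yield NOT_REACHED.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .base import (
    NOT_REACHED,
    PhenoPrediction,
    WindowBatch,
    cumsum_from,
    first_threshold_crossing,
    sigmoid,
    window_index_to_doy,
    zero_before,
)
from .drivers import DAYS_PER_YEAR, EMERGENCE, DriverWindow

#: photoperiod normalization constant for PTT/PTTs/M1 (hours)
PHOTOPERIOD_SCALE = 24.0


def _round_day(x: float) -> int:
    return int(np.clip(round(float(x)), 1, DAYS_PER_YEAR))


class EmergenceModel:
    """Base class: subclasses provide daily rates and a threshold."""

    name: str = ""
    phenophase: str = EMERGENCE
    param_names: tuple = ()
    integer_params: tuple = ("t0",)
    needs_sos_context: bool = False

    def predict_batch(self, params: Mapping[str, float], batch: WindowBatch) -> np.ndarray:
        """Calendar-DOY predictions for every window; NaN = NOT_REACHED."""
        idx = self._window_index(params, batch.T, batch.L)
        return window_index_to_doy(EMERGENCE, idx)

    def _window_index(self, params, T, L) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict(self, window: DriverWindow, params: Mapping[str, float]) -> PhenoPrediction:
        batch = WindowBatch.from_windows([window])
        doy = self.predict_batch(params, batch)[0]
        return PhenoPrediction(
            site_id=window.site_id,
            focal_year=window.focal_year,
            doy=NOT_REACHED if np.isnan(doy) else int(doy),
        )


class ThermalTime(EmergenceModel):
    """TT: linear forcing above a base temperature until F*."""

    name = "TT"
    param_names = ("t0", "T_base", "F_star")

    def _window_index(self, p, T, L):
        t0 = _round_day(p["t0"])
        rates = zero_before(np.maximum(T - p["T_base"], 0.0), t0)
        idx = first_threshold_crossing(np.cumsum(rates, axis=1), p["F_star"])
        return np.maximum(idx, t0)


class ThermalTimeSigmoid(EmergenceModel):
    """TTs: sigmoidal forcing response 1/(1+exp(-b (T - c)))."""

    name = "TTs"
    param_names = ("t0", "b", "c", "F_star")

    def _window_index(self, p, T, L):
        t0 = _round_day(p["t0"])
        rates = zero_before(sigmoid(p["b"] * (T - p["c"])), t0)
        idx = first_threshold_crossing(np.cumsum(rates, axis=1), p["F_star"])
        return np.maximum(idx, t0)


class PhotoThermalTime(EmergenceModel):
    """PTT: linear forcing weighted by relative photoperiod L/24."""

    name = "PTT"
    param_names = ("t0", "T_base", "F_star")

    def _window_index(self, p, T, L):
        t0 = _round_day(p["t0"])
        rates = zero_before((L / PHOTOPERIOD_SCALE) * np.maximum(T - p["T_base"], 0.0), t0)
        idx = first_threshold_crossing(np.cumsum(rates, axis=1), p["F_star"])
        return np.maximum(idx, t0)


class PhotoThermalTimeSigmoid(EmergenceModel):
    """PTTs: sigmoidal forcing weighted by L/24; also the SOS provider for
    the preceding-spring-adjusted senescence models."""

    name = "PTTs"
    param_names = ("t0", "b", "c", "F_star")

    def _window_index(self, p, T, L):
        t0 = _round_day(p["t0"])
        rates = zero_before((L / PHOTOPERIOD_SCALE) * sigmoid(p["b"] * (T - p["c"])), t0)
        idx = first_threshold_crossing(np.cumsum(rates, axis=1), p["F_star"])
        return np.maximum(idx, t0)


class M1(EmergenceModel):
    """M1: linear forcing weighted by (L/24)^k; k=0 recovers TT, k=1 PTT."""

    name = "M1"
    param_names = ("t0", "T_base", "k", "F_star")

    def _window_index(self, p, T, L):
        t0 = _round_day(p["t0"])
        rates = zero_before(
            (L / PHOTOPERIOD_SCALE) ** p["k"] * np.maximum(T - p["T_base"], 0.0), t0
        )
        idx = first_threshold_crossing(np.cumsum(rates, axis=1), p["F_star"])
        return np.maximum(idx, t0)


class Alternating(EmergenceModel):
    """AT: chill days (T < T_c, strict) and forcing above T_c accrue
    concurrently from t0; emergence once forcing exceeds a + b exp(c C(t))."""

    name = "AT"
    param_names = ("t0", "T_c", "a", "b", "c")

    def _window_index(self, p, T, L):
        t0 = _round_day(p["t0"])
        chill = zero_before((T < p["T_c"]).astype(float), t0)
        force = zero_before(np.maximum(T - p["T_c"], 0.0), t0)
        C = np.cumsum(chill, axis=1)
        S = np.cumsum(force, axis=1)
        thr = p["a"] + p["b"] * np.exp(np.clip(p["c"] * C, -500.0, 500.0))
        return np.maximum(first_threshold_crossing(S, thr), t0)


class Sequential(EmergenceModel):
    """SQ: triangular chilling response until C*, then linear forcing.

    The chilling rate rises linearly from 0 at T_min to 1 at T_opt and falls
    back to 0 at T_max; forcing starts the day the chilling requirement is
    first met (that day also accrues forcing)."""

    name = "SQ"
    param_names = ("t0_chill", "T_min", "T_opt", "T_max", "C_star", "T_base", "F_star")
    integer_params = ("t0_chill",)

    @staticmethod
    def chill_rate(T, T_min, T_opt, T_max):
        up = (T - T_min) / (T_opt - T_min)
        down = (T_max - T) / (T_max - T_opt)
        return np.where(
            (T <= T_min) | (T >= T_max), 0.0, np.where(T <= T_opt, up, down)
        )

    def _window_index(self, p, T, L):
        if not p["T_min"] < p["T_opt"] < p["T_max"]:
            return np.full(T.shape[0], np.nan)
        chill = zero_before(
            self.chill_rate(T, p["T_min"], p["T_opt"], p["T_max"]),
            _round_day(p["t0_chill"]),
        )
        done = first_threshold_crossing(np.cumsum(chill, axis=1), p["C_star"])
        force = np.maximum(T - p["T_base"], 0.0)
        F = cumsum_from(force, done)
        idx = first_threshold_crossing(F, p["F_star"])
        idx[np.isnan(done)] = np.nan
        return np.where(np.isnan(idx), np.nan, np.maximum(idx, done))


class Dormphot(EmergenceModel):
    """DP: dormancy induction, then chilling-adjusted photothermal release.

    Phase 1 accumulates f_T(T) f_L(L) (both decreasing sigmoids) from t0_di
    until D*; phase 2 accumulates chilling 1/(1+exp(a_ch (T - c_ch))) from
    the induction day; phase 3 concurrently accumulates forcing
    sig(b_f (T - c_f)) sig(g_L (L - h_L)) against the chilling-dependent
    requirement F_a exp(-F_b C(t))."""

    name = "DP"
    param_names = (
        "t0_di", "a_di", "b_di", "c_di", "D_star",
        "a_ch", "c_ch",
        "b_f", "c_f", "g_L", "h_L",
        "F_a", "F_b",
    )
    integer_params = ("t0_di",)

    def _window_index(self, p, T, L):
        f_T = sigmoid(-p["a_di"] * (T - p["b_di"]))
        f_L = sigmoid(-10.0 * (L - p["c_di"]))
        induction = zero_before(f_T * f_L, _round_day(p["t0_di"]))
        ind_day = first_threshold_crossing(np.cumsum(induction, axis=1), p["D_star"])

        chill = sigmoid(-p["a_ch"] * (T - p["c_ch"]))
        C = cumsum_from(chill, ind_day)
        force = sigmoid(p["b_f"] * (T - p["c_f"])) * sigmoid(p["g_L"] * (L - p["h_L"]))
        F = cumsum_from(force, ind_day)
        F_crit = p["F_a"] * np.exp(np.clip(-p["F_b"] * C, -500.0, 500.0))
        idx = first_threshold_crossing(F, F_crit)
        idx[np.isnan(ind_day)] = np.nan
        return idx


EMERGENCE_MODELS = {
    m.name: m
    for m in (
        ThermalTime(),
        ThermalTimeSigmoid(),
        PhotoThermalTime(),
        PhotoThermalTimeSigmoid(),
        M1(),
        Alternating(),
        Sequential(),
        Dormphot(),
    )
}


def _runner(name):
    model = EMERGENCE_MODELS[name]

    def run(window: DriverWindow, params: Mapping[str, float]) -> PhenoPrediction:
        return model.predict(window, params)

    run.__name__ = f"run_{name.lower()}"
    run.__doc__ = model.__doc__
    return run


run_tt = _runner("TT")
run_tts = _runner("TTs")
run_ptt = _runner("PTT")
run_ptts = _runner("PTTs")
run_m1 = _runner("M1")
run_at = _runner("AT")
run_sq = _runner("SQ")
run_dp = _runner("DP")
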