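"""Leaf-senescence models.

Six models over a calendar-year driver window.  WM is trigger-based; DM,
JM and DPDI accumulate cooling/short-day rates from a (calibrated or fixed
1 July) start until a threshold; DMs and DPDIs additionally scale that
threshold by the anomaly of the preceding leaf-emergence date relative to
the site's 30-year climatological emergence date, both estimated with a
fitted PTTs model.

Trigger and gate scans begin at the summer solstice (day 172) so that
short winter photoperiods at the start of the calendar year cannot fire
autumn transitions.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

from .base import (
    NOT_REACHED,
    PhenoPrediction,
    WindowBatch,
    cumsum_from,
    first_threshold_crossing,
    sigmoid,
    zero_before,
)
from .drivers import DAYS_PER_YEAR, SENESCENCE, Climatology, DriverWindow
from .emergence import PhotoThermalTimeSigmoid

#: first day scanned for senescence triggers / daylength gates
SOLSTICE_DOY = 172
#: fixed 1 July start for the accumulation models when not calibrated
JULY_FIRST = 182

THRESHOLD_FLOOR = 1e-6

_PTTS = PhotoThermalTimeSigmoid()


def _round_day(x: float) -> int:
    return int(np.clip(round(float(x)), 1, DAYS_PER_YEAR))


def adjust_threshold_by_sos(
    base_threshold: float, sos_current, sos_reference, alpha: float
):
    """Scale an accumulation threshold by the spring-emergence anomaly.

    ``threshold * (1 + alpha * (sos_current - sos_reference))``, floored at a
    small positive epsilon.  With alpha > 0 an earlier-than-reference spring
    shrinks the threshold and pulls senescence earlier.
    """
    adj = base_threshold * (1.0 + alpha * (np.asarray(sos_current, dtype=float) - sos_reference))
    return np.maximum(adj, THRESHOLD_FLOOR)


class SenescenceModel:
    name: str = ""
    phenophase: str = SENESCENCE
    param_names: tuple = ()
    integer_params: tuple = ()
    needs_sos_context: bool = False

    def predict_batch(self, params: Mapping[str, float], batch: WindowBatch) -> np.ndarray:
        return self._window_index(params, batch.T, batch.L)

    def _window_index(self, params, T, L) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict(self, window: DriverWindow, params: Mapping[str, float]) -> PhenoPrediction:
        doy = self.predict_batch(params, WindowBatch.from_windows([window]))[0]
        return PhenoPrediction(
            site_id=window.site_id,
            focal_year=window.focal_year,
            doy=NOT_REACHED if np.isnan(doy) else int(doy),
        )


class White(SenescenceModel):
    """WM: instant triggers — cool-and-short-day or extreme cold, scanned
    from the summer solstice."""

    name = "WM"
    param_names = ("L_crit", "T_crit", "T_frost")

    def _window_index(self, p, T, L):
        cond = ((T < p["T_crit"]) & (L < p["L_crit"])) | (T < p["T_frost"])
        cond = zero_before(cond.astype(float), SOLSTICE_DOY)
        return first_threshold_crossing(cond, 1.0)


class Delpierre(SenescenceModel):
    """DM: on days with T < T_b and L < L_b accumulate
    (T_b - T)^x (L/L_b)^y from the start day until Y*."""

    name = "DM"
    param_names = ("start", "T_b", "L_b", "x", "y", "Y_star")
    integer_params = ("start", "x", "y")

    def _rates(self, p, T, L):
        x = int(np.clip(round(float(p["x"])), 0, 2))
        y = int(np.clip(round(float(p["y"])), 0, 2))
        qual = (T < p["T_b"]) & (L < p["L_b"])
        return np.where(qual, (p["T_b"] - T) ** x * (L / p["L_b"]) ** y, 0.0)

    def _window_index(self, p, T, L):
        start = _round_day(p["start"])
        rates = zero_before(self._rates(p, T, L), start)
        idx = first_threshold_crossing(np.cumsum(rates, axis=1), p["Y_star"])
        return np.maximum(idx, start)


class Jeong(SenescenceModel):
    """JM: once autumn daylength first drops below P_crit, accumulate
    cold-degree-days max(T_b - T, 0) until Y*."""

    name = "JM"
    param_names = ("P_crit", "T_b", "Y_star")

    def _window_index(self, p, T, L):
        gate_open = zero_before((L < p["P_crit"]).astype(float), SOLSTICE_DOY)
        gate = first_threshold_crossing(gate_open, 1.0)
        rates = np.maximum(p["T_b"] - T, 0.0)
        idx = first_threshold_crossing(cumsum_from(rates, gate), p["Y_star"])
        return np.where(np.isnan(idx), np.nan, np.maximum(idx, gate))


class DormphotInduction(SenescenceModel):
    """DPDI: the dormancy-induction stage of the Dormphot model run as a
    stand-alone senescence model — cool-temperature and short-day sigmoids
    multiply into a daily rate accumulated from the start day until D*."""

    name = "DPDI"
    param_names = ("start", "a", "b", "c", "D_star")
    integer_params = ("start",)

    def _rates(self, p, T, L):
        return sigmoid(-p["a"] * (T - p["b"])) * sigmoid(-10.0 * (L - p["c"]))

    def _window_index(self, p, T, L):
        start = _round_day(p["start"])
        rates = zero_before(self._rates(p, T, L), start)
        idx = first_threshold_crossing(np.cumsum(rates, axis=1), p["D_star"])
        return np.maximum(idx, start)


class _SosAdjusted(SenescenceModel):
    """Mixin-style base: run PTTs for the focal and climatological emergence
    dates, scale the base model's threshold, then run the base model."""

    needs_sos_context = True
    base_cls: type = SenescenceModel
    threshold_name: str = ""

    def __init__(self) -> None:
        self._base = self.base_cls()

    def predict_batch(self, params: Mapping[str, float], batch: WindowBatch) -> np.ndarray:
        if batch.T_em is None or batch.T_clim is None or batch.sos_params is None:
            raise ValueError(
                f"{self.name} needs emergence/climatology windows and fitted "
                "PTTs parameters in the batch"
            )
        # the SOS provider's parameters are fixed during calibration of the
        # senescence parameters, so the PTTs runs are cached per batch
        cache_key = tuple(sorted(batch.sos_params.items()))
        cache = getattr(batch, "_sos_cache", None)
        if cache is None or cache[0] != cache_key:
            sos_cur = _PTTS._window_index(batch.sos_params, batch.T_em, batch.L_em)
            sos_ref = _PTTS._window_index(batch.sos_params, batch.T_clim, batch.L_clim)
            batch._sos_cache = (cache_key, sos_cur, sos_ref)
        else:
            _, sos_cur, sos_ref = cache
        thr = adjust_threshold_by_sos(
            params[self.threshold_name], sos_cur, sos_ref, params["alpha"]
        )
        thr = np.where(np.isnan(sos_cur) | np.isnan(sos_ref), np.nan, thr)
        start = _round_day(params["start"])
        rates = zero_before(self._base._rates(params, batch.T, batch.L), start)
        idx = first_threshold_crossing(np.cumsum(rates, axis=1), thr)
        idx = np.maximum(idx, start)
        idx[np.isnan(thr)] = np.nan
        return idx

    def predict(
        self,
        window: DriverWindow,
        params: Mapping[str, float],
        emergence_window: Optional[DriverWindow] = None,
        climatology_window: Optional[DriverWindow] = None,
        sos_params: Optional[Mapping[str, float]] = None,
    ) -> PhenoPrediction:
        batch = WindowBatch.from_windows(
            [window],
            T_em=None if emergence_window is None else emergence_window.tmean[None, :],
            L_em=None if emergence_window is None else emergence_window.daylength[None, :],
            T_clim=None if climatology_window is None else climatology_window.tmean[None, :],
            L_clim=None if climatology_window is None else climatology_window.daylength[None, :],
            sos_params=sos_params,
        )
        doy = self.predict_batch(params, batch)[0]
        return PhenoPrediction(
            site_id=window.site_id,
            focal_year=window.focal_year,
            doy=NOT_REACHED if np.isnan(doy) else int(doy),
        )


class DelpierreSos(_SosAdjusted):
    """DMs: the Delpierre model with its threshold Y* modulated by the
    preceding spring leaf-emergence anomaly."""

    name = "DMs"
    param_names = Delpierre.param_names + ("alpha",)
    integer_params = Delpierre.integer_params
    base_cls = Delpierre
    threshold_name = "Y_star"


class DormphotInductionSos(_SosAdjusted):
    """DPDIs: DPDI with its threshold D* modulated by the preceding spring
    leaf-emergence anomaly."""

    name = "DPDIs"
    param_names = DormphotInduction.param_names + ("alpha",)
    integer_params = DormphotInduction.integer_params
    base_cls = DormphotInduction
    threshold_name = "D_star"


SENESCENCE_MODELS = {
    m.name: m
    for m in (
        White(),
        Delpierre(),
        Jeong(),
        DormphotInduction(),
        DelpierreSos(),
        DormphotInductionSos(),
    )
}


def _runner(name):
    model = SENESCENCE_MODELS[name]

    def run(window, params, **kwargs):
        return model.predict(window, params, **kwargs)

    run.__name__ = f"run_{name.lower()}"
    run.__doc__ = model.__doc__
    return run


run_white = _runner("WM")
run_delpierre = _runner("DM")
run_jeong = _runner("JM")
run_dpdi = _runner("DPDI")
run_dms = _runner("DMs")
run_dpdis = _runner("DPDIs")
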