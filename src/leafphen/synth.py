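"""Synthetic weather, greenness and observation generators with known truth.

The generators emulate the study system — a multi-site temperate/boreal
temperature gradient with a seasonal cycle, AR(1) day-to-day noise and an
optional warming trend; double-logistic canopy greenness curves with
Gaussian noise and injected outliers; phenology observations produced by
running a chosen process model forward with known parameters plus rounded
observation noise; and scenario temperature ensembles for 2001-2100.
Everything is reproducible under a fixed integer seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .base import sigmoid
from .drivers import DAYS_PER_YEAR, EMERGENCE, SENESCENCE, SiteMeta
from .dataset import build_dataset
from .registry import get_model


@dataclass(frozen=True)
class WeatherGenSpec:
    """Daily mean temperature generator settings.

    ``tmean(d) = annual_mean + warming_trend*(year - first_year)
    + seasonal_amplitude*cos(2*pi*(doy - peak_doy)/365) + AR(1) noise``
    with ``noise_sd`` the marginal (stationary) noise standard deviation.
    """

    annual_mean: float = 7.0
    seasonal_amplitude: float = 14.0
    peak_doy: int = 200
    ar1_rho: float = 0.7
    noise_sd: float = 3.0
    warming_trend: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")


@dataclass(frozen=True)
class GccGenSpec:
    """Double-logistic greenness generator settings.

    ``g(d) = baseline + amplitude*(sig(r1*(d - s1)) - sig(r2*(d - s2)))``
    plus Gaussian noise; a fraction ``outlier_rate`` of points is displaced
    by +/-(5-10) noise standard deviations.
    """

    baseline: float = 0.33
    amplitude: float = 0.10
    s1: float = 140.0
    r1: float = 0.15
    s2: float = 280.0
    r2: float = 0.10
    noise_sd: float = 0.003
    outlier_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline < self.baseline + self.amplitude < 1.0:
            raise ValueError("need 0 < baseline < baseline + amplitude < 1")
        if not self.s1 < self.s2:
            raise ValueError("rise midpoint must precede fall midpoint")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")


def _dates_for_year(year: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(dt.date(year, 1, 1))
    return pd.date_range(start, periods=DAYS_PER_YEAR, freq="D")


def gen_weather(
    spec: WeatherGenSpec, site: SiteMeta, years: Sequence[int]
) -> pd.DataFrame:
    """Daily mean temperature table for one site over ``years``.

    The AR(1) noise runs continuously across year boundaries with
    innovation sd ``noise_sd*sqrt(1 - rho^2)`` so the marginal sd is
    ``noise_sd``.
    """
    years = list(years)
    rng = np.random.default_rng(spec.seed)
    n = DAYS_PER_YEAR * len(years)
    noise = np.zeros(n)
    if spec.noise_sd > 0:
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar1_rho**2)
        z = rng.standard_normal(n)
        innov = innov_sd * z
        innov[0] = spec.noise_sd * z[0]
        # AR(1) recursion noise[t] = rho*noise[t-1] + innov[t] via lfilter
        noise = lfilter([1.0], [1.0, -spec.ar1_rho], innov)
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), len(years))
    year_arr = np.repeat(np.asarray(years), DAYS_PER_YEAR)
    base = (
        spec.annual_mean
        + spec.warming_trend * (year_arr - years[0])
        + spec.seasonal_amplitude * np.cos(2.0 * np.pi * (doy - spec.peak_doy) / DAYS_PER_YEAR)
    )
    dates = pd.DatetimeIndex(np.concatenate([_dates_for_year(y) for y in years]))
    return pd.DataFrame(
        {
            "site_id": site.site_id,
            "date": dates,
            "year": year_arr,
            "doy": doy,
            "tmean": base + noise,
        }
    )


def gen_gcc(
    spec: GccGenSpec, year: int, roi_id: str = "roi1", site_id: str = "site1"
) -> Tuple[pd.DataFrame, dict]:
    """One year of daily greenness; returns (series, ground truth).

    Ground truth carries the generator's transition midpoints (sos=s1,
    eos=s2) and the injected-outlier day indices.
    """
    rng = np.random.default_rng(spec.seed)
    d = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    clean = spec.baseline + spec.amplitude * (
        sigmoid(spec.r1 * (d - spec.s1)) - sigmoid(spec.r2 * (d - spec.s2))
    )
    gcc = clean + rng.normal(0.0, spec.noise_sd, DAYS_PER_YEAR) if spec.noise_sd > 0 else clean.copy()
    is_outlier = rng.random(DAYS_PER_YEAR) < spec.outlier_rate
    magnitude = rng.uniform(5.0, 10.0, DAYS_PER_YEAR) * spec.noise_sd
    sign = np.where(rng.random(DAYS_PER_YEAR) < 0.5, -1.0, 1.0)
    gcc = np.where(is_outlier, gcc + sign * magnitude, gcc)
    df = pd.DataFrame(
        {
            "roi_id": roi_id,
            "site_id": site_id,
            "date": _dates_for_year(year),
            "doy": np.arange(1, DAYS_PER_YEAR + 1),
            "gcc": gcc,
            "qa_flag": "raw",
        }
    )
    truth = {
        "sos": spec.s1,
        "eos": spec.s2,
        "outlier_doys": np.flatnonzero(is_outlier) + 1,
    }
    return df, truth


def gen_observations(
    model_name: str,
    true_params: Mapping[str, float],
    site_specs: Sequence[Tuple[SiteMeta, WeatherGenSpec]],
    years: Sequence[int],
    obs_noise_sd: float = 3.0,
    seed: int = 0,
    species: str = "synthetic",
    sos_params: Optional[Mapping[str, float]] = None,
    acadian_fraction: float = 0.25,
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Ground-truth phenology observations from a forward model run.

    Weather is generated per site (an extra preceding year is added so
    emergence windows resolve), the named model is run forward with
    ``true_params`` for every site-year in ``years``, and rounded Gaussian
    noise (sd ``obs_noise_sd`` days) is added.  Site-years where the model
    returns NOT_REACHED are dropped and counted.  The first
    ``acadian_fraction`` of sites is tagged ``acadian`` (the regional
    network), the rest ``phenocam``.

    Returns (observations, weather, n_not_reached).
    """
    model = get_model(model_name)
    years = list(years)
    gen_years = [years[0] - 1] + years
    ss = np.random.SeedSequence(seed)
    site_seeds = ss.generate_state(len(site_specs))
    rng = np.random.default_rng(ss.spawn(1)[0])

    weather_parts = []
    sites = {}
    for (site, wspec), sseed in zip(site_specs, site_seeds):
        sites[site.site_id] = site
        wspec_seeded = WeatherGenSpec(**{**wspec.__dict__, "seed": int(sseed) & 0x7FFFFFFF})
        weather_parts.append(gen_weather(wspec_seeded, site, gen_years))
    weather = pd.concat(weather_parts, ignore_index=True)

    n_acadian = max(1, int(round(acadian_fraction * len(site_specs))))
    tags = {
        site.site_id: ("acadian" if i < n_acadian else "phenocam")
        for i, (site, _) in enumerate(site_specs)
    }

    rows = [
        {
            "site_id": site.site_id,
            "year": y,
            "species": species,
            "phenophase": model.phenophase,
            "doy": 0,
            "network_tag": tags[site.site_id],
        }
        for site, _ in site_specs
        for y in years
    ]
    skeleton = pd.DataFrame(rows)
    ds = build_dataset(skeleton, weather, sites, sos_params=sos_params)
    pred = model.predict_batch(true_params, ds.batch)
    reached = ~np.isnan(pred)
    n_not_reached = int((~reached).sum())
    if not reached.any():
        raise RuntimeError(
            f"{model_name}: no site-year reached its threshold; the true "
            "parameters do not match the generated weather"
        )
    obs = skeleton.loc[reached].reset_index(drop=True)
    clean = pred[reached]
    noise = rng.normal(0.0, obs_noise_sd, clean.size) if obs_noise_sd > 0 else 0.0
    obs["doy"] = np.round(clean + noise).astype(int)
    obs["true_doy"] = np.round(clean).astype(int)
    return obs, weather, n_not_reached


def gen_scenario_ensemble(
    base_spec: WeatherGenSpec,
    site: SiteMeta,
    n_members: int,
    trend_range: Tuple[float, float],
    seed: int = 0,
    years: Sequence[int] = tuple(range(2000, 2101)),
) -> List[pd.DataFrame]:
    """Scenario temperature ensemble: each member draws a warming trend
    uniformly from ``trend_range`` (degC/yr) and independent AR(1) noise."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    ss = np.random.SeedSequence(seed)
    member_seeds = ss.generate_state(n_members + 1)
    trend_rng = np.random.default_rng(member_seeds[-1])
    members = []
    for m in range(n_members):
        trend = float(trend_rng.uniform(*trend_range))
        spec = WeatherGenSpec(
            **{**base_spec.__dict__, "warming_trend": trend,
               "seed": int(member_seeds[m]) & 0x7FFFFFFF}
        )
        df = gen_weather(spec, site, list(years))
        df["member_id"] = m
        df.attrs["member_id"] = m
        df.attrs["warming_trend"] = trend
        members.append(df)
    return members
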