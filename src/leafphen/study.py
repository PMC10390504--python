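"""Frozen study conditions for the synthetic ground-truth experiments.

This module pins the default experimental design used by the analysis
scripts and the acceptance checks: an eight-site temperature gradient
(annual means 10 down to 4 degC over latitudes 44-47 N, emulating a
temperate-boreal transition), ten focal years per site (n = 80 site-years),
AR(1) daily temperature noise of 3 degC, observation noise of 3 days, and
one physiologically plausible ground-truth parameter set per model chosen
so every model resolves a date for every site-year with a clear
temperature signal (inter-annual/inter-site spread of roughly 5-13 days).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .drivers import SiteMeta
from .synth import WeatherGenSpec

N_SITES = 8
FOCAL_YEARS = tuple(range(2001, 2011))
OBS_NOISE_SD_DAYS = 3.0


def gradient_sites(
    n_sites: int = N_SITES,
    lat_range: Tuple[float, float] = (44.0, 47.0),
    mean_range: Tuple[float, float] = (10.0, 4.0),
    seasonal_amplitude: float = 14.0,
    ar1_rho: float = 0.7,
    noise_sd: float = 3.0,
    warming_trend: float = 0.0,
) -> List[Tuple[SiteMeta, WeatherGenSpec]]:
    """The multi-site temperature gradient: cooler and higher-latitude
    northeastward, as in a coastal temperate-boreal transect."""
    out = []
    for i in range(n_sites):
        frac = i / max(1, n_sites - 1)
        site = SiteMeta(f"site{i:02d}", latitude=lat_range[0] + frac * (lat_range[1] - lat_range[0]))
        spec = WeatherGenSpec(
            annual_mean=mean_range[0] + frac * (mean_range[1] - mean_range[0]),
            seasonal_amplitude=seasonal_amplitude,
            ar1_rho=ar1_rho,
            noise_sd=noise_sd,
            warming_trend=warming_trend,
            seed=i,  # reseeded per experiment by gen_observations
        )
        out.append((site, spec))
    return out


#: Ground-truth parameter vectors used to generate observations per model.
TRUE_PARAMS: Dict[str, dict] = {
    # emergence
    "TT": dict(t0=123, T_base=5.0, F_star=150.0),
    "TTs": dict(t0=123, b=0.5, c=8.0, F_star=30.0),
    "PTT": dict(t0=123, T_base=5.0, F_star=80.0),
    "PTTs": dict(t0=123, b=0.5, c=8.0, F_star=18.0),
    "M1": dict(t0=123, T_base=5.0, k=2.0, F_star=50.0),
    "AT": dict(t0=62, T_c=5.0, a=100.0, b=500.0, c=-0.05),
    "SQ": dict(
        t0_chill=32, T_min=-10.0, T_opt=2.0, T_max=12.0,
        C_star=60.0, T_base=5.0, F_star=100.0,
    ),
    "DP": dict(
        t0_di=10, a_di=0.2, b_di=15.0, c_di=13.0, D_star=20.0,
        a_ch=0.3, c_ch=5.0, b_f=1.0, c_f=10.0, g_L=0.5, h_L=10.0,
        F_a=80.0, F_b=0.01,
    ),
    # senescence
    "WM": dict(L_crit=14.0, T_crit=8.0, T_frost=-5.0),
    "DM": dict(start=182, T_b=20.0, L_b=14.0, x=1, y=1, Y_star=250.0),
    "JM": dict(P_crit=13.0, T_b=22.0, Y_star=300.0),
    "DPDI": dict(start=182, a=0.2, b=12.0, c=13.0, D_star=15.0),
    "DMs": dict(start=182, T_b=20.0, L_b=14.0, x=1, y=1, Y_star=250.0, alpha=0.02),
    "DPDIs": dict(start=182, a=0.2, b=12.0, c=13.0, D_star=15.0, alpha=0.02),
}

#: PTTs parameters used as the SOS provider when generating observations
#: for the preceding-spring-adjusted senescence models.
SOS_PROVIDER_PARAMS = TRUE_PARAMS["PTTs"]
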