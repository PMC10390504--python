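"""Century-scale phenology projection under scenario temperature series.

A fitted emergence model and a fitted senescence model are run over every
focal year 2001-2100 of each ensemble member's daily temperature series;
per-period changes (mid- and late-century versus a baseline) are
summarized per member and reported as ensemble means with 5th-95th
percentile bounds.  Years where a model's threshold is never reached are
recorded as missing, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .base import WindowBatch
from .calibrate import ModelFit
from .dataset import build_dataset
from .drivers import (
    DAYS_PER_YEAR,
    EMERGENCE,
    EMERGENCE_ANCHOR_DOY,
    EMERGENCE_TAIL_DAYS,
    SENESCENCE,
    SiteMeta,
    build_window,
    compute_daylength,
)
from .registry import get_model


def _stack_windows(weather: pd.DataFrame, site: SiteMeta, years) -> Tuple[WindowBatch, WindowBatch]:
    """Century-scale window stacks without per-year table filtering.

    Equivalent to calling :func:`leafphen.drivers.build_window` per focal
    year, but the site's standardized years are pivoted into one array
    first (a century of daily drivers is 36,500 rows; per-window filtering
    would rescan them 200 times).
    """
    sel = weather[weather["site_id"] == site.site_id]
    yr = sel["year"].to_numpy() if "year" in sel.columns else pd.to_datetime(sel["date"]).dt.year.to_numpy()
    tmean = sel["tmean"].to_numpy(dtype=float)
    by_year = {}
    for y in np.unique(yr):
        vals = tmean[yr == y]
        if len(vals) != DAYS_PER_YEAR:
            raise ValueError(f"year {y} of site {site.site_id!r} is not standardized")
        by_year[int(y)] = vals
    missing = [int(y) for y in list(years) + [min(years) - 1] if int(y) not in by_year]
    if missing:
        raise ValueError(f"scenario weather missing years {sorted(set(missing))}")
    em_T = np.stack(
        [
            np.concatenate(
                [by_year[y - 1][EMERGENCE_ANCHOR_DOY - 1 :],
                 by_year[y][: DAYS_PER_YEAR - EMERGENCE_TAIL_DAYS]]
            )
            for y in map(int, years)
        ]
    )
    sen_T = np.stack([by_year[int(y)] for y in years])
    em_doy = np.concatenate(
        [np.arange(EMERGENCE_ANCHOR_DOY, DAYS_PER_YEAR + 1),
         np.arange(1, DAYS_PER_YEAR - EMERGENCE_TAIL_DAYS + 1)]
    )
    em_L = np.tile(compute_daylength(site.latitude, em_doy), (len(years), 1))
    sen_L = np.tile(
        compute_daylength(site.latitude, np.arange(1, DAYS_PER_YEAR + 1)),
        (len(years), 1),
    )
    return (
        WindowBatch(phenophase=EMERGENCE, T=em_T, L=em_L),
        WindowBatch(phenophase=SENESCENCE, T=sen_T, L=sen_L),
    )


@dataclass
class ProjectionSeries:
    """Yearly projected phenology for one site and ensemble member."""

    site_id: str
    emergence_model: str
    senescence_model: str
    member_id: int
    years: np.ndarray
    sos: np.ndarray  # calendar DOY, NaN where NOT_REACHED
    eos: np.ndarray

    @property
    def season_length(self) -> np.ndarray:
        return self.eos - self.sos

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "member_id": self.member_id,
                "year": self.years,
                "sos": self.sos,
                "eos": self.eos,
                "season_length": self.season_length,
            }
        )


@dataclass
class ChangeSummary:
    """Ensemble change for one period relative to the baseline (days)."""

    period: str
    delta_sos: float
    delta_eos: float
    delta_season: float
    p5: Dict[str, float]
    p95: Dict[str, float]
    n_members_used: int
    per_member: pd.DataFrame = field(repr=False, default=None)


def simulate_series(
    emergence_fit: ModelFit,
    senescence_fit: ModelFit,
    scenario_weather: pd.DataFrame,
    site: SiteMeta,
    years: Sequence[int] = tuple(range(2001, 2101)),
    member_id: int = 0,
    sos_params: Optional[dict] = None,
) -> ProjectionSeries:
    """Run both fitted models over every focal year of one member.

    ``scenario_weather`` must cover ``min(years) - 1`` (emergence windows
    need the preceding autumn).  ``sos_params`` is only needed when the
    senescence model is one of the preceding-spring-adjusted variants.
    """
    years = np.asarray(sorted(years))
    sites = {site.site_id: site}
    em_model = get_model(emergence_fit.model_name)
    sen_model = get_model(senescence_fit.model_name)

    em_batch, sen_batch = _stack_windows(scenario_weather, site, years)
    sos = em_model.predict_batch(emergence_fit.params, em_batch)

    if sen_model.needs_sos_context:
        obs = pd.DataFrame(
            {
                "site_id": site.site_id,
                "year": years,
                "species": "projected",
                "phenophase": SENESCENCE,
                "doy": 0,
            }
        )
        ds = build_dataset(obs, scenario_weather, sites, sos_params=sos_params)
        eos = sen_model.predict_batch(senescence_fit.params, ds.batch)
    else:
        eos = sen_model.predict_batch(senescence_fit.params, sen_batch)
    return ProjectionSeries(
        site_id=site.site_id,
        emergence_model=emergence_fit.model_name,
        senescence_model=senescence_fit.model_name,
        member_id=member_id,
        years=years,
        sos=np.asarray(sos, dtype=float),
        eos=np.asarray(eos, dtype=float),
    )


def _window_mean(values: np.ndarray, years: np.ndarray, lo: int, hi: int) -> float:
    sel = values[(years >= lo) & (years <= hi)]
    sel = sel[~np.isnan(sel)]
    return float(np.mean(sel)) if sel.size else np.nan


def summarize_changes(
    series: Sequence[ProjectionSeries],
    baseline: Tuple[int, int] = (2001, 2020),
    mid: Tuple[int, int] = (2041, 2060),
    late: Tuple[int, int] = (2081, 2100),
) -> Dict[str, ChangeSummary]:
    """Per-member period-mean changes, then ensemble mean and percentiles.

    For each member and quantity (SOS, EOS, season length) the change is
    ``mean(period) - mean(baseline)`` over resolvable years; members with no
    resolvable years in a window are excluded and counted.  Output is
    invariant to member ordering.
    """
    periods = {"mid_century": mid, "late_century": late}
    for name, (lo, hi) in {"baseline": baseline, **periods}.items():
        if not 2001 <= lo <= hi <= 2100:
            raise ValueError(f"{name} window {lo}-{hi} outside 2001-2100")
    out: Dict[str, ChangeSummary] = {}
    ordered = sorted(series, key=lambda s: s.member_id)
    for pname, (lo, hi) in periods.items():
        rows = []
        for s in ordered:
            deltas = {}
            for qty, values in (
                ("sos", s.sos), ("eos", s.eos), ("season", s.season_length)
            ):
                base = _window_mean(values, s.years, *baseline)
                per = _window_mean(values, s.years, lo, hi)
                deltas[qty] = per - base
            rows.append({"member_id": s.member_id, **deltas})
        per_member = pd.DataFrame(rows)
        valid = per_member.dropna()
        if valid.empty:
            raise ValueError(f"no member has resolvable years for {pname}")
        mean = valid[["sos", "eos", "season"]].mean()
        p5 = valid[["sos", "eos", "season"]].quantile(0.05)
        p95 = valid[["sos", "eos", "season"]].quantile(0.95)
        out[pname] = ChangeSummary(
            period=pname,
            delta_sos=float(mean["sos"]),
            delta_eos=float(mean["eos"]),
            delta_season=float(mean["season"]),
            p5={q: float(p5[q]) for q in ("sos", "eos", "season")},
            p95={q: float(p95[q]) for q in ("sos", "eos", "season")},
            n_members_used=len(valid),
            per_member=per_member,
        )
    return out


def decompose_extension(delta_sos: float, delta_eos: float) -> float:
    """Fraction of the season-length extension due to earlier emergence:
    (-delta_sos) / (delta_eos - delta_sos)."""
    denom = delta_eos - delta_sos
    if denom == 0:
        raise ValueError("zero season-length change: decomposition undefined")
    return float(-delta_sos / denom)
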