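"""Observation datasets: phenology records matched to driver windows.

A :class:`Dataset` pairs a table of (site, year, species, phenophase,
day-of-year) observations with a stacked :class:`~leafphen.base.WindowBatch`
of matching driver windows, plus the per-observation metadata the
validation exercises need (network tag, annual mean temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .base import WindowBatch
from .drivers import (
    EMERGENCE,
    SENESCENCE,
    SiteMeta,
    build_climatology,
    build_window,
    climatology_window,
)

OBS_COLUMNS = ("site_id", "year", "species", "phenophase", "doy")


@dataclass
class Dataset:
    """Observations plus their driver windows for one phenophase."""

    observations: pd.DataFrame
    batch: WindowBatch

    def __post_init__(self) -> None:
        self.observations = self.observations.reset_index(drop=True)
        if len(self.observations) != self.batch.n:
            raise ValueError("one window required per observation")
        phases = set(self.observations["phenophase"])
        if len(phases) > 1:
            raise ValueError(f"mixed phenophases in dataset: {sorted(phases)}")

    @property
    def n(self) -> int:
        return len(self.observations)

    @property
    def phenophase(self) -> str:
        return self.batch.phenophase

    @property
    def obs_doy(self) -> np.ndarray:
        return self.observations["doy"].to_numpy(dtype=float)

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Dataset(
            observations=self.observations.iloc[idx],
            batch=self.batch.subset(idx),
        )

    def with_sos_params(self, sos_params: Mapping[str, float]) -> "Dataset":
        """Attach fitted PTTs parameters for the SOS-adjusted models."""
        return Dataset(
            observations=self.observations,
            batch=replace(self.batch, sos_params=dict(sos_params)),
        )


def build_dataset(
    observations: pd.DataFrame,
    weather: pd.DataFrame,
    sites: Mapping[str, SiteMeta],
    sos_params: Optional[Mapping[str, float]] = None,
) -> Dataset:
    """Assemble a Dataset from observation and weather tables.

    Observations must share one phenophase.  Senescence datasets also get
    emergence windows and site-climatology windows stacked alongside, so the
    preceding-spring-adjusted models can run; the climatology for a focal
    year uses all available years before it (falling back to all years when
    none precede), capped at 30.
    """
    missing = [c for c in OBS_COLUMNS if c not in observations.columns]
    if missing:
        raise ValueError(f"observations missing columns {missing}")
    obs = observations.reset_index(drop=True).copy()
    phases = set(obs["phenophase"])
    if len(phases) != 1:
        raise ValueError(f"need one phenophase per dataset, got {sorted(phases)}")
    phase = phases.pop()

    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    weather["_year"] = weather["date"].dt.year

    if "annual_mean_temp" not in obs.columns:
        amt = weather.groupby(["site_id", "_year"])["tmean"].mean()
        obs["annual_mean_temp"] = [
            amt.loc[(r.site_id, int(r.year))] for r in obs.itertuples()
        ]
    if "network_tag" not in obs.columns:
        obs["network_tag"] = "phenocam"

    windows, em_windows, clim_windows = [], [], []
    clim_cache: dict = {}
    for row in obs.itertuples():
        site = sites[row.site_id]
        year = int(row.year)
        windows.append(build_window(weather, site, year, phase))
        if phase == SENESCENCE:
            em_windows.append(build_window(weather, site, year, EMERGENCE))
            avail = sorted(weather.loc[weather["site_id"] == site.site_id, "_year"].unique())
            prior = tuple(y for y in avail if y < year) or tuple(avail)
            key = (site.site_id, prior)
            if key not in clim_cache:
                clim_cache[key] = build_climatology(weather, site.site_id, years=prior)
            clim_windows.append(
                climatology_window(clim_cache[key], site, year, EMERGENCE)
            )

    extras = {}
    if phase == SENESCENCE:
        extras = dict(
            T_em=np.stack([w.tmean for w in em_windows]),
            L_em=np.stack([w.daylength for w in em_windows]),
            T_clim=np.stack([w.tmean for w in clim_windows]),
            L_clim=np.stack([w.daylength for w in clim_windows]),
            sos_params=dict(sos_params) if sos_params else None,
        )
    return Dataset(observations=obs, batch=WindowBatch.from_windows(windows, **extras))
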