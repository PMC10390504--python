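"""Daily weather ingestion and model-ready driver windows.

Process-based phenology models consume one phenological year of daily mean
air temperature T(t) and photoperiod L(t) per site-year.  Leaf-emergence
models run on a window anchored at 1 September of the preceding calendar
year, so autumn dormancy induction and winter chilling fall inside the
window; leaf-senescence models run on the calendar year itself.  Every year
is standardized to 365 days (leap years drop 31 December, the Daymet
convention), so windows align day-for-day across years.

Weather tables are plain pandas DataFrames with columns
``site_id, date, tmean`` (ISO dates, degrees Celsius); optional
``tmin``/``tmax`` columns are ignored by the models.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
#: 1 September in the standardized (non-leap) calendar.
EMERGENCE_ANCHOR_DOY = 244
#: days of the preceding year inside an emergence window (1 Sep - 31 Dec)
EMERGENCE_TAIL_DAYS = DAYS_PER_YEAR - EMERGENCE_ANCHOR_DOY + 1  # 122

EMERGENCE = "emergence"
SENESCENCE = "senescence"
PHENOPHASES = (EMERGENCE, SENESCENCE)


@dataclass(frozen=True)
class SiteMeta:
    """Static site metadata; latitude drives the photoperiod model."""

    site_id: str
    latitude: float
    longitude: float = 0.0
    elevation: Optional[float] = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")


@dataclass
class DriverWindow:
    """One phenological year of drivers for one site.

    ``day_axis`` is 1..365; for emergence windows index 1 is 1 September of
    ``focal_year - 1`` and index 123 is 1 January of the focal year, for
    senescence windows index i is calendar day-of-year i.  ``doy`` holds the
    calendar day-of-year of each position (used for photoperiod and for
    converting window indices back to reportable dates).
    """

    site_id: str
    focal_year: int
    phenophase: str
    day_axis: np.ndarray
    tmean: np.ndarray
    daylength: np.ndarray
    doy: np.ndarray

    def __post_init__(self) -> None:
        if self.phenophase not in PHENOPHASES:
            raise ValueError(f"unknown phenophase {self.phenophase!r}")
        for name in ("day_axis", "tmean", "daylength", "doy"):
            arr = np.asarray(getattr(self, name), dtype=float if name != "day_axis" else int)
            if arr.shape != (DAYS_PER_YEAR,):
                raise ValueError(f"{name} must have {DAYS_PER_YEAR} entries")
            setattr(self, name, arr)

    def index_to_doy(self, index: int) -> int:
        """Map a 1-based window index to a calendar day of the focal year.

        For emergence windows, indices in the preceding autumn map to
        non-positive values (e.g. index 122 -> 0 = 31 Dec of the prior year).
        """
        if self.phenophase == EMERGENCE:
            return int(index) - EMERGENCE_TAIL_DAYS
        return int(index)


@dataclass
class Climatology:
    """Day-wise long-term mean temperature for one site."""

    site_id: str
    tmean_by_doy: np.ndarray
    n_years: int

    def __post_init__(self) -> None:
        self.tmean_by_doy = np.asarray(self.tmean_by_doy, dtype=float)
        if self.tmean_by_doy.shape != (DAYS_PER_YEAR,):
            raise ValueError("climatology needs exactly 365 day-wise means")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")


def compute_daylength(latitude: float, doy) -> np.ndarray | float:
    """Photoperiod in hours from latitude and day of year.

    Standard astronomical formulation: solar declination
    ``delta = -23.44 * cos(2*pi*(doy + 10)/365)`` degrees and hour angle
    ``cos(H0) = -tan(lat) * tan(delta)``, with the hour-angle argument
    clamped to [-1, 1] so polar day/night saturate at 24 h / 0 h.
    """
    doy_arr = np.asarray(doy)
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    if np.any(doy_arr < 1) or np.any(doy_arr > DAYS_PER_YEAR):
        raise ValueError("doy outside [1, 365]")
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy_arr + 10) / DAYS_PER_YEAR))
    cos_h0 = np.clip(-np.tan(np.deg2rad(latitude)) * np.tan(decl), -1.0, 1.0)
    hours = 24.0 * np.arccos(cos_h0) / np.pi
    if np.isscalar(doy):
        return float(hours)
    return hours


def standardize_year(records: pd.DataFrame) -> pd.DataFrame:
    """Standardize one site-year of daily weather to exactly 365 days.

    Accepts 365 or 366 consecutive daily records; in leap years the
    31 December record is dropped (Daymet convention).  Gaps or duplicated
    dates are rejected with the offending dates listed.  A ``doy`` column
    with positions 1..365 is (re)written.
    """
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    if df.empty:
        raise ValueError("empty site-year")
    dups = df.loc[df["date"].duplicated(), "date"]
    if len(dups):
        raise ValueError(f"duplicated dates: {[d.date().isoformat() for d in dups]}")
    year = int(df["date"].iloc[0].year)
    leap = calendar.isleap(year)
    full = pd.date_range(dt.date(year, 1, 1), dt.date(year, 12, 31), freq="D")
    have = pd.DatetimeIndex(df["date"])
    missing = full.difference(have)
    dec31 = pd.Timestamp(dt.date(year, 12, 31))
    if leap and list(missing) == [dec31]:
        missing = missing.delete(0)  # already Daymet-shaped
    if len(missing):
        raise ValueError(
            f"missing dates in {year}: {[d.date().isoformat() for d in missing]}"
        )
    if leap and (df["date"] == dec31).any():
        df = df[df["date"] != dec31].reset_index(drop=True)
    if len(df) != DAYS_PER_YEAR:
        raise ValueError(f"expected 365 days for {year}, got {len(df)}")
    df["doy"] = np.arange(1, DAYS_PER_YEAR + 1)
    return df


def standardize_site(weather: pd.DataFrame) -> pd.DataFrame:
    """Standardize every site-year in a multi-year weather table."""
    parts = []
    for (_, _), grp in weather.groupby(
        [weather["site_id"], pd.to_datetime(weather["date"]).dt.year], sort=True
    ):
        parts.append(standardize_year(grp))
    return pd.concat(parts, ignore_index=True)


def _year_slice(weather: pd.DataFrame, site_id: str, year: int) -> pd.DataFrame:
    sel = weather[(weather["site_id"] == site_id)]
    sel = sel[pd.to_datetime(sel["date"]).dt.year == year]
    if sel.empty:
        raise ValueError(f"no weather for site {site_id!r} year {year}")
    if len(sel) != DAYS_PER_YEAR or "doy" not in sel.columns:
        sel = standardize_year(sel)
    return sel.sort_values("doy" if "doy" in sel.columns else "date")


def build_window(
    weather: pd.DataFrame,
    site: SiteMeta,
    focal_year: int,
    phenophase: str,
) -> DriverWindow:
    """Assemble the driver window for one site-year.

    Emergence: 1 Sep of ``focal_year - 1`` through 31 Aug of ``focal_year``;
    senescence: the focal calendar year.  Photoperiod is computed from the
    site latitude and the calendar day of each position.
    """
    if phenophase not in PHENOPHASES:
        raise ValueError(f"unknown phenophase {phenophase!r}")
    if phenophase == EMERGENCE:
        prev = _year_slice(weather, site.site_id, focal_year - 1)
        cur = _year_slice(weather, site.site_id, focal_year)
        tmean = np.concatenate(
            [
                prev["tmean"].to_numpy()[EMERGENCE_ANCHOR_DOY - 1 :],
                cur["tmean"].to_numpy()[: DAYS_PER_YEAR - EMERGENCE_TAIL_DAYS],
            ]
        )
        doy = np.concatenate(
            [
                np.arange(EMERGENCE_ANCHOR_DOY, DAYS_PER_YEAR + 1),
                np.arange(1, DAYS_PER_YEAR - EMERGENCE_TAIL_DAYS + 1),
            ]
        )
    else:
        cur = _year_slice(weather, site.site_id, focal_year)
        tmean = cur["tmean"].to_numpy().copy()
        doy = np.arange(1, DAYS_PER_YEAR + 1)
    return DriverWindow(
        site_id=site.site_id,
        focal_year=focal_year,
        phenophase=phenophase,
        day_axis=np.arange(1, DAYS_PER_YEAR + 1),
        tmean=tmean,
        daylength=compute_daylength(site.latitude, doy),
        doy=doy,
    )


def build_climatology(
    weather: pd.DataFrame,
    site_id: str,
    years: Optional[Iterable[int]] = None,
    max_years: int = 30,
) -> Climatology:
    """Day-wise mean temperature over the supplied years (default: all).

    When more than ``max_years`` years are available the most recent
    ``max_years`` are used, mirroring a 30-year climatological window.
    """
    sel = weather[weather["site_id"] == site_id].copy()
    sel["date"] = pd.to_datetime(sel["date"])
    sel["year"] = sel["date"].dt.year
    avail = sorted(sel["year"].unique())
    use = sorted(set(avail) & set(years)) if years is not None else avail
    if not use:
        raise ValueError(f"no complete years for site {site_id!r} in requested range")
    use = use[-max_years:]
    parts = [_year_slice(sel, site_id, y)["tmean"].to_numpy() for y in use]
    return Climatology(
        site_id=site_id,
        tmean_by_doy=np.mean(np.stack(parts), axis=0),
        n_years=len(use),
    )


def climatology_window(
    clim: Climatology, site: SiteMeta, focal_year: int, phenophase: str
) -> DriverWindow:
    """Tile a climatology into a driver window (the 30-year reference year)."""
    if phenophase == EMERGENCE:
        tmean = np.concatenate(
            [
                clim.tmean_by_doy[EMERGENCE_ANCHOR_DOY - 1 :],
                clim.tmean_by_doy[: DAYS_PER_YEAR - EMERGENCE_TAIL_DAYS],
            ]
        )
        doy = np.concatenate(
            [
                np.arange(EMERGENCE_ANCHOR_DOY, DAYS_PER_YEAR + 1),
                np.arange(1, DAYS_PER_YEAR - EMERGENCE_TAIL_DAYS + 1),
            ]
        )
    elif phenophase == SENESCENCE:
        tmean = clim.tmean_by_doy.copy()
        doy = np.arange(1, DAYS_PER_YEAR + 1)
    else:
        raise ValueError(f"unknown phenophase {phenophase!r}")
    return DriverWindow(
        site_id=site.site_id,
        focal_year=focal_year,
        phenophase=phenophase,
        day_axis=np.arange(1, DAYS_PER_YEAR + 1),
        tmean=tmean,
        daylength=compute_daylength(site.latitude, doy),
        doy=doy,
    )
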