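"""Green chromatic coordinate extraction and phenophase dating.

The canopy greenness fraction G_CC = G/(R+G+B) is computed per image ROI,
then filtered: a 3-day moving 50th-percentile filter removes single-day
spikes; a LOESS fit replaces asymmetric outliers (residuals beyond +4 sd or
below -2 sd, prioritizing removal of anomalous greenness drops); dormant
season values are replaced by the dormant-season mode (the lowest local
maximum of a kernel density over the year's values).  Leaf emergence (SOS)
and senescence (EOS) are dated at 50% of the seasonal amplitude of the
rising and falling curves, and site-level observations average at least
three individuals.

Series are pandas DataFrames with columns
``roi_id, site_id, date, doy, gcc, qa_flag``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.nonparametric.smoothers_lowess import lowess

#: dormant-season day-of-year ranges (inclusive) used for the mode fill
DEFAULT_DORMANT_WINDOWS = ((1, 75), (320, 365))

UPPER_RESIDUAL_SD = 4.0  # spikes above the fit must exceed +4 sd
LOWER_RESIDUAL_SD = 2.0  # drops below the fit are replaced beyond -2 sd


class InsufficientAmplitudeError(ValueError):
    """Seasonal amplitude below the configured floor (low-signal curve)."""


@dataclass(frozen=True)
class TransitionEstimate:
    """50%-amplitude transition dates for one ROI-year."""

    roi_id: str
    site_id: str
    year: int
    sos: int
    eos: int
    amplitude: float

    @property
    def season_length(self) -> int:
        return self.eos - self.sos


def compute_gcc(r, g, b):
    """Green chromatic coordinate g/(r+g+b); scale-invariant in brightness."""
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(r < 0) or np.any(g < 0) or np.any(b < 0):
        raise ValueError("channel intensities must be >= 0")
    total = r + g + b
    if np.any(total <= 0):
        raise ValueError("all-zero colour channels: G_CC undefined")
    out = g / total
    return float(out) if out.ndim == 0 else out


def gcc_from_channels(channels: pd.DataFrame) -> pd.DataFrame:
    """Build a greenness series from an ``r_mean,g_mean,b_mean`` table,
    excluding (and not silently zeroing) all-dark rows."""
    df = channels.copy()
    total = df[["r_mean", "g_mean", "b_mean"]].sum(axis=1)
    bad = total <= 0
    if bad.any():
        df = df.loc[~bad]
    df = df.assign(gcc=df["g_mean"] / (df["r_mean"] + df["g_mean"] + df["b_mean"]))
    df["qa_flag"] = "raw"
    keep = [c for c in ("roi_id", "site_id", "date", "doy", "gcc", "qa_flag") if c in df.columns]
    return df[keep].reset_index(drop=True)


def _day_numbers(series: pd.DataFrame) -> np.ndarray:
    if "doy" in series.columns:
        return series["doy"].to_numpy(dtype=float)
    dates = pd.to_datetime(series["date"])
    return (dates - dates.iloc[0]).dt.days.to_numpy(dtype=float) + 1.0


def moving_percentile_filter(
    series: pd.DataFrame, window_days: int = 3, pct: float = 50.0
) -> pd.DataFrame:
    """Replace each day by the ``pct`` percentile of values within its
    centred ``window_days`` window (by date, so gaps are respected)."""
    if len(series) < 3:
        raise ValueError("need at least 3 points")
    df = series.reset_index(drop=True).copy()
    t = _day_numbers(df)
    g = df["gcc"].to_numpy(dtype=float)
    half = (window_days - 1) / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    out = np.array([np.percentile(g[a:b], pct) for a, b in zip(lo, hi)])
    df["gcc"] = out
    df.loc[df["qa_flag"] == "raw", "qa_flag"] = "filtered"
    return df


def outlier_replace(
    series: pd.DataFrame, span_days: float = 15.0, n_pass: Optional[int] = None
) -> pd.DataFrame:
    """LOESS-based asymmetric outlier replacement.

    A local regression with a span covering about ``span_days`` of data is
    fitted; points with residuals above ``+4 sd`` or below ``-2 sd`` of the
    residual scale are replaced by the fitted value and flagged
    ``imputed``.  The residual scale is computed once per pass as a
    Gaussian-consistent MAD (1.4826 * median absolute deviation), so the
    very outliers being screened do not inflate their own threshold.

    By default passes repeat until the series stops changing (at most 20;
    typically 4-6), which makes the filter a projection: applying it to its
    own output is a no-op.  Set ``n_pass=1`` for a single pass.

    The default 15-day span is short enough that a locally linear fit
    tracks the spring/autumn shoulders of a seasonal greenness curve; a
    residual scale below 0.2% of the seasonal range is treated as pure
    lack-of-fit (nothing to clean) and the series is returned unchanged.
    """
    if len(series) < 10:
        raise ValueError("need at least 10 points")
    df = series.reset_index(drop=True).copy()
    max_pass = 20 if n_pass is None else max(1, n_pass)
    for _ in range(max_pass):
        t = _day_numbers(df)
        g = df["gcc"].to_numpy(dtype=float)
        frac = float(np.clip(span_days / (t[-1] - t[0] + 1.0), 0.05, 1.0))
        fitted = lowess(g, t, frac=frac, return_sorted=False)
        resid = g - fitted
        # scale from not-yet-imputed points only: replaced points sit on the
        # fit with zero residual and would otherwise shrink the threshold
        live = (df["qa_flag"] != "imputed").to_numpy()
        live_resid = resid[live] if live.any() else resid
        sd = 1.4826 * float(np.median(np.abs(live_resid - np.median(live_resid))))
        if sd <= max(1e-12, 2e-3 * float(np.ptp(g))):
            break
        mask = (resid > UPPER_RESIDUAL_SD * sd) | (resid < -LOWER_RESIDUAL_SD * sd)
        if not mask.any():
            break
        df.loc[mask, "gcc"] = fitted[mask]
        df.loc[mask, "qa_flag"] = "imputed"
    return df


def dormant_mode(values: Iterable[float], grid_size: int = 512) -> float:
    """Dormant-season greenness: the KDE local maximum at the lowest G_CC.

    Falls back to the median (with a warning) when the density has no local
    maximum or the values are (near-)constant.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if np.ptp(v) < 1e-12:
        return float(v[0])
    try:
        kde = gaussian_kde(v)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate spread
        return float(np.median(v))
    grid = np.linspace(v.min(), v.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    maxima = np.flatnonzero(interior) + 1
    if dens[0] > dens[1]:
        maxima = np.concatenate([[0], maxima])
    if dens[-1] > dens[-2]:
        maxima = np.concatenate([maxima, [grid_size - 1]])
    if maxima.size == 0:
        warnings.warn("greenness density has no local maximum; using median")
        return float(np.median(v))
    return float(grid[maxima[0]])


def dormant_mode_fill(
    series: pd.DataFrame,
    dormant_windows: Sequence[Tuple[int, int]] = DEFAULT_DORMANT_WINDOWS,
) -> pd.DataFrame:
    """Replace dormant-window points with the dormant-season mode."""
    df = series.reset_index(drop=True).copy()
    doy = _day_numbers(df)
    mode = dormant_mode(df["gcc"].to_numpy(dtype=float))
    in_dormant = np.zeros(len(df), dtype=bool)
    for lo, hi in dormant_windows:
        in_dormant |= (doy >= lo) & (doy <= hi)
    df.loc[in_dormant, "gcc"] = mode
    df.loc[in_dormant, "qa_flag"] = "imputed"
    return df


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def extract_transitions(
    series: pd.DataFrame,
    year: int,
    baseline: Optional[float] = None,
    amplitude_floor: float = 0.0,
) -> TransitionEstimate:
    """Date SOS and EOS at 50% of the seasonal amplitude.

    ``amplitude = max(gcc) - baseline`` with the baseline defaulting to the
    dormant-season mode; SOS is the first upward crossing of
    ``baseline + amplitude/2`` (linear interpolation, rounded to a whole
    day) and EOS the last day above that level.  Raises
    :class:`InsufficientAmplitudeError` below the amplitude floor.
    """
    df = series.reset_index(drop=True)
    t = _day_numbers(df)
    g = df["gcc"].to_numpy(dtype=float)
    if baseline is None:
        baseline = dormant_mode(g)
    amplitude = float(g.max() - baseline)
    if amplitude <= amplitude_floor or amplitude <= 0:
        raise InsufficientAmplitudeError(
            f"amplitude {amplitude:.4f} at or below floor {amplitude_floor:.4f}"
        )
    thr = baseline + 0.5 * amplitude

    above = g >= thr
    if not above.any():
        raise InsufficientAmplitudeError("curve never reaches the 50% level")
    first = int(np.argmax(above))
    if first == 0:
        sos_day = t[0]
    else:
        g0, g1 = g[first - 1], g[first]
        sos_day = t[first - 1] + (thr - g0) / (g1 - g0) * (t[first] - t[first - 1])
    last = len(g) - 1 - int(np.argmax(above[::-1]))
    if last == len(g) - 1:
        eos_day = t[-1]
    else:
        g0, g1 = g[last], g[last + 1]
        eos_day = t[last] + (g0 - thr) / (g0 - g1) * (t[last + 1] - t[last])

    sos, eos = _round_half_up(sos_day), _round_half_up(eos_day)
    if not sos < eos:
        raise InsufficientAmplitudeError("no rising-then-falling season found")
    return TransitionEstimate(
        roi_id=str(df["roi_id"].iloc[0]) if "roi_id" in df.columns else "",
        site_id=str(df["site_id"].iloc[0]) if "site_id" in df.columns else "",
        year=year,
        sos=sos,
        eos=eos,
        amplitude=amplitude,
    )


def extract_pipeline(
    series: pd.DataFrame,
    year: int,
    span_days: float = 15.0,
    dormant_windows: Sequence[Tuple[int, int]] = DEFAULT_DORMANT_WINDOWS,
    amplitude_floor: float = 0.0,
) -> TransitionEstimate:
    """Full extraction: percentile filter -> LOESS outlier replacement ->
    dormant mode fill -> 50%-amplitude transition dating."""
    filtered = moving_percentile_filter(series)
    cleaned = outlier_replace(filtered, span_days=span_days)
    filled = dormant_mode_fill(cleaned, dormant_windows=dormant_windows)
    return extract_transitions(filled, year, amplitude_floor=amplitude_floor)


def site_aggregate(
    estimates: Sequence[TransitionEstimate],
    species: str,
    min_individuals: int = 3,
) -> pd.DataFrame:
    """Average individual transition dates into site-level observations.

    Groups by (site, year); groups with at least ``min_individuals``
    individuals yield one emergence and one senescence observation (the
    arithmetic mean day, rounded); smaller groups yield nothing.
    """
    rows = []
    by_site_year: dict = {}
    for est in estimates:
        by_site_year.setdefault((est.site_id, est.year), []).append(est)
    for (site_id, year), group in sorted(by_site_year.items()):
        if len(group) < min_individuals:
            continue
        for phase, attr in (("emergence", "sos"), ("senescence", "eos")):
            mean_day = float(np.mean([getattr(e, attr) for e in group]))
            rows.append(
                {
                    "site_id": site_id,
                    "year": year,
                    "species": species,
                    "phenophase": phase,
                    "doy": _round_half_up(mean_day),
                    "n_individuals": len(group),
                }
            )
    return pd.DataFrame(rows, columns=["site_id", "year", "species", "phenophase", "doy", "n_individuals"])
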