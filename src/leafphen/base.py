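"""Shared machinery for the daily-accumulation phenology models.

Every model is a daily state machine over a 365-day driver window: a
nonnegative daily rate is accumulated from a starting day until a critical
threshold is reached, and the phenophase is dated to the first day the
cumulative sum meets the threshold (the starting day itself accumulates).
Models are evaluated in batch over a stack of windows so that calibration
objectives stay cheap; ``NOT_REACHED`` outcomes are encoded as NaN in batch
output and as a sentinel object in the single-window API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .drivers import DAYS_PER_YEAR, EMERGENCE, EMERGENCE_TAIL_DAYS, SENESCENCE, DriverWindow


class _NotReached:
    """Sentinel for accumulations that never attain their threshold."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_REACHED"

    def __bool__(self) -> bool:
        return False


NOT_REACHED = _NotReached()


@dataclass(frozen=True)
class PhenoPrediction:
    """A single model prediction: calendar day of year or NOT_REACHED."""

    site_id: str
    focal_year: int
    doy: object  # int or NOT_REACHED

    @property
    def reached(self) -> bool:
        return self.doy is not NOT_REACHED


@dataclass
class WindowBatch:
    """A stack of driver windows aligned with a set of observations.

    ``T`` and ``L`` are (n, 365) temperature and photoperiod matrices.  For
    senescence datasets the optional emergence-window and climatology-window
    stacks carry the drivers the preceding-spring-adjusted models need, and
    ``sos_params`` holds the fitted PTTs parameters used to estimate the
    current and reference leaf-emergence dates.
    """

    phenophase: str
    T: np.ndarray
    L: np.ndarray
    site_ids: Sequence[str] = ()
    years: Sequence[int] = ()
    T_em: Optional[np.ndarray] = None
    L_em: Optional[np.ndarray] = None
    T_clim: Optional[np.ndarray] = None
    L_clim: Optional[np.ndarray] = None
    sos_params: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        self.T = np.atleast_2d(np.asarray(self.T, dtype=float))
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if self.T.shape != self.L.shape or self.T.shape[1] != DAYS_PER_YEAR:
            raise ValueError("T and L must both be (n, 365)")

    @property
    def n(self) -> int:
        return self.T.shape[0]

    def subset(self, idx: np.ndarray) -> "WindowBatch":
        take = lambda a: None if a is None else a[idx]
        return WindowBatch(
            phenophase=self.phenophase,
            T=self.T[idx],
            L=self.L[idx],
            site_ids=[self.site_ids[i] for i in idx] if len(self.site_ids) else (),
            years=[self.years[i] for i in idx] if len(self.years) else (),
            T_em=take(self.T_em),
            L_em=take(self.L_em),
            T_clim=take(self.T_clim),
            L_clim=take(self.L_clim),
            sos_params=self.sos_params,
        )

    @classmethod
    def from_windows(cls, windows: Sequence[DriverWindow], **extras) -> "WindowBatch":
        if not windows:
            raise ValueError("empty window list")
        phase = windows[0].phenophase
        if any(w.phenophase != phase for w in windows):
            raise ValueError("mixed phenophases in one batch")
        return cls(
            phenophase=phase,
            T=np.stack([w.tmean for w in windows]),
            L=np.stack([w.daylength for w in windows]),
            site_ids=[w.site_id for w in windows],
            years=[w.focal_year for w in windows],
            **extras,
        )


def window_index_to_doy(phenophase: str, index) -> np.ndarray:
    """Convert 1-based window indices to calendar day of the focal year."""
    index = np.asarray(index, dtype=float)
    if phenophase == EMERGENCE:
        return index - EMERGENCE_TAIL_DAYS
    return index


def accumulate_until(rates, threshold: float, start: int):
    """First 1-based day index at which the running sum of ``rates`` from
    ``start`` (inclusive) reaches ``threshold``; NOT_REACHED if never."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rates = np.asarray(rates, dtype=float)
    start = int(start)
    if start < 1:
        start = 1
    total = 0.0
    if threshold == 0:
        return start if start <= len(rates) else NOT_REACHED
    for day in range(start, len(rates) + 1):
        total += rates[day - 1]
        if total >= threshold:
            return day
    return NOT_REACHED


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clip keeps exp well-behaved for extreme annealer probes
    return 1.0 / (1.0 + np.exp(np.clip(-x, -500.0, 500.0)))


def zero_before(rates: np.ndarray, start: int) -> np.ndarray:
    """Zero all columns before 1-based day ``start`` (start itself kept)."""
    start = int(round(start))
    if start > 1:
        rates = rates.copy()
        rates[..., : min(start, DAYS_PER_YEAR + 1) - 1] = 0.0
    return rates


def first_threshold_crossing(cum: np.ndarray, threshold) -> np.ndarray:
    """Per-row first 1-based index with cum >= threshold; NaN if never.

    ``threshold`` may be a scalar or an (n,) vector or an (n, 365) matrix
    (for chilling-dependent forcing requirements).
    """
    thr = np.asarray(threshold, dtype=float)
    if thr.ndim == 1:
        thr = thr[:, None]
    reached = cum >= thr
    idx = np.argmax(reached, axis=1).astype(float) + 1.0
    idx[~reached.any(axis=1)] = np.nan
    return idx


def cumsum_from(rates: np.ndarray, start_idx: np.ndarray) -> np.ndarray:
    """Row-wise cumulative sum starting at per-row 1-based day ``start_idx``.

    Columns before the start day are set to 0; rows with NaN start are all 0.
    """
    n, m = rates.shape
    start = np.where(np.isnan(start_idx), m + 1, start_idx).astype(int)
    cols = np.arange(1, m + 1)
    masked = np.where(cols[None, :] >= start[:, None], rates, 0.0)
    return np.cumsum(masked, axis=1)
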