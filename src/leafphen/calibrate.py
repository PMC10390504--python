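"""Model calibration by generalized simulated annealing.

Parameters are fit by minimizing the root mean squared error between
predicted and observed phenophase days over a bounded parameter box, using
generalized (Tsallis-style) simulated annealing
(:func:`scipy.optimize.dual_annealing` with local search disabled), capped
at a maximum number of objective evaluations and a starting temperature of
10,000.  Integer-valued parameters (start days, exponent weights) are
searched continuously and rounded inside the objective.

NOT_REACHED predictions are mapped to a fixed far sentinel (the window's
last reportable day plus 100) so the objective stays finite and the search
is steered away from degenerate parameter regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import dual_annealing

from .dataset import Dataset
from .drivers import DAYS_PER_YEAR, EMERGENCE, EMERGENCE_TAIL_DAYS
from .registry import default_bounds, get_model

DEFAULT_MAX_ITER = 50_000
DEFAULT_INIT_TEMP = 10_000.0


def penalty_doy(phenophase: str) -> float:
    """Sentinel calendar day substituted for NOT_REACHED predictions."""
    if phenophase == EMERGENCE:
        return float(DAYS_PER_YEAR - EMERGENCE_TAIL_DAYS + 100)  # 343
    return float(DAYS_PER_YEAR + 100)  # 465


def rmse(pred, obs) -> float:
    """Root mean squared error in days."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("rmse needs equal-length, non-empty inputs")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def bias(pred, obs) -> float:
    """Mean signed error (predicted - observed) in days; negative = early."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("bias needs equal-length, non-empty inputs")
    return float(np.mean(pred - obs))


def null_model(train: Dataset, validate: Dataset) -> Tuple[float, float]:
    """Constant predictor at the training-set mean day; (rmse, bias)."""
    if train.n == 0:
        raise ValueError("empty training set")
    const = float(np.mean(train.obs_doy))
    pred = np.full(validate.n, const)
    return rmse(pred, validate.obs_doy), bias(pred, validate.obs_doy)


@dataclass
class ModelFit:
    """Result of one annealing run."""

    model_name: str
    params: dict
    bounds: dict
    train_rmse: float
    n_train: int
    n_evaluations: int
    seed: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            v = self.params[name]
            if not lo - 1e-9 <= v <= hi + 1e-9:
                raise ValueError(f"{self.model_name}.{name}={v} outside [{lo}, {hi}]")


def predict_dataset(model_name: str, params: Mapping[str, float], dataset: Dataset,
                    penalize: bool = False) -> np.ndarray:
    """Predictions (calendar DOY) for every observation; NaN = NOT_REACHED
    unless ``penalize``, in which case the far-sentinel day is substituted."""
    model = get_model(model_name)
    pred = model.predict_batch(params, dataset.batch)
    if penalize:
        pred = np.where(np.isnan(pred), penalty_doy(dataset.phenophase), pred)
    return pred


def _round_integer_params(params: dict, integer_names: Sequence[str]) -> dict:
    out = dict(params)
    for name in integer_names:
        if name in out:
            out[name] = float(round(out[name]))
    return out


def fit(
    model_name: str,
    dataset: Dataset,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    max_iter: int = DEFAULT_MAX_ITER,
    init_temp: float = DEFAULT_INIT_TEMP,
    seed: int = 0,
    x0: Optional[Mapping[str, float]] = None,
) -> ModelFit:
    """Fit one model to a dataset by bounded annealing of the RMSE.

    ``max_iter`` caps objective evaluations; ``x0`` (e.g. a previous global
    fit) seeds the search.  Deterministic under a fixed ``seed``.
    """
    if dataset.n < 2:
        raise ValueError("need at least 2 observations to calibrate")
    model = get_model(model_name)
    if bounds is None:
        bounds = default_bounds(model_name)
    names = list(model.param_names)
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)
    obs = dataset.obs_doy
    pen = penalty_doy(dataset.phenophase)
    batch = dataset.batch
    integer_names = model.integer_params
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        params = _round_integer_params(dict(zip(names, x)), integer_names)
        pred = model.predict_batch(params, batch)
        pred = np.where(np.isnan(pred), pen, pred)
        return float(np.sqrt(np.mean((pred - obs) ** 2)))

    degenerate = hi <= lo + 1e-12
    if degenerate.all():
        x_best = lo.copy()
        best_obj = objective(x_best)
    else:
        # dual_annealing rejects zero-width dimensions; pin them manually
        free = ~degenerate
        pinned = lo[degenerate]

        def obj_free(xf: np.ndarray) -> float:
            x = np.empty(len(names))
            x[free] = xf
            x[degenerate] = pinned
            return objective(x)

        x0_free = None
        if x0 is not None:
            x0_free = np.clip(
                np.array([x0[n] for n in names], dtype=float)[free],
                lo[free], hi[free],
            )
        result = dual_annealing(
            obj_free,
            bounds=list(zip(lo[free], hi[free])),
            maxiter=max(2, max_iter),
            maxfun=max_iter,
            initial_temp=init_temp,
            no_local_search=True,
            seed=seed,
            x0=x0_free,
        )
        x_best = np.empty(len(names))
        x_best[free] = result.x
        x_best[degenerate] = pinned
        best_obj = float(result.fun)

    params = _round_integer_params(dict(zip(names, x_best)), integer_names)
    params = {n: float(np.clip(params[n], bounds[n][0], bounds[n][1])) for n in names}
    final_pred = model.predict_batch(params, batch)
    if np.isnan(final_pred).all():
        raise RuntimeError(
            f"{model_name}: threshold never reached for any observation at the "
            "best parameters; revise the bounds or the driver data"
        )
    return ModelFit(
        model_name=model_name,
        params=params,
        bounds=dict(bounds),
        train_rmse=best_obj,
        n_train=dataset.n,
        n_evaluations=n_eval,
        seed=seed,
    )
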