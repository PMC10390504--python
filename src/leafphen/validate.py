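"""The seven validation exercises.

Each exercise scores a model with RMSE and mean bias against a Null model
(constant predictor at the training mean): pooled/global validation,
regional-only calibration, global-to-regional transfer, warm and cold
site-year quartiles, k-fold cross-validation (fold sizes of at least five)
and leave-one-out cross-validation.  Cross-validation refits use a reduced
evaluation cap and start from the supplied global fit's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .calibrate import ModelFit, bias, fit, null_model, predict_dataset, rmse
from .dataset import Dataset

EXERCISES = (
    "global",
    "acadian_only",
    "transfer_to_acadian",
    "warm_quartile",
    "cold_quartile",
    "kfold",
    "loocv",
)

CV_MAX_ITER = 4_000


@dataclass
class ValidationReport:
    model_name: str
    exercise: str
    rmse: float
    bias: float
    n_validate: int
    null_rmse: float

    @property
    def beats_null(self) -> bool:
        return self.rmse < self.null_rmse


def _report(model_name, exercise, pred, val: Dataset, train: Dataset) -> ValidationReport:
    null_rmse, _ = null_model(train, val)
    return ValidationReport(
        model_name=model_name,
        exercise=exercise,
        rmse=rmse(pred, val.obs_doy),
        bias=bias(pred, val.obs_doy),
        n_validate=val.n,
        null_rmse=null_rmse,
    )


def validate_pooled(
    fit_result: ModelFit,
    dataset: Dataset,
    train: Optional[Dataset] = None,
    exercise: str = "global",
) -> ValidationReport:
    """Score a fitted model on every observation of ``dataset``; the Null
    model is trained on ``train`` (default: the same dataset)."""
    pred = predict_dataset(fit_result.model_name, fit_result.params, dataset, penalize=True)
    return _report(fit_result.model_name, exercise, pred, dataset, train or dataset)


def subset_regional(dataset: Dataset, tag: str) -> Dataset:
    """Observations whose network tag matches (e.g. the regional network)."""
    mask = dataset.observations["network_tag"].to_numpy() == tag
    if not mask.any():
        raise ValueError(f"no observations tagged {tag!r}")
    return dataset.subset(mask)


def extreme_siteyears(dataset: Dataset, side: str) -> Dataset:
    """Warm (>= 75th percentile annual mean temperature) or cold (<= 25th)
    site-years, with linear-interpolation percentiles."""
    temps = dataset.observations["annual_mean_temp"].to_numpy(dtype=float)
    if side == "warm":
        cut = np.percentile(temps, 75.0)
        mask = temps >= cut
    elif side == "cold":
        cut = np.percentile(temps, 25.0)
        mask = temps <= cut
    else:
        raise ValueError("side must be 'warm' or 'cold'")
    return dataset.subset(mask)


def kfold_splits(n: int, seed: int) -> List[np.ndarray]:
    """Seeded balanced folds with k = max(2, min(10, n // 5))."""
    if n < 10:
        raise ValueError("need n >= 10 to form two folds of at least five")
    k = max(2, min(10, n // 5))
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def kfold_cv(
    model_name: str,
    dataset: Dataset,
    seed: int = 0,
    max_iter: int = CV_MAX_ITER,
    bounds=None,
    x0: Optional[dict] = None,
) -> ValidationReport:
    """Pooled out-of-fold RMSE/bias; each fold predicted by a model fitted
    on its complement.  The Null model is likewise trained per complement."""
    folds = kfold_splits(dataset.n, seed)
    pred = np.empty(dataset.n)
    null_pred = np.empty(dataset.n)
    for i, fold in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(dataset.n), fold)
        train = dataset.subset(train_idx)
        held = dataset.subset(fold)
        fold_fit = fit(
            model_name, train, bounds=bounds, max_iter=max_iter,
            seed=seed + i, x0=x0,
        )
        pred[fold] = predict_dataset(model_name, fold_fit.params, held, penalize=True)
        null_pred[fold] = float(np.mean(train.obs_doy))
    return ValidationReport(
        model_name=model_name,
        exercise="kfold",
        rmse=rmse(pred, dataset.obs_doy),
        bias=bias(pred, dataset.obs_doy),
        n_validate=dataset.n,
        null_rmse=rmse(null_pred, dataset.obs_doy),
    )


def loocv(
    model_name: str,
    dataset: Dataset,
    seed: int = 0,
    max_iter: int = CV_MAX_ITER,
    bounds=None,
    x0: Optional[dict] = None,
    return_predictions: bool = False,
):
    """Leave-one-out cross-validation: n fits, each excluding one record."""
    if dataset.n < 3:
        raise ValueError("need n >= 3 for leave-one-out")
    pred = np.empty(dataset.n)
    null_pred = np.empty(dataset.n)
    for i in range(dataset.n):
        train_idx = np.setdiff1d(np.arange(dataset.n), [i])
        train = dataset.subset(train_idx)
        held = dataset.subset(np.array([i]))
        one_fit = fit(
            model_name, train, bounds=bounds, max_iter=max_iter,
            seed=seed + i, x0=x0,
        )
        pred[i] = predict_dataset(model_name, one_fit.params, held, penalize=True)[0]
        null_pred[i] = float(np.mean(train.obs_doy))
    report = ValidationReport(
        model_name=model_name,
        exercise="loocv",
        rmse=rmse(pred, dataset.obs_doy),
        bias=bias(pred, dataset.obs_doy),
        n_validate=dataset.n,
        null_rmse=rmse(null_pred, dataset.obs_doy),
    )
    return (report, pred) if return_predictions else report


def model_ranking(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    """Ascending-RMSE table (ties broken alphabetically by model name),
    flagging models that fail to beat the Null model."""
    if not reports:
        raise ValueError("no reports to rank")
    exercises = {r.exercise for r in reports}
    if len(exercises) > 1:
        raise ValueError(f"reports mix exercises: {sorted(exercises)}")
    df = pd.DataFrame(
        {
            "model": [r.model_name for r in reports],
            "exercise": [r.exercise for r in reports],
            "rmse": [r.rmse for r in reports],
            "bias": [r.bias for r in reports],
            "n": [r.n_validate for r in reports],
            "null_rmse": [r.null_rmse for r in reports],
            "beats_null": [r.beats_null for r in reports],
        }
    )
    return df.sort_values(["rmse", "model"], kind="mergesort").reset_index(drop=True)


def run_all_exercises(
    model_name: str,
    dataset: Dataset,
    seed: int = 0,
    max_iter: int = 50_000,
    cv_max_iter: int = CV_MAX_ITER,
    bounds=None,
    regional_tag: str = "acadian",
) -> List[ValidationReport]:
    """Run the full validation suite for one model on one dataset."""
    global_fit = fit(model_name, dataset, bounds=bounds, max_iter=max_iter, seed=seed)
    reports = [validate_pooled(global_fit, dataset, exercise="global")]

    regional = subset_regional(dataset, regional_tag)
    regional_fit = fit(model_name, regional, bounds=bounds, max_iter=cv_max_iter,
                       seed=seed, x0=global_fit.params)
    reports.append(
        validate_pooled(regional_fit, regional, exercise="acadian_only")
    )
    reports.append(
        validate_pooled(global_fit, regional, train=dataset, exercise="transfer_to_acadian")
    )
    for side, name in (("warm", "warm_quartile"), ("cold", "cold_quartile")):
        sub = extreme_siteyears(dataset, side)
        reports.append(validate_pooled(global_fit, sub, train=dataset, exercise=name))
    reports.append(
        kfold_cv(model_name, dataset, seed=seed, max_iter=cv_max_iter,
                 bounds=bounds, x0=global_fit.params)
    )
    reports.append(
        loocv(model_name, dataset, seed=seed, max_iter=cv_max_iter,
              bounds=bounds, x0=global_fit.params)
    )
    return reports
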