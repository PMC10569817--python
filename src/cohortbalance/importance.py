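"""Partial-dependence curves and PDP-flatness variable importance.

The partial dependence of a fitted logistic model on a predictor is the
average fitted event probability as the predictor is swept over a grid
while every other column keeps its observed values.  A flat curve means the
predictor barely moves the model's output; the model-based importance score
is therefore a flatness measure of the curve on the probability scale:
the sample standard deviation over the grid for continuous predictors, and
range/4 over the levels for categorical ones (the usual scale-matching
convention for non-numeric predictors).  Predictors are ranked by
descending score, ties broken alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .classify import LogisticFit, predict_proba

__all__ = ["PDPCurve", "ImportanceRanking", "partial_dependence", "pdp_importance"]

DEFAULT_GRID_SIZE = 20


@dataclass
class PDPCurve:
    variable: str
    grid: list  # level labels or numeric grid points
    avg_prediction: np.ndarray  # event probability per grid point


@dataclass
class ImportanceRanking:
    scores: dict[str, float]
    order: list[str]  # descending score; alphabetical within ties


def partial_dependence(
    fit: LogisticFit,
    cohort: Cohort,
    variable: str,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> PDPCurve:
    """Average fitted probability as ``variable`` sweeps a grid.

    Categorical grids enumerate the levels the fit observed; continuous
    grids use ``grid_size`` equally spaced quantiles of the observed
    values (so the sweep stays inside the data's support).
    """
    if variable not in fit.predictors:
        raise ValueError(f"{variable!r} is not a predictor of this fit")
    var = cohort.variable(variable)
    if var.kind == "categorical":
        grid = list(fit.factor_levels[variable])
    else:
        if grid_size < 2:
            raise ValueError("grid_size must be >= 2 for continuous variables")
        x = cohort.records[variable].to_numpy(float)
        grid = list(np.quantile(x, np.linspace(0.0, 1.0, grid_size)))

    avg = np.empty(len(grid))
    work = cohort.records.copy()
    for i, g in enumerate(grid):
        work[variable] = g
        avg[i] = predict_proba(fit, work, cohort).mean()
    return PDPCurve(variable, grid, avg)


def pdp_importance(
    fit: LogisticFit,
    cohort: Cohort,
    variables: list[str],
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ImportanceRanking:
    """PDP-flatness importance scores and their descending ranking.

    Continuous: sample SD of the curve over the grid.  Categorical:
    (max − min)/4 over the levels.  A variable absent from the model has
    importance exactly 0.
    """
    scores: dict[str, float] = {}
    for name in variables:
        if name not in fit.predictors:
            scores[name] = 0.0
            continue
        curve = partial_dependence(fit, cohort, name, grid_size)
        if cohort.variable(name).kind == "categorical":
            scores[name] = float(
                (curve.avg_prediction.max() - curve.avg_prediction.min()) / 4.0
            )
        else:
            scores[name] = float(np.std(curve.avg_prediction, ddof=1))
    order = sorted(scores, key=lambda v: (-scores[v], v))
    return ImportanceRanking(scores, order)
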