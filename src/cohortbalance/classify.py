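"""Binary logistic regression and clinical evaluation metrics.

Fits maximum-likelihood logistic models (via statsmodels) with R-style
treatment coding of categorical predictors, computes confusion-table
metrics (sensitivity, specificity, precision, NPV, accuracy) with explicit
handling of undefined ratios, and provides the two inference helpers the
per-group analyses need: a pooled two-proportion chi-squared test with a
Wald confidence interval, and a joint Wald chi-squared test on all
coefficients of a multi-level factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
from sklearn.model_selection import train_test_split

from .cohort import Cohort, CohortError

__all__ = [
    "FitError",
    "SeparationError",
    "LogisticFit",
    "ConfusionMetrics",
    "fit_logistic",
    "predict_proba",
    "predict_classes",
    "confusion_metrics",
    "two_proportion_test",
    "wald_factor_test",
    "stratified_holdout",
]

SEPARATION_SE_THRESHOLD = 100.0  # log-odds scale; SEs this large flag separation


class FitError(RuntimeError):
    """Model could not be fitted."""


class SeparationError(FitError):
    """(Quasi-)perfect separation detected; the named term is degenerate."""


@dataclass
class LogisticFit:
    """A fitted binary logistic model with everything needed to predict.

    ``coefficients`` are on the log-odds scale.  Categorical predictors use
    treatment (reference-level) coding: a factor observed at L levels
    contributes L−1 terms named ``<factor><level>``; the reference level
    defaults to the most frequent one in the fitted data.
    """

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    aic: float
    bic: float
    deviance: float
    n_obs: int
    reference_levels: dict[str, str]
    predictors: list[str]
    factor_terms: dict[str, list[str]]  # factor -> its non-reference term names
    factor_levels: dict[str, dict[str, str]]  # factor -> level -> term name
    event_level: str
    cov_params: pd.DataFrame
    converged: bool = True

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)


def _design_matrix(
    records: pd.DataFrame,
    cohort: Cohort,
    predictors: list[str],
    reference_levels: dict[str, str],
    factor_levels: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Treatment-coded design matrix with a leading constant.

    At fit time (``factor_levels is None``) the levels observed in
    ``records`` define the coding; at predict time the stored coding is
    reused and an unseen level raises.
    """
    X = pd.DataFrame(index=records.index)
    X["(Intercept)"] = 1.0
    for name in predictors:
        var = cohort.variable(name)
        if var.kind == "continuous":
            X[name] = records[name].to_numpy(float)
            continue
        col = records[name]
        if factor_levels is None:
            observed = [l for l in var.levels if (col == l).any()]
            ref = reference_levels[name]
            coded = [l for l in observed if l != ref]
            terms = {l: f"{name}{l}" for l in coded}
        else:
            terms = {
                l: t for l, t in factor_levels[name].items() if l != reference_levels[name]
            }
            known = set(factor_levels[name])
            unseen = set(col.unique()) - known
            if unseen:
                raise FitError(
                    f"unseen level(s) {sorted(unseen)} of {name!r} at prediction time"
                )
        for level, term in terms.items():
            X[term] = (col == level).astype(float)
    return X


def fit_logistic(
    cohort: Cohort,
    predictors: list[str],
    reference_levels: dict[str, str] | None = None,
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression.

    The outcome's second declared level is the modeled event.  Reference
    levels default to each factor's most frequent level.  Raises
    :class:`SeparationError` when a term's standard error exceeds
    ``SEPARATION_SE_THRESHOLD`` (the signature of quasi-perfect
    separation) and :class:`FitError` on non-convergence.
    """
    reference_levels = dict(reference_levels or {})
    records = cohort.records
    for name in predictors:
        var = cohort.variable(name)
        if var.role == "outcome":
            raise FitError("outcome cannot be a predictor")
        if records[name].nunique() < 2:
            raise FitError(f"predictor {name!r} is constant")
        if var.kind == "categorical" and name not in reference_levels:
            reference_levels[name] = records[name].value_counts().idxmax()

    event_level = cohort.outcome.levels[1]
    y = (records[cohort.outcome.name] == event_level).astype(float).to_numpy()
    X = _design_matrix(records, cohort, predictors, reference_levels)

    with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=100)
        except Exception as exc:  # includes statsmodels' PerfectSeparation errors
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    separated = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    if separated:
        worst = X.columns[int(np.argmax(np.abs(res.params.to_numpy())))]
        raise SeparationError(
            f"perfect separation or prediction detected; largest-magnitude term "
            f"{worst!r} (coef {res.params[worst]:.2f})"
        )
    if not res.mle_retvals.get("converged", False):
        raise FitError(
            f"logistic fit did not converge in {res.mle_retvals.get('iterations')} iterations"
        )

    se = res.bse
    degenerate = [t for t in X.columns if se[t] > SEPARATION_SE_THRESHOLD]
    if degenerate:
        raise SeparationError(
            f"quasi-perfect separation: term(s) {degenerate} have SE > "
            f"{SEPARATION_SE_THRESHOLD:g} (coef {[round(res.params[t], 2) for t in degenerate]})"
        )

    k = len(res.params)
    ll = float(res.llf)
    factor_terms: dict[str, list[str]] = {}
    factor_levels: dict[str, dict[str, str]] = {}
    for name in predictors:
        var = cohort.variable(name)
        if var.kind != "categorical":
            continue
        observed = [l for l in var.levels if (records[name] == l).any()]
        factor_levels[name] = {
            l: (f"{name}{l}" if l != reference_levels[name] else "(reference)")
            for l in observed
        }
        factor_terms[name] = [f"{name}{l}" for l in observed if l != reference_levels[name]]

    return LogisticFit(
        coefficients={t: float(res.params[t]) for t in X.columns},
        std_errors={t: float(se[t]) for t in X.columns},
        loglik=ll,
        aic=-2 * ll + 2 * k,
        bic=-2 * ll + math.log(len(y)) * k,
        deviance=-2 * ll,
        n_obs=len(y),
        reference_levels={k_: v for k_, v in reference_levels.items() if k_ in predictors},
        predictors=list(predictors),
        factor_terms=factor_terms,
        factor_levels=factor_levels,
        event_level=event_level,
        cov_params=res.cov_params(),
    )


def predict_proba(fit: LogisticFit, records: pd.DataFrame, cohort: Cohort) -> np.ndarray:
    """Fitted event probabilities for new records."""
    X = _design_matrix(
        records, cohort, fit.predictors, fit.reference_levels, fit.factor_levels
    )
    beta = np.array([fit.coefficients[t] for t in X.columns])
    eta = X.to_numpy(float) @ beta
    return 1.0 / (1.0 + np.exp(-eta))


def predict_classes(
    fit: LogisticFit, cohort: Cohort, threshold: float = 0.5
) -> np.ndarray:
    """Predicted outcome labels: event iff fitted probability ≥ threshold."""
    p = predict_proba(fit, cohort.records, cohort)
    lev0, lev1 = cohort.outcome.levels
    non_event = lev0 if fit.event_level == lev1 else lev1
    return np.where(p >= threshold, fit.event_level, non_event)


@dataclass(frozen=True)
class ConfusionMetrics:
    """2×2 confusion-table metrics; undefined ratios are ``None``, never 0."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(actual, predicted, event_level: str) -> ConfusionMetrics:
    """Sensitivity/specificity/precision/NPV/accuracy from label vectors.

    ``precision`` is ``None`` exactly when no positive predictions exist
    (tp + fp = 0), as for the degenerate all-negative classifier an
    imbalanced fit tends to produce; likewise ``npv`` when tn + fn = 0.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if len(actual) == 0:
        raise ValueError("empty label vectors")
    if len(actual) != len(predicted):
        raise ValueError("label vectors must have equal length")
    a = actual == event_level
    p = predicted == event_level
    tp = int(np.sum(a & p))
    fp = int(np.sum(~a & p))
    tn = int(np.sum(~a & ~p))
    fn = int(np.sum(a & ~p))
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=(tp + tn) / (tp + fp + tn + fn),
    )


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, conf: float = 0.95
) -> tuple[float, tuple[float, float], float, float]:
    """Two-sample proportion comparison.

    Returns ``(diff, (lo, hi), chi2, p)`` where diff = x1/n1 − x2/n2, the
    CI is Wald-type (unpooled SE, no continuity correction) at level
    ``conf``, and chi2 is the pooled one-degree-of-freedom chi-squared
    statistic without continuity correction.  A degenerate pooled
    proportion of 0 or 1 yields chi2 = 0, p = 1.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2 and n1 >= 1 and n2 >= 1):
        raise ValueError("require 0 <= x <= n and n >= 1 for both samples")
    p1, p2 = x1 / n1, x2 / n2
    diff = p1 - p2
    z = stats.norm.ppf(0.5 + conf / 2)
    half = z * math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        chi2, p = 0.0, 1.0
    else:
        chi2 = diff**2 / (pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        p = float(stats.chi2.sf(chi2, df=1))
    return diff, (diff - half, diff + half), chi2, p


def wald_factor_test(fit: LogisticFit, factor: str) -> tuple[float, int, float]:
    """Joint Wald chi-squared test on all L−1 coefficients of a factor.

    Returns ``(chi2, df, p)`` with df = L−1 (e.g. df = 2 for a three-level
    race factor) using the fitted covariance.
    """
    if factor not in fit.factor_terms:
        raise FitError(f"{factor!r} is not a categorical predictor of this fit")
    terms = fit.factor_terms[factor]
    b = np.array([fit.coefficients[t] for t in terms])
    V = fit.cov_params.loc[terms, terms].to_numpy()
    if np.linalg.cond(V) > 1e12:
        raise FitError(f"singular covariance block for factor {factor!r}")
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(terms)
    return chi2, df, float(stats.chi2.sf(chi2, df=df))


def stratified_holdout(
    cohort: Cohort, test_fraction: float = 0.3, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Outcome-stratified train/test split (optional out-of-sample metrics)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    train_idx, test_idx = train_test_split(
        np.arange(cohort.n),
        test_size=test_fraction,
        random_state=seed,
        stratify=cohort.records[cohort.outcome.name],
    )
    df = cohort.records
    mk = lambda idx, tag: Cohort(
        df.iloc[np.sort(idx)].reset_index(drop=True),
        list(cohort.schema),
        provenance=f"{cohort.provenance} [{tag}]",
    )
    return mk(train_idx, "train"), mk(test_idx, "test")
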