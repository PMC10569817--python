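"""Class-imbalance correction: best-of-M distribution-matched undersampling
(plain and age/sex-stratified) and a SMOTE oversampler for comparison.

The undersampler draws M independent simple random samples of size
n_minority without replacement from the majority (non-event) class, scores
each candidate against the full majority population — a chi-squared
goodness-of-fit p-value per categorical variable and a two-sample
Kolmogorov-Smirnov p-value per continuous variable — and keeps the
candidate with the highest *summed* p-values, i.e. the subsample most
consistent with the majority class's own distribution.  The balanced output
is that subsample joined with every minority row, so undersampling never
synthesizes data.

The stratified variant fixes per-stratum quotas so the joint distribution
of the stratifying variables (typically the age>65 indicator and sex) among
sampled majority rows exactly matches the minority class's, and applies the
same best-of-M p-value criterion to the remaining variables.

SMOTE instead balances by synthesizing minority rows as uniform convex
combinations of a random minority point and one of its k nearest minority
neighbours (Euclidean distance on standardized one-hot-encoded features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .cohort import Cohort, CohortError, class_counts

__all__ = [
    "BalanceError",
    "CandidateSample",
    "BalanceResult",
    "score_candidate",
    "select_balanced_undersample",
    "stratified_undersample",
    "smote_oversample",
]

DEFAULT_M = 1000  # candidate samples per selection


class BalanceError(ValueError):
    """Invalid balancing request (sizes, strata, neighbours)."""


@dataclass
class CandidateSample:
    """One scored undersample of the majority class."""

    row_indices: np.ndarray  # positional ids into the majority population
    pvalues: dict[str, float]
    score: float

    def __post_init__(self) -> None:
        self.row_indices = np.asarray(self.row_indices)
        if len(np.unique(self.row_indices)) != len(self.row_indices):
            raise BalanceError("candidate rows must be distinct (sampling w/o replacement)")
        assert abs(self.score - sum(self.pvalues.values())) < 1e-12


@dataclass
class BalanceResult:
    """A balanced cohort plus provenance of how it was produced."""

    balanced: Cohort
    selected: CandidateSample | None
    n_candidates: int
    method: str  # {plain, stratified, smote}
    seed: int
    candidate_scores: list[float] = field(default_factory=list)
    # SMOTE only: per-synthetic-row (seed_row, neighbour_row, lambda) in the
    # minority table, plus the un-rounded synthetic points in encoded space.
    synthetic_parents: np.ndarray | None = None
    synthetic_encoded: np.ndarray | None = None
    encoded_minority: np.ndarray | None = None


# ----------------------------------------------------------------------
# Candidate scoring
# ----------------------------------------------------------------------

def score_candidate(
    candidate: pd.DataFrame,
    majority_population: pd.DataFrame,
    cohort: Cohort,
    variables: list[str],
    row_indices=None,
) -> CandidateSample:
    """Goodness-of-fit of a candidate subsample against the majority class.

    Categorical variables: chi-squared GOF of candidate level counts
    against expected counts from the population level proportions.
    Continuous variables: asymptotic two-sample KS of candidate values vs
    the population.  The score is the unweighted sum of p-values.

    A categorical level with zero expected count (absent from the
    population) causes the variable to be dropped from scoring with a
    warning.
    """
    if len(candidate) == 0:
        raise BalanceError("empty candidate")
    pvalues: dict[str, float] = {}
    for name in variables:
        var = cohort.variable(name)
        if var.kind == "categorical":
            pop_counts = majority_population[name].value_counts()
            levels = [l for l in var.levels if pop_counts.get(l, 0) > 0]
            dropped = [l for l in var.levels if pop_counts.get(l, 0) == 0]
            if dropped and (candidate[name].isin(dropped)).any():
                # cannot happen for candidate ⊆ population; defensive
                raise BalanceError(f"candidate has levels absent from population: {dropped}")
            if len(levels) < 2:
                warnings.warn(
                    f"variable {name!r} has <2 populated levels; dropped from scoring",
                    stacklevel=2,
                )
                continue
            obs = np.array([np.sum(candidate[name].to_numpy() == l) for l in levels], float)
            pop = np.array([pop_counts[l] for l in levels], float)
            expected = pop / pop.sum() * obs.sum()
            _, p = stats.chisquare(obs, expected)
        else:
            _, p = stats.ks_2samp(
                candidate[name].to_numpy(float),
                majority_population[name].to_numpy(float),
                method="asymp",
            )
        pvalues[name] = float(p)
    idx = row_indices if row_indices is not None else np.arange(len(candidate))
    return CandidateSample(idx, pvalues, float(sum(pvalues.values())))


# ----------------------------------------------------------------------
# Best-of-M undersampling
# ----------------------------------------------------------------------

def _split_classes(cohort: Cohort):
    # the event (second declared outcome level) is the minority by role
    out = cohort.outcome.name
    non_event, event = cohort.outcome.levels
    is_min = cohort.records[out] == event
    minority = cohort.records[is_min]
    majority = cohort.records[~is_min]
    if len(minority) > len(majority):
        raise BalanceError(
            f"event class {event!r} ({len(minority)}) outnumbers non-event class "
            f"({len(majority)}): not an imbalance problem"
        )
    return majority, minority, len(majority), len(minority), event


def _candidate_rngs(seed: int, m: int):
    """One child stream per candidate: results are independent of the
    order in which candidates are scored."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(m)]


def _assemble(cohort, majority, minority, sample_positions, selected, m, method, seed, scores):
    balanced_df = pd.concat(
        [majority.iloc[sample_positions], minority], axis=0
    ).reset_index(drop=True)
    balanced = Cohort(balanced_df, list(cohort.schema), provenance=f"{method} seed={seed}")
    return BalanceResult(balanced, selected, m, method, seed, candidate_scores=scores)


def select_balanced_undersample(
    cohort: Cohort,
    m: int = DEFAULT_M,
    variables: list[str] | None = None,
    seed: int = 0,
) -> BalanceResult:
    """Best-of-M distribution-matched undersample of the majority class.

    Draws ``m`` simple random samples of size n_minority without
    replacement from the majority class, scores each with
    :func:`score_candidate` over ``variables`` (default: every predictor),
    and returns the maximizer joined with all minority rows.  Ties are
    broken by the lowest candidate index.  Deterministic given ``seed``.
    """
    if m < 1:
        raise BalanceError("m must be >= 1")
    majority, minority, n_maj, n_min, _ = _split_classes(cohort)
    if variables is None:
        variables = [v.name for v in cohort.schema if v.role != "outcome"]

    best: CandidateSample | None = None
    scores: list[float] = []
    for rng in _candidate_rngs(seed, m):
        pos = rng.choice(n_maj, size=n_min, replace=False)
        cand = score_candidate(majority.iloc[pos], majority, cohort, variables, row_indices=pos)
        scores.append(cand.score)
        if best is None or cand.score > best.score:
            best = cand
    return _assemble(cohort, majority, minority, best.row_indices, best, m, "plain", seed, scores)


def stratified_undersample(
    cohort: Cohort,
    strata_vars: list[str],
    m: int = DEFAULT_M,
    variables: list[str] | None = None,
    seed: int = 0,
) -> BalanceResult:
    """Best-of-M undersample with per-stratum quotas fixed to the minority's.

    Within each cell of the cross of ``strata_vars`` (categorical, e.g. the
    age>65 indicator and sex) the sampled majority count equals the
    minority count, so the joint strata distribution of the sampled rows
    matches the minority class exactly; best-of-M selection then scores
    only the non-stratum variables.
    """
    if m < 1:
        raise BalanceError("m must be >= 1")
    for s in strata_vars:
        if cohort.variable(s).kind != "categorical":
            raise BalanceError(f"stratum variable {s!r} must be categorical")
    majority, minority, n_maj, n_min, _ = _split_classes(cohort)
    if variables is None:
        variables = [
            v.name
            for v in cohort.schema
            if v.role != "outcome" and v.name not in strata_vars
        ]
    if set(variables) & set(strata_vars):
        raise BalanceError("scored variables must not include stratum variables")

    min_key = minority[strata_vars].apply(tuple, axis=1)
    maj_key = majority[strata_vars].apply(tuple, axis=1)
    quotas = min_key.value_counts().sort_index()
    maj_positions = {
        key: np.flatnonzero((maj_key == key).to_numpy()) for key in quotas.index
    }
    short = [
        (key, int(q), len(maj_positions[key]))
        for key, q in quotas.items()
        if len(maj_positions[key]) < q
    ]
    if short:
        detail = "; ".join(f"stratum {k}: need {q}, have {h}" for k, q, h in short)
        raise BalanceError(f"insufficient majority rows in strata: {detail}")

    best: CandidateSample | None = None
    scores: list[float] = []
    for rng in _candidate_rngs(seed, m):
        parts = [
            rng.choice(maj_positions[key], size=int(q), replace=False)
            for key, q in quotas.items()
        ]
        pos = np.concatenate(parts)
        cand = score_candidate(majority.iloc[pos], majority, cohort, variables, row_indices=pos)
        scores.append(cand.score)
        if best is None or cand.score > best.score:
            best = cand
    return _assemble(
        cohort, majority, minority, best.row_indices, best, m, "stratified", seed, scores
    )


# ----------------------------------------------------------------------
# SMOTE oversampling (comparison method)
# ----------------------------------------------------------------------

def _encode_predictors(cohort: Cohort, df: pd.DataFrame):
    """One-hot encode categorical predictors, keep continuous as-is.

    Returns (matrix, column descriptors); descriptors map encoded columns
    back to (variable, level-or-None).
    """
    cols: list[np.ndarray] = []
    desc: list[tuple[str, str | None]] = []
    for v in cohort.schema:
        if v.role == "outcome":
            continue
        if v.kind == "continuous":
            cols.append(df[v.name].to_numpy(float))
            desc.append((v.name, None))
        else:
            for level in v.levels:
                cols.append((df[v.name].to_numpy() == level).astype(float))
                desc.append((v.name, level))
    return np.column_stack(cols), desc


def _decode_predictors(X: np.ndarray, desc, cohort: Cohort) -> pd.DataFrame:
    out: dict[str, np.ndarray] = {}
    j = 0
    for v in cohort.schema:
        if v.role == "outcome":
            continue
        if v.kind == "continuous":
            out[v.name] = X[:, j]
            j += 1
        else:
            block = X[:, j : j + len(v.levels)]
            # indicators rounded back to {0,1}: one-hot via argmax
            out[v.name] = np.array(v.levels)[np.argmax(block, axis=1)]
            j += len(v.levels)
    return pd.DataFrame(out)


def smote_oversample(cohort: Cohort, k: int = 5, seed: int = 0) -> BalanceResult:
    """Balance by synthesizing minority rows via SMOTE.

    Generates n_majority − n_minority synthetic minority rows, each a
    uniform convex combination of a random minority seed row and one of its
    ``k`` nearest minority neighbours (Euclidean distance on features
    standardized by the pooled mean/SD).  One-hot indicator columns of the
    synthetic rows are rounded back to {0, 1} (argmax within each
    variable's block) before decoding.
    """
    majority, minority, n_maj, n_min, minority_level = _split_classes(cohort)
    if k >= n_min:
        raise BalanceError(f"k={k} must be < n_minority={n_min}")
    if k < 1:
        raise BalanceError("k must be >= 1")
    rng = np.random.default_rng(seed)

    X_min, desc = _encode_predictors(cohort, minority)
    X_all, _ = _encode_predictors(cohort, cohort.records)
    mu = X_all.mean(axis=0)
    sd = X_all.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z_min = (X_min - mu) / sd

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z_min)
    _, neigh = nn.kneighbors(Z_min)  # column 0 is the point itself

    n_new = n_maj - n_min
    seeds = rng.integers(0, n_min, size=n_new)
    picks = rng.integers(0, k, size=n_new)
    lams = rng.random(n_new)
    neighbours = neigh[seeds, picks + 1]

    Z_new = (1 - lams[:, None]) * Z_min[seeds] + lams[:, None] * Z_min[neighbours]
    X_new = Z_new * sd + mu

    synth = _decode_predictors(X_new, desc, cohort)
    synth[cohort.outcome.name] = minority_level
    balanced_df = pd.concat([cohort.records, synth], axis=0).reset_index(drop=True)
    balanced = Cohort(balanced_df, list(cohort.schema), provenance=f"smote seed={seed}")
    parents = np.column_stack([seeds, neighbours, lams])
    return BalanceResult(
        balanced,
        None,
        0,
        "smote",
        seed,
        synthetic_parents=parents,
        synthetic_encoded=Z_new,
        encoded_minority=Z_min,
    )
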