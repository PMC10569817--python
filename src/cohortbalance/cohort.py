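"""Cohort data model: schemas, loading, relative proportions, class accounting.

A :class:`Cohort` is the universal currency of the pipeline — a rectangular
record table (one row per participant) together with a declared variable
schema.  The schema distinguishes categorical from continuous variables and
assigns each a role: ``predictor``, ``outcome`` (exactly one, binary) or
``group`` (a categorical column used for per-subpopulation analyses, e.g.
race/ethnicity; group variables may also enter models as predictors).

Continuous variables may carry schema-declared threshold transforms (e.g.
``age_gt65`` as the indicator of age > 65) producing binary categorical
views while keeping the continuous original available for distributional
scoring.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortError",
    "LoadError",
    "VariableSchema",
    "ThresholdSpec",
    "Cohort",
    "load_schema",
    "save_schema",
    "load_cohort",
    "write_cohort",
    "apply_thresholds",
    "relative_proportion",
    "class_counts",
]


class CohortError(ValueError):
    """Invalid cohort structure or schema violation."""


class LoadError(CohortError):
    """Raised when a CSV cannot be validated against its schema."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of a single cohort variable.

    Parameters
    ----------
    name : str
        Unique column name.
    kind : {"categorical", "continuous"}
    levels : tuple of str, optional
        Ordered level labels; required for categorical variables, forbidden
        for continuous ones.  For the outcome, the order is
        (non-event, event) by convention, and the second level breaks
        class-count ties.
    role : {"predictor", "outcome", "group"}
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    role: str = "predictor"

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise CohortError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.role not in ("predictor", "outcome", "group"):
            raise CohortError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise CohortError(f"categorical variable {self.name!r} needs levels")
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise CohortError(f"duplicate levels for {self.name!r}")
        elif self.levels is not None:
            raise CohortError(f"continuous variable {self.name!r} must not declare levels")
        if self.role == "outcome":
            if self.kind != "categorical" or len(self.levels or ()) != 2:
                raise CohortError("outcome must be categorical with exactly 2 levels")
        if self.role == "group" and self.kind != "categorical":
            raise CohortError(f"group variable {self.name!r} must be categorical")


@dataclass(frozen=True)
class ThresholdSpec:
    """Binary indicator derived from a continuous variable.

    ``name`` takes level ``levels[1]`` where ``source > threshold`` and
    ``levels[0]`` otherwise (so e.g. age_gt65 with levels ("No", "Yes")).
    """

    name: str
    source: str
    threshold: float
    levels: tuple[str, str] = ("No", "Yes")

    def schema_entry(self) -> VariableSchema:
        return VariableSchema(self.name, "categorical", tuple(self.levels), "predictor")


def _check_schema(schema: list[VariableSchema]) -> VariableSchema:
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        raise CohortError("variable names must be unique")
    outcomes = [v for v in schema if v.role == "outcome"]
    if len(outcomes) != 1:
        raise CohortError(f"schema must declare exactly one outcome, found {len(outcomes)}")
    return outcomes[0]


@dataclass
class Cohort:
    """A validated record table plus its variable schema."""

    records: pd.DataFrame
    schema: list[VariableSchema]
    provenance: str = ""

    def __post_init__(self) -> None:
        outcome = _check_schema(self.schema)
        if len(self.records) < 1:
            raise CohortError("cohort must contain at least one record")
        missing = [v.name for v in self.schema if v.name not in self.records.columns]
        if missing:
            raise CohortError(f"columns missing from records: {missing}")
        if self.records[outcome.name].isna().any():
            raise CohortError("records with missing outcome are not allowed")
        for v in self.schema:
            if v.kind == "categorical":
                col = self.records[v.name]
                bad = set(col.dropna().unique()) - set(v.levels)
                if bad:
                    raise CohortError(
                        f"column {v.name!r} contains undeclared levels: {sorted(bad)}"
                    )

    # -- schema helpers -------------------------------------------------
    @property
    def outcome(self) -> VariableSchema:
        return next(v for v in self.schema if v.role == "outcome")

    def variable(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise CohortError(f"variable {name!r} not in schema")

    @property
    def n(self) -> int:
        return len(self.records)

    def subset(self, mask_or_index) -> "Cohort":
        """A new cohort restricted to the given boolean mask or index."""
        if isinstance(mask_or_index, (pd.Series, np.ndarray)) and getattr(
            mask_or_index, "dtype", None
        ) == bool:
            sub = self.records.loc[mask_or_index]
        else:
            sub = self.records.loc[mask_or_index]
        return Cohort(sub.copy(), list(self.schema), self.provenance)


def load_schema(path) -> tuple[list[VariableSchema], list[ThresholdSpec]]:
    """Read a variable schema (and optional thresholds block) from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    variables = [
        VariableSchema(
            name=str(e["name"]),
            kind=e["kind"],
            levels=tuple(map(str, e["levels"])) if e.get("levels") else None,
            role=e.get("role", "predictor"),
        )
        for e in doc["variables"]
    ]
    thresholds = [
        ThresholdSpec(
            name=str(t["name"]),
            source=str(t["source"]),
            threshold=float(t["threshold"]),
            levels=tuple(map(str, t.get("levels", ("No", "Yes")))),
        )
        for t in doc.get("thresholds", [])
    ]
    _check_schema(variables + [t.schema_entry() for t in thresholds])
    return variables, thresholds


def save_schema(path, schema: list[VariableSchema], thresholds: list[ThresholdSpec] = ()) -> None:
    doc = {
        "variables": [
            {
                "name": v.name,
                "kind": v.kind,
                **({"levels": list(v.levels)} if v.levels else {}),
                "role": v.role,
            }
            for v in schema
            if v.name not in {t.name for t in thresholds}
        ],
        "thresholds": [
            {
                "name": t.name,
                "source": t.source,
                "threshold": t.threshold,
                "levels": list(t.levels),
            }
            for t in thresholds
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def apply_thresholds(records: pd.DataFrame, thresholds: list[ThresholdSpec]) -> pd.DataFrame:
    """Add threshold-derived binary indicator columns to ``records``."""
    out = records.copy()
    for t in thresholds:
        if t.source not in out.columns:
            raise CohortError(f"threshold {t.name!r}: source column {t.source!r} missing")
        x = pd.to_numeric(out[t.source])
        out[t.name] = np.where(x > t.threshold, t.levels[1], t.levels[0])
        out.loc[x.isna(), t.name] = np.nan
    return out


def load_cohort(
    path,
    schema: list[VariableSchema],
    missing_policy: str = "drop_row",
    thresholds: list[ThresholdSpec] | None = None,
    provenance: str | None = None,
) -> tuple[Cohort, int]:
    """Load and validate a cohort CSV against a schema.

    Categorical cells are compared as exact strings after trimming
    surrounding whitespace (case-sensitive).  Rows with any missing value
    are dropped under ``missing_policy="drop_row"`` (row-wise deletion —
    no imputation) or rejected under ``"error"``.

    Returns
    -------
    (cohort, n_dropped)
    """
    if missing_policy not in ("drop_row", "error"):
        raise LoadError(f"unknown missing_policy {missing_policy!r}")
    thresholds = list(thresholds or [])
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    base_names = [v.name for v in schema]
    derived = {t.name for t in thresholds}
    unknown = [c for c in raw.columns if c not in base_names and c not in derived]
    if unknown:
        raise LoadError(f"unknown column(s) in CSV: {unknown}")
    # threshold-derived columns present in the file are recomputed from source
    raw = raw.drop(columns=[c for c in raw.columns if c in derived and c not in base_names])
    absent = [n for n in base_names if n not in raw.columns]
    if absent:
        raise LoadError(f"schema column(s) missing from CSV: {absent}")

    df = pd.DataFrame(index=raw.index)
    for v in schema:
        col = raw[v.name].str.strip()
        col = col.replace({"": np.nan, "NA": np.nan, "NaN": np.nan})
        if v.kind == "continuous":
            parsed = pd.to_numeric(col, errors="coerce")
            bad = parsed.isna() & col.notna()
            if bad.any():
                row = int(bad.idxmax())
                raise LoadError(
                    f"unparseable numeric value {col[row]!r} in column {v.name!r}, row {row}"
                )
            df[v.name] = parsed
        else:
            bad = col.notna() & ~col.isin(v.levels)
            if bad.any():
                row = int(bad.idxmax())
                raise LoadError(
                    f"undeclared level {col[row]!r} for column {v.name!r}, row {row} "
                    f"(declared: {list(v.levels)})"
                )
            df[v.name] = col

    df = apply_thresholds(df, thresholds)
    full_schema = list(schema) + [t.schema_entry() for t in thresholds]

    incomplete = df.isna().any(axis=1)
    n_drop = int(incomplete.sum())
    if n_drop and missing_policy == "error":
        row = int(incomplete.idxmax())
        raise LoadError(f"missing value(s) in row {row} under missing_policy='error'")
    df = df.loc[~incomplete].reset_index(drop=True)
    if len(df) == 0:
        raise LoadError("no complete records remain after dropping missing rows")
    cohort = Cohort(df, full_schema, provenance or f"loaded from {path}")
    return cohort, n_drop


def write_cohort(cohort: Cohort, path) -> None:
    """Write the record table as RFC-4180 CSV (round-trips with load_cohort)."""
    cohort.records.to_csv(path, index=False)


def relative_proportion(
    cohort: Cohort, variable: str, group_var: str, group_level: str
) -> dict[str, float]:
    """Within-group level proportions of a categorical variable.

    For each level k of ``variable``, the fraction of records in the
    subpopulation ``group_var == group_level`` taking value k.  Values are
    non-negative and sum to 1.
    """
    var = cohort.variable(variable)
    grp = cohort.variable(group_var)
    if var.kind != "categorical" or grp.kind != "categorical":
        raise CohortError("relative_proportion requires categorical variable and group")
    if group_level not in grp.levels:
        raise CohortError(f"{group_level!r} is not a level of {group_var!r}")
    members = cohort.records[cohort.records[group_var] == group_level]
    total = len(members)
    if total == 0:
        raise CohortError(f"group {group_var}={group_level!r} has no members")
    counts = members[variable].value_counts()
    return {k: float(counts.get(k, 0)) / total for k in var.levels}


def class_counts(cohort: Cohort) -> tuple[int, int, str]:
    """Majority/minority counts of the binary outcome.

    Returns ``(n_majority, n_minority, minority_level)``; on an exact tie
    the level declared second in the schema is the minority.
    """
    lev0, lev1 = cohort.outcome.levels
    counts = cohort.records[cohort.outcome.name].value_counts()
    n0, n1 = int(counts.get(lev0, 0)), int(counts.get(lev1, 0))
    if n1 <= n0:  # tie -> second-declared level is the minority
        return n0, n1, lev1
    return n1, n0, lev0
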