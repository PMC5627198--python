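"""Stage 1: remove litter/maternal covariate effects before mapping.

Each (trait, role, day) combination gets its own Gaussian least-squares
GLM on the six litter covariates.  Non-significant terms (p > alpha) are
removed one at a time — always the single term with the largest p —
and the model refit until every remaining term is significant.  Batch
enters and leaves as a whole categorical factor, tested by a partial
F-test; continuous covariates are tested by their coefficient t-test.
Residuals from the final model are averaged per BXD line to give the
line-mean vectors that the genome scan maps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import COVARIATES, FamilyTable

__all__ = [
    "ModelSpec",
    "AdjustedTrait",
    "LineTraitVector",
    "backward_eliminate",
    "residualize",
    "line_means",
    "adjust_trait",
]


@dataclass
class ModelSpec:
    """Outcome of backward elimination for one trait."""

    trait: str
    role: str
    day: int
    retained: list[str]
    removal_log: list[dict]  # [{"step": k, "term": name, "p": float}]
    term_pvalues: dict[str, float]
    coefficients: dict[str, float]
    alpha: float
    row_index: pd.Index  # rows of the FamilyTable the model was fit on

    def to_json(self) -> str:
        d = {
            "trait": self.trait,
            "role": self.role,
            "day": self.day,
            "alpha": self.alpha,
            "retained": self.retained,
            "removal_log": self.removal_log,
            "term_pvalues": self.term_pvalues,
            "coefficients": self.coefficients,
        }
        return json.dumps(d, indent=2)


@dataclass
class AdjustedTrait:
    """Covariate-adjusted residuals for one (trait, role, day)."""

    spec: ModelSpec
    residuals: pd.Series  # indexed like the source rows
    excluded_rows: pd.Index = field(default_factory=lambda: pd.Index([]))


@dataclass
class LineTraitVector:
    """Per-line mean residual — the unit of QTL mapping."""

    trait: str
    role: str
    day: int
    effect_class: str
    values: pd.Series  # index: line_id
    n_replicates: pd.Series

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)


def _design(
    rows: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Build the design matrix with intercept; batch expands to dummies."""
    cols: list[np.ndarray] = [np.ones(len(rows))]
    names = ["Intercept"]
    groups: dict[str, list[int]] = {}
    for t in terms:
        if t == "batch":
            dummies = pd.get_dummies(rows["batch"].astype(str), drop_first=True)
            groups["batch"] = []
            for level in dummies.columns:
                groups["batch"].append(len(names))
                names.append(f"batch[{level}]")
                cols.append(dummies[level].to_numpy(dtype=float))
        else:
            groups[t] = [len(names)]
            names.append(t)
            cols.append(rows[t].to_numpy(dtype=float))
    return np.column_stack(cols), names, groups


def _term_pvalues(
    res, X: np.ndarray, groups: dict[str, list[int]]
) -> dict[str, float]:
    """Per-term p: coefficient t-test for single columns, partial F for factors."""
    pvals: dict[str, float] = {}
    for term, idx in groups.items():
        if len(idx) == 1:
            pvals[term] = float(res.pvalues[idx[0]])
        else:
            contrast = np.zeros((len(idx), X.shape[1]))
            for row, j in enumerate(idx):
                contrast[row, j] = 1.0
            pvals[term] = float(res.f_test(contrast).pvalue)
    return pvals


def backward_eliminate(
    tbl: FamilyTable,
    trait: str,
    role: str,
    day: int,
    covariates: tuple[str, ...] = COVARIATES,
    alpha: float = 0.05,
) -> ModelSpec:
    """Stepwise backward elimination of covariates for one trait.

    At each step the term with the largest p > ``alpha`` is dropped (ties
    broken by dropping the term later in the declared covariate order) and
    the model refit, until all remaining terms are significant or none
    remain.
    """
    unknown = set(covariates) - set(COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    rows = tbl.rows_for(trait, role, day)
    if rows.empty:
        raise ValueError(f"no rows for trait={trait!r} role={role!r} day={day}")
    cont = [c for c in covariates if c != "batch"]
    complete = ~rows[cont].isna().any(axis=1)
    if "batch" in covariates:
        complete &= rows["batch"].notna()
    rows = rows[complete]

    terms = list(covariates)
    y = rows["value"].to_numpy(dtype=float)
    removal_log: list[dict] = []
    step = 0
    while True:
        X, names, groups = _design(rows, terms)
        if len(rows) < X.shape[1] + 2:
            raise ValueError(
                f"too few rows ({len(rows)}) for {X.shape[1]} model columns"
            )
        if terms and np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"rank-deficient design; collinear terms among {terms}"
            )
        if not terms:
            pvals, coefs = {}, {"Intercept": float(np.mean(y))}
            break
        if np.var(y) == 0:
            # degenerate: nothing to explain, drop everything
            removal_log += [
                {"step": step + i, "term": t, "p": 1.0} for i, t in enumerate(terms)
            ]
            terms = []
            continue
        res = sm.OLS(y, X).fit()
        pvals = _term_pvalues(res, X, groups)
        coefs = dict(zip(names, map(float, res.params)))
        worst, worst_p = None, alpha
        for t in terms:  # declared order; >= keeps the later term on ties
            if pvals[t] >= worst_p and pvals[t] > alpha:
                worst, worst_p = t, pvals[t]
        if worst is None:
            break
        step += 1
        removal_log.append({"step": step, "term": worst, "p": worst_p})
        terms = [t for t in terms if t != worst]
    return ModelSpec(
        trait=trait,
        role=role,
        day=day,
        retained=terms,
        removal_log=removal_log,
        term_pvalues=pvals,
        coefficients=coefs,
        alpha=alpha,
        row_index=rows.index,
    )


def residualize(tbl: FamilyTable, spec: ModelSpec) -> AdjustedTrait:
    """Residuals (observed − fitted) under the eliminated model.

    With no retained terms the residuals are the mean-centred trait.  Rows
    with missing covariate values are excluded and reported on the result.
    """
    rows = tbl.rows_for(spec.trait, spec.role, spec.day)
    needed = [c for c in spec.retained if c != "batch"]
    complete = ~rows[needed].isna().any(axis=1) if needed else pd.Series(True, index=rows.index)
    if "batch" in spec.retained:
        complete &= rows["batch"].notna()
    excluded = rows.index[~complete]
    if len(excluded):
        warnings.warn(f"{len(excluded)} rows excluded for missing covariates")
    rows = rows[complete]
    y = rows["value"].to_numpy(dtype=float)
    if not spec.retained:
        fitted = np.full(len(rows), np.mean(y))
    else:
        X, names, _ = _design(rows, spec.retained)
        res = sm.OLS(y, X).fit()
        fitted = np.asarray(res.fittedvalues)
    resid = pd.Series(y - fitted, index=rows.index, name="residual")
    return AdjustedTrait(spec=spec, residuals=resid, excluded_rows=excluded)


def line_means(adj: AdjustedTrait, tbl: FamilyTable) -> LineTraitVector:
    """Average residuals per BXD line (the line fostered into each family).

    For indirect traits (B6 offspring, mother) the attribution to the BXD
    line comes from the family table's ``line_id`` column, so the same
    function serves both effect classes.
    """
    lines = tbl.data.loc[adj.residuals.index, "line_id"]
    grouped = adj.residuals.groupby(lines)
    means = grouped.mean()
    counts = grouped.size()
    if (counts < 1).any():
        warnings.warn("lines with no residual rows omitted")
    effect_class = "direct" if adj.spec.role == "BXD_offspring" else "indirect"
    return LineTraitVector(
        trait=adj.spec.trait,
        role=adj.spec.role,
        day=adj.spec.day,
        effect_class=effect_class,
        values=means.sort_index(),
        n_replicates=counts.sort_index(),
    )


def adjust_trait(
    tbl: FamilyTable,
    trait: str,
    role: str,
    day: int,
    covariates: tuple[str, ...] = COVARIATES,
    alpha: float = 0.05,
) -> tuple[AdjustedTrait, LineTraitVector]:
    """Convenience: eliminate, residualize and line-average in one call."""
    spec = backward_eliminate(tbl, trait, role, day, covariates, alpha)
    adj = residualize(tbl, spec)
    return adj, line_means(adj, tbl)
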