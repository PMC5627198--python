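"""Stage 4: effect sizes and consistency statistics.

Three quantities back up a mapped locus: the coefficient of determination
(R²) of the line means on the peak-marker genotype, with the allele that
increases the trait value; the phenotypic correlation between directly
and indirectly affected traits across lines; and a broad-sense
heritability estimate (eta² from a one-way ANOVA with line as the factor)
on replicate-level adjusted residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariate_adjust import LineTraitVector

__all__ = [
    "CorrelationRecord",
    "HeritabilityRecord",
    "peak_r2",
    "trait_correlation",
    "heritability_anova",
]


@dataclass
class CorrelationRecord:
    """Across-line correlation between a direct and an indirect trait."""

    trait_x: tuple[str, str]  # (role, trait)
    trait_y: tuple[str, str]
    day: int
    r: float
    p: float
    n_lines: int


@dataclass
class HeritabilityRecord:
    """Broad-sense heritability (between-line eta²) for one trait."""

    trait: str
    role: str
    day: int
    h2: float
    f_stat: float
    p: float
    n_lines: int
    n_obs: int


def peak_r2(
    y: LineTraitVector | pd.Series, calls: pd.Series
) -> tuple[float, str | None]:
    """R² of line means on the peak-marker genotype, plus allele direction.

    ``allele_increasing`` is ``"D2"`` when the D-coded (code 1) coefficient
    is positive, ``"B6"`` when negative, None for an exactly zero slope.
    Raises on a monomorphic marker.
    """
    vals = y.values if isinstance(y, LineTraitVector) else y
    shared = vals.index.intersection(calls.index)
    yy = vals.loc[shared].to_numpy(dtype=float)
    gg = calls.loc[shared].to_numpy(dtype=float)
    ok = ~np.isnan(gg) & ~np.isnan(yy)
    yy, gg = yy[ok], gg[ok]
    if len(np.unique(gg)) < 2:
        raise ValueError("marker is monomorphic over the mapped lines")
    yc = yy - yy.mean()
    gc = gg - gg.mean()
    syy = float(yc @ yc)
    sxx = float(gc @ gc)
    sxy = float(yc @ gc)
    if syy == 0:
        return 0.0, None
    r2 = sxy**2 / (sxx * syy)
    slope = sxy / sxx
    allele = "D2" if slope > 0 else ("B6" if slope < 0 else None)
    return float(r2), allele


def trait_correlation(
    x: LineTraitVector, y: LineTraitVector
) -> CorrelationRecord:
    """Product-moment correlation between two line-mean vectors.

    Uses the lines present in both vectors; two-sided p from the t
    transform (scipy's pearsonr).  Requires >= 3 shared lines.
    """
    shared = x.values.index.intersection(y.values.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared lines; need >= 3")
    res = stats.pearsonr(
        x.values.loc[shared].to_numpy(dtype=float),
        y.values.loc[shared].to_numpy(dtype=float),
    )
    day = x.day if x.day == y.day else x.day
    return CorrelationRecord(
        trait_x=(x.role, x.trait),
        trait_y=(y.role, y.trait),
        day=day,
        r=float(res.statistic),
        p=float(res.pvalue),
        n_lines=len(shared),
    )


def heritability_anova(
    residuals: pd.Series,
    lines: pd.Series,
    trait: str = "",
    role: str = "",
    day: int = 0,
) -> HeritabilityRecord:
    """Broad-sense heritability as eta² from a one-way ANOVA on line.

    ``residuals`` are replicate-level adjusted trait values and ``lines``
    the BXD line of each observation (same index).  H² = SS_between /
    SS_total; F and its p-value come from the usual decomposition.
    Requires at least two lines with two or more replicates.
    """
    df = pd.DataFrame({"y": residuals, "line": lines.loc[residuals.index]}).dropna()
    counts = df.groupby("line").size()
    k = len(counts)
    n = len(df)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 lines with >= 2 replicates for the ANOVA")
    grand = df["y"].mean()
    group_means = df.groupby("line")["y"].mean()
    ss_between = float((counts * (group_means - grand) ** 2).sum())
    ss_total = float(((df["y"] - grand) ** 2).sum())
    if ss_total == 0:
        warnings.warn("zero total variance; H2 undefined, reporting 0")
        return HeritabilityRecord(trait, role, day, 0.0, 0.0, 1.0, k, n)
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    return HeritabilityRecord(
        trait=trait,
        role=role,
        day=day,
        h2=ss_between / ss_total,
        f_stat=float(f_stat),
        p=p,
        n_lines=k,
        n_obs=n,
    )
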