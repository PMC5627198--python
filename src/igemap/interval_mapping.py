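"""Stage 2: genome scan of line means on RI genotypes.

Haley–Knott regression at markers and pseudomarkers: the phenotype
line-mean vector is regressed on the conditional probability of the D
allele given the flanking typed markers, under the two-state Markov model
with sib-mating-expanded recombination fractions.  The test statistic is
the likelihood ratio statistic

    LRS = n * ln(RSS0 / RSS1)

with RSS0 from the intercept-only model, and LOD = LRS / 4.61 by the
GeneNetwork convention (exact 2*ln(10) selectable).  Genome-wide
significance comes from permuting line labels of the phenotype and
re-recording the genome-wide maximum LRS; support intervals are the
1.5-LOD drop from the peak, reported in Mb by linear interpolation of the
marker (cM, Mb) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneticMap, GenotypeMatrix
from .synthetic_data import expand_rf, haldane
from .covariate_adjust import LineTraitVector

__all__ = [
    "LOD_DIVISOR_GN",
    "LOD_DIVISOR_EXACT",
    "ScanResult",
    "PermutationNull",
    "genotype_prob",
    "genotype_prob_matrix",
    "scan",
    "lrs_to_lod",
    "permutation_null",
    "lod_drop_interval",
    "pointwise_p",
    "plot_scan",
]

#: GeneNetwork's LRS-to-LOD divisor; the exact value is 2*ln(10).
LOD_DIVISOR_GN = 4.61
LOD_DIVISOR_EXACT = 2.0 * np.log(10.0)

#: Cap on RSS0/RSS1 when the QTL model fits perfectly (documented ceiling:
#: LRS <= n * ln(1e12)).
_MAX_RSS_RATIO = 1e12


@dataclass
class PermutationNull:
    """Genome-wide maximum LRS under phenotype permutation."""

    max_lrs: np.ndarray
    alpha: float
    seed: int | None
    n_perm: int

    @property
    def threshold(self) -> float:
        """Empirical (1 - alpha) quantile of the null maxima."""
        return float(np.quantile(self.max_lrs, 1.0 - self.alpha))

    def genomewide_p(self, observed_max: float, estimator: str = "add_one") -> float:
        """P-value of an observed genome-wide maximum against the null.

        ``add_one`` uses (1 + #{perm >= obs}) / (n_perm + 1) so p is never
        zero; ``raw`` is the plain permutation fraction.
        """
        exceed = int(np.sum(self.max_lrs >= observed_max))
        if estimator == "add_one":
            return (1 + exceed) / (self.n_perm + 1)
        if estimator == "raw":
            return exceed / self.n_perm
        raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class ScanResult:
    """LRS/LOD profile and peak summary for one (trait, effect-class) scan."""

    trait: str
    role: str
    day: int
    effect_class: str
    grid: pd.DataFrame  # columns: chromosome, cM, Mb, LRS, LOD, n
    lod_divisor: float
    n_lines: int
    peak_index: int
    threshold: float | None = None
    genomewide_p: float | None = None
    p_is_protected: bool = False
    ci_Mb: tuple[float, float] | None = None

    @property
    def peak(self) -> pd.Series:
        return self.grid.loc[self.peak_index]

    @property
    def peak_chromosome(self) -> str:
        return str(self.peak["chromosome"])

    @property
    def peak_Mb(self) -> float:
        return float(self.peak["Mb"])

    @property
    def max_lrs(self) -> float:
        return float(self.peak["LRS"])

    @property
    def max_lod(self) -> float:
        return float(self.peak["LOD"])

    def to_frame(self) -> pd.DataFrame:
        return self.grid.copy()


def lrs_to_lod(lrs, divisor: float = LOD_DIVISOR_GN):
    """Convert a likelihood ratio statistic to a LOD score (LRS / divisor)."""
    arr = np.asarray(lrs, dtype=float)
    if np.any(arr < 0):
        raise ValueError("LRS must be non-negative")
    out = arr / divisor
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------


def _flank_prob(g_left, d_left, g_right, d_right) -> float:
    """P(D at target | flanking calls) under the two-state chain.

    Distances are in cM; either flank may be None (conditions on the other
    alone).  Step probability over distance d is expand_rf(haldane(d)).
    """

    def step(a: float, b: float, d: float) -> float:
        R = expand_rf(haldane(d))
        return R if a != b else 1.0 - R

    if g_left is None and g_right is None:
        return np.nan
    if g_left is None:
        return step(1.0, g_right, d_right) / (
            step(1.0, g_right, d_right) + step(0.0, g_right, d_right)
        )
    if g_right is None:
        return step(g_left, 1.0, d_left) / (
            step(g_left, 1.0, d_left) + step(g_left, 0.0, d_left)
        )
    num = step(g_left, 1.0, d_left) * step(1.0, g_right, d_right)
    den = num + step(g_left, 0.0, d_left) * step(0.0, g_right, d_right)
    return num / den


def genotype_prob(
    gmap: GeneticMap,
    G: GenotypeMatrix,
    line: str,
    chromosome: str,
    position_cm: float,
) -> float:
    """Conditional P(D allele) for one line at a chromosome position.

    At a typed marker this returns the call itself; between markers it
    conditions on the nearest informative flanking calls; a line untyped on
    the whole chromosome yields NaN (excluded position-wise downstream).
    """
    sub = gmap.chrom_slice(chromosome)
    i = G.line_index(line)
    cms = sub["cM"].to_numpy()
    calls = G.calls[i, sub.index.to_numpy()]
    typed = ~np.isnan(calls)
    if not typed.any():
        return np.nan
    at = np.flatnonzero(typed & np.isclose(cms, position_cm))
    if at.size:
        return float(calls[at[0]])
    left = np.flatnonzero(typed & (cms < position_cm))
    right = np.flatnonzero(typed & (cms > position_cm))
    g_l = float(calls[left[-1]]) if left.size else None
    d_l = position_cm - cms[left[-1]] if left.size else None
    g_r = float(calls[right[0]]) if right.size else None
    d_r = cms[right[0]] - position_cm if right.size else None
    return float(_flank_prob(g_l, d_l, g_r, d_r))


def _chrom_grid(sub: pd.DataFrame, step_cm: float) -> np.ndarray:
    cms = sub["cM"].to_numpy()
    if step_cm <= 0:
        return np.unique(cms)
    grid = np.arange(cms[0], cms[-1] + 1e-9, step_cm)
    return np.unique(np.concatenate([grid, cms]))


def genotype_prob_matrix(
    gmap: GeneticMap, G: GenotypeMatrix, step_cm: float = 0.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """P(D) design matrix (lines x grid positions) over the whole map.

    The grid is the typed markers, plus pseudomarkers every ``step_cm``
    (0 = markers only).  Returns the grid table (chromosome, cM, Mb) and
    the probability matrix with NaN where a line is uninformative.
    """
    grids = []
    mats = []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_slice(chrom)
        pos = _chrom_grid(sub, step_cm)
        mb = np.interp(pos, sub["cM"].to_numpy(), sub["Mb"].to_numpy())
        grids.append(pd.DataFrame({"chromosome": chrom, "cM": pos, "Mb": mb}))
        cms = sub["cM"].to_numpy()
        calls = G.calls[:, sub.index.to_numpy()]  # lines x markers on chrom
        X = np.empty((G.n_lines, pos.size))
        for i in range(G.n_lines):
            c = calls[i]
            typed = ~np.isnan(c)
            if not typed.any():
                X[i] = np.nan
                continue
            tc, tg = cms[typed], c[typed]
            for k, p in enumerate(pos):
                j = np.searchsorted(tc, p)
                if j < tc.size and np.isclose(tc[j], p):
                    X[i, k] = tg[j]
                    continue
                g_l = tg[j - 1] if j > 0 else None
                d_l = p - tc[j - 1] if j > 0 else None
                g_r = tg[j] if j < tc.size else None
                d_r = tc[j] - p if j < tc.size else None
                X[i, k] = _flank_prob(g_l, d_l, g_r, d_r)
        mats.append(X)
    grid = pd.concat(grids, ignore_index=True)
    return grid, np.concatenate(mats, axis=1)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


def _lrs_profile(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position LRS for one phenotype vector; complete-case per position.

    Returns (lrs, n_used) arrays over positions.
    """
    n, P = X.shape
    lrs = np.zeros(P)
    n_used = np.zeros(P, dtype=int)
    finite = ~np.isnan(X)
    if finite.all():
        yc = y - y.mean()
        syy = float(yc @ yc)
        n_used[:] = n
        if syy == 0:
            warnings.warn("zero phenotypic variance; LRS profile is all zero")
            return lrs, n_used
        Xc = X - X.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Xc, Xc)
        sxy = yc @ Xc
        with np.errstate(invalid="ignore", divide="ignore"):
            rss1 = syy - np.where(sxx > 0, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)
        ratio = np.where(rss1 > syy / _MAX_RSS_RATIO, syy / np.maximum(rss1, 1e-300), _MAX_RSS_RATIO)
        if np.any(rss1 <= syy / _MAX_RSS_RATIO):
            warnings.warn("perfect fit at some positions; LRS capped")
        lrs = n * np.log(ratio)
        return np.maximum(lrs, 0.0), n_used
    for j in range(P):
        ok = finite[:, j]
        yj, xj = y[ok], X[ok, j]
        n_used[j] = ok.sum()
        if n_used[j] < 3:
            continue
        yc = yj - yj.mean()
        syy = float(yc @ yc)
        if syy == 0:
            continue
        xc = xj - xj.mean()
        sxx = float(xc @ xc)
        rss1 = syy - (float(yc @ xc) ** 2 / sxx if sxx > 0 else 0.0)
        if rss1 <= syy / _MAX_RSS_RATIO:
            warnings.warn("perfect fit at a position; LRS capped")
            rss1 = syy / _MAX_RSS_RATIO
        lrs[j] = n_used[j] * np.log(syy / rss1)
    return np.maximum(lrs, 0.0), n_used


def _align(y: LineTraitVector, G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype vector and line-row indices shared between y and G."""
    shared = [l for l in G.line_ids if l in y.values.index]
    if len(shared) < 8:
        raise ValueError(f"only {len(shared)} lines shared between phenotype and genotypes")
    rows = np.array([G.line_index(l) for l in shared])
    return y.values.loc[shared].to_numpy(dtype=float), rows


def scan(
    y: LineTraitVector,
    G: GenotypeMatrix,
    gmap: GeneticMap,
    step_cm: float = 0.0,
    lod_divisor: float = LOD_DIVISOR_GN,
    _prob: tuple[pd.DataFrame, np.ndarray] | None = None,
) -> ScanResult:
    """Haley–Knott genome scan of one line-mean vector.

    ``_prob`` lets callers reuse a precomputed genotype-probability matrix
    (as the permutation test does).  Peak ties break toward the smallest
    Mb position.
    """
    yv, rows = _align(y, G)
    if _prob is None:
        grid, X = genotype_prob_matrix(gmap, G, step_cm)
    else:
        grid, X = _prob
    lrs, n_used = _lrs_profile(yv, X[rows])
    lod = lrs / lod_divisor
    out = grid.copy()
    out["LRS"] = lrs
    out["LOD"] = lod
    out["n"] = n_used
    # smallest-Mb tie-break: stable argmax over ties
    best = np.flatnonzero(lrs == lrs.max())
    peak = int(best[np.argmin(out.loc[best, "Mb"].to_numpy())]) if len(best) > 1 else int(best[0])
    return ScanResult(
        trait=y.trait,
        role=y.role,
        day=y.day,
        effect_class=y.effect_class,
        grid=out,
        lod_divisor=lod_divisor,
        n_lines=len(yv),
        peak_index=peak,
    )


def permutation_null(
    y: LineTraitVector,
    G: GenotypeMatrix,
    gmap: GeneticMap,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    step_cm: float = 0.0,
    _prob: tuple[pd.DataFrame, np.ndarray] | None = None,
) -> PermutationNull:
    """Null distribution of the genome-wide max LRS by permuting line labels.

    Genotypes stay fixed; the phenotype vector is shuffled across lines
    ``n_perm`` times and the maximum LRS over the whole grid recorded each
    time.  Deterministic given the seed.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable null tail")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yv, rows = _align(y, G)
    if _prob is None:
        grid, X = genotype_prob_matrix(gmap, G, step_cm)
    else:
        grid, X = _prob
    Xr = X[rows]
    n = len(yv)
    finite = ~np.isnan(Xr)
    maxima = np.empty(n_perm)
    if finite.all():
        # vectorised: all permutations share Syy and the centred X
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
        Y = yv[perms]  # n x n_perm
        Yc = Y - Y.mean(axis=0)
        syy = np.einsum("ij,ij->j", Yc, Yc)
        Xc = Xr - Xr.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Xc, Xc)
        sxy = Xc.T @ Yc  # positions x n_perm
        with np.errstate(invalid="ignore", divide="ignore"):
            rss1 = syy[None, :] - np.where(
                sxx[:, None] > 0, sxy**2 / np.where(sxx[:, None] > 0, sxx[:, None], 1.0), 0.0
            )
        floor = syy[None, :] / _MAX_RSS_RATIO
        rss1 = np.maximum(rss1, floor)
        if np.all(syy > 0):
            lrs = n * np.log(syy[None, :] / rss1)
            maxima = lrs.max(axis=0)
        else:
            maxima[:] = 0.0
    else:
        for b in range(n_perm):
            yp = yv[rng.permutation(n)]
            lrs, _ = _lrs_profile(yp, Xr)
            maxima[b] = lrs.max()
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return PermutationNull(max_lrs=maxima, alpha=alpha, seed=seed_val, n_perm=n_perm)


def lod_drop_interval(
    sr: ScanResult, drop: float = 1.5
) -> tuple[float, float]:
    """Support interval: walk out from the peak until LOD < max_LOD − drop.

    Endpoints are the Mb positions of the outermost grid points that still
    satisfy LOD >= max_LOD − drop before the first failure, clamped at the
    chromosome ends.
    """
    chrom = sr.peak_chromosome
    sub = sr.grid[sr.grid["chromosome"] == chrom]
    lod = sub["LOD"].to_numpy()
    mb = sub["Mb"].to_numpy()
    pk = sub.index.get_loc(sr.peak_index)
    cut = lod[pk] - drop
    lo = pk
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = pk
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    return float(mb[lo]), float(mb[hi])


def pointwise_p(y: LineTraitVector | pd.Series, calls: pd.Series) -> float:
    """Point-wise F-test p for a single-marker regression of line means.

    Equivalent to the two-group comparison at a biallelic marker; feeds the
    protected (BY) step.  Returns NaN (with a warning) if one genotype
    group is empty.
    """
    vals = y.values if isinstance(y, LineTraitVector) else y
    shared = vals.index.intersection(calls.index)
    sub_y = vals.loc[shared].to_numpy(dtype=float)
    sub_g = calls.loc[shared].to_numpy(dtype=float)
    ok = ~np.isnan(sub_g) & ~np.isnan(sub_y)
    sub_y, sub_g = sub_y[ok], sub_g[ok]
    n = len(sub_y)
    if n < 3 or len(np.unique(sub_g)) < 2:
        warnings.warn("marker monomorphic or too few lines; point-wise p undefined")
        return float("nan")
    yc = sub_y - sub_y.mean()
    gc = sub_g - sub_g.mean()
    syy = float(yc @ yc)
    sxx = float(gc @ gc)
    rss1 = syy - float(yc @ gc) ** 2 / sxx
    if syy == 0 or rss1 == syy:
        return 1.0
    if rss1 <= 0:
        return 0.0 if syy > 0 else 1.0
    F = (syy - rss1) / (rss1 / (n - 2))
    return float(stats.f.sf(F, 1, n - 2))


def plot_scan(sr: ScanResult, path=None, ax=None):
    """Manhattan-style LRS profile with chromosome boundaries."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0.0
    ticks, labels = [], []
    for chrom, grp in sr.grid.groupby("chromosome", sort=False):
        x = grp["Mb"].to_numpy() + offset
        ax.plot(x, grp["LRS"].to_numpy(), lw=1)
        ticks.append(offset + grp["Mb"].mean())
        labels.append(chrom)
        offset = x[-1] + 5
    if sr.threshold is not None:
        ax.axhline(sr.threshold, ls="--", c="grey", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("LRS")
    ax.set_title(f"{sr.role}:{sr.trait} d{sr.day} ({sr.effect_class})")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
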