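"""Stage 3: multiple-testing control and locus assembly.

The 24 genome scans (8 role-traits x 3 days) form one Benjamini–Hochberg
family on their genome-wide permutation p-values.  At each BH-selected
locus, the remaining indirect traits are given a protected point-wise test
at the peak marker, controlled by the Benjamini–Yekutieli step-up at
q = 0.10.  Direct and indirect effects whose 1.5-LOD support intervals
mutually overlap on a chromosome are fused into a named social-interaction
locus (``SocInt{chromosome}``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .interval_mapping import ScanResult, lod_drop_interval, pointwise_p

__all__ = [
    "bh_select",
    "by_protected",
    "LocusMember",
    "LocusReport",
    "member_from_scan",
    "co_locate",
    "protected_members",
    "assemble_locus_table",
]


def _step_up(pvals: Sequence[float], thresholds: np.ndarray) -> list[int]:
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    below = np.flatnonzero(p[order] <= thresholds)
    if below.size == 0:
        return []
    k_star = below[-1]
    return sorted(order[: k_star + 1].tolist())


def bh_select(pvals: Sequence[float], q: float = 0.05) -> list[int]:
    """Benjamini–Hochberg step-up: indices selected at FDR ``q``.

    k* = max{k : p(k) <= k q / m}; all ranks <= k* are selected.
    """
    m = len(list(pvals))
    if m == 0:
        return []
    thresholds = (np.arange(1, m + 1) / m) * q
    return _step_up(pvals, thresholds)


def by_protected(pvals: Sequence[float], q: float = 0.10) -> list[int]:
    """Benjamini–Yekutieli step-up with harmonic correction c(m) = sum 1/i.

    Valid under arbitrary dependence; uniformly more conservative than BH
    at equal q.  Used for the protected within-locus tests.
    """
    m = len(list(pvals))
    if m == 0:
        return []
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    thresholds = (np.arange(1, m + 1) / (m * c_m)) * q
    return _step_up(pvals, thresholds)


# ---------------------------------------------------------------------------
# locus reports
# ---------------------------------------------------------------------------


@dataclass
class LocusMember:
    """One trait's statistics at a locus (mirrors a report-table row)."""

    trait: str
    role: str
    day: int
    effect_class: str
    chromosome: str
    peak_Mb: float
    ci_Mb: tuple[float, float]
    max_lrs: float
    max_lod: float
    genomewide_p: float | None
    p_is_protected: bool = False
    allele_increasing: str | None = None
    r2: float | None = None

    @property
    def key(self) -> tuple:
        return (self.role, self.trait, self.day, self.effect_class)


@dataclass
class LocusReport:
    """A named social-interaction locus grouping co-located effects."""

    name: str
    chromosome: str
    members: list[LocusMember] = field(default_factory=list)

    @property
    def has_direct(self) -> bool:
        return any(m.effect_class == "direct" for m in self.members)

    def sorted_members(self) -> list[LocusMember]:
        return sorted(
            self.members,
            key=lambda m: (0 if m.effect_class == "direct" else 1, m.day, m.role, m.trait),
        )


def member_from_scan(sr: ScanResult, drop: float = 1.5) -> LocusMember:
    """Summarise a scan as a locus member, computing its CI if absent."""
    ci = sr.ci_Mb if sr.ci_Mb is not None else lod_drop_interval(sr, drop)
    return LocusMember(
        trait=sr.trait,
        role=sr.role,
        day=sr.day,
        effect_class=sr.effect_class,
        chromosome=sr.peak_chromosome,
        peak_Mb=sr.peak_Mb,
        ci_Mb=ci,
        max_lrs=sr.max_lrs,
        max_lod=sr.max_lod,
        genomewide_p=sr.genomewide_p,
        p_is_protected=sr.p_is_protected,
    )


def _chrom_key(label: str) -> tuple[int, str]:
    s = str(label)
    return (0, f"{int(s):04d}") if s.isdigit() else (1, s)


def co_locate(
    members: Iterable[LocusMember | ScanResult],
) -> tuple[list[LocusReport], list[LocusReport]]:
    """Group significant effects whose support intervals mutually overlap.

    Members on the same chromosome are merged while every pair of closed
    CIs intersects (max of lows <= min of highs); chains that would break
    mutual overlap are split greedily in peak-Mb order.  Groups with at
    least one direct member become ``SocInt{chr}`` loci; purely indirect
    groups are returned separately (they are not loci).
    """
    mems = [m if isinstance(m, LocusMember) else member_from_scan(m) for m in members]
    by_chrom: dict[str, list[LocusMember]] = {}
    for m in mems:
        by_chrom.setdefault(str(m.chromosome), []).append(m)

    loci: list[LocusReport] = []
    indirect_only: list[LocusReport] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        group: list[LocusMember] = []
        groups: list[list[LocusMember]] = []
        max_lo = -np.inf
        min_hi = np.inf
        for m in sorted(by_chrom[chrom], key=lambda m: (m.peak_Mb, m.ci_Mb[0], m.key)):
            lo, hi = m.ci_Mb
            if group and max(max_lo, lo) <= min(min_hi, hi):
                group.append(m)
                max_lo, min_hi = max(max_lo, lo), min(min_hi, hi)
            else:
                if group:
                    groups.append(group)
                group, max_lo, min_hi = [m], lo, hi
        if group:
            groups.append(group)
        named = [g for g in groups if any(m.effect_class == "direct" for m in g)]
        for i, g in enumerate(groups):
            has_direct = any(m.effect_class == "direct" for m in g)
            if has_direct:
                suffix = chr(ord("a") + named.index(g)) if len(named) > 1 else ""
                rep = LocusReport(name=f"SocInt{chrom}{suffix}", chromosome=chrom, members=g)
                loci.append(rep)
            else:
                rep = LocusReport(name=f"chr{chrom}_indirect", chromosome=chrom, members=g)
                indirect_only.append(rep)
    return loci, indirect_only


def protected_members(
    locus_scans: Sequence[ScanResult],
    candidates: dict[tuple, "object"],
    peak_calls,
    q: float = 0.10,
    drop: float = 1.5,
) -> tuple[list[LocusMember], dict]:
    """Protected BY tests for additional indirect effects at a locus.

    ``candidates`` maps (role, trait, day, effect_class) to a pair
    ``(line_mean_vector, scan_result)`` for an indirect trait not already
    selected genome-wide; ``peak_calls`` are the genotype calls at the
    locus peak marker.  Each selected candidate is summarised from its own
    scan profile restricted to the locus chromosome (local peak within the
    direct member's CI, then a local LOD-drop walk).  Returns the new
    members plus an audit record of candidate p-values and selections.
    """
    direct = [s for s in locus_scans if s.effect_class == "direct"]
    if not direct:
        raise ValueError("protected tests require a direct-effect scan at the locus")
    anchor = direct[0]
    ci = anchor.ci_Mb if anchor.ci_Mb is not None else lod_drop_interval(anchor, drop)
    chrom = anchor.peak_chromosome

    keys = sorted(candidates.keys())
    pvals = [pointwise_p(candidates[k][0], peak_calls) for k in keys]
    usable = [i for i, p in enumerate(pvals) if not np.isnan(p)]
    selected = by_protected([pvals[i] for i in usable], q=q)
    chosen = [keys[usable[i]] for i in selected]

    members: list[LocusMember] = []
    for key in chosen:
        sr = candidates[key][1]
        members.append(_local_member(sr, chrom, ci, drop, pval=pvals[keys.index(key)]))
    audit = {
        "candidates": [list(k) for k in keys],
        "pointwise_p": pvals,
        "q": q,
        "selected": [list(k) for k in chosen],
    }
    return members, audit


def _local_member(
    sr: ScanResult, chrom: str, anchor_ci: tuple[float, float], drop: float, pval: float
) -> LocusMember:
    """Member stats for a protected trait: local peak inside the anchor CI."""
    sub = sr.grid[sr.grid["chromosome"] == chrom].reset_index()
    inside = sub[(sub["Mb"] >= anchor_ci[0]) & (sub["Mb"] <= anchor_ci[1])]
    if inside.empty:
        inside = sub
    k = inside["LRS"].idxmax()
    local = replace(
        sr,
        peak_index=int(inside.loc[k, "index"]),
        p_is_protected=True,
        genomewide_p=pval,
        ci_Mb=None,
    )
    ci = lod_drop_interval(local, drop)
    m = member_from_scan(local, drop)
    m.ci_Mb = ci
    return m


def assemble_locus_table(
    reports: Sequence[LocusReport], validation: dict[tuple, dict]
) -> list[LocusReport]:
    """Merge validation stats (R², allele direction) and order the table.

    ``validation`` maps member.key -> {"r2": float, "allele_increasing": str}.
    Loci are ordered by chromosome then leftmost peak; members direct-first.
    Raises if a member lacks validation stats.
    """
    out: list[LocusReport] = []
    for rep in reports:
        members = []
        for m in rep.sorted_members():
            if m.key not in validation:
                raise ValueError(f"no validation stats for member {m.key} of {rep.name}")
            v = validation[m.key]
            members.append(
                replace(m, r2=v["r2"], allele_increasing=v["allele_increasing"])
            )
        out.append(LocusReport(name=rep.name, chromosome=rep.chromosome, members=members))
    out.sort(key=lambda r: (_chrom_key(r.chromosome), min(m.peak_Mb for m in r.members)))
    return out
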