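"""End-to-end orchestration: adjust, scan, select, co-locate, validate.

The full design is 8 role-trait combinations (BXD offspring:
solicitation/sucking/activity; B6 offspring: the same three; mother:
suckling/activity) observed on postpartum days 6, 10 and 14 — 24 genome
scans, 9 direct and 15 indirect.  Genome-wide permutation p-values of the
24 scans enter one Benjamini–Hochberg family; each selected locus then
receives protected Benjamini–Yekutieli tests for further indirect effects
at its peak marker, and co-located effects are fused into SocInt loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DAYS, ROLES, TRAITS_BY_ROLE, FamilyTable, GeneticMap, GenotypeMatrix
from .covariate_adjust import AdjustedTrait, LineTraitVector, adjust_trait
from .interval_mapping import (
    LOD_DIVISOR_GN,
    ScanResult,
    genotype_prob_matrix,
    lod_drop_interval,
    permutation_null,
    scan,
)
from .discovery import (
    LocusMember,
    LocusReport,
    assemble_locus_table,
    bh_select,
    co_locate,
    member_from_scan,
    protected_members,
)
from .validation import (
    CorrelationRecord,
    HeritabilityRecord,
    heritability_anova,
    peak_r2,
    trait_correlation,
)

__all__ = ["ScanSpec", "PipelineConfig", "PipelineResult", "enumerate_scans", "run_pipeline"]


@dataclass(frozen=True)
class ScanSpec:
    role: str
    trait: str
    day: int

    @property
    def effect_class(self) -> str:
        return "direct" if self.role == "BXD_offspring" else "indirect"

    @property
    def key(self) -> tuple:
        return (self.role, self.trait, self.day, self.effect_class)


def enumerate_scans(days: tuple[int, ...] = DAYS) -> list[ScanSpec]:
    """The full scan design: every valid role-trait at every day (24 scans)."""
    return [
        ScanSpec(role=role, trait=trait, day=day)
        for day in days
        for role in ROLES
        for trait in TRAITS_BY_ROLE[role]
    ]


@dataclass
class PipelineConfig:
    """Tunables of the four-stage analysis.

    Defaults follow the reference analysis: covariate elimination at
    alpha = 0.05, 5000 phenotype permutations per scan, genome-wide
    alpha = 0.05, BH FDR q = 0.05 over the 24 scans, protected BY FDR
    q = 0.10, 1.5-LOD support intervals, GeneNetwork LOD divisor 4.61.
    """

    covariate_alpha: float = 0.05
    n_perm: int = 5000
    alpha: float = 0.05
    bh_q: float = 0.05
    by_q: float = 0.10
    ci_drop: float = 1.5
    step_cm: float = 0.0
    lod_divisor: float = LOD_DIVISOR_GN
    p_estimator: str = "add_one"
    days: tuple[int, ...] = DAYS
    #: scan keys retained as locus members despite missing the BH cut —
    #: explicit, audited overrides only (never silent).
    retain_overrides: tuple[tuple, ...] = ()
    seed: int = 0


@dataclass
class PipelineResult:
    scans: dict
    vectors: dict
    adjusted: dict
    pvalues: dict
    bh_selected: list
    loci: list
    indirect_only: list
    locus_table: list
    correlations: list
    heritability: list
    audit: dict

    def locus_frame(self) -> pd.DataFrame:
        from .io_formats import LOCUS_COLUMNS, _report_rows

        return pd.DataFrame(_report_rows(self.locus_table), columns=list(LOCUS_COLUMNS))


def _nearest_marker(gmap: GeneticMap, chromosome: str, mb: float) -> str:
    sub = gmap.chrom_slice(chromosome)
    j = (sub["Mb"] - mb).abs().idxmin()
    return str(sub.loc[j, "marker"])


def run_pipeline(
    gmap: GeneticMap,
    G: GenotypeMatrix,
    tbl: FamilyTable,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the four analysis stages on one family table.

    Stage 1 adjusts each of the 24 role-trait-day combinations for litter
    covariates and averages residuals per BXD line; stage 2 scans each
    line-mean vector genome-wide with permutation significance and
    1.5-LOD support intervals; stage 3 applies BH across the 24
    genome-wide p-values, runs protected BY tests at each selected locus
    and fuses co-located effects into SocInt loci; stage 4 attaches peak
    R², allele direction, trait correlations and heritability estimates.
    """
    cfg = config or PipelineConfig()
    specs = enumerate_scans(cfg.days)

    # stage 1 — covariate adjustment and line means
    adjusted: dict[tuple, AdjustedTrait] = {}
    vectors: dict[tuple, LineTraitVector] = {}
    for sp in specs:
        adj, lv = adjust_trait(tbl, sp.trait, sp.role, sp.day, alpha=cfg.covariate_alpha)
        adjusted[sp.key] = adj
        vectors[sp.key] = lv

    # stage 2 — genome scans with permutation significance
    prob = genotype_prob_matrix(gmap, G, cfg.step_cm)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(specs))
    scans: dict[tuple, ScanResult] = {}
    pvalues: dict[tuple, float] = {}
    for sp, child in zip(specs, children):
        sr = scan(vectors[sp.key], G, gmap, cfg.step_cm, cfg.lod_divisor, _prob=prob)
        null = permutation_null(
            vectors[sp.key],
            G,
            gmap,
            n_perm=cfg.n_perm,
            alpha=cfg.alpha,
            seed=np.random.default_rng(child),
            _prob=prob,
        )
        sr.threshold = null.threshold
        sr.genomewide_p = null.genomewide_p(sr.max_lrs, cfg.p_estimator)
        sr.ci_Mb = lod_drop_interval(sr, cfg.ci_drop)
        scans[sp.key] = sr
        pvalues[sp.key] = sr.genomewide_p

    # stage 3 — BH over the 24 scans, protected tests, co-location
    keys = [sp.key for sp in specs]
    selected_idx = bh_select([pvalues[k] for k in keys], q=cfg.bh_q)
    bh_keys = [keys[i] for i in selected_idx]
    override_keys = [k for k in cfg.retain_overrides if k in scans and k not in bh_keys]

    members: list[LocusMember] = [member_from_scan(scans[k], cfg.ci_drop) for k in bh_keys]
    for k in override_keys:
        m = member_from_scan(scans[k], cfg.ci_drop)
        members.append(m)

    prelim_loci, _ = co_locate(members)
    protected_audit = []
    for rep in prelim_loci:
        direct = [m for m in rep.members if m.effect_class == "direct"]
        anchor = direct[0]
        peak_marker = _nearest_marker(gmap, rep.chromosome, anchor.peak_Mb)
        peak_calls = G.marker_calls(peak_marker)
        taken = {m.key for m in members}
        candidates = {
            k: (vectors[k], scans[k])
            for k in keys
            if k[3] == "indirect" and k[2] == anchor.day and k not in taken
        }
        if not candidates:
            continue
        anchor_scan = scans[anchor.key]
        new_members, audit = protected_members(
            [anchor_scan], candidates, peak_calls, q=cfg.by_q, drop=cfg.ci_drop
        )
        audit["locus"] = rep.name
        audit["peak_marker"] = peak_marker
        protected_audit.append(audit)
        members.extend(new_members)

    loci, indirect_only = co_locate(members)

    # stage 4 — validation statistics
    validation: dict[tuple, dict] = {}
    for rep in loci:
        for m in rep.members:
            marker = _nearest_marker(gmap, m.chromosome, m.peak_Mb)
            r2, allele = peak_r2(vectors[m.key], G.marker_calls(marker))
            validation[m.key] = {"r2": r2, "allele_increasing": allele}
    locus_table = assemble_locus_table(loci, validation)

    correlations: list[CorrelationRecord] = []
    for rep in locus_table:
        direct = [m for m in rep.members if m.effect_class == "direct"]
        indirect = [m for m in rep.members if m.effect_class == "indirect"]
        for d in direct:
            for i in indirect:
                if d.day == i.day:
                    correlations.append(trait_correlation(vectors[d.key], vectors[i.key]))

    heritability: list[HeritabilityRecord] = []
    for sp in specs:
        adj = adjusted[sp.key]
        lines = tbl.data["line_id"]
        counts = lines.loc[adj.residuals.index].value_counts()
        if (counts >= 2).sum() >= 2:
            heritability.append(
                heritability_anova(adj.residuals, lines, sp.trait, sp.role, sp.day)
            )

    audit = {
        "n_scans": len(specs),
        "bh_selected": [list(k) for k in bh_keys],
        "bh_q": cfg.bh_q,
        "overrides_applied": [list(k) for k in override_keys],
        "protected": protected_audit,
        "genomewide_p": {"|".join(map(str, k)): p for k, p in pvalues.items()},
    }
    return PipelineResult(
        scans=scans,
        vectors=vectors,
        adjusted=adjusted,
        pvalues=pvalues,
        bh_selected=bh_keys,
        loci=loci,
        indirect_only=indirect_only,
        locus_table=locus_table,
        correlations=correlations,
        heritability=heritability,
        audit=audit,
    )
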