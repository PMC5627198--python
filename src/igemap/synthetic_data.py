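"""Simulate an RI panel and cross-fostered families with planted QTL.

The generator emulates the split-litter cross-fostering design: B6 foster
mothers each rear half a litter of B6 pups and half a litter from one BXD
recombinant inbred line.  Direct QTL act on the BXD pups' own traits;
indirect QTL act on the B6 pups' and the mother's traits through the BXD
half-litter genotype.  Every planted effect is recorded in a "truth" file
so downstream recovery can be tested without any external data.

Genomes are simulated as a two-state Markov chain over markers, with the
single-meiosis Haldane recombination fraction expanded for a sib-mated RI
panel (R = 4r / (1 + 6r)).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    COVARIATES,
    DAYS,
    ROLES,
    TRAITS_BY_ROLE,
    FamilyTable,
    GeneticMap,
    GenotypeMatrix,
    write_geno,
    write_pheno,
)

__all__ = [
    "haldane",
    "expand_rf",
    "default_map",
    "simulate_ri_genotypes",
    "QtlEffect",
    "SimScenario",
    "simulate_families",
    "generate_fixture",
]


def haldane(d_cm: float) -> float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def expand_rf(r):
    """Expand a per-meiosis recombination fraction to the RI-panel scale.

    For a sib-mated RI panel the apparent recombination fraction between
    fixed lines is R = 4r / (1 + 6r) (Haldane–Waddington map expansion).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    out = 4.0 * r / (1.0 + 6.0 * r)
    return float(out) if out.ndim == 0 else out


def default_map(
    n_autosomes: int = 19,
    include_x: bool = True,
    markers_per_chrom: int = 16,
    spacing_cm: float = 5.0,
    mb_per_cm: float = 2.0,
) -> GeneticMap:
    """Deterministic evenly spaced marker grid standing in for a real panel map.

    Defaults give 20 chromosomes x 16 markers at 5 cM spacing — a scaled
    grid dense enough that interval-mapping peaks land on or next to the
    causal marker.
    """
    rows = []
    chroms = [str(i) for i in range(1, n_autosomes + 1)]
    if include_x:
        chroms.append("X")
    for chrom in chroms:
        for i in range(markers_per_chrom):
            cm = i * spacing_cm
            rows.append(
                {
                    "marker": f"M{chrom}_{i + 1:02d}",
                    "chromosome": chrom,
                    "cM": cm,
                    "Mb": 3.0 + cm * mb_per_cm,
                }
            )
    return GeneticMap(pd.DataFrame(rows))


def simulate_ri_genotypes(
    gmap: GeneticMap, n_lines: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Draw fully inbred RI genomes as a Markov chain along each chromosome.

    The first marker on a chromosome is B or D with probability 1/2; each
    step to the next marker flips the allele with probability
    ``expand_rf(haldane(delta_cM))``.  No heterozygous or missing calls are
    produced.
    """
    if gmap.n_markers == 0:
        raise ValueError("map is empty")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    calls = np.empty((n_lines, gmap.n_markers), dtype=float)
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_slice(chrom)
        idx = sub.index.to_numpy()
        cm = sub["cM"].to_numpy()
        flip_p = expand_rf(haldane(np.diff(cm)))
        state = rng.integers(0, 2, size=n_lines).astype(float)
        calls[:, idx[0]] = state
        for k, p in enumerate(np.atleast_1d(flip_p)):
            flips = rng.random(n_lines) < p
            state = np.where(flips, 1.0 - state, state)
            calls[:, idx[k + 1]] = state
    line_ids = [f"BXD{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(line_ids=line_ids, calls=calls, gmap=gmap)


# ---------------------------------------------------------------------------
# family phenotype simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QtlEffect:
    """A planted additive QTL effect on one role-trait.

    ``effect_class`` is implied by the role: BXD offspring traits respond to
    their own genotype (direct); B6 offspring and mother traits respond to
    the BXD half-litter genotype (indirect).  ``days`` restricts the effect
    to particular observation days (None = all days).
    """

    marker: str
    trait: str
    role: str
    size: float
    days: tuple[int, ...] | None = None

    @property
    def effect_class(self) -> str:
        return "direct" if self.role == "BXD_offspring" else "indirect"

    def validate(self, gmap: GeneticMap) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.trait not in TRAITS_BY_ROLE[self.role]:
            raise ValueError(f"trait {self.trait!r} invalid for role {self.role!r}")
        try:
            gmap.marker_index(self.marker)
        except KeyError:
            raise ValueError(f"QTL marker {self.marker!r} absent from map") from None
        if self.days is not None and not set(self.days) <= set(DAYS):
            raise ValueError(f"days {self.days} outside {DAYS}")


#: Baseline trait levels (scan-sampling scores averaged over the half
#: litter), roughly matching the scale of 15-minute focal observations.
DEFAULT_INTERCEPTS = {
    ("BXD_offspring", "solicitation"): 5.0,
    ("BXD_offspring", "sucking"): 10.0,
    ("BXD_offspring", "activity"): 4.0,
    ("B6_offspring", "solicitation"): 5.0,
    ("B6_offspring", "sucking"): 10.0,
    ("B6_offspring", "activity"): 4.0,
    ("mother", "suckling"): 20.0,
    ("mother", "activity"): 8.0,
}

#: Modest covariate slopes so that backward elimination has real signal to
#: keep; batch effects are per-level shifts.
DEFAULT_COVARIATE_EFFECTS = {
    "maternal_bodyweight": 0.10,
    "avg_B6_pup_weight": 0.30,
    "B6_litter_size": 0.20,
    "avg_BXD_pup_weight": 0.30,
    "BXD_litter_size": 0.20,
}


@dataclass
class SimScenario:
    """Study conditions for one simulated cross-fostering experiment.

    Defaults follow the design the pipeline targets: 32 BXD lines with up
    to 3 replicate families each, 8 role-trait combinations observed on
    postpartum days 6, 10 and 14 (24 genome scans), litter covariates with
    modest effects, and batch as a categorical nuisance factor.
    """

    n_lines: int = 32
    replicates_per_line: int = 3
    days: tuple[int, ...] = DAYS
    role_traits: tuple[tuple[str, str], ...] = tuple(
        (role, trait) for role in ROLES for trait in TRAITS_BY_ROLE[role]
    )
    qtl_effects: tuple[QtlEffect, ...] = ()
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    batch_levels: int = 4
    batch_effects: tuple[float, ...] | None = (0.0, 0.3, -0.2, 0.1)
    covariate_means: dict = field(
        default_factory=lambda: {
            "maternal_bodyweight": 25.0,
            "avg_B6_pup_weight": 6.0,
            "avg_BXD_pup_weight": 5.5,
        }
    )
    covariate_sds: dict = field(
        default_factory=lambda: {
            "maternal_bodyweight": 2.5,
            "avg_B6_pup_weight": 0.7,
            "avg_BXD_pup_weight": 0.7,
        }
    )
    litter_size_range: tuple[int, int] = (3, 5)
    noise_sd_within_family: float = 1.0
    line_env_sd: float = 0.5
    dropout_prob: float = 0.0
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    seed: int = 0

    def validate(self, gmap: GeneticMap) -> None:
        if self.n_lines < 1 or self.replicates_per_line < 1:
            raise ValueError("n_lines and replicates_per_line must be >= 1")
        for sd in (self.noise_sd_within_family, self.line_env_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.batch_effects is not None and len(self.batch_effects) != self.batch_levels:
            raise ValueError("batch_effects length must equal batch_levels")
        for eff in self.qtl_effects:
            eff.validate(gmap)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qtl_effects"] = [dataclasses.asdict(e) for e in self.qtl_effects]
        return d


def _draw_covariates(scen: SimScenario, n_families: int, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = scen.litter_size_range
    cov = pd.DataFrame(
        {
            "maternal_bodyweight": rng.normal(
                scen.covariate_means["maternal_bodyweight"],
                scen.covariate_sds["maternal_bodyweight"],
                n_families,
            ),
            "avg_B6_pup_weight": rng.normal(
                scen.covariate_means["avg_B6_pup_weight"],
                scen.covariate_sds["avg_B6_pup_weight"],
                n_families,
            ),
            "B6_litter_size": rng.integers(lo, hi + 1, n_families).astype(float),
            "avg_BXD_pup_weight": rng.normal(
                scen.covariate_means["avg_BXD_pup_weight"],
                scen.covariate_sds["avg_BXD_pup_weight"],
                n_families,
            ),
            "BXD_litter_size": rng.integers(lo, hi + 1, n_families).astype(float),
            "batch": [
                f"batch{rng.integers(0, scen.batch_levels) + 1}" for _ in range(n_families)
            ],
        }
    )
    return cov


def simulate_families(
    G: GenotypeMatrix, gmap: GeneticMap, scen: SimScenario
) -> tuple[FamilyTable, pd.DataFrame]:
    """Simulate the family phenotype table under a scenario.

    Returns the :class:`FamilyTable` and a truth frame recording the
    planted QTL (marker, role, trait, effect class, size, days).

    Trait value per row = intercept + planted QTL effects (keyed on the BXD
    half-litter genotype) + covariate effects + a line-level environmental
    deviate shared by replicate families of the same line + within-family
    noise.
    """
    scen.validate(gmap)
    if G.n_lines < scen.n_lines:
        raise ValueError(
            f"genotype matrix has {G.n_lines} lines but scenario needs {scen.n_lines}"
        )
    rng = np.random.default_rng(scen.seed)
    lines = G.line_ids[: scen.n_lines]

    # replicate families per line, with optional dropout beyond the first
    fam_rows: list[tuple[str, str]] = []  # (family_id, line_id)
    for line in lines:
        for rep in range(scen.replicates_per_line):
            if rep > 0 and rng.random() < scen.dropout_prob:
                continue
            fam_rows.append((f"{line}_F{rep + 1}", line))
    fam = pd.DataFrame(fam_rows, columns=["family_id", "line_id"])
    cov = _draw_covariates(scen, len(fam), rng)
    fam = pd.concat([fam, cov], axis=1)

    # planted QTL genotype codes per line
    codes: dict[str, pd.Series] = {}
    for eff in scen.qtl_effects:
        if eff.marker not in codes:
            codes[eff.marker] = G.marker_calls(eff.marker)

    batch_shift = {
        f"batch{i + 1}": (scen.batch_effects[i] if scen.batch_effects else 0.0)
        for i in range(scen.batch_levels)
    }
    cont_covs = [c for c in COVARIATES if c != "batch"]

    # line-level environmental deviates, one per (line, role, trait, day)
    env: dict[tuple, float] = {}
    for line in lines:
        for role, trait in scen.role_traits:
            for day in scen.days:
                env[(line, role, trait, day)] = (
                    rng.normal(0.0, scen.line_env_sd) if scen.line_env_sd > 0 else 0.0
                )

    records = []
    for _, f in fam.iterrows():
        line = f["line_id"]
        cov_part = sum(
            scen.covariate_effects.get(c, 0.0) * f[c] for c in cont_covs
        ) + batch_shift[f["batch"]]
        for day in scen.days:
            for role, trait in scen.role_traits:
                value = scen.intercepts[(role, trait)] + cov_part
                value += env[(line, role, trait, day)]
                for eff in scen.qtl_effects:
                    if (eff.role, eff.trait) != (role, trait):
                        continue
                    if eff.days is not None and day not in eff.days:
                        continue
                    code = codes[eff.marker].loc[line]
                    value += eff.size * (0.5 if np.isnan(code) else code)
                if scen.noise_sd_within_family > 0:
                    value += rng.normal(0.0, scen.noise_sd_within_family)
                records.append(
                    {
                        "family_id": f["family_id"],
                        "line_id": line,
                        "day": day,
                        "role": role,
                        "trait": trait,
                        "value": value,
                        **{c: f[c] for c in COVARIATES},
                    }
                )
    tbl = FamilyTable(pd.DataFrame(records))
    truth = pd.DataFrame(
        [
            {
                "marker": e.marker,
                "chromosome": gmap.table.loc[gmap.marker_index(e.marker), "chromosome"],
                "role": e.role,
                "trait": e.trait,
                "effect_class": e.effect_class,
                "size": e.size,
                "days": list(e.days) if e.days is not None else list(scen.days),
            }
            for e in scen.qtl_effects
        ],
        columns=["marker", "chromosome", "role", "trait", "effect_class", "size", "days"],
    )
    return tbl, truth


def generate_fixture(
    scen: SimScenario, out_dir: str | Path, gmap: GeneticMap | None = None
) -> dict[str, Path]:
    """Write a complete on-disk fixture: .geno, phenotype CSV, truth JSON, scenario YAML.

    Deterministic given the scenario seed: running twice produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if gmap is None:
        gmap = default_map()
    # distinct stream from the family simulation (which re-seeds on scen.seed)
    geno_rng = np.random.default_rng(np.random.SeedSequence([scen.seed, 7]))
    G = simulate_ri_genotypes(gmap, scen.n_lines, geno_rng)
    tbl, truth = simulate_families(G, gmap, scen)
    paths = {
        "geno": out / "panel.geno",
        "pheno": out / "families.csv",
        "truth": out / "truth.json",
        "scenario": out / "scenario.yaml",
    }
    write_geno(gmap, G, paths["geno"])
    write_pheno(tbl, paths["pheno"])
    paths["truth"].write_text(
        json.dumps(truth.to_dict(orient="records"), indent=2) + "\n"
    )
    paths["scenario"].write_text(yaml.safe_dump(scen.to_dict(), sort_keys=True))
    return paths
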