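"""Canned simulation studies: calibration, power and recovery experiments.

These functions run the package end-to-end under the study conditions the
pipeline targets (32 BXD lines, up to 3 replicate families per line, the
8 x 3 scan design) and measure operating characteristics: type-I rate of
the permutation scan, power and CI coverage for a planted direct QTL with
line-level R² around 0.6, recovery of a paired indirect effect by the
protected BY test, and the null behaviour of the heritability estimator.
Every study is deterministic given its seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_formats import GeneticMap
from .synthetic_data import QtlEffect, SimScenario, default_map, simulate_families, simulate_ri_genotypes
from .covariate_adjust import adjust_trait
from .interval_mapping import genotype_prob_matrix, lod_drop_interval, permutation_null, pointwise_p, scan
from .discovery import by_protected
from .validation import heritability_anova, peak_r2

__all__ = [
    "null_scan_calibration",
    "planted_qtl_recovery",
    "null_eta2_study",
]

#: Effect size giving a line-level R² near 0.6 under the default noise
#: settings: var(line means) = line_env_sd² + noise²/reps = 0.5833, and
#: R² = (a²/4) / (a²/4 + 0.5833) = 0.6 at a ≈ 1.87.
EFFECT_R2_06 = 1.87

_INDIRECT_CANDIDATES = (
    ("B6_offspring", "solicitation"),
    ("B6_offspring", "sucking"),
    ("B6_offspring", "activity"),
    ("mother", "suckling"),
    ("mother", "activity"),
)


def _seeds(seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), tag])
    return [int(s) for s in ss.generate_state(n) // 2]  # keep below 2**31


def null_scan_calibration(
    n_reps: int = 500,
    n_perm: int = 200,
    seed: int = 0,
    gmap: GeneticMap | None = None,
) -> dict:
    """Type-I rate of the genome-wide permutation test under no QTL.

    Each replicate simulates a 32-line x 3-replicate family table with no
    planted effect, adjusts one trait for covariates, averages per line,
    scans genome-wide and records whether the genome-wide p (n_perm
    permutations) falls at or below 0.05.
    """
    gmap = gmap or default_map()
    G = simulate_ri_genotypes(gmap, 32, seed=np.random.default_rng([seed, 11]))
    prob = genotype_prob_matrix(gmap, G, 0.0)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _seeds(seed, n_reps, tag=1):
            scen = SimScenario(
                days=(6,),
                role_traits=(("BXD_offspring", "sucking"),),
                seed=s,
            )
            tbl, _ = simulate_families(G, gmap, scen)
            _, lv = adjust_trait(tbl, "sucking", "BXD_offspring", 6)
            sr = scan(lv, G, gmap, _prob=prob)
            null = permutation_null(
                lv, G, gmap, n_perm=n_perm, seed=np.random.default_rng([s, 2]), _prob=prob
            )
            hits += null.genomewide_p(sr.max_lrs) <= 0.05
    return {"type1_rate": hits / n_reps, "n_reps": n_reps, "n_perm": n_perm}


def planted_qtl_recovery(
    n_reps: int = 100,
    n_perm: int = 500,
    seed: int = 0,
    effect: float = EFFECT_R2_06,
    marker: str = "M5_08",
    day: int = 6,
    gmap: GeneticMap | None = None,
) -> dict:
    """Power, CI coverage and protected-test recovery for a planted locus.

    Plants a direct QTL on BXD sucking and a paired indirect QTL (same
    marker, same size) on maternal suckling.  Per replicate: fresh
    genotypes and families, covariate adjustment, genome scan with
    permutation significance for the direct trait; when detected
    (genome-wide p <= 0.05), checks whether the 1.5-LOD interval covers
    the causal marker and runs the protected BY test (q = 0.10) over the
    five indirect role-traits at the locus peak marker.
    """
    gmap = gmap or default_map()
    true_mb = float(gmap.table.loc[gmap.marker_index(marker), "Mb"])
    qtl = (
        QtlEffect(marker, "sucking", "BXD_offspring", effect, days=(day,)),
        QtlEffect(marker, "suckling", "mother", effect, days=(day,)),
    )
    role_traits = (("BXD_offspring", "sucking"),) + _INDIRECT_CANDIDATES
    detected = covered = protected_hits = 0
    r2_direct: list[float] = []
    r2_indirect: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _seeds(seed, n_reps, tag=2):
            G = simulate_ri_genotypes(gmap, 32, seed=np.random.default_rng([s, 3]))
            prob = genotype_prob_matrix(gmap, G, 0.0)
            scen = SimScenario(days=(day,), role_traits=role_traits, qtl_effects=qtl, seed=s)
            tbl, _ = simulate_families(G, gmap, scen)
            _, lv = adjust_trait(tbl, "sucking", "BXD_offspring", day)
            sr = scan(lv, G, gmap, _prob=prob)
            null = permutation_null(
                lv, G, gmap, n_perm=n_perm, seed=np.random.default_rng([s, 4]), _prob=prob
            )
            if null.genomewide_p(sr.max_lrs) > 0.05:
                continue
            detected += 1
            lo, hi = lod_drop_interval(sr)
            if sr.peak_chromosome == "5" and lo <= true_mb <= hi:
                covered += 1
            # protected BY test at the detected peak marker
            sub = gmap.chrom_slice(sr.peak_chromosome)
            peak_marker = str(
                sub.loc[(sub["Mb"] - sr.peak_Mb).abs().idxmin(), "marker"]
            )
            calls = G.marker_calls(peak_marker)
            vectors = {}
            for role, trait in _INDIRECT_CANDIDATES:
                _, v = adjust_trait(tbl, trait, role, day)
                vectors[(role, trait)] = v
            keys = list(vectors)
            pvals = [pointwise_p(vectors[k], calls) for k in keys]
            chosen = {keys[i] for i in by_protected(pvals, q=0.10)}
            if ("mother", "suckling") in chosen:
                protected_hits += 1
            true_calls = G.marker_calls(marker)
            r2_direct.append(peak_r2(lv, true_calls)[0])
            r2_indirect.append(peak_r2(vectors[("mother", "suckling")], true_calls)[0])
    return {
        "n_reps": n_reps,
        "power": detected / n_reps,
        "ci_coverage_given_detection": covered / detected if detected else float("nan"),
        "protected_recovery_given_detection": protected_hits / detected if detected else float("nan"),
        "mean_r2_direct": float(np.mean(r2_direct)) if r2_direct else float("nan"),
        "mean_r2_indirect": float(np.mean(r2_indirect)) if r2_indirect else float("nan"),
    }


def null_eta2_study(n_reps: int = 1000, n_lines: int = 32, reps: int = 3, seed: int = 0) -> dict:
    """Mean broad-sense H² (eta²) when all lines share one distribution.

    The null expectation of eta² with k groups and N observations is
    (k-1)/(N-1) — about 31/95 for 32 lines x 3 replicates.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 5])
    h2s = np.empty(n_reps)
    lines = pd.Series(np.repeat([f"L{i}" for i in range(n_lines)], reps))
    for b in range(n_reps):
        y = pd.Series(rng.normal(size=n_lines * reps))
        h2s[b] = heritability_anova(y, lines).h2
    return {
        "mean_h2": float(h2s.mean()),
        "expected_null": (n_lines - 1) / (n_lines * reps - 1),
        "n_reps": n_reps,
    }
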