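# igemap

QTL mapping of **direct and indirect genetic effects** in cross-fostered
recombinant inbred (RI) mouse families.

In a split-litter cross-fostering design, each genetically uniform B6
(C57BL/6J) foster mother rears half a litter of B6 pups and half a litter
from one BXD recombinant inbred line. Because mothers and B6 pups carry no
genetic variation of their own, any mapping signal in *their* behaviour —
maternal suckling and activity; B6 sibling solicitation, sucking and
activity — must come from the genotype of the BXD half-litter they interact
with: an **indirect genetic effect (IGE)**. Variation in the BXD pups' own
behaviour maps to their own genotype: a direct effect. `igemap` implements
the full analysis for such an experiment and ships a simulator so every
stage can be exercised and calibrated without any animal data.

## Method

For each of the 24 genome scans (8 role-trait combinations × postpartum
days 6, 10, 14):

1. **Covariate adjustment** — a Gaussian GLM of the trait on maternal
   bodyweight, average B6 pup weight, B6 litter size, average BXD pup
   weight, BXD litter size and batch; non-significant terms (p > 0.05) are
   removed one at a time (largest p first, batch as a whole factor by
   partial F-test) and the model refit until only significant covariates
   remain. Residuals are averaged per BXD line.
2. **Interval mapping** — Haley–Knott regression of the line means on
   P(D allele) at markers and pseudomarkers, with the conditional genotype
   probabilities computed under a two-state Markov chain using
   sib-mating-expanded recombination fractions R = 4r/(1+6r),
   r = Haldane(Δ cM). The statistic is LRS = n·ln(RSS₀/RSS₁);
   LOD = LRS/4.61. Genome-wide significance comes from 5000 permutations
   of line labels; support intervals are the 1.5-LOD drop from the peak,
   reported in Mb.
3. **Discovery** — Benjamini–Hochberg FDR (q = 0.05) over the 24
   genome-wide permutation p-values; at each selected locus, protected
   Benjamini–Yekutieli tests (q = 0.10) for further indirect effects at the
   peak marker; direct and indirect effects whose support intervals
   mutually overlap on a chromosome are fused into a named locus
   (`SocInt{chromosome}`).
4. **Validation** — peak-marker R² and the allele increasing the trait
   (B6 vs D2), across-line correlations between directly and indirectly
   affected traits, and broad-sense heritability as η² from a one-way
   ANOVA with line as the factor.

## Worked example

Simulate a 32-line panel with a planted locus on chromosome 4 (direct
effect on BXD pup sucking; indirect effects on maternal suckling and B6
sibling sucking, all at marker `M4_03`, day 6) and run the full pipeline:

```python
import igemap as ig

gmap = ig.default_map()
G = ig.simulate_ri_genotypes(gmap, 32, seed=11)
scen = ig.SimScenario(
    seed=3,
    qtl_effects=(
        ig.QtlEffect("M4_03", "sucking", "BXD_offspring", 1.87, days=(6,)),
        ig.QtlEffect("M4_03", "suckling", "mother", 1.87, days=(6,)),
        ig.QtlEffect("M4_03", "sucking", "B6_offspring", 1.87, days=(6,)),
    ),
)
tbl, truth = ig.simulate_families(G, gmap, scen)
res = ig.run_pipeline(gmap, G, tbl, ig.PipelineConfig(n_perm=5000, seed=5))
print(res.locus_frame().round(3).to_string(index=False))
for c in res.correlations:
    print(f"r({c.trait_x[1]} ~ {c.trait_y[0]}:{c.trait_y[1]}, d{c.day}) = "
          f"{c.r:.2f} (p = {c.p:.2g}, n = {c.n_lines})")
```

Output:

```text
  locus             phenotype effect_class  day  peak_Mb  CI_Mb_low  CI_Mb_high  max_LRS  max_LOD  genomewide_p  p_is_protected allele_increasing    R2
SocInt4 BXD_offspring:sucking       direct    6     23.0       23.0        23.0   33.271    7.217         0.000           False                D2 0.646
SocInt4  B6_offspring:sucking     indirect    6     23.0       23.0        23.0   23.021    4.994         0.000           False                D2 0.513
SocInt4       mother:suckling     indirect    6     23.0       13.0        23.0   10.307    2.236         0.002            True                D2 0.275
r(sucking ~ B6_offspring:sucking, d6) = 0.61 (p = 0.00022, n = 32)
r(sucking ~ mother:suckling, d6) = 0.43 (p = 0.014, n = 32)
```

All three planted effects are recovered and fused into one locus,
`SocInt4`, whose members' 1.5-LOD intervals contain the causal marker
(Mb 23). The direct effect and the B6 sibling effect clear the genome-wide
BH threshold outright; the maternal effect enters through the protected BY
test at the peak marker (`p_is_protected`). The R² column is the variance
in line means explained by peak-marker genotype, and `allele_increasing`
says which founder allele (here D2) raises the trait. The trailing lines
show that directly and indirectly affected traits are positively
correlated across lines — the phenotypic signature of an indirect effect
arising from a direct one.

## File formats

* **`.geno`** — tab-separated GeneNetwork-style genotypes: `@`-prefixed
  metadata lines (`@mat B`, `@pat D`, `@unk U`), `#` comments, a header
  `Chr Locus cM Mb <line ids...>`, then one marker per row with codes
  B/D/H/U (H and U read as missing).
* **Phenotype CSV** — one row per family × day × role × trait:
  `family_id, line_id, day, role, trait, value`, the six covariates
  (`maternal_bodyweight, avg_B6_pup_weight, B6_litter_size,
  avg_BXD_pup_weight, BXD_litter_size, batch`). `line_id` is the BXD line
  fostered into the family for *every* role.
* **Locus table** — TSV + JSON with columns `locus, phenotype,
  effect_class, day, peak_Mb, CI_Mb_low, CI_Mb_high, max_LRS, max_LOD,
  genomewide_p, p_is_protected, allele_increasing, R2`; direct rows first
  within each locus.

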