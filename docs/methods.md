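# Methods

## The experimental design being modelled

The unit of analysis is a cross-fostered family: one B6 (C57BL/6J) mother
rearing half a litter of B6 pups and half a litter from one of 32 BXD
recombinant inbred lines, observed on postpartum days 6, 10 and 14. Eight
role-trait combinations are recorded per family and day — BXD offspring
solicitation/sucking/activity, B6 offspring the same three, mother
suckling/activity — giving 24 genome scans (9 direct, 15 indirect). BXD
traits map to the BXD line's own genotype (direct effects); B6 sibling and
maternal traits map to the genotype of the BXD half-litter fostered into
the family (indirect genetic effects), which is valid because mothers and
B6 pups are genetically uniform.

## Stage 1 — covariate adjustment

Each (trait, role, day) combination gets its own ordinary least-squares
GLM on six litter covariates (maternal bodyweight, average B6 pup weight,
B6 litter size, average BXD pup weight, BXD litter size, batch). Backward
elimination removes, one per iteration, the single term with the largest
p > 0.05, refitting after each removal until only significant terms
remain. Continuous terms are tested by their coefficient t-test; batch
enters and leaves as a whole categorical factor via a partial F-test,
because testing individual dummy columns would depend on an arbitrary
reference level. Ties in p are broken by removing the term appearing later
in the declared covariate order, making the procedure deterministic.
Residuals (observed − fitted; mean-centred trait when nothing is retained)
are averaged per BXD line to give the line-mean vectors used for mapping.
Rows with missing covariate values are excluded from scoring and reported.

A simulation note: under a global null the per-term retention frequency of
this stepwise rule is slightly above the nominal 5% (≈ 6% at n = 96),
a known selection effect of refitting after removal; the test suite checks
this calibration against an independent from-scratch implementation.

## Stage 2 — interval mapping on the RI panel

Genotype probabilities. RI genomes are treated as a two-state Markov chain
along each chromosome. The per-meiosis recombination fraction between
positions Δ cM apart is Haldane's r = (1 − e^(−2Δ/100))/2, expanded for a
sib-mated RI panel to R = 4r/(1+6r). Between typed markers, P(D allele)
conditions on the nearest informative flank on each side (or on a single
flank at chromosome ends); at a typed marker it is the call itself. Lines
untyped on a whole chromosome are dropped position-wise (complete-case per
position, with n in the LRS formula the per-position count).

Scan statistic. At each grid position (markers, plus optional
pseudomarkers every `step_cm`), the line means are regressed on P(D)
(Haley–Knott). LRS = n·ln(RSS₀/RSS₁) with RSS₀ from the intercept-only
model; LOD = LRS/4.61 (the GeneNetwork convention; the exact 2·ln 10 is
selectable). With inbred line means and little missing data this matches
the full likelihood-ratio scan to high accuracy; the divergence risk is
confined to positions with heavy missingness. A perfect fit (RSS₁ → 0) is
capped at LRS = n·ln(10¹²) with a warning; a zero-variance phenotype
yields an all-zero profile with a warning. Peak ties break toward the
smallest Mb. All reported positions are physical (Mb), interpolated
linearly from the marker (cM, Mb) pairs, since support intervals are
conventionally quoted in Mb while mapping runs on the genetic grid.

Significance. Genome-wide p-values come from permuting the line labels of
the phenotype vector (genotypes fixed), recording the genome-wide maximum
LRS per permutation (default 5000), and applying the add-one estimator
p = (1 + #{max ≥ observed})/(n_perm + 1), which cannot return zero; the
raw fraction is selectable. The genome-wide threshold is the empirical
95th percentile of the null maxima. Support intervals are the 1.5-LOD
drop: walking outward from the peak, the interval ends at the last grid
points whose LOD is still within 1.5 of the maximum, clamped at
chromosome ends.

## Stage 3 — discovery across 24 scans

The 24 genome-wide permutation p-values form one Benjamini–Hochberg
step-up family at q = 0.05. At each selected locus (anchored by its direct
member), the indirect traits of the same day not already selected receive
a protected test: the point-wise F-test of their line means at the locus
peak marker, controlled by the Benjamini–Yekutieli step-up at q = 0.10
(harmonic correction c(m) = Σ 1/i, valid under arbitrary dependence).
A protected member's peak is the maximum of its own profile inside the
anchor's support interval, and its own 1.5-LOD walk defines its interval.

Co-location groups effects on one chromosome whose closed support
intervals mutually overlap (a set of intervals pairwise overlaps iff
max(lows) ≤ min(highs)); chains that would break mutual overlap are split
greedily in peak-Mb order. Groups containing a direct member become loci
named `SocInt{chromosome}` (letter suffixes if a chromosome hosts several);
purely indirect groups are reported separately and are not loci. A scan
that narrowly misses the BH cut can be retained only through an explicit,
audited override in the configuration — never silently.

## Stage 4 — validation

Per member: R² of the line means on the nearest typed marker to the peak,
with the allele increasing the trait (D2 for a positive D-coded slope, B6
for negative). Per locus: product-moment correlations between the direct
and each indirect member's line means at matching days. Per scan:
broad-sense heritability as η² = SS_between/SS_total from a one-way ANOVA
of replicate-level adjusted residuals with line as the factor — replicate
level because an ANOVA on line means (one value per line) is degenerate.
Under the null, E[η²] = (k−1)/(N−1) ≈ 31/95 for 32 lines × 3 replicates,
which the test suite verifies by simulation.

## The simulator

`synthetic_data` emulates the design above. RI genomes are first-order
Markov chains over expanded recombination fractions (the standard HMM
treatment of RI panels); crossover interference beyond Haldane is ignored
and heterozygous calls are never generated (fully inbred lines), though
readers accept `H` as missing. The default marker grid is a scaled panel —
20 chromosomes (19 autosomes + X) × 16 markers at 5 cM spacing, Mb = 2·cM
+ 3 — dense enough that scan peaks land on or beside the causal marker
while keeping the repeated simulation studies fast; marker count affects
only scan resolution, not the operating characteristics being measured.

Phenotypes are continuous trait scores (the field maps litter-average scan
counts, not event streams): value = role-trait baseline + planted direct
effects (own genotype, BXD rows) + planted indirect effects (BXD
half-litter genotype, B6/mother rows) + covariate effects + a line-level
environmental deviate shared by replicate families of a line (per trait
and day) + within-family noise. Defaults: 32 lines × 3 replicate
families; covariates drawn with realistic means/SDs (maternal bodyweight
25 ± 2.5 g, pup weights ≈ 6 ± 0.7 g, litter sizes 3–5, batch with 4
levels); modest nonzero covariate slopes so backward elimination has real
signal to keep; within-family noise SD 1.0 and line-environment SD 0.5 in
trait units. Since replicate-family counts achieved per line vary in real
breeding, the simulator exposes a dropout probability (default 0) applied
to replicates beyond the first. Effect sizes for the recovery studies use
a = 1.87, which yields a line-level R² near 0.6 under the default noise —
the middle of the variance-explained range such experiments report.

What the simulator does *not* model: pre-natal maternal (genetic or
environmental) effects among B6 mothers, cross-fostering logistics,
behavioural event streams, and genotyping error. Passing tests therefore
demonstrate correctness and calibration of the statistical machinery under
an additive-Gaussian rendering of the design, not robustness to those
real-data complications.

## Numerical and design choices

* Permutation estimator: add-one by default (never zero); raw selectable.
* LOD divisor: 4.61 by default, 2·ln 10 by flag.
* Complete-case handling per scan position; lines need ≥ 8 shared between
  phenotype and genotypes for a scan.
* The point-wise protected test returns NaN (flagged) at a monomorphic
  marker; such candidates are excluded from the BY family.
* Study sizes in `igemap.studies` (500 null replicates × 200 permutations
  for calibration; 100 replicates × 500 permutations for recovery; 1000
  replicates for the η² null) were chosen to put Monte-Carlo error well
  inside the bands being checked while keeping each study under a minute.
* All randomness flows through numpy `SeedSequence` children of a single
  seed; identical seeds give byte-identical fixture files.

## Known limitations

Single-QTL scans only (no composite interval mapping, multi-QTL or
epistasis); Gaussian least-squares GLMs only (no mixed models — line
enters as a fixed averaging unit, not a random effect); heritability is
the broad-sense η², an upwardly biased estimator in small samples (its
null mean is (k−1)/(N−1), not 0); co-location by CI overlap cannot
distinguish one pleiotropic locus from tightly linked distinct loci.
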