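# Methods

This note documents the models, simulation conditions, numerical choices
and known limitations of `imprintqtl`.

## Design and data model

The package targets an F0→F3 cross of two fully inbred lines carrying
alleles *A* and *B*. Two reciprocal F0 pairs (A♂×B♀ and B♂×A♀) each
produce one male and one female F1; two reciprocal F1 couples produce the
F2; F3 families come from random non-sibling F2 pairings. Default sizes
are 94 F2 and 345 F3, of which 331 are flagged analyzable — the missing 14
emulate genotyping drop-out and are chosen at random under the simulation
seed. The published design does not state how many F1 couples produced
the F2; two reciprocal couples is the minimal structure consistent with a
reciprocal design and is configurable (`CrossConfig`).

Genotypes are *ordered* pairs (paternal allele, maternal allele): the four
classes *AA, AB, BA, BB* are the substrate of every parent-of-origin
contrast. The matrilineal `grandmaternal_line` label records the direction
of cross an animal descends from and enters the analysis as the
direction-of-cross covariate.

## Transmission model

Gametes are simulated with the Haldane map function, r = (1 − e^(−2d/100))/2
for adjacent markers d cM apart, with independent intervals (no crossover
interference). No published map function exists for this design; Haldane
is the simplest standard choice and its closed form doubles as the
independent oracle in the tests. The default marker map places 164 markers
over the 19 autosomes at 5 cM spacing with a nominal physical position of
2 Mb/cM — it emulates the density of an informative-marker panel in a
two-line cross without copying any real marker list. X and Y are excluded:
the imprinting model on X is confounded with dosage and inactivation
effects and is out of scope.

## Phenotype generator

Each trait is generated as

    y = grand_mean + sex_effect·[male] + cross_direction_effect·[line-B matriline]
        + Σ_q (a_q·x_a + d_q·x_d + i_q·x_i) + u_family + m·(dam's B count) + ε

with u_family ~ N(0, family_sd²) shared by full sibs, ε ~ N(0,
residual_sd²), and index scores taken from the ordered genotype at the
marker nearest the nominal QTL position. The maternal genetic effect is
parameterized as additive in the dam's B-allele count at a locus — the
simplest form that reproduces the reciprocal-heterozygote signature of
imprinting and therefore exercises the discrimination test. Defaults used
throughout the tests put effects in residual-SD units (residual_sd = 1,
family_sd = 0.5); imprinted effects of i ≈ 0.4 correspond to roughly 4–6%
of phenotypic variance, the magnitude reported for single imprinted loci
in this design. The generator does not model litter size, parity, shared
cage environment, genotyping error, or linkage disequilibrium structure
inherited from the founder haplotype mosaic — passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those real-data features.

## Phasing

Ordering is recovered from unordered calls by deterministic transmission
rules: homozygotes are trivially ordered; a heterozygote with a homozygous
parent is forced; when both parents are heterozygous the order is assigned
from the nearest already-phased flanking markers in the individual's
paternal and maternal haplotypes. A candidate order is accepted only when
its Haldane log-likelihood exceeds the alternative's by at least
log(min_odds) (default min_odds = 1e5); everything else stays missing and
is dropped per marker by the scan. The margin is what makes resolved
entries reliable: with 5 cM flanks on both sides the accepted assignments
have posterior error around 1e-5, so on a default-size cross (~60k
resolved entries) discordance with simulated truth is expected to be zero
or near zero. A genuine double crossover flanking the focal marker on
both gametes is indistinguishable from the no-crossover alternative by any
local rule (a global minimum-recombinant configuration would make the same
call), which is why completeness is not claimed and resolution plateaus
near 80% on default-size data. Unresolved entries concentrate in
heterozygotes — exactly the genotypes that carry imprinting information —
so scans of phased data lose roughly a third of the imprinting contrast
relative to scans of fully ordered data.

## Mixed model and LOD statistics

Each marker is fitted with y = r + a·x_a + d·x_d + i·x_i + u_family + ε.
With a single random intercept the fit reduces, via the Woodbury identity,
to a one-dimensional profile likelihood in the variance ratio
λ = σ²_f/σ²_e; the optimiser runs on log λ (bounded search, absolute
tolerance 1e-8) and the λ = 0 boundary is always checked explicitly. The
fitter is cross-checked against statsmodels `MixedLM` in the test suite to
~1e-5 in likelihood and estimates.

LOD contrasts use **maximum-likelihood** fits: REML likelihoods are not
comparable between models with different fixed effects, so the module fits
ML for the four likelihood-ratio statistics (mLOD drops all three index
columns; aLOD/dLOD/iLOD drop one each) and a separate REML fit of the full
model for the reported variance components and standard errors. Both
conventions are recorded in the scan metadata. Negative LODs from
optimiser noise are clamped to zero (tolerance 1e-8). With fewer than two
families λ is not identifiable and is constrained to zero, which makes
every LOD identical to its ordinary-least-squares counterpart — a property
the acceptance suite verifies against a brute-force OLS oracle.

Covariates (sex, direction of cross) are removed *before* the scan by
ordinary least squares, and residuals are re-centred at the grand mean so
effect estimates keep trait units. Whether the original analysis
re-estimated these covariates inside the mixed model is unstated; fixed
pre-adjustment matches the stated procedure of adjusting phenotypes before
QTL analysis. Phenotypic variance for R² is taken from the adjusted trait
over analyzable animals, consistent with adjustment being motivated as
removing variance not attributable to QTL.

F2 and F3 animals are scanned jointly by default, with the family label of
an F2 being its F1 couple and of an F3 its F2 couple; a `generations`
switch restricts to F3. Markers with fewer than `min_per_class = 5`
animals in any ordered class are skipped and logged.

## Permutation thresholds and calling

The permutation null shuffles the (phenotype, family) rows as a unit
against the genotype rows: family variance structure survives, the
genotype–phenotype link does not. Thresholds are the ⌈(1−α)·n_perm⌉-th
order statistic of the per-trait genome-wide maximum, kept separately per
statistic (mLOD, aLOD, dLOD, iLOD) because the calling rule references
both the joint and the single-effect tests. The acceptance suite verifies
5% type-I calibration at reduced scale (200 permutations, 200 fresh null
scans, 20-marker map) — reduced from the production default of 1000
permutations so the suite completes quickly at an unchanged nominal level.

A locus is called when any statistic reaches its genome-wide threshold;
significant markers on a chromosome are chain-merged within a 20 cM window
(configurable; the published analysis reports one peak per region), the
peak is the marker with the largest significant statistic (ties break to
the smaller cM), and other traits are attached when any of their LODs
reaches the pointwise 1.3 bar at the peak. The support interval is a
1-LOD drop by default — no interval method was published, and the LOD-drop
convention is standard, configurable via `ci_drop`. Loci are named
`Mc<chromosome>.<k>` in cM order within each chromosome.

## Imprinting patterns and maternal effects

Pattern classification runs only at loci with a significant imprinting
effect. Pure paternal expression forces i = a and d = 0 under the
genotypic-value algebra, maternal expression i = −a; the classifier
accepts a parental-expression call when |i/a| is within a factor
`ratio_tol = 2` (exact equality holds only asymptotically). A significant
i without a significant a is *bipolar*; everything else is *other*
(extended taxonomies such as polar dominance are deliberately not
distinguished). Effect-presence flags default to per-effect LOD ≥ 1.3,
the same pointwise bar the calling rule uses, since no explicit
effect-presence criterion was published.

The maternal-effect test augments the locus model with a mother-class
indicator (heterozygous vs homozygous dam, the homozygous classes pooled)
and its interaction with x_i, testing the interaction by a 1-df ML
likelihood-ratio test. Under a maternal genetic effect the apparent
imprinting contrast is carried entirely by hom-dam offspring (whose
maternal allele is fixed by the dam), so the interaction is the exact
signature that separates the two mechanisms. The verdict is
`maternal_effect` when p < α, `imprinting` otherwise, and `inconclusive`
when either mother class has fewer than `min_n = 5` informative
(heterozygous) offspring. Simulation shows ~95% `imprinting` verdicts
under pure imprinting (the nominal 1 − α) and a large majority of
`maternal_effect` verdicts under a pure maternal effect of one residual SD
per dam allele at the default design size.

## Fixtures

The published per-locus effect table (27 locus–trait rows, 9 loci) and
per-trait variance table (8 traits) ship inside the package as plain TSV
strings. Boldface significance is encoded as explicit 0/1 flags because
the per-trait permutation thresholds behind the boldface were never
published and cannot be recomputed. Trait labels are kept verbatim so
round-trips are exact; report formatting uses two decimals to match. The
variance table's per-trait locus/effect counts are not internally
consistent with the effect table (a known discrepancy of the printed
tables); only row-level quantities — flag counts and orthogonal row sums —
are treated as reproducible.

## Problem sizes used in the tests

Statistical suites run at reduced but representative scale chosen as the
package's own test conditions: parameter recovery at the full analyzable
F3 size (200 replicates, n = 331, a = 0.5, d = 0.25, i = 0.4, σ_f = 0.5,
σ_e = 1); permutation calibration on a 20-marker map (200 + 200);
discrimination at 200 replicates per scenario; phasing soundness at the
full default design (164 markers, 94 F2 + 345 F3). Fixed seeds make every
suite deterministic.

## Known limitations

* Marker-based tests only; no interval mapping between markers (with ≲5 cM
  spacing additional pseudomarkers add nothing in this pedigree) and no
  multi-QTL or epistatic models.
* The phaser is local; it does not implement a global minimum-recombinant
  haplotype configuration and leaves ~20% of entries unresolved on
  default-size data.
* Permutation thresholds are per trait and per statistic; no multiplicity
  control across traits or across the four statistics is attempted, so the
  union calling rule has a per-trait spurious-locus rate near the sum of
  the four nominal levels.
* The maternal-effect model is additive in the dam's allele count;
  dominance-shaped maternal effects would partially load on the
  interaction test but are not explicitly modelled.
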