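# Methods

## Scope and model

`pedpop` estimates three quantities for a long-lived, polygamous wildlife
population surveyed by genetic sampling: the number of *breeders* (animals
with ≥1 offspring in the study window) alive at a reference year, the
number of *adults* (breeders plus animals with independent evidence of age
≥ 4), and a *minimum population size* (animals demonstrably present in the
reference year). The central idea is that a reconstructed pedigree counts
parents even when they were never sampled themselves, so the breeding
population can be bounded from both sides:

* the **minimum** counts only animals directly identified during the
  intensive survey years plus parents whose reproduction around the
  reference year proves they were alive then;
* the **maximum** assumes the breeding population cannot exceed the total
  number of parents of the surveyed cohort, with explicit mortality
  corrections for parents not seen recently.

No confidence intervals are attached to these bounds; none are defined for
this family of estimators.

## Parentage likelihoods

For a locus with offspring genotype *g_o*, the single-parent transition
probability integrates the unknown parent over Hardy–Weinberg proportions;
the parent-pair version enumerates one transmitted allele per parent. Both
are compared with the unrelated hypothesis P_HWE(g_o), and LOD scores sum
the log-ratios over loci called in the offspring and at least one
candidate. A candidate with no called loci scores exactly 0.

Genotyping error enters as per-genotype replacement with an HWE random
genotype at rate *e*: a comparison involving *k* genotypes (2 for a dyad, 3
for a trio) uses

L = (1−e)^k · T(g_o | parents) + (1−(1−e)^k) · P_HWE(g_o).

This is the classic tractable simplification: any mistyping makes the
offspring genotype uninformative at that locus, so true parents are never
excluded outright by a single bad call. The mixture choice matters only
near exclusions; with *e* = 0 the likelihood reduces to exact Mendelian
exclusion, which the test suite verifies against brute-force enumeration.

Loci where one parent of a trio is uncalled degrade to the single-parent
kernel against the called parent; loci with both parents uncalled
contribute nothing.

## Δ calibration

Assignment confidence is calibrated on Δ = LOD(best) − LOD(second best).
Each Monte-Carlo cycle draws a true family from the observed allele
frequencies, mistypes every genotype at rate *e*, builds a candidate panel
of `n_candidates_per_offspring` HWE genotypes in which each true parent
appears with probability `prop_candidates_sampled`, and records Δ together
with whether the top candidate was the true parent. The threshold for a
confidence level c is the smallest Δ such that the fraction of correct
assignments among all cycles at or above it is ≥ c (the most permissive
such cutoff). Cycles whose best candidate is Mendelian-excluded contribute
Δ = 0; a cycle with a single non-excluded candidate contributes Δ = +∞,
which sorts above every finite value. If no cutoff reaches the requested
confidence the threshold is +∞ and a warning is emitted (no assignments
will be accepted at that level). Calibration is deterministic given the
seed. Defaults follow the study design: 10,000 cycles, 150 candidates, 40%
of candidates sampled, e = 1%, confidence 80% (relaxed) and 95% (strict).

## The cascade

Candidates are pre-filtered before any likelihood is computed: mothers must
carry the offspring's mtDNA haplotype (when both are known), fathers of
male offspring its Y haplotype; mothers must survive to the birth year,
fathers to the conception year (birth − 1); candidates with known birth
years must be at least `min_maternal_age`/`min_paternal_age` (default 4)
years older than the offspring. Unknown values pass every filter —
age-unaware data therefore admit child-as-parent reversals, which is why
age metadata matter (see *Simulator* below).

Step 1 accepts the best parent pair when Δ ≥ Δ₈₀ with zero trio
mismatches, or when Δ ≥ Δ₉₅ with ≤1 mismatch *and* the same mother and
father independently top the maternity-only and paternity-only rankings
with ≤1 pairwise mismatch each. Step 2 assigns single parents at Δ ≥ Δ₈₀
with zero mismatches; when both a mother and a father pass step 2 for the
same offspring, only the better-supported slot is kept, so a dyad route
always carries exactly one parent. Ties in LOD break lexicographically on
individual id for reproducibility.

Because a parent–offspring pair is genetically symmetric, the accepted
link set is post-processed to be acyclic: while a directed cycle exists,
the lowest-Δ link in it is dropped. A true pedigree can never be cyclic,
and the weakest link in a cycle is the least trustworthy.

Males whose mtDNA haplotype no sampled female carries are flagged as
immigrants: excluded as candidate offspring (their parents are not in the
population) but retained as candidate fathers.

## Sibship surrogate and hypothetical parents

Survey-cohort offspring with an empty mother (father) slot are clustered
by pairwise relationship likelihoods under the standard IBD mixture —
unrelated k=(1,0,0), half-sib (½,½,0), full-sib (¼,½,¼) — with the
one-IBD term supplied by the parent–offspring kernel and the two-IBD term
by genotype identity. An edge joins two offspring when the better of the
half-sib or full-sib log-LR against unrelated exceeds a threshold
(default 0) and their uniparental haplotypes are consistent; groups are
connected components. Transitive merging is deliberate: fewer hypothetical
parents mean a smaller maximum, the conservative direction. Components
bridged into haplotype conflicts (possible through members lacking the
marker) are split on the observed labels. One hypothetical parent is
created per group, inheriting the group haplotype and an age anchored at
the earliest offspring birth year minus the generation interval. A
full-sib pair with both slots empty naturally yields one hypothetical
mother *and* one hypothetical father shared by the pair.

Two safeguards keep hypothetical parents honest in the *minimum* tally
(they always count toward the maximum):

* only offspring for which **no** catalogued same-sex, haplotype-consistent
  individual is Mendelian-compatible can prove that a genuinely unsampled
  parent existed; other group members may simply have failed the Δ test
  against a known bear;
* the compatibility scan keeps fellow group members as candidates, because
  a mother can be mis-clustered as a "sib" of her own cub.

This surrogate reproduces what the downstream estimator consumes — group
counts, offspring lists and anchor birth years — without full-likelihood
sibship MCMC; run-length/precision semantics of such samplers are out of
scope.

## Liveness rules and aggregation

Each unresampled or hypothetical parent is classified, in priority order:

1. **dead-confirmed** — a known death year before the reference year;
2. **counted-minimum** — demonstrably produced a cub around the reference
   year R: mothers with a cub born in R or R+1, or born in R−1 and alive
   at age ≥1 in R (a dependent cub cannot outlive its mother before
   separation); fathers with a cub born in R+1 (mating in R);
3. **dead-monitoring** — an explicit override list (e.g. mothers of
   resident adults unobserved for many years);
4. **dead-senescence** — estimated age ≥ 30 (♀) / 28 (♂) at R, using the
   known birth year or (reference − oldest-offspring-birth) + 7.3; the
   comparison is ≥ on the real-valued age, so 30.3 is dead;
5. **dead-generation-limit** — a hypothetical parent whose chain of living
   lineal descendants reaches 4 (matrilineal) or 3 (patrilineal)
   generations, i.e. would be a living great-great-grandmother or
   great-grandfather;
6. **alive** — everyone else; existing parents weighted s^(R − last seen)
   with s = 0.94 (♀) / 0.89 (♂), hypothetical parents weighted 1.

Bounds: min = confirmed + counted-minimum; max = min + Σ weights of alive
existing parents + count of alive hypotheticals, with fractional weights
summed **before** rounding to the nearest integer (so 128 + 9.3 + 36 →
173, 66 + 5.3 + 20 → 91). Adult bounds add the non-breeders with age ≥4
evidence: a known birth year, first identification ≥4 years before R, a
parent's death year d (born ≤ d+1), or a cementum age at death.

The minimum census unions (a) bears identified in year R, including those
dying in R; (b) counted-minimum parents; (c) bears ≥1 year old first
identified in R+1, where the age evidence is a pedigree birth year, an
earlier first identification, a parent-death bound, or a monitoring/video
flag — bears that could be cubs of the year R+1 are excluded. Age-class
breakdowns use the minimum established age; density is count/area × 100,
rounded to one decimal at presentation only.

## Simulator

The generator runs an annual mortality → immigration → mating → birth
cycle over the study years (1998–2020 by default) with overlapping
generations. Defaults chosen to match the study system's texture: 21 loci
with 4–8 alleles (mean ≈ 5.8, Dirichlet frequencies), seven mtDNA and
seven Y haplotypes, litters of 1–3 cubs (p = 0.30/0.50/0.20), a 3-year
inter-birth interval with early return to estrus if the litter dies,
female first reproduction at 5, male mating success 0.2 from age 4 and
full from 9, survival 0.65 (cubs), 0.85 (ages 1–3), 0.94/0.89 (adult
♀/♂), reproductive caps at 30/28, ~0.3 immigrant males per year carrying
foreign mtDNA labels. Dependent cubs die with their mother before
separation — the biological fact the counted-minimum rule relies on.
Sampling is per-method, per-year: background hair/fecal detection 0.10 and
0.08, intensive-year (2019–2020) detection 0.55 and 0.30, dead recovery
0.60 with an exact cementum age, per-locus mistyping 1% (a redraw forced
to differ from the truth, so the realized corruption rate equals the
nominal rate) and 2% missingness. A `monitored_fraction` (default 0.6)
of individuals carries a known birth year, standing in for the long-term
monitoring and video data of the study system.

What the simulator does **not** emulate: space (home ranges, trap
geometry, edge effects), within-year timing, heteroplasmy, null alleles
or allelic dropout structure, and density dependence. Passing tests
therefore demonstrate the estimator's logic under the stated demographic
and sampling model, not robustness to spatial sampling bias — the main
caveat the maximum bound carries in the field as well.

## Problem sizes in the test suite

The statistical suites run at desk scale, chosen so the full suite
finishes in minutes: interval-coverage and minimum-census tests use 100
replicate pipelines of ~100 founders simulated from 2004, with 600
calibration cycles and 60 candidates per offspring; the precision test
uses one ~800-bear pedigree at the full 21-locus panel with e = 1% and
1,000 calibration cycles; recovery tests give the catalogue known ages
(`monitored_fraction = 1`), reflecting a system with comprehensive age
records — without age data the cascade admits parent/child reversals and
the minimum loses its undercount guarantee, which is a property of the
method, not of the implementation.

## Known limitations

* The Δ criterion is a calibrated threshold-on-correct-fraction; other
  parentage software uses proprietary variants, so thresholds are not
  numerically interchangeable.
* With 80% relaxed confidence, up to one in five accepted dyads may be
  wrong by construction; the bounds inherit that error rate.
* Hypothetical-parent counts depend on the sib-LR threshold; the default
  (log-LR > 0) is permissive, which is conservative for the maximum but
  relies on the duplicate-guard for the minimum.
* The estimator is aspatial: animals resident outside the effective
  sampling area are invisible to both bounds.
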