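# pedpop

Pedigree-reconstruction estimation of **breeding**, **adult** and **minimum
population sizes** for wildlife populations surveyed by multilocus
microsatellite genotyping — built around the kind of long-term, noninvasive
genetic monitoring used for brown bears (*Ursus arctos*), where hair, fecal
and carcass samples accumulate over decades and an intensive two-year survey
closes the books.

## What it does

Given per-sample diploid genotypes at ~21 microsatellite loci (plus a sex
marker, an mtDNA haplotype and, for males, a Y haplotype), the pipeline:

1. **Identifies individuals** from samples: a 6-locus screening panel first
   (samples failing any screening locus are discarded), full-panel
   comparison for non-matches. The multilocus probability of identity
   PI = ∏ₗ (Σᵢ pᵢ⁴ + Σᵢ<ⱼ (2pᵢpⱼ)²) quantifies collision risk.
2. **Assigns parentage** by a likelihood cascade. For a candidate parent
   (or pair) the LOD score is Σₗ ln[ T(g_o | g_parents, e) / P_HWE(g_o) ],
   with Mendelian transition probabilities T and a per-genotype mistyping
   rate *e*. Confidence is calibrated on Δ = LOD(best) − LOD(second best)
   by Monte-Carlo simulation from the observed allele frequencies
   (defaults: 10,000 cycles, 150 candidates per offspring, 40% of parents
   sampled, *e* = 1%). A parent pair is accepted at 80% confidence with
   zero trio mismatches, or at 95% with at most one mismatch when the
   maternity-only and paternity-only analyses independently agree; single
   parents are accepted at 80% with zero mismatches. Candidate mothers are
   pre-filtered by mtDNA, candidate fathers of sons by Y haplotype, and all
   candidates by age and death-year compatibility.
3. **Reconstructs sibships** for survey-cohort offspring whose parent slots
   stay empty: pairwise full-/half-sib/unrelated likelihoods (IBD mixture
   with k = (¼,½,¼), (½,½,0), (1,0,0)), haplotype-consistent graph
   clustering, and one *hypothetical parent* per group (promiscuous mating:
   one hypothetical bear may carry many offspring).
4. **Estimates population sizes** as of a reference year:
   - `breeders_min` = confirmed breeders (identified in the survey years
     with ≥1 assigned offspring) + parents proven alive by a cub born
     around the reference year;
   - `breeders_max` adds unresampled parents discounted by survival
     s^(years unseen) (s = 0.94 ♀ / 0.89 ♂) and surviving hypothetical
     parents, after removing parents presumed dead by reproductive
     senescence (≥30 ♀ / ≥28 ♂, ages anchored at oldest offspring + 7.3-yr
     generation interval), by coexisting-generation limits (≤4 matrilineal,
     ≤3 patrilineal) or by monitoring evidence;
   - adult bounds add non-breeders with independent evidence of age ≥4;
   - the minimum census is the deduplicated union of bears identified in
     the reference year, pedigree-inferred parents, and yearlings-or-older
     first seen the following year; densities are reported per 100 km².

A fully tested individual-based **simulator** (overlapping generations,
polygamy, sex-specific survival, Mendelian loci, uniparental haplotypes,
heterogeneous multi-year sampling, genotyping error) provides ground truth
for every stage.

## Worked example

Bookkeeping with published category counts — 125 confirmed female breeders,
1 existing + 2 hypothetical minimum-counted parents, 9.3 survival-weighted
existing + 36 surviving hypothetical parents:

```python
>>> from pedpop import (ParentCategoryCounts, breeding_bounds_from_counts,
...                     survival_weight, density, DemographyConfig, Sex)
>>> breeding_bounds_from_counts(ParentCategoryCounts(125, 1, 2, 9.3, 36))
Bounds(min=128, max=173)
>>> breeding_bounds_from_counts(ParentCategoryCounts(65, 0, 1, 5.3, 20))
Bounds(min=66, max=91)
>>> survival_weight(2017, Sex.FEMALE, DemographyConfig())   # unseen 2 years
0.8836
>>> round(density(449, 1760), 1), round(density(449, 1378), 1)
(25.5, 32.6)
```

The female breeding population is therefore bounded at 128–173 (66–91 for
males): the minimum counts only bears demonstrably alive and reproducing,
the maximum assumes every parent of the surveyed cohort might survive.
A female breeder unseen for two years contributes 0.94² ≈ 0.88 of an
individual to the maximum. A census of 449 bears over 1760 km² (1378 km²
of forest) is 25.5 (32.6) bears per 100 km².

End-to-end on a synthetic population:

```bash
pedpop run-all --config demo.yaml --seed 7 --out out/
# {"breeding_F": [22, 40], "breeding_M": [14, 21], "minimum_population_total": 76}
```

which prints the estimated female/male breeding bounds and the minimum
census for the simulated population (intermediate TSV/CSV/JSON artifacts,
including a per-individual audit ledger, are written to `out/`).

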