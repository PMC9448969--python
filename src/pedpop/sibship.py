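"""Sibship reconstruction and hypothetical parents.

Offspring whose mother and/or father slot the likelihood cascade left empty
are clustered into maternal/paternal sib groups by pairwise likelihood
ratios, and each group is explained by one unsampled "hypothetical" parent
allowed to have multiple offspring (both sexes are treated as promiscuous,
so maternal groups are generally half-sib groups).

Pairwise relationship likelihoods use the standard IBD-sharing mixture: for
a relationship with coefficients k = (k0, k1, k2) the per-locus likelihood
of a genotype pair (g1, g2) is

    L = k0·P(g1)P(g2) + k1·P(g1)·T(g2|g1) + k2·P(g1)·[g2 = g1]

where T is the single-parent Mendelian transition (one allele IBD) and P is
the HWE genotype probability.  Unrelated k = (1,0,0); half-sib (0.5,0.5,0);
full-sib (0.25,0.5,0.25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
from sklearn.base import BaseEstimator

from .genotypes import AlleleFrequencyTable, Genotype
from .individuals import Individual, Sex
from .parentage import ParentageAssignment, transition_prob

KINSHIP = {
    "unrelated": (1.0, 0.0, 0.0),
    "half_sib": (0.5, 0.5, 0.0),
    "full_sib": (0.25, 0.5, 0.25),
}


@dataclass
class HypotheticalParent:
    """An unsampled parent postulated to explain a sib group."""

    id: str
    sex: Sex
    offspring_ids: Tuple[str, ...]
    haplotype: Optional[str] = None  # mt (mothers) or Y (fathers), when consistent
    min_birth_year_estimate: Optional[float] = None
    anchor_offspring_birth_year: Optional[int] = None
    liveness: str = "alive"
    #: a catalogued same-sex individual is genetically compatible with the
    #: whole group, so this "unsampled" parent may duplicate a known bear
    compatible_sampled_parent: bool = False
    #: offspring for which *no* catalogued individual could be the parent —
    #: the only members that can prove a genuinely unsampled parent existed;
    #: None means the check was not run and every offspring counts
    unexplained_offspring_ids: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not self.offspring_ids:
            raise ValueError("hypothetical parent needs at least one offspring")


def pairwise_sib_lr(
    g1: Genotype,
    g2: Genotype,
    freqs: AlleleFrequencyTable,
    e: float,
) -> Dict[str, float]:
    """Log-likelihood of a genotype pair under three relationships.

    Returns {"full_sib": ..., "half_sib": ..., "unrelated": ...} summed over
    loci called in both genotypes.  Genotyping error enters as in the
    parentage likelihoods: the IBD-informed term is downweighted by (1−e)²
    toward the unrelated (HWE) term.
    """
    out = {name: 0.0 for name in KINSHIP}
    w = (1.0 - e) ** 2
    for locus, pair1 in g1.calls.items():
        if pair1 is None or locus not in freqs.freqs:
            continue
        pair2 = g2.calls.get(locus)
        if pair2 is None:
            continue
        p1 = freqs.hwe_genotype_prob(locus, pair1)
        p2 = freqs.hwe_genotype_prob(locus, pair2)
        t = transition_prob(locus, pair2, pair1, freqs, 0.0)  # one-IBD kernel
        ident = 1.0 if pair1 == pair2 else 0.0
        for name, (k0, k1, k2) in KINSHIP.items():
            core = k0 * p2 + k1 * t + k2 * ident
            lik = p1 * (w * core + (1.0 - w) * p2)
            out[name] += math.log(lik) if lik > 0 else -math.inf
    return out


@dataclass
class SibGroup:
    slot: str  # "mother" or "father"
    offspring_ids: Tuple[str, ...]
    haplotype: Optional[str] = None
    anchor_birth_year: Optional[int] = None


def _slot_haplotype(ind: Individual, slot: str) -> Optional[str]:
    if slot == "mother":
        return ind.mt_haplotype
    return ind.y_haplotype if ind.sex is Sex.MALE else None


def build_sib_groups(
    unassigned: Sequence[Individual],
    assignments: Dict[str, ParentageAssignment],
    freqs: AlleleFrequencyTable,
    e: float,
    slot: str,
    threshold: float = 0.0,
) -> List[SibGroup]:
    """Cluster offspring missing a parent slot into sib groups.

    An edge joins two offspring when the half-sib vs unrelated log-LR exceeds
    ``threshold``, their uniparental haplotypes for the slot are consistent,
    and — when both already have the *other* parent assigned — those other
    parents differ (a shared other parent makes them full sibs, which is also
    allowed).  Groups are connected components, a deliberately transitive and
    conservative merge (fewer hypothetical parents).
    """
    if slot not in ("mother", "father"):
        raise ValueError("slot must be 'mother' or 'father'")
    g = nx.Graph()
    pool = [ind for ind in unassigned if ind.genotype is not None]
    g.add_nodes_from(ind.id for ind in pool)
    by_id = {ind.id: ind for ind in pool}
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            a, b = pool[i], pool[j]
            ha, hb = _slot_haplotype(a, slot), _slot_haplotype(b, slot)
            if ha is not None and hb is not None and ha != hb:
                continue
            lr = pairwise_sib_lr(a.genotype, b.genotype, freqs, e)
            score = lr["half_sib"] - lr["unrelated"]
            full_score = lr["full_sib"] - lr["unrelated"]
            if max(score, full_score) > threshold:
                g.add_edge(a.id, b.id)
    groups: List[SibGroup] = []
    for comp in sorted(nx.connected_components(g), key=min):
        members = sorted(comp)
        haps = {
            h
            for h in (_slot_haplotype(by_id[m], slot) for m in members)
            if h is not None
        }
        if len(haps) > 1:
            # transitive merges can bridge haplotypes through members whose
            # uniparental marker is unobserved; split on the observed labels
            # and attach unmarked members to the largest fragment
            fragments: Dict[Optional[str], List[str]] = {h: [] for h in sorted(haps)}
            unmarked: List[str] = []
            for m in members:
                h = _slot_haplotype(by_id[m], slot)
                (fragments[h] if h is not None else unmarked).append(m)
            largest = max(fragments, key=lambda h: (len(fragments[h]), h))
            fragments[largest].extend(unmarked)
            member_sets = [sorted(v) for v in fragments.values() if v]
        else:
            member_sets = [members]
        for mset in member_sets:
            mhaps = {
                h
                for h in (_slot_haplotype(by_id[m], slot) for m in mset)
                if h is not None
            }
            births = [
                by_id[m].birth_year for m in mset if by_id[m].birth_year is not None
            ]
            groups.append(
                SibGroup(
                    slot=slot,
                    offspring_ids=tuple(mset),
                    haplotype=next(iter(mhaps)) if mhaps else None,
                    anchor_birth_year=min(births) if births else None,
                )
            )
    return groups


def generate_hypothetical_parents(
    sib_groups: Sequence[SibGroup],
    generation_interval: float = 7.3,
    id_prefix: str = "HYP",
) -> List[HypotheticalParent]:
    """One hypothetical parent per sib group.

    The parent's minimum birth year is anchored at the earliest offspring
    birth year minus one generation interval; the uniparental haplotype is
    inherited from the offspring when determined.
    """
    seen: set = set()
    out: List[HypotheticalParent] = []
    counters = {"mother": 0, "father": 0}
    for grp in sib_groups:
        overlap = seen.intersection(
            (grp.slot, oid) for oid in grp.offspring_ids
        )
        if overlap:
            raise ValueError(f"offspring in multiple {grp.slot} groups: {overlap}")
        seen.update((grp.slot, oid) for oid in grp.offspring_ids)
        counters[grp.slot] += 1
        sex = Sex.FEMALE if grp.slot == "mother" else Sex.MALE
        tag = "F" if sex is Sex.FEMALE else "M"
        min_birth = (
            grp.anchor_birth_year - generation_interval
            if grp.anchor_birth_year is not None
            else None
        )
        out.append(
            HypotheticalParent(
                id=f"{id_prefix}-{tag}-{counters[grp.slot]:03d}",
                sex=sex,
                offspring_ids=grp.offspring_ids,
                haplotype=grp.haplotype,
                min_birth_year_estimate=min_birth,
                anchor_offspring_birth_year=grp.anchor_birth_year,
            )
        )
    return out


class SibshipClusterer(BaseEstimator):
    """Cluster parent-less offspring and emit hypothetical parents.

    ``fit_predict`` consumes the intensive-survey offspring with empty
    mother/father slots and returns the hypothetical parents for both slots.

    Attributes
    ----------
    groups_ : list of SibGroup
    hypothetical_parents_ : list of HypotheticalParent
    """

    def __init__(
        self,
        error_rate: float = 0.01,
        threshold: float = 0.0,
        generation_interval: float = 7.3,
    ):
        self.error_rate = error_rate
        self.threshold = threshold
        self.generation_interval = generation_interval

    def fit_predict(
        self,
        individuals: Sequence[Individual],
        assignments: Sequence[ParentageAssignment],
        freqs: AlleleFrequencyTable,
    ) -> List[HypotheticalParent]:
        a_by_id = {a.offspring_id: a for a in assignments}
        cohort = [
            ind
            for ind in individuals
            if ind.identified_2019_20 and not ind.immigrant and ind.id in a_by_id
        ]
        motherless = [i for i in cohort if a_by_id[i.id].mother_id is None]
        fatherless = [i for i in cohort if a_by_id[i.id].father_id is None]
        self.groups_ = build_sib_groups(
            motherless, a_by_id, freqs, self.error_rate, "mother", self.threshold
        ) + build_sib_groups(
            fatherless, a_by_id, freqs, self.error_rate, "father", self.threshold
        )
        self.hypothetical_parents_ = generate_hypothetical_parents(
            self.groups_, generation_interval=self.generation_interval
        )
        self._flag_compatible_sampled_parents(individuals)
        self._write_back(a_by_id)
        return self.hypothetical_parents_

    def _flag_compatible_sampled_parents(
        self, individuals: Sequence[Individual]
    ) -> None:
        """Flag hypothetical parents a surveyed bear could stand in for.

        If any catalogued individual of the right sex is Mendelian-compatible
        (no exclusions) with every offspring in the group and carries a
        consistent uniparental haplotype, the group's parent may in fact be
        that already-known bear; such hypotheticals must not enter the
        minimum tally (they may still enter the maximum).
        """
        from .genotypes import pair_mismatches

        by_id = {ind.id: ind for ind in individuals}
        for hyp in self.hypothetical_parents_:
            kids = [by_id[o] for o in hyp.offspring_ids if o in by_id]
            # note: other group members stay in the candidate pool — a
            # mother can be mis-clustered as a "sib" of her own cub
            candidates = [
                ind
                for ind in individuals
                if ind.sex is hyp.sex and ind.genotype is not None
            ]

            def explained(kid: Individual) -> bool:
                if kid.genotype is None:
                    return True  # cannot prove anything without a genotype
                khap = (
                    kid.mt_haplotype
                    if hyp.sex is Sex.FEMALE
                    else (kid.y_haplotype if kid.sex is Sex.MALE else None)
                )
                for ind in candidates:
                    if ind.id == kid.id:
                        continue
                    hap = (
                        ind.mt_haplotype if hyp.sex is Sex.FEMALE else ind.y_haplotype
                    )
                    if khap is not None and hap is not None and khap != hap:
                        continue
                    if pair_mismatches(kid.genotype, ind.genotype) == 0:
                        return True
                return False

            unexplained = tuple(k.id for k in kids if not explained(k))
            hyp.unexplained_offspring_ids = unexplained
            hyp.compatible_sampled_parent = len(unexplained) == 0

    def _write_back(self, a_by_id) -> None:
        # write the hypothetical ids back into the assignment table
        for hyp in self.hypothetical_parents_:
            for oid in hyp.offspring_ids:
                assignment = a_by_id[oid]
                if hyp.sex is Sex.FEMALE:
                    assignment.mother_id = hyp.id
                else:
                    assignment.father_id = hyp.id
                if assignment.route == "unassigned":
                    assignment.route = "sibship"
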