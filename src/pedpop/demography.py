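"""Breeding, adult and minimum population estimation from a reconstructed
pedigree.

The estimator classifies every parent that produced offspring identified in
the intensive-survey years into one of a few liveness categories as of a
reference year, then aggregates:

* minimum breeders = confirmed breeders (identified in the survey years)
  plus parents — sampled or hypothetical — that demonstrably produced a cub
  around the reference year;
* maximum breeders = the minimum plus survival-discounted unresampled
  parents and surviving hypothetical parents, on the assumption that the
  breeding population cannot exceed the total number of parents of the
  surveyed cohort;
* adults add individuals with independent evidence of age ≥ 4;
* the minimum population is the deduplicated union of bears identified in
  the reference year, bears whose presence then is implied by the pedigree,
  and bears ≥ 1 year old first identified the following year.

Mortality among unresampled parents is handled by survival discounting
(s^years-unseen), a reproductive-senescence age cap, a limit on coexisting
matrilineal/patrilineal generations, and explicit monitoring overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from sklearn.base import BaseEstimator

from .individuals import AgeEvidence, Individual, Sex
from .parentage import ParentageAssignment
from .sibship import HypotheticalParent


@dataclass
class DemographyConfig:
    reference_year: int = 2019
    adult_age_min: int = 4
    survival_f: float = 0.94
    survival_m: float = 0.89
    senescence_age_f: float = 30.0
    senescence_age_m: float = 28.0
    generation_interval: float = 7.3
    max_matrilineal_generations: int = 4
    max_patrilineal_generations: int = 3
    study_area_km2: float = 1760.0
    forest_area_km2: float = 1378.0

    def __post_init__(self) -> None:
        for name in (
            "adult_age_min", "survival_f", "survival_m", "senescence_age_f",
            "senescence_age_m", "generation_interval",
            "max_matrilineal_generations", "max_patrilineal_generations",
            "study_area_km2", "forest_area_km2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.senescence_age_f <= self.adult_age_min:
            raise ValueError("senescence age must exceed adult age")
        if self.senescence_age_m <= self.adult_age_min:
            raise ValueError("senescence age must exceed adult age")


@dataclass
class Bounds:
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError("min exceeds max")


@dataclass
class ParentCategoryCounts:
    """The bookkeeping inputs of the breeder aggregation, per sex."""

    n_confirmed: int
    n_existing_min: int
    n_hypothetical_min: int
    existing_max_weight: float
    n_hypothetical_max: int


@dataclass
class ParentStatus:
    """Liveness classification of one unresampled or hypothetical parent."""

    id: str
    sex: Sex
    kind: str  # "existing" | "hypothetical"
    liveness: str  # alive | counted-minimum | dead-confirmed | dead-senescence
    #              | dead-generation-limit | dead-monitoring
    weight: float = 0.0
    estimated_age: Optional[float] = None


@dataclass
class PopulationEstimate:
    breeding: Dict[Sex, Bounds]
    adult: Dict[Sex, Bounds]
    minimum_population: Dict[Sex, int]
    age_breakdown: Dict[Sex, Dict[str, int]]
    density_study_area: float
    density_forest: float
    audit: List[dict] = field(default_factory=list)

    @property
    def minimum_population_total(self) -> int:
        return sum(self.minimum_population.values())


AGE_CLASSES = (">=4", "2-3", "1", "0", "unknown")


def survival_weight(last_id_year: int, sex: Sex, config: DemographyConfig) -> float:
    """Fractional-individual weight s^(reference_year − last_id_year)."""
    if last_id_year > config.reference_year:
        raise ValueError("last identification postdates the reference year")
    s = config.survival_f if sex is Sex.FEMALE else config.survival_m
    return s ** (config.reference_year - last_id_year)


def hypothetical_parent_age(
    anchor_offspring_birth_year: int, config: DemographyConfig
) -> float:
    """Minimum age at the reference year from the oldest offspring's birth year."""
    if anchor_offspring_birth_year > config.reference_year + 1:
        raise ValueError("anchor year beyond the sampling horizon")
    return (
        config.reference_year - anchor_offspring_birth_year
        + config.generation_interval
    )


def density(count: float, area_km2: float) -> float:
    """Bears per 100 km² (presentation rounds to one decimal)."""
    return count / area_km2 * 100.0


# ---------------------------------------------------------------------------
# pedigree helpers
# ---------------------------------------------------------------------------


def pedigree_links(
    assignments: Iterable[ParentageAssignment],
) -> Dict[str, Tuple[Optional[str], Optional[str]]]:
    return {a.offspring_id: (a.mother_id, a.father_id) for a in assignments}


def _offspring_of(
    parent_id: str,
    slot: int,
    links: Dict[str, Tuple[Optional[str], Optional[str]]],
) -> List[str]:
    return [o for o, parents in links.items() if parents[slot] == parent_id]


def lineal_descendant_depth(
    parent_id: str,
    slot: int,
    links: Dict[str, Tuple[Optional[str], Optional[str]]],
    living: Set[str],
) -> int:
    """Longest chain of living lineal descendants below a parent.

    ``slot`` 0 follows mother links (matrilineal), 1 follows father links
    (patrilineal).  Only chains of individuals in ``living`` count.
    """
    best = 0
    for child in _offspring_of(parent_id, slot, links):
        if child not in living:
            continue
        best = max(best, 1 + lineal_descendant_depth(child, slot, links, living))
    return best


def classify_breeders(
    individuals: Sequence[Individual],
    assignments: Sequence[ParentageAssignment],
) -> Dict[Sex, Set[str]]:
    """Confirmed breeders: identified 2019–2020 with ≥1 offspring in the pedigree."""
    parents: Set[str] = set()
    for a in assignments:
        if a.mother_id is not None:
            parents.add(a.mother_id)
        if a.father_id is not None:
            parents.add(a.father_id)
    out: Dict[Sex, Set[str]] = {Sex.FEMALE: set(), Sex.MALE: set()}
    for ind in individuals:
        if ind.identified_2019_20 and ind.id in parents and ind.sex in out:
            out[ind.sex].add(ind.id)
    return out


def classify_adults_no_record(
    individuals: Sequence[Individual],
    breeders: Dict[Sex, Set[str]],
    config: DemographyConfig,
) -> Dict[Sex, Set[str]]:
    """Non-breeders identified 2019–2020 with evidence of age ≥ adult_age_min.

    Evidence: a known birth year, first identification ≥4 years before the
    reference year, an upper bound on the birth year from a parent's death
    (parent dead in year d ⇒ born ≤ d+1), or a cementum age at death.
    """
    out: Dict[Sex, Set[str]] = {Sex.FEMALE: set(), Sex.MALE: set()}
    ref = config.reference_year
    for ind in individuals:
        if not ind.identified_2019_20 or ind.sex not in out:
            continue
        if ind.id in breeders.get(ind.sex, ()):
            continue
        min_age = ind.min_age_in(ref)
        from_first_id = (
            ind.first_id_year is not None
            and ref - ind.first_id_year >= config.adult_age_min
        )
        if from_first_id or (
            min_age is not None and min_age >= config.adult_age_min
        ):
            out[ind.sex].add(ind.id)
    return out


# ---------------------------------------------------------------------------
# liveness of unresampled and hypothetical parents
# ---------------------------------------------------------------------------


def _estimated_age(
    ind_birth_year: Optional[int],
    anchor_offspring_birth: Optional[int],
    config: DemographyConfig,
) -> Optional[float]:
    if ind_birth_year is not None:
        return float(config.reference_year - ind_birth_year)
    if anchor_offspring_birth is not None:
        return hypothetical_parent_age(anchor_offspring_birth, config)
    return None


def _minimum_rule_applies(
    sex: Sex,
    offspring: Sequence[Individual],
    config: DemographyConfig,
) -> bool:
    """Did this parent demonstrably produce a cub around the reference year?

    Mothers: a cub born in the reference year, a cub born the following year
    (conceived in the reference year), or a cub born the year before that was
    still alive at age ≥1 in the reference year (mother survives to
    separation).  Fathers: a cub born the year after the reference year
    (mating in the reference year).
    """
    ref = config.reference_year
    for off in offspring:
        if off.birth_year is None:
            continue
        if sex is Sex.FEMALE:
            if off.birth_year in (ref, ref + 1):
                return True
            if off.birth_year == ref - 1:
                seen_alive = ref in off.id_years or (ref + 1) in off.id_years
                died_as_yearling = off.death_year == ref
                if seen_alive or died_as_yearling:
                    return True
        else:
            if off.birth_year == ref + 1:
                return True
    return False


def apply_liveness_rules(
    existing_parents: Sequence[Individual],
    hypotheticals: Sequence[HypotheticalParent],
    assignments: Sequence[ParentageAssignment],
    individuals: Sequence[Individual],
    config: DemographyConfig,
    monitoring_dead: Set[str] = frozenset(),
) -> List[ParentStatus]:
    """Classify each unresampled/hypothetical parent as of the reference year."""
    links = pedigree_links(assignments)
    by_id = {ind.id: ind for ind in individuals}
    ref = config.reference_year
    living = {
        ind.id
        for ind in individuals
        if ind.identified_2019_20 or ind.alive_in(ref) is True
    }

    statuses: List[ParentStatus] = []

    def offspring_records(pid: str, slot: int) -> List[Individual]:
        return [by_id[o] for o in _offspring_of(pid, slot, links) if o in by_id]

    for ind in existing_parents:
        slot = 0 if ind.sex is Sex.FEMALE else 1
        kids = offspring_records(ind.id, slot)
        anchor = min(
            (k.birth_year for k in kids if k.birth_year is not None), default=None
        )
        age = _estimated_age(ind.birth_year, anchor, config)
        senescence = (
            config.senescence_age_f if ind.sex is Sex.FEMALE else config.senescence_age_m
        )
        if ind.death_year is not None and ind.death_year < ref:
            liveness, weight = "dead-confirmed", 0.0
        elif _minimum_rule_applies(ind.sex, kids, config):
            liveness, weight = "counted-minimum", 1.0
        elif ind.id in monitoring_dead:
            liveness, weight = "dead-monitoring", 0.0
        elif age is not None and age >= senescence:
            liveness, weight = "dead-senescence", 0.0
        else:
            liveness = "alive"
            weight = survival_weight(
                ind.last_id_year if ind.last_id_year is not None else ref,
                ind.sex,
                config,
            )
        statuses.append(
            ParentStatus(ind.id, ind.sex, "existing", liveness, weight, age)
        )

    for hyp in hypotheticals:
        slot = 0 if hyp.sex is Sex.FEMALE else 1
        kids = offspring_records(hyp.id, slot)
        age = _estimated_age(None, hyp.anchor_offspring_birth_year, config)
        senescence = (
            config.senescence_age_f if hyp.sex is Sex.FEMALE else config.senescence_age_m
        )
        max_gen = (
            config.max_matrilineal_generations
            if hyp.sex is Sex.FEMALE
            else config.max_patrilineal_generations
        )
        depth = lineal_descendant_depth(hyp.id, slot, links, living)
        # only offspring no catalogued bear could have produced can prove a
        # genuinely new (uncounted) parent for the minimum tally
        unexplained = getattr(hyp, "unexplained_offspring_ids", None)
        if unexplained is None:
            proving_kids = kids
        else:
            proving_kids = [k for k in kids if k.id in unexplained]
        if _minimum_rule_applies(hyp.sex, proving_kids, config):
            liveness, weight = "counted-minimum", 1.0
        elif hyp.id in monitoring_dead:
            liveness, weight = "dead-monitoring", 0.0
        elif age is not None and age >= senescence:
            liveness, weight = "dead-senescence", 0.0
        elif depth >= max_gen:
            liveness, weight = "dead-generation-limit", 0.0
        else:
            liveness, weight = "alive", 1.0
        hyp.liveness = liveness
        statuses.append(
            ParentStatus(hyp.id, hyp.sex, "hypothetical", liveness, weight, age)
        )
    return statuses


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def breeding_bounds_from_counts(counts: ParentCategoryCounts) -> Bounds:
    """The breeder aggregation rule on category counts.

    minimum = confirmed + minimum-counted parents; maximum adds the
    survival-weighted existing parents and surviving hypothetical parents,
    rounding to the nearest integer only after summation.
    """
    mn = counts.n_confirmed + counts.n_existing_min + counts.n_hypothetical_min
    mx = mn + counts.existing_max_weight + counts.n_hypothetical_max
    return Bounds(min=mn, max=int(math.floor(mx + 0.5)))


def parent_category_counts(
    sex: Sex,
    confirmed: Dict[Sex, Set[str]],
    statuses: Sequence[ParentStatus],
) -> ParentCategoryCounts:
    mine = [s for s in statuses if s.sex is sex]
    return ParentCategoryCounts(
        n_confirmed=len(confirmed.get(sex, ())),
        n_existing_min=sum(
            1 for s in mine if s.kind == "existing" and s.liveness == "counted-minimum"
        ),
        n_hypothetical_min=sum(
            1
            for s in mine
            if s.kind == "hypothetical" and s.liveness == "counted-minimum"
        ),
        existing_max_weight=sum(
            s.weight for s in mine if s.kind == "existing" and s.liveness == "alive"
        ),
        n_hypothetical_max=sum(
            1 for s in mine if s.kind == "hypothetical" and s.liveness == "alive"
        ),
    )


def breeding_population_bounds(
    confirmed: Dict[Sex, Set[str]],
    statuses: Sequence[ParentStatus],
) -> Dict[Sex, Bounds]:
    return {
        sex: breeding_bounds_from_counts(
            parent_category_counts(sex, confirmed, statuses)
        )
        for sex in (Sex.FEMALE, Sex.MALE)
    }


def adult_population_bounds(
    breeding: Dict[Sex, Bounds],
    adults_no_record: Dict[Sex, Set[str]],
) -> Dict[Sex, Bounds]:
    return {
        sex: Bounds(
            breeding[sex].min + len(adults_no_record.get(sex, ())),
            breeding[sex].max + len(adults_no_record.get(sex, ())),
        )
        for sex in (Sex.FEMALE, Sex.MALE)
    }


def _age_class(min_age: Optional[int], exact: bool) -> str:
    if min_age is None:
        return "unknown"
    if min_age >= 4:
        return ">=4"
    if min_age >= 2:
        return "2-3"
    if min_age == 1:
        return "1"
    if exact and min_age == 0:
        return "0"
    return "0" if exact else "unknown"


def minimum_population(
    individuals: Sequence[Individual],
    statuses: Sequence[ParentStatus],
    config: DemographyConfig,
) -> Tuple[Dict[Sex, int], Dict[Sex, Dict[str, int]], List[dict]]:
    """Deduplicated count of bears demonstrably present in the reference year.

    Three categories: (1) bears identified in the reference year, including
    those that died during it; (2) parents not identified in the survey years
    whose presence is implied by the minimum rules; (3) bears ≥1 year old
    identified only in the following year (possible cubs-of-the-year are
    excluded).
    """
    ref = config.reference_year
    counts = {Sex.FEMALE: 0, Sex.MALE: 0}
    breakdown = {
        Sex.FEMALE: {c: 0 for c in AGE_CLASSES},
        Sex.MALE: {c: 0 for c in AGE_CLASSES},
    }
    audit: List[dict] = []
    counted: Set[str] = set()

    def add(uid: str, sex: Sex, cls: str, category: str) -> None:
        if uid in counted or sex not in counts:
            return
        counted.add(uid)
        counts[sex] += 1
        breakdown[sex][cls] += 1
        audit.append(
            {"id": uid, "sex": sex.value, "age_class": cls, "category": category}
        )

    for ind in individuals:
        if ref not in ind.id_years:
            continue
        exact = ind.birth_year is not None
        add(ind.id, ind.sex, _age_class(ind.min_age_in(ref), exact), "identified-ref-year")

    for st in statuses:
        if st.liveness == "counted-minimum":
            add(st.id, st.sex, ">=4", f"pedigree-inferred-{st.kind}")

    for ind in individuals:
        if ref in ind.id_years or (ref + 1) not in ind.id_years:
            continue
        if ind.birth_year is not None and ind.birth_year > ref:
            continue  # born after the reference year
        min_age_next = ind.min_age_in(ref + 1)
        has_age_evidence = (
            (min_age_next is not None and min_age_next >= 1)
            or (ind.first_id_year is not None and ind.first_id_year <= ref)
            or ind.age_evidence
            in (AgeEvidence.MONITORING, AgeEvidence.PARENT_DEATH, AgeEvidence.CEMENTUM)
        )
        if not has_age_evidence:
            continue  # could be a cub of the following year
        exact = ind.birth_year is not None
        add(ind.id, ind.sex, _age_class(ind.min_age_in(ref), exact), "identified-next-year")

    return counts, breakdown, audit


# ---------------------------------------------------------------------------
# estimator front end
# ---------------------------------------------------------------------------


class DemographicEstimator(BaseEstimator):
    """Population bounds and minimum census from a reconstructed pedigree.

    ``fit`` consumes the individual catalogue, the parentage assignments
    (real and sibship-derived links) and the hypothetical parents, and
    exposes the estimates as fitted attributes.
    """

    def __init__(
        self,
        config: Optional[DemographyConfig] = None,
        monitoring_dead: Iterable[str] = (),
    ):
        self.config = config
        self.monitoring_dead = monitoring_dead

    def fit(
        self,
        individuals: Sequence[Individual],
        assignments: Sequence[ParentageAssignment],
        hypotheticals: Sequence[HypotheticalParent] = (),
    ) -> "DemographicEstimator":
        cfg = self.config or DemographyConfig()
        self.config_ = cfg
        by_id = {ind.id: ind for ind in individuals}

        self.breeders_ = classify_breeders(individuals, assignments)
        self.adults_no_record_ = classify_adults_no_record(
            individuals, self.breeders_, cfg
        )
        parent_ids = {
            pid
            for a in assignments
            for pid in (a.mother_id, a.father_id)
            if pid is not None
        }
        existing_unresampled = [
            by_id[pid]
            for pid in sorted(parent_ids)
            if pid in by_id and not by_id[pid].identified_2019_20
        ]
        self.parent_statuses_ = apply_liveness_rules(
            existing_unresampled,
            hypotheticals,
            assignments,
            individuals,
            cfg,
            set(self.monitoring_dead),
        )
        self.breeding_bounds_ = breeding_population_bounds(
            self.breeders_, self.parent_statuses_
        )
        self.adult_bounds_ = adult_population_bounds(
            self.breeding_bounds_, self.adults_no_record_
        )
        min_counts, breakdown, audit = minimum_population(
            individuals, self.parent_statuses_, cfg
        )
        total = sum(min_counts.values())
        self.estimate_ = PopulationEstimate(
            breeding=self.breeding_bounds_,
            adult=self.adult_bounds_,
            minimum_population=min_counts,
            age_breakdown=breakdown,
            density_study_area=density(total, cfg.study_area_km2),
            density_forest=density(total, cfg.forest_area_km2),
            audit=audit,
        )
        return self
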