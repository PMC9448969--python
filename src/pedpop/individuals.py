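"""Individuals, field samples, and sample-to-individual matching.

Noninvasively collected samples (hair, feces, ...) are screened on a small
locus subset; a sample failing any screening locus is discarded.  Surviving
samples either match a catalogued individual exactly or found a new one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from sklearn.base import BaseEstimator

from .genotypes import Genotype, LocusPanel


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"
    UNKNOWN = "U"


class AgeEvidence(str, Enum):
    """Provenance of an individual's age or minimum-age assignment."""

    CEMENTUM = "cementum"
    FIRST_ID = "first-identification"
    PARENT_DEATH = "parent-death"
    MONITORING = "monitoring"
    NONE = "none"


class DeathCause(str, Enum):
    MANAGED_KILL = "managed-kill"
    HUNTING = "hunting"
    NATURAL = "natural"
    NONE = "none"


@dataclass
class Individual:
    """A genetically identified animal with its life-history metadata.

    ``birth_year`` is the known birth year when available; ``min_birth_year``
    and ``max_birth_year`` carry bounds derived from evidence (first
    identification, parent death, cementum age at death).
    """

    id: str
    sex: Sex = Sex.UNKNOWN
    genotype: Optional[Genotype] = None
    mt_haplotype: Optional[str] = None
    y_haplotype: Optional[str] = None
    birth_year: Optional[int] = None
    min_birth_year: Optional[int] = None
    max_birth_year: Optional[int] = None
    death_year: Optional[int] = None
    death_cause: DeathCause = DeathCause.NONE
    first_id_year: Optional[int] = None
    last_id_year: Optional[int] = None
    identified_2019_20: bool = False
    id_years: set = field(default_factory=set)
    age_evidence: AgeEvidence = AgeEvidence.NONE
    immigrant: bool = False

    def __post_init__(self) -> None:
        if (
            self.first_id_year is not None
            and self.last_id_year is not None
            and self.first_id_year > self.last_id_year
        ):
            raise ValueError(f"{self.id}: first_id_year > last_id_year")
        if (
            self.death_year is not None
            and self.first_id_year is not None
            and self.death_year < self.first_id_year
        ):
            raise ValueError(f"{self.id}: death_year precedes first_id_year")
        if self.y_haplotype is not None and self.sex is Sex.FEMALE:
            raise ValueError(f"{self.id}: Y haplotype on a female")

    def age_in(self, year: int) -> Optional[int]:
        if self.birth_year is None:
            return None
        return year - self.birth_year

    def min_age_in(self, year: int) -> Optional[int]:
        """Lower bound on age, from the known birth year or its upper bound."""
        if self.birth_year is not None:
            return year - self.birth_year
        if self.max_birth_year is not None:
            return year - self.max_birth_year
        return None

    def alive_in(self, year: int) -> Optional[bool]:
        """True/False when determinable; individuals dying in `year` count alive."""
        if self.birth_year is not None and year < self.birth_year:
            return False
        if self.death_year is not None:
            return year <= self.death_year
        return None


class SampleMethod(str, Enum):
    HAIR = "hair"
    FECES = "feces"
    BIOPSY = "biopsy"
    DEAD_RECOVERY = "dead-recovery"
    OTHER = "other"


@dataclass
class SampleRecord:
    """One field sample: a year, a collection method and a genotype."""

    sample_id: str
    year: int
    method: SampleMethod
    genotype: Genotype
    sex: Sex = Sex.UNKNOWN
    mt_haplotype: Optional[str] = None
    y_haplotype: Optional[str] = None
    cementum_age: Optional[int] = None  # dead recoveries only
    death_cause: DeathCause = DeathCause.NONE
    resolved_individual: Optional[str] = None
    true_source: Optional[str] = None  # simulator ground truth, if any


class MatchOutcome(str, Enum):
    RESOLVED = "resolved"
    NEW_INDIVIDUAL = "new-individual"
    DISCARDED = "discarded"


@dataclass
class MatchResult:
    outcome: MatchOutcome
    individual_id: Optional[str] = None


def match_sample(
    sample: SampleRecord,
    catalogue: Sequence[Individual],
    panel: LocusPanel,
) -> MatchResult:
    """Resolve a sample against the catalogue.

    Screening loci are checked first; a missing screening locus discards the
    sample.  A unique exact screening match resolves immediately.  Ambiguous
    screening matches (shared screening profile) and screening misses fall
    through to full-panel comparison; a full-panel match resolves, otherwise
    the sample founds a new individual.
    """
    screening = panel.screening_subset or panel.loci
    for locus in screening:
        if sample.genotype.is_missing(locus):
            return MatchResult(MatchOutcome.DISCARDED)

    hits = [
        ind
        for ind in catalogue
        if ind.genotype is not None
        and sample.genotype.matches_exactly(ind.genotype, screening)
    ]
    if len(hits) == 1:
        return MatchResult(MatchOutcome.RESOLVED, hits[0].id)

    pool = hits if len(hits) > 1 else list(catalogue)
    for ind in pool:
        if ind.genotype is not None and sample.genotype.consistent_with(
            ind.genotype, panel.loci
        ):
            # require at least the screening information plus no conflicts
            return MatchResult(MatchOutcome.RESOLVED, ind.id)
    return MatchResult(MatchOutcome.NEW_INDIVIDUAL)


class GenotypeMatcher(BaseEstimator):
    """Sequential sample-to-individual matcher building a catalogue.

    ``fit`` seeds the catalogue (possibly empty); ``predict`` resolves a
    stream of samples in order, creating new individuals as needed and
    accumulating per-individual metadata (first/last identification years,
    haplotypes, death information from recovered carcasses).

    Attributes
    ----------
    individuals_ : list of Individual
        The catalogue after prediction.
    results_ : list of MatchResult
        One outcome per input sample, aligned with the input order.
    """

    def __init__(self, panel: Optional[LocusPanel] = None, id_prefix: str = "IND"):
        self.panel = panel
        self.id_prefix = id_prefix

    def fit(self, catalogue: Iterable[Individual] = (), y=None) -> "GenotypeMatcher":
        if self.panel is None:
            raise ValueError("panel is required")
        self.individuals_ = list(catalogue)
        self._by_id = {ind.id: ind for ind in self.individuals_}
        if len(self._by_id) != len(self.individuals_):
            raise ValueError("duplicate individual ids in catalogue")
        self.results_ = []
        self._counter = len(self.individuals_)
        return self

    def predict(self, samples: Sequence[SampleRecord]) -> List[MatchResult]:
        if not hasattr(self, "individuals_"):
            raise RuntimeError("call fit before predict")
        ordered = sorted(range(len(samples)), key=lambda i: samples[i].year)
        results: List[Optional[MatchResult]] = [None] * len(samples)
        for idx in ordered:
            sample = samples[idx]
            res = match_sample(sample, self.individuals_, self.panel)
            if res.outcome is MatchOutcome.NEW_INDIVIDUAL:
                ind = self._found_individual(sample)
                res = MatchResult(MatchOutcome.RESOLVED, ind.id)
            if res.outcome is MatchOutcome.RESOLVED:
                sample.resolved_individual = res.individual_id
                self._update_metadata(self._by_id[res.individual_id], sample)
            results[idx] = res
        self.results_ = list(results)
        return self.results_

    # -- internals ---------------------------------------------------------

    def _found_individual(self, sample: SampleRecord) -> Individual:
        self._counter += 1
        ind = Individual(
            id=f"{self.id_prefix}-{self._counter:04d}",
            sex=sample.sex,
            genotype=sample.genotype,
            mt_haplotype=sample.mt_haplotype,
            y_haplotype=sample.y_haplotype if sample.sex is Sex.MALE else None,
        )
        self.individuals_.append(ind)
        self._by_id[ind.id] = ind
        return ind

    def _update_metadata(self, ind: Individual, sample: SampleRecord) -> None:
        if ind.first_id_year is None or sample.year < ind.first_id_year:
            ind.first_id_year = sample.year
        if ind.last_id_year is None or sample.year > ind.last_id_year:
            ind.last_id_year = sample.year
        ind.id_years.add(sample.year)
        if sample.year in (2019, 2020):
            ind.identified_2019_20 = True
        if ind.sex is Sex.UNKNOWN:
            ind.sex = sample.sex
        if ind.mt_haplotype is None:
            ind.mt_haplotype = sample.mt_haplotype
        if ind.y_haplotype is None and ind.sex is Sex.MALE:
            ind.y_haplotype = sample.y_haplotype
        # fill loci missing from the current consensus; explicit overwrite only
        if ind.genotype is None:
            ind.genotype = sample.genotype
        else:
            merged = dict(ind.genotype.calls)
            for locus, pair in sample.genotype.calls.items():
                if merged.get(locus) is None and pair is not None:
                    merged[locus] = pair
            ind.genotype = Genotype(merged)
        if sample.method is SampleMethod.DEAD_RECOVERY:
            ind.death_year = sample.year
            ind.death_cause = sample.death_cause
            if sample.cementum_age is not None:
                ind.birth_year = sample.year - sample.cementum_age
                ind.age_evidence = AgeEvidence.CEMENTUM


def identify_individuals(
    samples: Sequence[SampleRecord], panel: LocusPanel
) -> Tuple[List[Individual], List[MatchResult]]:
    """Convenience wrapper: run :class:`GenotypeMatcher` on a sample stream."""
    matcher = GenotypeMatcher(panel=panel).fit([])
    results = matcher.predict(samples)
    return matcher.individuals_, results


def flag_immigrant_males(individuals: Sequence[Individual]) -> None:
    """Mark males whose mtDNA haplotype no sampled female carries.

    A maternal lineage absent from every sampled female cannot have a resident
    mother, so such males are treated as immigrants: excluded as candidate
    offspring but retained as candidate fathers.
    """
    female_haps = {
        ind.mt_haplotype
        for ind in individuals
        if ind.sex is Sex.FEMALE and ind.mt_haplotype is not None
    }
    for ind in individuals:
        if (
            ind.sex is Sex.MALE
            and ind.mt_haplotype is not None
            and ind.mt_haplotype not in female_haps
        ):
            ind.immigrant = True
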